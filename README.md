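# palmflow

Landscape-genetics toolkit for codominant microsatellite data: spatial
genetic structure from pairwise kinship, likelihood-based parentage
assignment, and forest-cover statistics with Monte Carlo randomization
tests — plus a synthetic-data generator with a ground-truth pedigree ledger
for recovery testing.

## What it does

- **`palmflow.genodata`** — data model (loci, atomic diploid genotype
  calls, staged/georeferenced individuals, sites with a forest-cover
  covariate), I/O in a long CSV dialect and GenePop (2/3-digit coding),
  site tables, minimum-count site filtering, and allele-frequency
  estimation against a stated reference set.
- **`palmflow.synthetic_data`** — seeded generator: sites on a cover
  gradient, adults in 15 × 400 m plots with seedlings in nested 2 × 400 m
  subplots, Mendelian inheritance with per-locus mistyping, local pollen,
  and a log-normal seed-dispersal kernel whose median distance is
  `exp(a + b·cover)`; emits a `TruthLedger` of true parents and realized
  dispersal distances.
- **`palmflow.kinship_sgs`** — Loiselle et al. (1995) pairwise kinship with
  the finite-sample correction, distance-class profiles (default eight
  50 m classes, 0–400 m) with 2.5/97.5% location-permutation envelopes,
  stage comparison t-test, and kinship-vs-cover regression.
- **`palmflow.parentage`** — single-parent (unknown-sex) LOD scores with a
  mistyping blend, the Δ statistic (best minus second-best LOD),
  simulation-derived critical Δ at a confidence level, Mendelian exclusion
  counts, and per-locus paternity index / combined index / paternity
  probability under a flat prior.
- **`palmflow.landscape_stats`** — binomial GLMs (presence and
  events/trials forms, Wald z tests, separation detection), deviance and
  R² randomization tests (4999 draws + the observed arrangement, inclusive
  ties), a random-intercept LMM on log gene-flow distance, and
  study-table-style assignment summaries.
- **`palmflow.pipeline` / `palmflow.cli`** — orchestration with per-stage
  seed fan-out, CSV outputs and a JSON run manifest.
- **`palmflow.tables`** — the published per-site count table and
  cross-landscape gene-flow records, packaged as CSV fixtures.

## CLI

```sh
# simulate a dataset + truth ledger
palmflow simulate --config sim.yaml --seed 5 --out results/sim

# SGS profiles per site and stage
palmflow sgs --genotypes results/sim/genotypes.csv \
             --sites results/sim/sites.csv --n-perm 10000 --seed 1 \
             --out results/sgs

# parentage assignment
palmflow parentage --genotypes results/sim/genotypes.csv \
                   --sites results/sim/sites.csv --n-sim 10000 \
                   --error-rate 0.01 --seed 2 --out results/parentage

# GLM + Monte Carlo battery on a per-site count table
palmflow landstats --counts counts.csv --n-rand 4999 --seed 42 \
                   --out results/landstats

# everything, driven by a YAML config
palmflow all --config pipeline.yaml --out results/run
```

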