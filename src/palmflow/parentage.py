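"""Single-parent (unknown-sex) likelihood assignment with simulated critical
values, Mendelian exclusion, and paternity-index probabilities.

Per locus scored in both individuals the LOD contribution is

    LOD_l = ln( T*(g_o | g_c) / P(g_o) )

with T the single-parent transmission probability (the candidate transmits
one allele, the other parent's allele is drawn from the population
frequencies), P the Hardy-Weinberg genotype probability, and the mistyping
blend ``T* = (1-e)^2 T + (1 - (1-e)^2) P(g_o)``. An excluding locus at e = 0
drives the contribution to the configurable floor. The assignment statistic
is delta = LOD(best) - LOD(second best) among candidates with positive LOD
(delta = LOD(best) when only one is positive); the critical delta comes from
simulated parentage tests at a stated confidence level.

The paternity index per locus is PI = X / Y (candidate vs random-individual
probability of transmitting a compatible allele), combined multiplicatively
across loci, and converted to a paternity probability under a flat prior:
PP = CPI * prior / (CPI * prior + 1 - prior).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import (
    MISSING,
    AlleleFreqTable,
    Genotype,
    StudyDataset,
    allele_frequencies,
)

__all__ = [
    "LOD_FLOOR",
    "ParentageAssignment",
    "CriticalDelta",
    "lod_single_parent",
    "delta_statistic",
    "simulate_critical_delta",
    "assign_parents",
    "exclusion_mismatches",
    "paternity_index",
    "combined_pi",
    "paternity_probability",
    "assignments_to_dataframe",
]

#: Per-locus floor for ln-likelihood ratios (an exclusion at e = 0).
LOD_FLOOR = -37.0


@dataclass
class ParentageAssignment:
    offspring_id: str
    parent_id: str | None
    lod: float | None
    delta: float | None
    confidence: str                     # "strict95" | "unassigned"
    mismatches: int | None
    pi_per_locus: dict[str, float] | None
    cpi: float | None
    pp: float | None
    geneflow_distance: float | None     # meters
    same_site: bool | None


@dataclass
class CriticalDelta:
    delta_crit: float
    confidence_level: float
    n_simulations: int
    n_candidates: int
    prop_sampled: float
    error_rate: float
    seed: int | None


# ---------------------------------------------------------------------------
# Scalar likelihood machinery
# ---------------------------------------------------------------------------

def _hw_prob(go: tuple[int, int], p: dict[int, float]) -> float:
    a, b = go
    return p[a] * p[a] if a == b else 2.0 * p[a] * p[b]


def _transmission_prob(go: tuple[int, int], gc: tuple[int, int],
                       p: dict[int, float]) -> float:
    """P(offspring genotype | candidate is a parent), other allele from p."""
    a, b = go
    c, d = gc
    # candidate transmits c or d with probability 1/2 each
    t = {}
    t[c] = t.get(c, 0.0) + 0.5
    t[d] = t.get(d, 0.0) + 0.5
    if a == b:
        return t.get(a, 0.0) * p[a]
    return t.get(a, 0.0) * p[b] + t.get(b, 0.0) * p[a]


def _locus_lod(go, gc, p, error_rate: float, floor: float) -> float:
    P = _hw_prob(go, p)
    T = _transmission_prob(go, gc, p)
    keep = (1.0 - error_rate) ** 2
    T_star = keep * T + (1.0 - keep) * P
    if T_star <= 0.0 or P <= 0.0:
        return floor
    return max(math.log(T_star / P), floor)


def lod_single_parent(offspring: Genotype, candidate: Genotype,
                      freqs: AlleleFreqTable, error_rate: float = 0.01,
                      lod_floor: float = LOD_FLOOR) -> float:
    """Total LOD that ``candidate`` is a parent of ``offspring``.

    Loci missing in either individual contribute 0. Alleles absent from
    ``freqs`` raise ``KeyError``.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")
    total = 0.0
    for locus in freqs.loci:
        go = offspring.get(locus)
        gc = candidate.get(locus)
        if go is None or gc is None or go[0] == MISSING or gc[0] == MISSING:
            continue
        p = freqs.table(locus)
        for a in set(go) | set(gc):
            if a not in p:
                raise KeyError(
                    f"allele {a} at locus {locus!r} absent from frequencies"
                )
        total += _locus_lod(go, gc, p, error_rate, lod_floor)
    return total


def delta_statistic(lods) -> float | None:
    """Delta over candidate LODs; ``None`` when no candidate has LOD > 0."""
    lods = np.asarray(list(lods), dtype=float)
    pos = lods[lods > 0]
    if pos.size == 0:
        return None
    if pos.size == 1:
        return float(pos[0])
    top = np.sort(pos)[-2:]
    return float(top[1] - top[0])


def exclusion_mismatches(offspring: Genotype, candidate: Genotype) -> int:
    """Number of loci scored in both where the pair shares no allele."""
    count = 0
    for locus, go in offspring.items():
        gc = candidate.get(locus)
        if gc is None or go[0] == MISSING or gc[0] == MISSING:
            continue
        if not set(go) & set(gc):
            count += 1
    return count


# ---------------------------------------------------------------------------
# Paternity index / probability
# ---------------------------------------------------------------------------

def paternity_index(offspring: Genotype, candidate: Genotype,
                    freqs: AlleleFreqTable,
                    error_rate: float = 0.0) -> dict[str, float]:
    """Per-locus PI = X/Y over loci scored in both individuals.

    X is the probability the candidate transmits an allele compatible with
    the offspring genotype; Y the probability a random individual drawn from
    ``freqs`` does. Under nonzero ``error_rate`` X is blended toward Y
    (``X* = (1-e) X + e Y``) so an excluding locus yields PI = e rather
    than 0, keeping the combined index positive.
    """
    pis: dict[str, float] = {}
    for locus in freqs.loci:
        go = offspring.get(locus)
        gc = candidate.get(locus)
        if go is None or gc is None or go[0] == MISSING or gc[0] == MISSING:
            continue
        compatible = set(go)
        X = sum(0.5 for a in gc if a in compatible)
        Y = sum(freqs.freq(locus, a) for a in compatible)
        if Y <= 0.0:
            raise ValueError(f"locus {locus!r}: offspring alleles have zero "
                             "population frequency")
        X_star = (1.0 - error_rate) * X + error_rate * Y
        pis[locus] = X_star / Y
    return pis


def combined_pi(pi_per_locus: dict[str, float]) -> float:
    """Product of per-locus paternity indices."""
    cpi = 1.0
    for v in pi_per_locus.values():
        cpi *= v
    return cpi


def paternity_probability(cpi: float, prior: float = 0.5) -> float:
    """Posterior parentage probability from the combined index and a prior."""
    if cpi <= 0.0:
        raise ValueError("combined paternity index must be positive")
    if not 0.0 < prior < 1.0:
        raise ValueError("prior must lie in (0, 1)")
    return cpi * prior / (cpi * prior + (1.0 - prior))


# ---------------------------------------------------------------------------
# Vectorized LOD engine (lookup tables over the per-locus genotype space)
# ---------------------------------------------------------------------------

class _LodTables:
    """Per-locus LOD lookup tables indexed by genotype: O(G^2) scalar
    evaluations once, then O(1) per comparison. Index G (= n_genotypes)
    encodes a missing call and contributes 0."""

    def __init__(self, freqs: AlleleFreqTable, error_rate: float,
                 lod_floor: float = LOD_FLOOR):
        self.freqs = freqs
        self.error_rate = error_rate
        self.loci = list(freqs.loci)
        self.genotypes: dict[str, list[tuple[int, int]]] = {}
        self.geno_index: dict[str, dict[tuple[int, int], int]] = {}
        self.tables: dict[str, np.ndarray] = {}
        for locus in self.loci:
            alleles = sorted(freqs.alleles(locus))
            genos = [(alleles[i], alleles[j])
                     for i in range(len(alleles))
                     for j in range(i, len(alleles))]
            p = freqs.table(locus)
            G = len(genos)
            tab = np.zeros((G + 1, G + 1))
            for i, go in enumerate(genos):
                for j, gc in enumerate(genos):
                    tab[i, j] = _locus_lod(go, gc, p, error_rate, lod_floor)
            self.genotypes[locus] = genos
            self.geno_index[locus] = {g: k for k, g in enumerate(genos)}
            self.tables[locus] = tab

    def encode(self, genotype: Genotype) -> np.ndarray:
        """Vector of per-locus genotype indices (missing -> G)."""
        idx = np.empty(len(self.loci), dtype=np.int64)
        for k, locus in enumerate(self.loci):
            pair = genotype.get(locus)
            if pair is None or pair[0] == MISSING:
                idx[k] = len(self.genotypes[locus])
            else:
                key = (min(pair), max(pair))
                try:
                    idx[k] = self.geno_index[locus][key]
                except KeyError:
                    raise KeyError(
                        f"allele(s) {pair} at locus {locus!r} absent from "
                        "frequencies"
                    ) from None
        return idx

    def lod_matrix(self, off_idx: np.ndarray, cand_idx: np.ndarray) -> np.ndarray:
        """LOD totals, shape (n_offspring, n_candidates)."""
        n_off, n_cand = off_idx.shape[0], cand_idx.shape[0]
        out = np.zeros((n_off, n_cand))
        for k, locus in enumerate(self.loci):
            out += self.tables[locus][np.ix_(off_idx[:, k], cand_idx[:, k])]
        return out


# ---------------------------------------------------------------------------
# Critical-delta simulation
# ---------------------------------------------------------------------------

def _draw_genotype_indices(rng, tables: _LodTables, n: int) -> np.ndarray:
    """n Hardy-Weinberg genotype index vectors (one column per locus)."""
    out = np.empty((n, len(tables.loci)), dtype=np.int64)
    for k, locus in enumerate(tables.loci):
        genos = tables.genotypes[locus]
        p = tables.freqs.table(locus)
        probs = np.array([_hw_prob(g, p) for g in genos])
        probs = probs / probs.sum()
        out[:, k] = rng.choice(len(genos), size=n, p=probs)
    return out


def simulate_critical_delta(freqs: AlleleFreqTable, n_candidates: int,
                            prop_sampled: float = 0.5,
                            error_rate: float = 0.01,
                            n_sim: int = 10000,
                            confidence: float = 0.95,
                            seed: int | None = None) -> CriticalDelta:
    """Critical delta from simulated parentage tests.

    Each simulated offspring receives one allele from a true parent drawn
    from ``freqs`` and one from the population, with per-locus mistyping at
    ``error_rate``; it is scored against ``n_candidates`` candidates of
    which the true parent is present with probability ``prop_sampled`` (an
    unrelated individual replaces it otherwise). ``delta_crit`` is the
    smallest threshold such that among simulated tests with delta above it
    the proportion in which the best candidate is the true parent reaches
    ``confidence``; +inf (with a warning) when no threshold does.
    """
    if n_candidates < 2:
        raise ValueError("need at least 2 candidate parents")
    rng = np.random.default_rng(seed)
    tables = _LodTables(freqs, error_rate)
    n_loci = len(tables.loci)

    parent_idx = _draw_genotype_indices(rng, tables, n_sim)
    unrelated = _draw_genotype_indices(rng, tables, n_sim * n_candidates)
    cand_idx = unrelated.reshape(n_sim, n_candidates, n_loci)
    included = rng.random(n_sim) < prop_sampled
    cand_idx[included, 0, :] = parent_idx[included]

    # offspring: one allele from the parent, one from the population,
    # whole-call mistyping with probability error_rate per locus
    off_idx = np.empty((n_sim, n_loci), dtype=np.int64)
    for k, locus in enumerate(tables.loci):
        genos = tables.genotypes[locus]
        alleles = sorted(freqs.alleles(locus))
        p = np.array([freqs.freq(locus, a) for a in alleles])
        geno_arr = np.array(genos)                       # (G, 2)
        index = tables.geno_index[locus]
        par = geno_arr[parent_idx[:, k]]                 # (n_sim, 2)
        transmitted = par[np.arange(n_sim), rng.integers(2, size=n_sim)]
        other = np.array(alleles)[rng.choice(len(alleles), size=n_sim, p=p)]
        err = rng.random(n_sim) < error_rate
        # random replacement genotypes for mistyped calls
        probs = np.array([_hw_prob(g, freqs.table(locus)) for g in genos])
        probs = probs / probs.sum()
        rand_geno = rng.choice(len(genos), size=n_sim, p=probs)
        for i in range(n_sim):
            if err[i]:
                off_idx[i, k] = rand_geno[i]
            else:
                a, b = int(transmitted[i]), int(other[i])
                off_idx[i, k] = index[(a, b) if a <= b else (b, a)]

    lods = np.zeros((n_sim, n_candidates))
    for k, locus in enumerate(tables.loci):
        tab = tables.tables[locus]
        lods += tab[off_idx[:, k][:, None], cand_idx[:, :, k]]

    deltas = np.full(n_sim, np.nan)
    correct = np.zeros(n_sim, dtype=bool)
    for i in range(n_sim):
        d = delta_statistic(lods[i])
        if d is None:
            continue
        deltas[i] = d
        best = int(np.argmax(lods[i]))
        # ties for best leave delta = 0 and count as incorrect
        n_best = int(np.sum(lods[i] == lods[i, best]))
        correct[i] = included[i] and best == 0 and n_best == 1

    crit = _smallest_threshold(deltas, correct, confidence)
    if not math.isfinite(crit):
        warnings.warn("no delta threshold reaches the requested confidence",
                      stacklevel=2)
    return CriticalDelta(
        delta_crit=crit, confidence_level=confidence, n_simulations=n_sim,
        n_candidates=n_candidates, prop_sampled=prop_sampled,
        error_rate=error_rate,
        seed=seed,
    )


def _smallest_threshold(deltas: np.ndarray, correct: np.ndarray,
                        confidence: float) -> float:
    """Smallest t >= 0 with P(correct | delta > t) >= confidence."""
    if confidence <= 0.0:
        return 0.0
    ok = ~np.isnan(deltas)
    deltas, correct = deltas[ok], correct[ok]
    if deltas.size == 0:
        return math.inf
    order = np.argsort(-deltas)
    d_sorted = deltas[order]
    c_sorted = correct[order]
    cum_correct = np.cumsum(c_sorted)
    counts = np.arange(1, d_sorted.size + 1)
    rates = cum_correct / counts
    # candidate thresholds: just below each distinct delta value, and 0.
    # tests with delta > t for t = d_sorted[i] - eps are exactly the prefix
    # ending at the last occurrence of d_sorted[i].
    best = math.inf
    i = 0
    while i < d_sorted.size:
        j = i
        while j + 1 < d_sorted.size and d_sorted[j + 1] == d_sorted[i]:
            j += 1
        if rates[j] >= confidence:
            # all tests with delta >= d_sorted[i] are correct often enough:
            # the next-lower distinct delta (or 0) is an admissible threshold
            thresh = d_sorted[j + 1] if j + 1 < d_sorted.size else 0.0
            best = min(best, max(thresh, 0.0))
        i = j + 1
    return best


# ---------------------------------------------------------------------------
# Assignment against a dataset
# ---------------------------------------------------------------------------

def assign_parents(ds: StudyDataset, crit: CriticalDelta,
                   freqs: AlleleFreqTable | None = None,
                   prior: float = 0.5) -> list[ParentageAssignment]:
    """Score every seedling against every adult and assign by delta.

    A parent is called when delta exceeds ``crit.delta_crit`` (confidence
    ``strict95``); unassigned seedlings carry ``parent_id=None`` but retain
    the best candidate's LOD and delta when one exists. Gene-flow distance
    is individual-to-individual within a site and site-centroid distance
    across sites.
    """
    if freqs is None:
        freqs = allele_frequencies(ds, "all_adults")
    adults = ds.adults()
    seedlings = ds.seedlings()
    site_map = ds.site_map()
    out: list[ParentageAssignment] = []
    if not adults:
        return [
            ParentageAssignment(
                offspring_id=s.id, parent_id=None, lod=None, delta=None,
                confidence="unassigned", mismatches=None, pi_per_locus=None,
                cpi=None, pp=None, geneflow_distance=None, same_site=None)
            for s in seedlings
        ]
    tables = _LodTables(freqs, crit.error_rate)
    adult_idx = np.vstack([tables.encode(a.genotype) for a in adults])
    seed_idx = np.vstack([tables.encode(s.genotype) for s in seedlings])
    lods = tables.lod_matrix(seed_idx, adult_idx)

    for i, s in enumerate(seedlings):
        row = lods[i]
        delta = delta_statistic(row)
        if delta is None:
            out.append(ParentageAssignment(
                offspring_id=s.id, parent_id=None, lod=None, delta=None,
                confidence="unassigned", mismatches=None, pi_per_locus=None,
                cpi=None, pp=None, geneflow_distance=None, same_site=None))
            continue
        best = int(np.argmax(row))
        n_best = int(np.sum(row == row[best]))
        parent = adults[best]
        assigned = (delta > crit.delta_crit) and n_best == 1
        mism = exclusion_mismatches(s.genotype, parent.genotype)
        pis = paternity_index(s.genotype, parent.genotype, freqs,
                              error_rate=crit.error_rate)
        cpi = combined_pi(pis)
        pp = paternity_probability(cpi, prior=prior) if cpi > 0 else None
        same_site = parent.site_id == s.site_id
        if same_site:
            dist = math.hypot(parent.x - s.x, parent.y - s.y)
        else:
            ps, ss_ = site_map[parent.site_id], site_map[s.site_id]
            dist = math.hypot(ps.centroid_x - ss_.centroid_x,
                              ps.centroid_y - ss_.centroid_y)
        out.append(ParentageAssignment(
            offspring_id=s.id,
            parent_id=parent.id if assigned else None,
            lod=float(row[best]), delta=float(delta),
            confidence="strict95" if assigned else "unassigned",
            mismatches=mism if assigned else None,
            pi_per_locus=pis if assigned else None,
            cpi=cpi if assigned else None,
            pp=pp if assigned else None,
            geneflow_distance=dist if assigned else None,
            same_site=same_site if assigned else None))
    return out


def assignments_to_dataframe(assignments: list[ParentageAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        rows.append({
            "offspring_id": a.offspring_id,
            "parent_id": a.parent_id if a.parent_id is not None else "",
            "lod": a.lod, "delta": a.delta, "confidence": a.confidence,
            "mismatches": a.mismatches, "cpi": a.cpi, "pp": a.pp,
            "distance_m": a.geneflow_distance,
            "same_site": a.same_site,
        })
    return pd.DataFrame(rows, columns=[
        "offspring_id", "parent_id", "lod", "delta", "confidence",
        "mismatches", "cpi", "pp", "distance_m", "same_site"])
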