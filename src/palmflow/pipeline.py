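"""End-to-end orchestration: simulate -> SGS -> parentage -> landscape stats.

A single top-level seed fans out to per-stage seeds through a fixed
``numpy.random.SeedSequence`` derivation, so each stochastic stage
(location permutations, critical-delta simulation, randomization tests) is
independently reproducible and the whole run is byte-deterministic for a
given config. A JSON manifest records the config, derived seeds and library
versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genodata import (
    StudyDataset,
    allele_frequencies,
    filter_sites_min_count,
    load_dataset,
    save_genotypes,
    save_site_table,
)
from .kinship_sgs import (
    DistanceClassSpec,
    sgs_by_population,
    sgs_vs_cover_regression,
    stage_mean_sgs_ttest,
)
from .landscape_stats import landscape_battery, lmm_log_distance, summarize_assignments
from .parentage import assign_parents, assignments_to_dataframe, simulate_critical_delta
from .synthetic_data import SimulationConfig, simulate_dataset

logger = logging.getLogger("palmflow")

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("simulate", "sgs", "parentage", "landstats")


@dataclass
class PipelineConfig:
    """All analysis constants, defaulting to the study's printed settings."""

    simulation: SimulationConfig | None = None
    genotypes_path: str | None = None
    sites_path: str | None = None
    dialect: str = "csv"
    run_sgs: bool = True
    run_parentage: bool = True
    run_landstats: bool = True
    n_perm: int = 10000
    n_rand: int = 4999
    n_sim: int = 10000
    error_rate: float = 0.01
    prior: float = 0.5
    min_per_stage: int = 5
    n_distance_classes: int = 8
    class_width_m: float = 50.0
    prop_sampled: float = 0.5
    confidence: float = 0.95
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            if "covers" in sim:
                sim["covers"] = tuple(sim["covers"])
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage_seed(root_seed: int, stage: str) -> int:
    """Fixed per-stage derivation from the top-level seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run the configured stages, writing result CSVs and a manifest.

    Returns a dict of in-memory results keyed by stage. Any stage error
    aborts with the stage name; partial outputs written so far remain.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "setup"
    try:
        # -- data ------------------------------------------------------------
        stage = "simulate"
        if cfg.simulation is not None:
            sim_cfg = dataclasses.replace(
                cfg.simulation, seed=_stage_seed(cfg.seed, "simulate"))
            ds, ledger = simulate_dataset(sim_cfg)
            ledger.write_csv(out / "truth_ledger.csv")
        elif cfg.genotypes_path and cfg.sites_path:
            ds = load_dataset(cfg.genotypes_path, cfg.sites_path, cfg.dialect)
            ledger = None
        else:
            raise ValueError("config needs a simulation block or input paths")
        dropped: list[str] = []
        ds = filter_sites_min_count(ds, cfg.min_per_stage, log=dropped)
        if dropped:
            logger.info("dropped under-sampled sites: %s", dropped)
        save_genotypes(ds, out / "genotypes.csv", dialect="csv")
        save_site_table(ds.sites, out / "sites.csv")
        results["dataset"] = ds

        spec = DistanceClassSpec(cfg.n_distance_classes, cfg.class_width_m)

        # -- spatial genetic structure --------------------------------------
        if cfg.run_sgs:
            stage = "sgs"
            prof = sgs_by_population(ds, spec=spec, n_perm=cfg.n_perm,
                                     seed=_stage_seed(cfg.seed, "sgs"))
            prof.to_csv(out / "sgs_profiles.csv", index=False)
            summary = _sgs_summary(ds, prof)
            summary.to_csv(out / "sgs_summary.csv", index=False)
            results["sgs"] = prof
            results["sgs_summary"] = summary

        # -- parentage -------------------------------------------------------
        assignments = None
        if cfg.run_parentage:
            stage = "parentage"
            freqs = allele_frequencies(ds, "all_adults")
            n_cand = max(len(ds.adults()), 2)
            crit = simulate_critical_delta(
                freqs, n_candidates=n_cand, prop_sampled=cfg.prop_sampled,
                error_rate=cfg.error_rate, n_sim=cfg.n_sim,
                confidence=cfg.confidence,
                seed=_stage_seed(cfg.seed, "parentage"))
            assignments = assign_parents(ds, crit, freqs=freqs,
                                         prior=cfg.prior)
            adf = assignments_to_dataframe(assignments)
            adf.to_csv(out / "assignments.csv", index=False)
            results["critical_delta"] = crit
            results["assignments"] = assignments

        # -- landscape statistics -------------------------------------------
        if cfg.run_landstats and assignments is not None:
            stage = "landstats"
            counts, crossings, percent = summarize_assignments(assignments, ds)
            counts.to_csv(out / "site_counts.csv", index=False)
            crossings.to_csv(out / "geneflow_records.csv", index=False)
            battery = landscape_battery(
                counts, n_rand=cfg.n_rand,
                seed=_stage_seed(cfg.seed, "landstats"))
            battery.to_csv(out / "landstats.csv", index=False)
            results["site_counts"] = counts
            results["geneflow_records"] = crossings
            results["percent_assigned"] = percent
            results["landstats"] = battery
            lmm = _maybe_lmm(assignments, ds)
            if lmm is not None:
                pd.DataFrame([dataclasses.asdict(lmm)]).to_csv(
                    out / "lmm_log_distance.csv", index=False)
                results["lmm"] = lmm
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "palmflow_version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {s: _stage_seed(cfg.seed, s) for s in _STAGES},
        "config": _jsonable(cfg.to_dict()),
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    results["manifest"] = manifest
    return results


def _sgs_summary(ds: StudyDataset, profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-population mean kinship plus the stage t-test and cover slopes."""
    pop = (profiles.groupby(["site_id", "stage"], as_index=False)
           ["overall_mean_fij"].first())
    cover = {s.site_id: s.forest_cover for s in ds.sites}
    pop["forest_cover"] = pop["site_id"].map(cover)
    rows = [pop]
    seed_means = pop.loc[pop.stage == "seedling", "overall_mean_fij"]
    adult_means = pop.loc[pop.stage == "adult", "overall_mean_fij"]
    extra = []
    if len(seed_means) >= 2 and len(adult_means) >= 2:
        try:
            t, p = stage_mean_sgs_ttest(seed_means, adult_means)
            extra.append({"site_id": "_ttest_stage", "stage": "both",
                          "overall_mean_fij": t, "forest_cover": p})
        except ValueError:
            pass
    for stage_name, means in (("seedling", seed_means), ("adult", adult_means)):
        sub = pop[pop.stage == stage_name]
        if len(sub) >= 3 and sub["forest_cover"].nunique() > 1:
            slope, r2, p = sgs_vs_cover_regression(
                sub["overall_mean_fij"], sub["forest_cover"])
            extra.append({"site_id": f"_regression_{stage_name}",
                          "stage": stage_name, "overall_mean_fij": r2,
                          "forest_cover": p})
    if extra:
        rows.append(pd.DataFrame(extra))
    return pd.concat(rows, ignore_index=True)


def _maybe_lmm(assignments, ds):
    rows = [(a.geneflow_distance, a.offspring_id) for a in assignments
            if a.parent_id is not None and a.geneflow_distance
            and a.geneflow_distance > 0]
    if len(rows) < 3:
        return None
    ind_site = {i.id: i.site_id for i in ds.individuals}
    cover = {s.site_id: s.forest_cover for s in ds.sites}
    sites = [ind_site[oid] for _, oid in rows]
    if len(set(sites)) < 2:
        return None
    dists = [d for d, _ in rows]
    covers = [cover[s] for s in sites]
    return lmm_log_distance(dists, covers, sites)


def _versions() -> dict:
    import scipy
    import statsmodels
    return {
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
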