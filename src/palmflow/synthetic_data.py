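"""Synthetic dataset generator with a ground-truth pedigree ledger.

Produces datasets with the statistical structure the analysis layer assumes:
sites on a forest-cover gradient, adults censused in a 15 x 400 m plot with
seedlings in a nested 2 x 400 m subplot, Mendelian inheritance with per-locus
mistyping, and a log-normal seed-dispersal kernel whose median distance is a
log-linear function of forest cover (``median_d = exp(a + b * cover)``).

Pollen stays local (fathers drawn from the mother's site with weight
``exp(-d / lambda_pollen)``); rare long kernel draws become cross-site
dispersal events, so long-distance parentage is seed-mediated. Parents not
placed inside a sampled plot ("ghosts") carry genotypes drawn from the
founder frequencies and generate the unassigned background.

All defaults are generator choices exposed in :class:`SimulationConfig`,
not biological claims.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genodata import (
    MISSING,
    Genotype,
    IndividualRecord,
    LocusDef,
    SiteRecord,
    Stage,
    StudyDataset,
    ValidationError,
)

__all__ = [
    "DEFAULT_COVERS",
    "SimulationConfig",
    "LedgerEntry",
    "TruthLedger",
    "simulate_dataset",
    "ledger_summary",
]

#: The nine-site cover gradient used as the default landscape.
DEFAULT_COVERS = (19.0, 28.0, 34.0, 43.0, 50.0, 59.0, 63.0, 70.0, 83.0)

# Adult plot: 400 m long (x), 15 m wide (y). Seedling subplot: same length,
# 2 m wide, centered in the adult plot.
PLOT_LENGTH = 400.0
PLOT_WIDTH = 15.0
SUBPLOT_WIDTH = 2.0


class ConfigError(ValueError):
    """Raised for inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    n_sites: int = 9
    covers: tuple[float, ...] = DEFAULT_COVERS
    adults_per_site: int | tuple[int, ...] = 25
    seedlings_per_site: int | tuple[int, ...] = 25
    n_loci: int = 13
    alleles_per_locus: int = 8
    founder_dirichlet_alpha: float = 1.0
    error_rate: float = 0.01
    # median dispersal distance (m) = exp(a + b * cover)
    dispersal_intercept: float = 3.0
    dispersal_slope: float = 0.02
    dispersal_sigma_log: float = 1.0
    lambda_pollen: float = 200.0
    prop_parents_sampled: float = 0.9
    cross_site_threshold_m: float = 1000.0
    site_spacing_km: float = 5.0
    site_centroids: tuple[tuple[float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.covers) != self.n_sites:
            raise ConfigError(
                f"{len(self.covers)} covers for {self.n_sites} sites"
            )
        if any(not 0.0 <= c <= 100.0 for c in self.covers):
            raise ConfigError("covers must lie in [0, 100]")
        for name in ("error_rate", "prop_parents_sampled"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.site_centroids is not None and len(self.site_centroids) != self.n_sites:
            raise ConfigError("site_centroids length must equal n_sites")

    def counts(self, which: str) -> list[int]:
        v = getattr(self, which)
        if isinstance(v, int):
            return [v] * self.n_sites
        v = list(v)
        if len(v) != self.n_sites:
            raise ConfigError(f"{which} length must equal n_sites")
        return [int(x) for x in v]

    def centroids(self) -> np.ndarray:
        if self.site_centroids is not None:
            return np.asarray(self.site_centroids, dtype=float)
        # sites along a line, spaced site_spacing_km apart
        xs = np.arange(self.n_sites) * self.site_spacing_km * 1000.0
        return np.column_stack([xs, np.zeros(self.n_sites)])

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "covers" in raw:
            raw["covers"] = tuple(raw["covers"])
        if raw.get("site_centroids") is not None:
            raw["site_centroids"] = tuple(tuple(c) for c in raw["site_centroids"])
        for key in ("adults_per_site", "seedlings_per_site"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["covers"] = list(d["covers"])
        if d["site_centroids"] is not None:
            d["site_centroids"] = [list(c) for c in d["site_centroids"]]
        for key in ("adults_per_site", "seedlings_per_site"):
            if isinstance(d[key], tuple):
                d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass(frozen=True)
class LedgerEntry:
    seedling_id: str
    mother_id: str
    father_id: str
    distance_m: float
    mother_sampled: bool
    father_sampled: bool
    mother_site: str
    seedling_site: str


@dataclass
class TruthLedger:
    """True pedigree and realized dispersal distances for every seedling."""

    entries: list[LedgerEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.seedling_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("ledger: seedling appears more than once")
        if any(e.distance_m < 0 for e in self.entries):
            raise ValidationError("ledger: negative realized distance")

    def by_seedling(self) -> dict[str, LedgerEntry]:
        return {e.seedling_id: e for e in self.entries}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(e) for e in self.entries],
            columns=[f.name for f in dataclasses.fields(LedgerEntry)],
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "TruthLedger":
        df = pd.read_csv(path, float_precision="round_trip", dtype={
            "seedling_id": str, "mother_id": str, "father_id": str,
            "mother_site": str, "seedling_site": str})
        entries = [
            LedgerEntry(
                seedling_id=r["seedling_id"], mother_id=r["mother_id"],
                father_id=r["father_id"], distance_m=float(r["distance_m"]),
                mother_sampled=bool(r["mother_sampled"]),
                father_sampled=bool(r["father_sampled"]),
                mother_site=r["mother_site"], seedling_site=r["seedling_site"],
            )
            for r in df.to_dict("records")
        ]
        return cls(entries=entries)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _draw_hw_genotype(rng, locus_names, allele_labels, founder_freqs):
    calls = {}
    for name in locus_names:
        labels = allele_labels[name]
        p = founder_freqs[name]
        pair = rng.choice(labels, size=2, p=p)
        calls[name] = (int(pair[0]), int(pair[1]))
    return Genotype(calls)


def _plot_origin(centroid: np.ndarray) -> np.ndarray:
    return centroid - np.array([PLOT_LENGTH / 2.0, PLOT_WIDTH / 2.0])


def _uniform_in_adult_plot(rng, origin):
    return origin + np.array([rng.uniform(0, PLOT_LENGTH),
                              rng.uniform(0, PLOT_WIDTH)])


def _uniform_in_subplot(rng, origin):
    y0 = (PLOT_WIDTH - SUBPLOT_WIDTH) / 2.0
    return origin + np.array([rng.uniform(0, PLOT_LENGTH),
                              y0 + rng.uniform(0, SUBPLOT_WIDTH)])


def _in_subplot(point, origin) -> bool:
    dx = point[0] - origin[0]
    dy = point[1] - origin[1]
    y0 = (PLOT_WIDTH - SUBPLOT_WIDTH) / 2.0
    return 0 <= dx <= PLOT_LENGTH and y0 <= dy <= y0 + SUBPLOT_WIDTH


def simulate_dataset(cfg: SimulationConfig) -> tuple[StudyDataset, TruthLedger]:
    """Generate a dataset and its truth ledger from ``cfg`` (seed-determined).

    Per seedling censused at a site: a kernel distance is drawn; draws beyond
    ``cross_site_threshold_m`` recruit the parents from another site (chosen
    with probability inversely proportional to inter-site centroid distance)
    and the realized dispersal distance is the centroid distance, matching
    the analysis convention for cross-site gene flow. Otherwise the mother
    is local and the deposition point is rejection-sampled into the seedling
    subplot. Offspring inherit one allele per parent per locus; with
    probability ``error_rate`` per locus the recorded call is replaced by a
    random draw from the founder frequencies.
    """
    rng = np.random.default_rng(cfg.seed)
    centroids = cfg.centroids()
    site_ids = [f"s{i + 1}" for i in range(cfg.n_sites)]
    sites = [
        SiteRecord(site_id=sid, centroid_x=float(c[0]), centroid_y=float(c[1]),
                   forest_cover=float(cov))
        for sid, c, cov in zip(site_ids, centroids, cfg.covers)
    ]

    locus_names = [f"L{i + 1:02d}" for i in range(cfg.n_loci)]
    allele_labels = {
        name: np.array([100 + 2 * j for j in range(cfg.alleles_per_locus)])
        for name in locus_names
    }
    founder_freqs = {
        name: rng.dirichlet(
            np.full(cfg.alleles_per_locus, cfg.founder_dirichlet_alpha))
        for name in locus_names
    }
    loci = [LocusDef(name=n, allele_labels=tuple(int(a) for a in allele_labels[n]))
            for n in locus_names]

    adults_n = cfg.counts("adults_per_site")
    seedlings_n = cfg.counts("seedlings_per_site")

    # -- adults ---------------------------------------------------------------
    adults_by_site: dict[str, list[IndividualRecord]] = {s: [] for s in site_ids}
    individuals: list[IndividualRecord] = []
    for si, sid in enumerate(site_ids):
        origin = _plot_origin(centroids[si])
        for k in range(adults_n[si]):
            pos = _uniform_in_adult_plot(rng, origin)
            ind = IndividualRecord(
                id=f"{sid}_A{k + 1:03d}", site_id=sid, stage=Stage.ADULT,
                x=float(pos[0]), y=float(pos[1]),
                genotype=_draw_hw_genotype(rng, locus_names, allele_labels,
                                           founder_freqs),
            )
            adults_by_site[sid].append(ind)
            individuals.append(ind)

    inter_site = np.linalg.norm(
        centroids[:, None, :] - centroids[None, :, :], axis=-1)

    ghost_counter = [0]

    def draw_parent(site_idx: int, near: np.ndarray | None):
        """A (record-like, sampled?) parent from the given site's pool."""
        sid = site_ids[site_idx]
        pool = adults_by_site[sid]
        sampled = bool(pool) and rng.random() < cfg.prop_parents_sampled
        if sampled:
            if near is not None:
                pos = np.array([[a.x, a.y] for a in pool])
                d = np.linalg.norm(pos - near, axis=1)
                w = np.exp(-d / cfg.lambda_pollen)
                w = w / w.sum()
                parent = pool[int(rng.choice(len(pool), p=w))]
            else:
                parent = pool[int(rng.choice(len(pool)))]
            return parent.id, np.array([parent.x, parent.y]), parent.genotype, True
        ghost_counter[0] += 1
        origin = _plot_origin(centroids[site_idx])
        pos = _uniform_in_adult_plot(rng, origin)
        geno = _draw_hw_genotype(rng, locus_names, allele_labels, founder_freqs)
        return f"ghost_{sid}_{ghost_counter[0]:04d}", pos, geno, False

    # -- seedlings ------------------------------------------------------------
    entries: list[LedgerEntry] = []
    for si, sid in enumerate(site_ids):
        origin = _plot_origin(centroids[si])
        cover = cfg.covers[si]
        median_d = math.exp(cfg.dispersal_intercept + cfg.dispersal_slope * cover)
        for k in range(seedlings_n[si]):
            kernel_d = rng.lognormal(mean=math.log(median_d),
                                     sigma=cfg.dispersal_sigma_log)
            cross = (kernel_d > cfg.cross_site_threshold_m and cfg.n_sites > 1)
            if cross:
                weights = np.where(inter_site[si] > 0, 1.0, 0.0)
                with np.errstate(divide="ignore"):
                    weights = np.where(weights > 0, 1.0 / inter_site[si], 0.0)
                weights /= weights.sum()
                mother_site_idx = int(rng.choice(cfg.n_sites, p=weights))
                mid, mpos, mgeno, msamp = draw_parent(mother_site_idx, None)
                spos = _uniform_in_subplot(rng, origin)
                realized = float(inter_site[si, mother_site_idx])
            else:
                mother_site_idx = si
                mid, mpos, mgeno, msamp = draw_parent(si, None)
                spos = None
                for _ in range(100):
                    theta = rng.uniform(0, 2 * math.pi)
                    cand = mpos + kernel_d * np.array([math.cos(theta),
                                                       math.sin(theta)])
                    if _in_subplot(cand, origin):
                        spos = cand
                        break
                if spos is None:
                    # mother too far from the subplot for this draw; deposit
                    # uniformly and keep the realized (not the drawn) distance
                    spos = _uniform_in_subplot(rng, origin)
                realized = float(np.linalg.norm(spos - mpos))
            fid, _, fgeno, fsamp = draw_parent(mother_site_idx, mpos)

            calls = {}
            for name in locus_names:
                if rng.random() < cfg.error_rate:
                    labels = allele_labels[name]
                    p = founder_freqs[name]
                    pair = rng.choice(labels, size=2, p=p)
                    calls[name] = (int(pair[0]), int(pair[1]))
                else:
                    ma = mgeno[name][int(rng.integers(2))]
                    fa = fgeno[name][int(rng.integers(2))]
                    calls[name] = (int(ma), int(fa))

            seedling_id = f"{sid}_S{k + 1:03d}"
            individuals.append(
                IndividualRecord(
                    id=seedling_id, site_id=sid, stage=Stage.SEEDLING,
                    x=float(spos[0]), y=float(spos[1]),
                    genotype=Genotype(calls),
                )
            )
            entries.append(
                LedgerEntry(
                    seedling_id=seedling_id, mother_id=mid, father_id=fid,
                    distance_m=realized, mother_sampled=msamp,
                    father_sampled=fsamp,
                    mother_site=site_ids[mother_site_idx], seedling_site=sid,
                )
            )

    ds = StudyDataset(loci=loci, individuals=individuals, sites=sites)
    return ds, TruthLedger(entries=entries)


def ledger_summary(ledger: TruthLedger, ds: StudyDataset) -> pd.DataFrame:
    """Per-site truth counts: the ground-truth analogue of the study table.

    A seedling counts under ``parent_sampled_same_site`` when at least one
    true parent was sampled in the seedling's own site, under
    ``parent_sampled_other_site`` when a sampled true parent sits in another
    site and none in its own, and under ``parent_sampled_total`` when either
    applies.
    """
    ds_ids = {i.id for i in ds.individuals}
    known_seedlings = {i.id for i in ds.seedlings()}
    for e in ledger.entries:
        if e.seedling_id not in known_seedlings:
            raise ValidationError(
                f"ledger seedling {e.seedling_id!r} absent from dataset"
            )
        for pid, sampled in ((e.mother_id, e.mother_sampled),
                             (e.father_id, e.father_sampled)):
            if sampled and pid not in ds_ids:
                raise ValidationError(
                    f"ledger parent {pid!r} flagged sampled but absent"
                )
    rows = []
    for site in ds.sites:
        sid = site.site_id
        n_adults = len(ds.individuals_at(sid, Stage.ADULT))
        site_entries = [e for e in ledger.entries if e.seedling_site == sid]
        same = other = 0
        for e in site_entries:
            has_same = ((e.mother_sampled and e.mother_site == sid)
                        or (e.father_sampled and e.mother_site == sid))
            has_other = ((e.mother_sampled or e.father_sampled)
                         and e.mother_site != sid)
            if has_same:
                same += 1
            elif has_other:
                other += 1
        rows.append({
            "site_id": sid,
            "forest_cover": site.forest_cover,
            "adults": n_adults,
            "seedlings": len(site_entries),
            "parent_sampled_same_site": same,
            "parent_sampled_other_site": other,
            "parent_sampled_total": same + other,
        })
    return pd.DataFrame(rows)
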