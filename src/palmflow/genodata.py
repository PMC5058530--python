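"""Data model and I/O for codominant microsatellite datasets.

The substrate for every downstream analysis: loci, diploid genotypes with
atomic missing calls, staged and georeferenced individuals, sites carrying a
forest-cover covariate, and allele-frequency estimation against a stated
reference set.

Coordinates are planar projected meters; all distances are Euclidean.
"""

from __future__ import annotations

import io
import math
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "Stage",
    "LocusDef",
    "Genotype",
    "IndividualRecord",
    "SiteRecord",
    "StudyDataset",
    "AlleleFreqTable",
    "ValidationError",
    "ParseError",
    "load_genotypes",
    "save_genotypes",
    "load_site_table",
    "save_site_table",
    "load_dataset",
    "filter_sites_min_count",
    "allele_frequencies",
]

#: Sentinel allele label for a missing call (both alleles or neither).
MISSING = 0


class ValidationError(ValueError):
    """Raised when dataset contents violate a structural invariant."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed under the named dialect."""


class Stage(str, Enum):
    ADULT = "adult"
    SEEDLING = "seedling"


@dataclass(frozen=True)
class LocusDef:
    """A named locus with its ordered roster of allele labels.

    Allele labels are opaque positive integers (nominally fragment sizes in
    base pairs); no binning or size correction is applied.
    """

    name: str
    allele_labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("locus name must be non-empty")
        if len(self.allele_labels) < 1:
            raise ValidationError(f"locus {self.name!r} has no allele labels")
        if any(a <= 0 for a in self.allele_labels):
            raise ValidationError(
                f"locus {self.name!r}: allele labels must be positive integers"
            )
        if len(set(self.allele_labels)) != len(self.allele_labels):
            raise ValidationError(f"locus {self.name!r}: duplicate allele labels")


class Genotype(Mapping):
    """Per-locus unordered allele pairs; a call is atomic (both or neither).

    Behaves as a read-only mapping ``locus name -> (allele, allele)`` with
    pairs stored in canonical sorted order so equality is order-insensitive.
    """

    __slots__ = ("_calls",)

    def __init__(self, calls: Mapping[str, tuple[int, int]]):
        canonical: dict[str, tuple[int, int]] = {}
        for locus, pair in calls.items():
            a, b = int(pair[0]), int(pair[1])
            if (a == MISSING) != (b == MISSING):
                raise ValidationError(
                    f"locus {locus!r}: half-call {pair} (alleles must be both "
                    "present or both missing)"
                )
            canonical[locus] = (a, b) if a <= b else (b, a)
        self._calls = canonical

    def __getitem__(self, locus: str) -> tuple[int, int]:
        return self._calls[locus]

    def __iter__(self):
        return iter(self._calls)

    def __len__(self) -> int:
        return len(self._calls)

    def is_missing(self, locus: str) -> bool:
        return self._calls[locus][0] == MISSING

    def scored_loci(self) -> list[str]:
        return [l for l, (a, _) in self._calls.items() if a != MISSING]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        return self._calls == other._calls

    def __hash__(self):
        return hash(tuple(sorted(self._calls.items())))

    def __repr__(self) -> str:
        return f"Genotype({self._calls!r})"


@dataclass(frozen=True)
class IndividualRecord:
    id: str
    site_id: str
    stage: Stage
    x: float
    y: float
    genotype: Genotype

    def __post_init__(self) -> None:
        if not math.isfinite(self.x) or not math.isfinite(self.y):
            raise ValidationError(f"individual {self.id!r}: non-finite coordinates")
        object.__setattr__(self, "stage", Stage(self.stage))


@dataclass(frozen=True)
class SiteRecord:
    site_id: str
    centroid_x: float
    centroid_y: float
    forest_cover: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.forest_cover <= 100.0:
            raise ValidationError(
                f"site {self.site_id!r}: forest_cover {self.forest_cover} "
                "outside [0, 100]"
            )
        if not (math.isfinite(self.centroid_x) and math.isfinite(self.centroid_y)):
            raise ValidationError(f"site {self.site_id!r}: non-finite centroid")


@dataclass
class StudyDataset:
    """Loci, individuals and sites bundled together with cross-validation."""

    loci: list[LocusDef]
    individuals: list[IndividualRecord]
    sites: list[SiteRecord]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        locus_names = [l.name for l in self.loci]
        if len(set(locus_names)) != len(locus_names):
            raise ValidationError("duplicate locus names")
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate individual ids: {dups}")
        site_ids = [s.site_id for s in self.sites]
        if len(set(site_ids)) != len(site_ids):
            raise ValidationError("duplicate site ids")
        centroids = {(s.centroid_x, s.centroid_y) for s in self.sites}
        if len(centroids) != len(self.sites):
            raise ValidationError("site centroids must be pairwise distinct")
        known_sites = set(site_ids)
        labels = {l.name: set(l.allele_labels) for l in self.loci}
        for ind in self.individuals:
            if known_sites and ind.site_id not in known_sites:
                raise ValidationError(
                    f"individual {ind.id!r}: unknown site {ind.site_id!r}"
                )
            for locus, (a, b) in ind.genotype.items():
                if locus not in labels:
                    raise ValidationError(
                        f"individual {ind.id!r}: genotype at unknown locus {locus!r}"
                    )
                if a != MISSING and not {a, b} <= labels[locus]:
                    raise ValidationError(
                        f"individual {ind.id!r}: allele(s) {(a, b)} at locus "
                        f"{locus!r} not in its LocusDef"
                    )

    # -- convenience accessors -------------------------------------------------

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def site_map(self) -> dict[str, SiteRecord]:
        return {s.site_id: s for s in self.sites}

    def adults(self) -> list[IndividualRecord]:
        return [i for i in self.individuals if i.stage is Stage.ADULT]

    def seedlings(self) -> list[IndividualRecord]:
        return [i for i in self.individuals if i.stage is Stage.SEEDLING]

    def individuals_at(self, site_id: str, stage: Stage | None = None):
        out = [i for i in self.individuals if i.site_id == site_id]
        if stage is not None:
            out = [i for i in out if i.stage is Stage(stage)]
        return out


class AlleleFreqTable:
    """Per-locus relative allele frequencies over a stated reference set."""

    def __init__(self, freqs: Mapping[str, Mapping[int, float]], reference: str = ""):
        self._freqs: dict[str, dict[int, float]] = {}
        self.reference = reference
        for locus, table in freqs.items():
            table = {int(a): float(f) for a, f in table.items()}
            if any(f < 0 for f in table.values()):
                raise ValidationError(f"locus {locus!r}: negative frequency")
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"locus {locus!r}: frequencies sum to {total}, not 1"
                )
            self._freqs[locus] = table

    @property
    def loci(self) -> list[str]:
        return list(self._freqs)

    def alleles(self, locus: str) -> list[int]:
        return list(self._freqs[locus])

    def freq(self, locus: str, allele: int) -> float:
        if locus not in self._freqs:
            raise KeyError(f"locus {locus!r} absent from frequency table")
        table = self._freqs[locus]
        if allele not in table:
            raise KeyError(f"allele {allele} absent from locus {locus!r} frequencies")
        return table[allele]

    def table(self, locus: str) -> dict[int, float]:
        return dict(self._freqs[locus])

    def as_dict(self) -> dict[str, dict[int, float]]:
        return {l: dict(t) for l, t in self._freqs.items()}

    def __contains__(self, locus: str) -> bool:
        return locus in self._freqs


# ---------------------------------------------------------------------------
# I/O — long CSV dialect
# ---------------------------------------------------------------------------

_META_COLUMNS = ["individual_id", "site_id", "stage", "x", "y"]


def _loci_from_individuals(individuals: Iterable[IndividualRecord],
                           locus_names: list[str]) -> list[LocusDef]:
    observed: dict[str, set[int]] = {name: set() for name in locus_names}
    for ind in individuals:
        for locus, (a, b) in ind.genotype.items():
            if a != MISSING:
                observed[locus].update((a, b))
    loci = []
    for name in locus_names:
        labels = tuple(sorted(observed[name])) or (1,)
        loci.append(LocusDef(name=name, allele_labels=labels))
    return loci


def _read_csv_dialect(path) -> tuple[list[LocusDef], list[IndividualRecord]]:
    try:
        df = pd.read_csv(path, dtype={"individual_id": str, "site_id": str})
    except pd.errors.EmptyDataError:
        return [], []
    missing_cols = [c for c in _META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"CSV genotype file lacks columns {missing_cols}")
    locus_names: list[str] = []
    for col in df.columns:
        if col.endswith(".a1"):
            name = col[:-3]
            if f"{name}.a2" not in df.columns:
                raise ParseError(f"locus column {col!r} has no matching {name}.a2")
            locus_names.append(name)
    individuals = []
    for row_no, rec in enumerate(df.to_dict("records"), start=2):
        calls = {}
        for name in locus_names:
            a1 = rec[f"{name}.a1"]
            a2 = rec[f"{name}.a2"]
            a1_missing = pd.isna(a1)
            a2_missing = pd.isna(a2)
            if a1_missing != a2_missing:
                raise ParseError(
                    f"line {row_no}: half-missing call at locus {name!r}"
                )
            if a1_missing:
                calls[name] = (MISSING, MISSING)
            else:
                try:
                    calls[name] = (int(a1), int(a2))
                except (TypeError, ValueError) as exc:
                    raise ParseError(
                        f"line {row_no}: malformed allele field at locus "
                        f"{name!r}: {a1!r}/{a2!r}"
                    ) from exc
        individuals.append(
            IndividualRecord(
                id=str(rec["individual_id"]),
                site_id=str(rec["site_id"]),
                stage=Stage(str(rec["stage"])),
                x=float(rec["x"]),
                y=float(rec["y"]),
                genotype=Genotype(calls),
            )
        )
    ids = [i.id for i in individuals]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate individual ids: {dups}")
    return _loci_from_individuals(individuals, locus_names), individuals


def _write_csv_dialect(loci, individuals, path) -> None:
    rows = []
    for ind in individuals:
        rec: dict[str, object] = {
            "individual_id": ind.id,
            "site_id": ind.site_id,
            "stage": ind.stage.value,
            "x": ind.x,
            "y": ind.y,
        }
        for locus in loci:
            a, b = ind.genotype.get(locus.name, (MISSING, MISSING))
            rec[f"{locus.name}.a1"] = "" if a == MISSING else a
            rec[f"{locus.name}.a2"] = "" if b == MISSING else b
        rows.append(rec)
    cols = _META_COLUMNS + [f"{l.name}.{s}" for l in loci for s in ("a1", "a2")]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# I/O — GenePop dialect
# ---------------------------------------------------------------------------

def _parse_genepop_allele(tok: str, line_no: int) -> tuple[int, int]:
    if len(tok) == 4:
        w = 2
    elif len(tok) == 6:
        w = 3
    else:
        raise ParseError(
            f"line {line_no}: allele field {tok!r} is neither 4 nor 6 digits"
        )
    if not tok.isdigit():
        raise ParseError(f"line {line_no}: malformed allele field {tok!r}")
    return int(tok[:w]), int(tok[w:])


def _read_genepop(path, meta: pd.DataFrame | None):
    text = Path(path).read_text().splitlines()
    if not text:
        raise ParseError("empty GenePop file")
    # Line 1 is a free-form title; locus names follow, one per line or
    # comma-separated, until the first "Pop" marker.
    locus_names: list[str] = []
    i = 1
    while i < len(text) and text[i].strip().lower() != "pop":
        chunk = [t.strip() for t in text[i].split(",") if t.strip()]
        locus_names.extend(chunk)
        i += 1
    if i == len(text):
        raise ParseError("GenePop file has no Pop block")
    meta_by_id: dict[str, dict] = {}
    if meta is not None:
        meta_by_id = {
            str(r["individual_id"]): r for _, r in meta.iterrows()
        }
    individuals = []
    pop_idx = 0
    for line_no in range(i, len(text)):
        line = text[line_no]
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise ParseError(f"line {line_no + 1}: expected 'id , alleles...'")
        ind_id, rest = line.split(",", 1)
        ind_id = ind_id.strip()
        toks = rest.split()
        if len(toks) != len(locus_names):
            raise ParseError(
                f"line {line_no + 1}: {len(toks)} allele fields for "
                f"{len(locus_names)} loci"
            )
        calls = {
            name: _parse_genepop_allele(tok, line_no + 1)
            for name, tok in zip(locus_names, toks)
        }
        if ind_id in meta_by_id:
            m = meta_by_id[ind_id]
            site_id, stage = str(m["site_id"]), Stage(str(m["stage"]))
            x, y = float(m["x"]), float(m["y"])
        else:
            site_id, stage, x, y = f"pop{pop_idx}", Stage.ADULT, 0.0, 0.0
        individuals.append(
            IndividualRecord(id=ind_id, site_id=site_id, stage=stage,
                             x=x, y=y, genotype=Genotype(calls))
        )
    ids = [i.id for i in individuals]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate individual ids: {dups}")
    return _loci_from_individuals(individuals, locus_names), individuals


def _write_genepop(loci, individuals, path, title="palmflow export") -> None:
    digits = 3 if any(a > 99 for l in loci for a in l.allele_labels) else 2
    lines = [title]
    lines.extend(l.name for l in loci)
    # one Pop block per site, in order of first appearance
    site_order: list[str] = []
    for ind in individuals:
        if ind.site_id not in site_order:
            site_order.append(ind.site_id)
    for site_id in site_order:
        lines.append("Pop")
        for ind in individuals:
            if ind.site_id != site_id:
                continue
            toks = []
            for l in loci:
                a, b = ind.genotype.get(l.name, (MISSING, MISSING))
                toks.append(f"{a:0{digits}d}{b:0{digits}d}")
            lines.append(f"{ind.id} ,  " + " ".join(toks))
    Path(path).write_text("\n".join(lines) + "\n")


def _write_meta(individuals, path) -> None:
    pd.DataFrame(
        [
            {"individual_id": i.id, "site_id": i.site_id,
             "stage": i.stage.value, "x": i.x, "y": i.y}
            for i in individuals
        ],
        columns=_META_COLUMNS,
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Public I/O surface
# ---------------------------------------------------------------------------

def load_genotypes(path, dialect: str = "csv", meta_path=None):
    """Read loci and individuals from ``path`` under the named dialect.

    Parameters
    ----------
    path : path-like
        Genotype file. For ``dialect="csv"`` this is the long-form CSV with
        ``individual_id, site_id, stage, x, y`` plus paired ``LOCUS.a1`` /
        ``LOCUS.a2`` columns (missing = empty cells). For
        ``dialect="genepop"`` it is a Pop-delimited GenePop file with 4- or
        6-digit allele coding (missing = all zeros).
    meta_path : path-like, optional
        Companion CSV supplying site/stage/coordinates for the GenePop
        dialect, which cannot carry them itself.

    Returns
    -------
    (list[LocusDef], list[IndividualRecord])
    """
    if dialect == "csv":
        return _read_csv_dialect(path)
    if dialect == "genepop":
        meta = pd.read_csv(meta_path, dtype=str) if meta_path is not None else None
        return _read_genepop(path, meta)
    raise ValueError(f"unknown dialect {dialect!r}")


def save_genotypes(ds: StudyDataset, path, dialect: str = "csv",
                   meta_path=None) -> None:
    """Write a dataset's loci and individuals under the named dialect."""
    if dialect == "csv":
        _write_csv_dialect(ds.loci, ds.individuals, path)
    elif dialect == "genepop":
        _write_genepop(ds.loci, ds.individuals, path)
        if meta_path is not None:
            _write_meta(ds.individuals, meta_path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def load_site_table(path) -> list[SiteRecord]:
    """Read a site CSV: site_id, centroid_x, centroid_y, forest_cover."""
    try:
        df = pd.read_csv(path, dtype={"site_id": str})
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    needed = ["site_id", "centroid_x", "centroid_y", "forest_cover"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(f"site table lacks columns {missing}")
    if df["site_id"].duplicated().any():
        dups = sorted(df.loc[df["site_id"].duplicated(), "site_id"])
        raise ValidationError(f"duplicate site ids: {dups}")
    return [
        SiteRecord(site_id=str(r.site_id), centroid_x=float(r.centroid_x),
                   centroid_y=float(r.centroid_y),
                   forest_cover=float(r.forest_cover))
        for r in df.itertuples(index=False)
    ]


def save_site_table(sites: Iterable[SiteRecord], path) -> None:
    pd.DataFrame(
        [
            {"site_id": s.site_id, "centroid_x": s.centroid_x,
             "centroid_y": s.centroid_y, "forest_cover": s.forest_cover}
            for s in sites
        ],
        columns=["site_id", "centroid_x", "centroid_y", "forest_cover"],
    ).to_csv(path, index=False)


def load_dataset(genotype_path, site_path, dialect: str = "csv",
                 meta_path=None) -> StudyDataset:
    """Convenience loader combining genotypes and the site table."""
    loci, individuals = load_genotypes(genotype_path, dialect, meta_path)
    sites = load_site_table(site_path)
    return StudyDataset(loci=loci, individuals=individuals, sites=sites)


# ---------------------------------------------------------------------------
# Dataset operations
# ---------------------------------------------------------------------------

def filter_sites_min_count(ds: StudyDataset, min_per_stage: int = 5,
                           log: list[str] | None = None) -> StudyDataset:
    """Drop sites (and their individuals) with fewer than ``min_per_stage``
    adults or seedlings. Idempotent; dropped site ids are appended to ``log``.
    """
    keep: list[SiteRecord] = []
    for site in ds.sites:
        n_adult = len(ds.individuals_at(site.site_id, Stage.ADULT))
        n_seed = len(ds.individuals_at(site.site_id, Stage.SEEDLING))
        if n_adult >= min_per_stage and n_seed >= min_per_stage:
            keep.append(site)
        elif log is not None:
            log.append(site.site_id)
    kept_ids = {s.site_id for s in keep}
    individuals = [i for i in ds.individuals if i.site_id in kept_ids]
    return StudyDataset(loci=list(ds.loci), individuals=individuals, sites=keep)


def allele_frequencies(ds: StudyDataset, reference: str = "all_adults",
                       site_id: str | None = None) -> AlleleFreqTable:
    """Relative allele frequencies over 2N observed alleles per locus.

    ``reference`` selects the estimation set: ``all_adults`` (default),
    ``all_individuals``, or ``per_site_adults`` (requires ``site_id``).
    A locus with zero observed alleles in the reference set is an error.
    """
    if reference == "all_adults":
        pool = ds.adults()
    elif reference == "all_individuals":
        pool = list(ds.individuals)
    elif reference == "per_site_adults":
        if site_id is None:
            raise ValueError("per_site_adults reference requires site_id")
        pool = ds.individuals_at(site_id, Stage.ADULT)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return frequencies_from_individuals(pool, ds.locus_names, reference)


def frequencies_from_individuals(individuals, locus_names,
                                 reference: str = "") -> AlleleFreqTable:
    """Allele frequencies over an explicit set of individuals."""
    freqs: dict[str, dict[int, float]] = {}
    for name in locus_names:
        counts: dict[int, int] = {}
        for ind in individuals:
            pair = ind.genotype.get(name)
            if pair is None or pair[0] == MISSING:
                continue
            for a in pair:
                counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        if total == 0:
            raise ValidationError(
                f"locus {name!r}: zero observed alleles in reference set"
            )
        freqs[name] = {a: c / total for a, c in sorted(counts.items())}
    return AlleleFreqTable(freqs, reference=reference)
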