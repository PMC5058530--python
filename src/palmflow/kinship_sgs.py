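"""Pairwise kinship coefficients and distance-class spatial genetic structure.

The pairwise estimator is the correlation-type kinship coefficient of
Loiselle et al. (1995) with the finite-sample correction: per locus,

    f_ij = [ sum_a (p_ia - pbar_a)(p_ja - pbar_a)
             + sum_a pbar_a (1 - pbar_a) / (n_l - 1) ] / sum_a pbar_a (1 - pbar_a)

where p_ia is individual i's allele frequency at allele a (0, 0.5 or 1),
pbar_a the reference frequency, and n_l the number of individuals genotyped
at the locus. The multilocus value is the per-locus values weighted by
w_l = sum_a pbar_a (1 - pbar_a), so a monomorphic locus carries zero weight.

Spatial profiles average f_ij within half-open distance classes (default
eight 50 m classes spanning 0-400 m); the null envelope per class is the
2.5/97.5 percentile band of class means under random permutation of the
individual locations (genotypes held fixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .genodata import (
    MISSING,
    AlleleFreqTable,
    IndividualRecord,
    StudyDataset,
    Stage,
    frequencies_from_individuals,
)

__all__ = [
    "DistanceClassSpec",
    "KinshipResult",
    "pairwise_kinship_loiselle",
    "sgs_profile",
    "sgs_by_population",
    "stage_mean_sgs_ttest",
    "sgs_vs_cover_regression",
]


@dataclass(frozen=True)
class DistanceClassSpec:
    """Contiguous half-open distance classes ``[lo, hi)`` starting at 0."""

    n_classes: int = 8
    class_width: float = 50.0

    @property
    def upper(self) -> float:
        return self.n_classes * self.class_width

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.n_classes + 1) * self.class_width

    def classify(self, d: np.ndarray) -> np.ndarray:
        """Class index per distance; -1 marks the out-of-range bucket."""
        idx = np.floor(np.asarray(d, dtype=float) / self.class_width).astype(int)
        idx[idx >= self.n_classes] = -1
        return idx


@dataclass
class KinshipResult:
    ids: list[str]
    fij: np.ndarray                      # symmetric, nan diagonal/undefined
    spec: DistanceClassSpec
    class_mean: np.ndarray               # nan where class has no pairs
    class_n_pairs: np.ndarray
    env_lo: np.ndarray
    env_hi: np.ndarray
    overall_mean: float                  # mean over all defined pairs
    mean_of_class_means: float
    out_of_range_pairs: int
    n_permutations: int

    @property
    def empty_classes(self) -> list[int]:
        return [k for k in range(self.spec.n_classes)
                if self.class_n_pairs[k] == 0]

    def to_dataframe(self) -> pd.DataFrame:
        e = self.spec.edges
        return pd.DataFrame({
            "class_lo": e[:-1],
            "class_hi": e[1:],
            "mean_fij": self.class_mean,
            "n_pairs": self.class_n_pairs,
            "env_lo": self.env_lo,
            "env_hi": self.env_hi,
        })


def _dosage_matrices(individuals, freqs: AlleleFreqTable):
    """Per-locus (dosage deviations, weight, n typed) for kinship algebra."""
    out = []
    for locus in freqs.loci:
        alleles = freqs.alleles(locus)
        pbar = np.array([freqs.freq(locus, a) for a in alleles])
        col = {a: j for j, a in enumerate(alleles)}
        n = len(individuals)
        D = np.full((n, len(alleles)), np.nan)
        for i, ind in enumerate(individuals):
            pair = ind.genotype.get(locus)
            if pair is None or pair[0] == MISSING:
                continue
            row = np.zeros(len(alleles))
            for a in pair:
                if a not in col:
                    raise KeyError(
                        f"allele {a} at locus {locus!r} absent from "
                        "frequency table"
                    )
                row[col[a]] += 0.5
            D[i] = row - pbar
        w = float(np.sum(pbar * (1.0 - pbar)))
        n_typed = int(np.sum(~np.isnan(D[:, 0])))
        out.append((D, w, n_typed))
    return out


def pairwise_kinship_loiselle(individuals: list[IndividualRecord],
                              freqs: AlleleFreqTable) -> np.ndarray:
    """Symmetric matrix of multilocus kinship coefficients.

    Entries are nan on the diagonal and for pairs sharing no scored locus
    (or when every shared locus is monomorphic).
    """
    n = len(individuals)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for D, w, n_typed in _dosage_matrices(individuals, freqs):
        if n_typed == 0:
            continue
        typed = ~np.isnan(D[:, 0])
        Dz = np.where(np.isnan(D), 0.0, D)
        cross = Dz @ Dz.T
        correction = w / (n_typed - 1) if n_typed > 1 else 0.0
        pair_ok = np.outer(typed, typed)
        num += np.where(pair_ok, cross + correction, 0.0)
        den += np.where(pair_ok, w, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = num / den
    F[den == 0] = np.nan
    np.fill_diagonal(F, np.nan)
    return F


def _class_means(fvals: np.ndarray, class_idx: np.ndarray,
                 n_classes: int) -> np.ndarray:
    means = np.full(n_classes, np.nan)
    for k in range(n_classes):
        sel = class_idx == k
        if sel.any():
            v = fvals[sel]
            v = v[~np.isnan(v)]
            if v.size:
                means[k] = v.mean()
    return means


def sgs_profile(individuals: list[IndividualRecord],
                spec: DistanceClassSpec | None = None,
                freqs: AlleleFreqTable | None = None,
                n_perm: int = 10000,
                seed: int | None = None) -> KinshipResult:
    """Distance-class kinship profile with a location-permutation envelope.

    ``freqs`` defaults to frequencies computed from ``individuals``
    themselves (per-population reference). The envelope per class is the
    empirical 2.5/97.5 percentile of class means over ``n_perm`` random
    reassignments of the coordinate tuples among individuals; the observed
    value is not added to the null set.
    """
    spec = spec or DistanceClassSpec()
    if len(individuals) < 2:
        raise ValueError("need at least 2 individuals with coordinates")
    locus_names = sorted({l for ind in individuals for l in ind.genotype})
    if freqs is None:
        freqs = frequencies_from_individuals(individuals, locus_names,
                                             "per_population")
    F = pairwise_kinship_loiselle(individuals, freqs)
    n = len(individuals)
    iu = np.triu_indices(n, k=1)
    fvals = F[iu]
    coords = np.array([[ind.x, ind.y] for ind in individuals])
    dmat = squareform(pdist(coords))
    dists = dmat[iu]
    class_idx = spec.classify(dists)

    class_mean = _class_means(fvals, class_idx, spec.n_classes)
    class_n = np.array([(class_idx == k).sum() for k in range(spec.n_classes)])
    out_of_range = int((class_idx == -1).sum())
    defined = fvals[~np.isnan(fvals)]
    overall = float(defined.mean()) if defined.size else float("nan")
    with np.errstate(invalid="ignore"):
        mocm = float(np.nanmean(class_mean)) if np.any(~np.isnan(class_mean)) \
            else float("nan")

    rng = np.random.default_rng(seed)
    perm_means = np.full((n_perm, spec.n_classes), np.nan)
    for p in range(n_perm):
        perm = rng.permutation(n)
        dperm = dmat[np.ix_(perm, perm)][iu]
        perm_means[p] = _class_means(fvals, spec.classify(dperm), spec.n_classes)
    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN classes
        env_lo = np.nanpercentile(perm_means, 2.5, axis=0)
        env_hi = np.nanpercentile(perm_means, 97.5, axis=0)
    env_lo = np.where(np.all(np.isnan(perm_means), axis=0), np.nan, env_lo)
    env_hi = np.where(np.all(np.isnan(perm_means), axis=0), np.nan, env_hi)

    return KinshipResult(
        ids=[i.id for i in individuals], fij=F, spec=spec,
        class_mean=class_mean, class_n_pairs=class_n,
        env_lo=env_lo, env_hi=env_hi, overall_mean=overall,
        mean_of_class_means=mocm, out_of_range_pairs=out_of_range,
        n_permutations=n_perm,
    )


def sgs_by_population(ds: StudyDataset, spec: DistanceClassSpec | None = None,
                      n_perm: int = 10000, seed: int | None = None,
                      min_individuals: int = 2) -> pd.DataFrame:
    """SGS profiles for every site x stage population, stacked long-form.

    Populations below ``min_individuals`` are skipped. Seeds fan out
    deterministically per population from ``seed``.
    """
    spec = spec or DistanceClassSpec()
    ss = np.random.SeedSequence(seed)
    rows = []
    pops = [(site.site_id, stage) for site in ds.sites
            for stage in (Stage.SEEDLING, Stage.ADULT)]
    child_seeds = ss.spawn(len(pops))
    for (site_id, stage), child in zip(pops, child_seeds):
        inds = ds.individuals_at(site_id, stage)
        if len(inds) < min_individuals:
            continue
        res = sgs_profile(inds, spec=spec, n_perm=n_perm,
                          seed=child.generate_state(1)[0])
        df = res.to_dataframe()
        df.insert(0, "site_id", site_id)
        df.insert(1, "stage", stage.value)
        df["overall_mean_fij"] = res.overall_mean
        rows.append(df)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["site_id", "stage", "class_lo", "class_hi", "mean_fij",
                 "n_pairs", "env_lo", "env_hi", "overall_mean_fij"])


def stage_mean_sgs_ttest(means_seedlings, means_adults):
    """Two-sided independent-samples t-test on per-population mean kinship."""
    a = np.asarray(means_seedlings, dtype=float)
    b = np.asarray(means_adults, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("zero variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def sgs_vs_cover_regression(means, covers):
    """OLS of per-population mean kinship on forest cover.

    Returns ``(slope, r_squared, p)`` with a two-sided slope test.
    """
    y = np.asarray(means, dtype=float)
    x = np.asarray(covers, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need equal-length inputs with >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant covers: slope undefined")
    if np.ptp(y) == 0:
        return 0.0, 0.0, 1.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue ** 2), float(res.pvalue)
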