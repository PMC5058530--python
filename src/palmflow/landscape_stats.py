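"""Forest-cover inference layer: binomial GLMs, a mixed model on log
gene-flow distance, and Monte Carlo randomization tests.

Parametric slope inference is the Wald z test for the GLMs and a t-ratio
test for the mixed model. The randomization tests permute the response
against the covers (proportions travel with their totals as units), refit,
and compare deviances: significance is the proportion of deviances less
than or equal to the observed one, with the observed arrangement included
in the comparison set, so p >= 1/(n_rand + 1). The regression analogue
permutes covers at the landscape level and counts randomized R-squared
values greater than or equal to the observed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    DomainWarning,
    PerfectSeparationWarning,
)

from .genodata import SiteRecord, StudyDataset
from .parentage import ParentageAssignment

__all__ = [
    "GlmResult",
    "McTestResult",
    "LmmResult",
    "glm_binomial_presence",
    "glm_binomial_proportion",
    "mc_glm_deviance_test",
    "mc_regression_r2_test",
    "lmm_log_distance",
    "summarize_assignments",
    "landscape_battery",
]


@dataclass
class GlmResult:
    intercept: float
    slope: float
    null_deviance: float
    deviance: float
    z: float | None
    p: float | None
    separation_flag: bool


@dataclass
class McTestResult:
    observed_stat: float
    p: float
    n_randomizations: int
    seed: int | None
    include_observed: bool = True


@dataclass
class LmmResult:
    intercept: float
    slope: float
    t: float
    p: float
    df: int
    group_var: float
    resid_var: float


# ---------------------------------------------------------------------------
# Binomial GLMs
# ---------------------------------------------------------------------------

def _fit_binomial(endog, covers, var_weights=None):
    X = sm.add_constant(np.asarray(covers, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", DomainWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = sm.GLM(np.asarray(endog, dtype=float), X,
                       family=sm.families.Binomial(),
                       var_weights=var_weights)
        return model.fit()


def _is_separated(y, fitted, tol: float = 1e-6) -> bool:
    """Perfect or quasi-complete separation of a binary response."""
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        return False
    if (y == 1).all() or (y == 0).all():
        return True
    return (fitted[y == 1].min() > 1 - tol) and (fitted[y == 0].max() < tol)


def glm_binomial_presence(presence, covers) -> GlmResult:
    """Logistic GLM of a 0/1 presence response on forest cover.

    Complete or quasi-complete separation (including an all-0 or all-1
    response) is flagged and suppresses the parametric Wald p.
    """
    presence = np.asarray(presence, dtype=float)
    covers = np.asarray(covers, dtype=float)
    if presence.size != covers.size or presence.size < 3:
        raise ValueError("need equal-length inputs with >= 3 points")
    res = _fit_binomial(presence, covers)
    separated = _is_separated(presence, res.fittedvalues)
    return GlmResult(
        intercept=float(res.params[0]), slope=float(res.params[1]),
        null_deviance=float(res.null_deviance), deviance=float(res.deviance),
        z=None if separated else float(res.tvalues[1]),
        p=None if separated else float(res.pvalues[1]),
        separation_flag=separated,
    )


def glm_binomial_proportion(successes, totals, covers) -> GlmResult:
    """Weighted binomial GLM in events/trials form (totals as weights)."""
    successes = np.asarray(successes, dtype=float)
    totals = np.asarray(totals, dtype=float)
    covers = np.asarray(covers, dtype=float)
    if not (successes.size == totals.size == covers.size):
        raise ValueError("inputs must have equal length")
    if (totals < 1).any():
        raise ValueError("all totals must be >= 1")
    if ((successes < 0) | (successes > totals)).any():
        raise ValueError("successes must lie in [0, totals]")
    props = successes / totals
    res = _fit_binomial(props, covers, var_weights=totals)
    degenerate = (props == 1).all() or (props == 0).all()
    return GlmResult(
        intercept=float(res.params[0]), slope=float(res.params[1]),
        null_deviance=float(res.null_deviance), deviance=float(res.deviance),
        z=None if degenerate else float(res.tvalues[1]),
        p=None if degenerate else float(res.pvalues[1]),
        separation_flag=degenerate,
    )


# ---------------------------------------------------------------------------
# Monte Carlo randomization tests
# ---------------------------------------------------------------------------

def mc_glm_deviance_test(response, totals, covers, n_rand: int = 4999,
                         seed: int | None = None) -> McTestResult:
    """Deviance randomization test for a binomial GLM against covers.

    ``totals=None`` selects the 0/1 presence form; otherwise the response is
    a vector of success counts permuted together with its totals. The
    observed arrangement is included in the comparison set and ties count
    toward significance (deviance <= observed).
    """
    response = np.asarray(response, dtype=float)
    covers = np.asarray(covers, dtype=float)
    tot = None if totals is None else np.asarray(totals, dtype=float)

    def deviance(resp, t):
        if t is None:
            res = _fit_binomial(resp, covers)
        else:
            res = _fit_binomial(resp / t, covers, var_weights=t)
        if not res.converged:
            warnings.warn("GLM did not converge in a randomization; using "
                          "the deviance at the final iterate", stacklevel=2)
        return float(res.deviance)

    observed = deviance(response, tot)
    rng = np.random.default_rng(seed)
    n = response.size
    count = 1  # the observed arrangement
    cache: dict[tuple, float] = {}
    for _ in range(n_rand):
        perm = rng.permutation(n)
        resp_p = response[perm]
        tot_p = None if tot is None else tot[perm]
        key = (tuple(resp_p),) if tot is None else \
            (tuple(resp_p), tuple(tot_p))
        d = cache.get(key)
        if d is None:
            d = deviance(resp_p, tot_p)
            cache[key] = d
        if d <= observed:
            count += 1
    return McTestResult(observed_stat=observed, p=count / (n_rand + 1),
                        n_randomizations=n_rand, seed=seed)


def mc_regression_r2_test(y, covers, n_rand: int = 4999,
                          seed: int | None = None,
                          landscape_ids=None) -> McTestResult:
    """R-squared randomization test for a linear regression on cover.

    With ``landscape_ids`` given (one per observation), covers are permuted
    at the landscape level — every observation in a landscape receives that
    landscape's randomized cover — which accounts for the non-independence
    of observations sharing a landscape. p counts randomized R-squared
    values >= observed, observed included.
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant response: R-squared undefined")
    covers = np.asarray(covers, dtype=float)

    def r2(x):
        if np.ptp(x) == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1] ** 2)

    if landscape_ids is not None:
        landscape_ids = np.asarray(landscape_ids)
        if landscape_ids.size != y.size:
            raise ValueError("landscape_ids must match y in length")
        uniq, inverse = np.unique(landscape_ids, return_inverse=True)
        land_cover = np.empty(uniq.size)
        for k in range(uniq.size):
            vals = covers[inverse == k]
            if np.ptp(vals) != 0:
                raise ValueError("inconsistent covers within a landscape")
            land_cover[k] = vals[0]
        obs_x = land_cover[inverse]

        def draw(rng):
            return land_cover[rng.permutation(uniq.size)][inverse]
    else:
        if covers.size != y.size:
            raise ValueError("covers must match y in length")
        obs_x = covers

        def draw(rng):
            return covers[rng.permutation(covers.size)]

    observed = r2(obs_x)
    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(n_rand):
        if r2(draw(rng)) >= observed:
            count += 1
    return McTestResult(observed_stat=observed, p=count / (n_rand + 1),
                        n_randomizations=n_rand, seed=seed)


# ---------------------------------------------------------------------------
# Mixed model on log gene-flow distance
# ---------------------------------------------------------------------------

def lmm_log_distance(distances_m, covers, landscape_ids) -> LmmResult:
    """Random-intercept LMM of ln(gene-flow distance) on forest cover.

    Fit by REML; the fixed-slope test uses t with df = n - n_groups - 1
    (approximate). Requires positive distances and >= 2 landscapes.
    """
    d = np.asarray(distances_m, dtype=float)
    covers = np.asarray(covers, dtype=float)
    groups = np.asarray(landscape_ids)
    if (d <= 0).any():
        raise ValueError("distances must be positive")
    n_groups = np.unique(groups).size
    if n_groups < 2:
        raise ValueError("a single landscape cannot support a random "
                         "intercept; use plain regression")
    y = np.log(d)
    df = int(d.size - n_groups - 1)
    if np.ptp(y) == 0:
        return LmmResult(intercept=float(y[0]), slope=0.0, t=0.0, p=1.0,
                         df=df, group_var=0.0, resid_var=0.0)
    X = sm.add_constant(covers)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = model.fit(reml=True)
    slope = float(res.fe_params[1])
    bse = float(res.bse_fe[1])
    t = slope / bse if bse > 0 else 0.0
    p = 2.0 * stats.t.sf(abs(t), df) if df > 0 else float("nan")
    return LmmResult(
        intercept=float(res.fe_params[0]), slope=slope, t=float(t),
        p=float(p), df=df,
        group_var=float(np.asarray(res.cov_re)[0, 0]),
        resid_var=float(res.scale),
    )


# ---------------------------------------------------------------------------
# Assignment summaries (study-table analogues)
# ---------------------------------------------------------------------------

def summarize_assignments(assignments: list[ParentageAssignment],
                          ds: StudyDataset):
    """Per-site counts and cross-landscape gene-flow records.

    Returns ``(counts, crossings, percent_assigned)``: a per-site table of
    adults, seedlings, same-landscape and other-landscape assignments with
    an overall row; a record list for cross-landscape assignments (progeny
    and parent covers, paternity probability, centroid distance in km); and
    the overall percentage of seedlings assigned, rounded to two decimals.
    """
    site_map = ds.site_map()
    ind_map = {i.id: i for i in ds.individuals}
    by_offspring = {a.offspring_id: a for a in assignments}
    rows = []
    cross_rows = []
    tot_seed = tot_same = tot_other = 0
    for site in ds.sites:
        sid = site.site_id
        seedlings = ds.individuals_at(sid, "seedling")
        adults = ds.individuals_at(sid, "adult")
        same = other = 0
        for s in seedlings:
            a = by_offspring.get(s.id)
            if a is None or a.parent_id is None:
                continue
            if a.same_site:
                same += 1
            else:
                other += 1
                parent = ind_map[a.parent_id]
                cross_rows.append({
                    "progeny_id": s.id,
                    "progeny_cover": site.forest_cover,
                    "parent_id": parent.id,
                    "parent_cover": site_map[parent.site_id].forest_cover,
                    "pp": a.pp,
                    "distance_km": (a.geneflow_distance or 0.0) / 1000.0,
                })
        rows.append({
            "site_id": sid, "forest_cover": site.forest_cover,
            "adults": len(adults), "seedlings": len(seedlings),
            "assigned_same_landscape": same,
            "assigned_other_landscape": other,
            "assigned_total": same + other,
        })
        tot_seed += len(seedlings)
        tot_same += same
        tot_other += other
    counts = pd.DataFrame(rows)
    crossings = pd.DataFrame(cross_rows, columns=[
        "progeny_id", "progeny_cover", "parent_id", "parent_cover", "pp",
        "distance_km"])
    assigned = tot_same + tot_other
    percent = round(100.0 * assigned / tot_seed, 2) if tot_seed else 0.0
    return counts, crossings, percent


def landscape_battery(counts: pd.DataFrame, n_rand: int = 4999,
                      seed: int | None = None) -> pd.DataFrame:
    """All presence/proportion GLMs with parametric and Monte Carlo p.

    ``counts`` must carry the per-site columns produced by
    :func:`summarize_assignments` (forest_cover, seedlings,
    assigned_same_landscape, assigned_other_landscape, assigned_total).
    Seeds fan out deterministically per test.
    """
    covers = counts["forest_cover"].to_numpy(dtype=float)
    totals = counts["seedlings"].to_numpy(dtype=float)
    series = {
        "overall": counts["assigned_total"].to_numpy(dtype=float),
        "same_landscape": counts["assigned_same_landscape"].to_numpy(dtype=float),
        "other_landscape": counts["assigned_other_landscape"].to_numpy(dtype=float),
    }
    ss = np.random.SeedSequence(seed)
    seeds = iter(s.generate_state(1)[0] for s in ss.spawn(6))
    rows = []
    for name, successes in series.items():
        presence = (successes > 0).astype(float)
        g = glm_binomial_presence(presence, covers)
        mc = mc_glm_deviance_test(presence, None, covers, n_rand=n_rand,
                                  seed=int(next(seeds)))
        rows.append({
            "test": f"presence_{name}", "slope": g.slope,
            "deviance": g.deviance, "p_parametric": g.p, "p_mc": mc.p,
            "separation": g.separation_flag, "n_rand": n_rand,
        })
        g = glm_binomial_proportion(successes, totals, covers)
        mc = mc_glm_deviance_test(successes, totals, covers, n_rand=n_rand,
                                  seed=int(next(seeds)))
        rows.append({
            "test": f"proportion_{name}", "slope": g.slope,
            "deviance": g.deviance, "p_parametric": g.p, "p_mc": mc.p,
            "separation": g.separation_flag, "n_rand": n_rand,
        })
    return pd.DataFrame(rows)
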