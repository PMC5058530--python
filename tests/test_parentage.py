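import dataclasses
import math

import numpy as np
import pytest

from palmflow.genodata import (
    AlleleFreqTable,
    Genotype,
    IndividualRecord,
    LocusDef,
    SiteRecord,
    StudyDataset,
    allele_frequencies,
)
from palmflow.parentage import (
    LOD_FLOOR,
    CriticalDelta,
    assign_parents,
    assignments_to_dataframe,
    combined_pi,
    delta_statistic,
    exclusion_mismatches,
    lod_single_parent,
    paternity_index,
    paternity_probability,
    simulate_critical_delta,
)
from palmflow.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture
def freqs_half():
    return AlleleFreqTable({"L1": {1: 0.5, 2: 0.5}})


# -- LOD ---------------------------------------------------------------------

def test_lod_exclusion_hits_floor(freqs_half):
    off = Genotype({"L1": (1, 1)})
    cand = Genotype({"L1": (2, 2)})
    assert lod_single_parent(off, cand, freqs_half, error_rate=0.0) == LOD_FLOOR


def test_lod_uninformative_zero(freqs_half):
    # candidate AA, offspring AB: T = 0.5 * 1 * p_B..., equals P(g_o) here
    off = Genotype({"L1": (1, 2)})
    cand = Genotype({"L1": (1, 1)})
    assert lod_single_parent(off, cand, freqs_half, error_rate=0.0) == \
        pytest.approx(0.0)


def enumeration_lod_oracle(off_pair, cand_pair, p, e):
    """Independent oracle: enumerate candidate transmissions explicitly and
    blend with the mistyping model."""
    alleles = list(p)
    # P(offspring) under HW
    def hw(pair):
        a, b = pair
        return p[a] ** 2 if a == b else 2 * p[a] * p[b]
    # T: candidate passes each of its alleles w.p. 1/2; the other parental
    # allele is an independent draw from the population
    T = 0.0
    for t in cand_pair:
        for other in alleles:
            produced = tuple(sorted((t, other)))
            if produced == tuple(sorted(off_pair)):
                T += 0.5 * p[other]
    P = hw(off_pair)
    keep = (1 - e) ** 2
    T_star = keep * T + (1 - keep) * P
    return math.log(T_star / P)


@pytest.mark.parametrize("off,cand,e", [
    ((1, 2), (1, 1), 0.0),
    ((1, 2), (1, 2), 0.0),
    ((1, 1), (1, 2), 0.01),
    ((2, 2), (1, 2), 0.05),
    ((1, 2), (2, 2), 0.01),
])
def test_lod_matches_enumeration_oracle(off, cand, e):
    p = {1: 0.3, 2: 0.7}
    freqs = AlleleFreqTable({"L1": p})
    got = lod_single_parent(Genotype({"L1": off}), Genotype({"L1": cand}),
                            freqs, error_rate=e)
    assert got == pytest.approx(enumeration_lod_oracle(off, cand, p, e))


def test_lod_missing_locus_contributes_zero(freqs_half):
    off = Genotype({"L1": (0, 0)})
    cand = Genotype({"L1": (1, 1)})
    assert lod_single_parent(off, cand, freqs_half) == 0.0


def test_lod_unknown_allele_errors():
    freqs = AlleleFreqTable({"L1": {1: 1.0}})
    with pytest.raises(KeyError):
        lod_single_parent(Genotype({"L1": (1, 3)}), Genotype({"L1": (1, 1)}),
                          freqs)


def test_lod_bad_error_rate(freqs_half):
    with pytest.raises(ValueError):
        lod_single_parent(Genotype({"L1": (1, 1)}), Genotype({"L1": (1, 1)}),
                          freqs_half, error_rate=1.0)


# -- delta -------------------------------------------------------------------

def test_delta_two_positive():
    assert delta_statistic([5.2, 3.1]) == pytest.approx(2.1)


def test_delta_single_positive():
    assert delta_statistic([4.0, -1.0, -2.0]) == pytest.approx(4.0)


def test_delta_none_positive():
    assert delta_statistic([-0.5, 0.0]) is None
    assert delta_statistic([]) is None


# -- exclusion ---------------------------------------------------------------

def test_exclusion_counts():
    off = Genotype({"L1": (1, 2), "L2": (1, 2)})
    assert exclusion_mismatches(off, Genotype({"L1": (3, 4), "L2": (1, 3)})) == 1
    assert exclusion_mismatches(off, Genotype({"L1": (1, 3), "L2": (2, 9)})) == 0


def test_exclusion_thirteen_locus_fixture():
    loci = [f"E{k}" for k in range(13)]
    off = Genotype({l: (1, 2) for l in loci})
    cand_calls = {l: (1, 3) for l in loci}
    for bad in ("E3", "E7", "E11"):
        cand_calls[bad] = (5, 6)
    assert exclusion_mismatches(off, Genotype(cand_calls)) == 3


def test_exclusion_skips_missing():
    off = Genotype({"L1": (1, 2), "L2": (0, 0)})
    cand = Genotype({"L1": (0, 0), "L2": (5, 6)})
    assert exclusion_mismatches(off, cand) == 0


def test_exclusion_implies_floor(freqs_half):
    # mismatch at error 0 <=> LOD at the per-locus floor
    off = Genotype({"L1": (1, 1)})
    cand = Genotype({"L1": (2, 2)})
    assert exclusion_mismatches(off, cand) == 1
    assert lod_single_parent(off, cand, freqs_half, error_rate=0.0) == LOD_FLOOR


# -- PI / CPI / PP -----------------------------------------------------------

def test_pi_homozygote_match(freqs_half):
    pis = paternity_index(Genotype({"L1": (1, 1)}), Genotype({"L1": (1, 1)}),
                          freqs_half)
    assert pis == {"L1": pytest.approx(2.0)}


def test_pi_enumeration_oracle():
    # X and Y as explicit transmission enumerations
    p = {1: 0.2, 2: 0.3, 3: 0.5}
    freqs = AlleleFreqTable({"L1": p})
    off = (1, 2)
    cand = (1, 3)
    pis = paternity_index(Genotype({"L1": off}), Genotype({"L1": cand}), freqs)
    X = sum(0.5 for a in cand if a in off)
    Y = sum(p[a] for a in set(off))
    assert pis["L1"] == pytest.approx(X / Y)


def test_pi_excluding_locus_error_blend():
    p = {1: 0.5, 2: 0.5}
    freqs = AlleleFreqTable({"L1": p})
    pis = paternity_index(Genotype({"L1": (1, 1)}), Genotype({"L1": (2, 2)}),
                          freqs, error_rate=0.01)
    assert pis["L1"] == pytest.approx(0.01)
    with pytest.raises(ValueError):
        paternity_probability(combined_pi(
            paternity_index(Genotype({"L1": (1, 1)}), Genotype({"L1": (2, 2)}),
                            freqs, error_rate=0.0)))


def test_cpi_product():
    assert combined_pi({"a": 2.0, "b": 3.0, "c": 0.5}) == pytest.approx(3.0)


def test_pp_prior_identity():
    assert paternity_probability(1.0) == pytest.approx(0.5)
    for cpi in (0.1, 1.0, 7.3, 1e4):
        assert paternity_probability(cpi) == pytest.approx(cpi / (cpi + 1))


def test_pp_published_value_roundtrip():
    pp = 0.998672931
    cpi = pp / (1 - pp)
    assert paternity_probability(cpi, prior=0.5) == pytest.approx(pp, abs=1e-15)


def test_pp_monotone_in_cpi():
    cpis = np.logspace(-3, 3, 25)
    pps = [paternity_probability(c) for c in cpis]
    assert all(a < b for a, b in zip(pps, pps[1:]))


def test_pp_bad_inputs():
    with pytest.raises(ValueError):
        paternity_probability(0.0)
    with pytest.raises(ValueError):
        paternity_probability(1.0, prior=1.0)


# -- critical delta ----------------------------------------------------------

def _rich_freqs(n_loci=6, n_alleles=8, seed=0):
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n_loci):
        f = rng.dirichlet(np.full(n_alleles, 5.0))
        out[f"L{i}"] = {100 + 2 * j: f[j] for j in range(n_alleles)}
    return AlleleFreqTable(out)


def test_critical_delta_deterministic():
    freqs = _rich_freqs()
    a = simulate_critical_delta(freqs, 20, n_sim=400, seed=9)
    b = simulate_critical_delta(freqs, 20, n_sim=400, seed=9)
    assert a == b


def test_critical_delta_zero_confidence():
    freqs = _rich_freqs()
    crit = simulate_critical_delta(freqs, 10, n_sim=200, confidence=0.0,
                                   seed=1)
    assert crit.delta_crit == 0.0


def test_critical_delta_clean_near_zero():
    freqs = _rich_freqs(n_loci=10, n_alleles=10, seed=3)
    crit = simulate_critical_delta(freqs, 10, prop_sampled=1.0,
                                   error_rate=0.0, n_sim=1500,
                                   confidence=0.95, seed=2)
    assert crit.delta_crit < 1.5


def test_critical_delta_requires_candidates():
    with pytest.raises(ValueError):
        simulate_critical_delta(_rich_freqs(), 1, n_sim=10, seed=0)


def test_critical_delta_seed_stability():
    freqs = _rich_freqs(n_loci=8, seed=4)
    crits = [simulate_critical_delta(freqs, 30, prop_sampled=0.5,
                                     error_rate=0.01, n_sim=2000,
                                     seed=s).delta_crit
             for s in range(6)]
    crits = np.array(crits)
    if crits.mean() > 0:
        assert crits.std() / crits.mean() < 0.5


# -- assignment --------------------------------------------------------------

def test_assign_no_adults():
    loci = [LocusDef("L1", (1, 2))]
    sites = [SiteRecord("s1", 0, 0, 50)]
    inds = [IndividualRecord("k1", "s1", "seedling", 0, 0,
                             Genotype({"L1": (1, 2)}))]
    ds = StudyDataset(loci=loci, individuals=inds, sites=sites)
    crit = CriticalDelta(0.0, 0.95, 0, 2, 1.0, 0.0, None)
    out = assign_parents(ds, crit,
                         freqs=AlleleFreqTable({"L1": {1: .5, 2: .5}}))
    assert len(out) == 1
    assert out[0].parent_id is None
    assert out[0].confidence == "unassigned"


def test_assign_duplicate_parent_genotype_withheld(clean_sim):
    cfg, ds, ledger = clean_sim
    # duplicate one true mother's genotype into a new adult: the tie drives
    # delta to 0 and the call must be withheld for that seedling
    e = ledger.entries[0]
    mother = next(i for i in ds.individuals if i.id == e.mother_id)
    clone = IndividualRecord("clone", mother.site_id, "adult",
                             mother.x + 1, mother.y, mother.genotype)
    ds2 = StudyDataset(loci=ds.loci, individuals=ds.individuals + [clone],
                       sites=ds.sites)
    freqs = allele_frequencies(ds2, "all_adults")
    crit = CriticalDelta(0.0, 0.95, 0, 2, 1.0, 0.0, None)
    out = {a.offspring_id: a for a in assign_parents(ds2, crit, freqs=freqs)}
    a = out[e.seedling_id]
    # the clone ties the true mother unless the father scores higher alone
    if a.parent_id is not None:
        assert a.parent_id == e.father_id
    else:
        assert a.delta is None or a.delta == pytest.approx(0.0, abs=1e-9)


def test_assign_recovery_clean(clean_sim):
    cfg, ds, ledger = clean_sim
    freqs = allele_frequencies(ds, "all_adults")
    crit = simulate_critical_delta(
        freqs, n_candidates=len(ds.adults()), prop_sampled=1.0,
        error_rate=0.0, n_sim=1000, confidence=0.95, seed=11)
    out = assign_parents(ds, crit, freqs=freqs)
    truth = ledger.by_seedling()
    assigned = [a for a in out if a.parent_id is not None]
    assert assigned, "no assignments made"
    correct = sum(a.parent_id in (truth[a.offspring_id].mother_id,
                                  truth[a.offspring_id].father_id)
                  for a in assigned)
    assert correct / len(assigned) >= 0.95


def test_assign_distance_conventions(clean_sim):
    cfg, ds, ledger = clean_sim
    freqs = allele_frequencies(ds, "all_adults")
    crit = CriticalDelta(0.0, 0.95, 0, 2, 1.0, 0.0, None)
    ind = {i.id: i for i in ds.individuals}
    smap = ds.site_map()
    for a in assign_parents(ds, crit, freqs=freqs):
        if a.parent_id is None:
            continue
        parent = ind[a.parent_id]
        child = ind[a.offspring_id]
        if a.same_site:
            want = math.hypot(parent.x - child.x, parent.y - child.y)
        else:
            ps, cs = smap[parent.site_id], smap[child.site_id]
            want = math.hypot(ps.centroid_x - cs.centroid_x,
                              ps.centroid_y - cs.centroid_y)
        assert a.geneflow_distance == pytest.approx(want)


def test_assignments_dataframe_columns(clean_sim):
    cfg, ds, _ = clean_sim
    crit = CriticalDelta(0.0, 0.95, 0, 2, 1.0, 0.0, None)
    df = assignments_to_dataframe(assign_parents(ds, crit))
    assert list(df.columns) == [
        "offspring_id", "parent_id", "lod", "delta", "confidence",
        "mismatches", "cpi", "pp", "distance_m", "same_site"]
    assert len(df) == len(ds.seedlings())
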