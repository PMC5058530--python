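import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palmflow import tables
from palmflow.genodata import (
    MISSING,
    AlleleFreqTable,
    Genotype,
    IndividualRecord,
    LocusDef,
    ParseError,
    SiteRecord,
    Stage,
    StudyDataset,
    ValidationError,
    allele_frequencies,
    filter_sites_min_count,
    load_genotypes,
    load_site_table,
    save_genotypes,
    save_site_table,
)
from palmflow.synthetic_data import SimulationConfig, simulate_dataset


def test_genotype_half_call_rejected():
    with pytest.raises(ValidationError):
        Genotype({"L1": (1, MISSING)})


def test_genotype_pair_order_insensitive():
    assert Genotype({"L1": (2, 1)}) == Genotype({"L1": (1, 2)})


def test_locusdef_requires_alleles():
    with pytest.raises(ValidationError):
        LocusDef("L1", ())


def test_site_cover_bounds():
    with pytest.raises(ValidationError):
        SiteRecord("s1", 0, 0, 101.0)


def test_dataset_rejects_unknown_site():
    with pytest.raises(ValidationError):
        StudyDataset(
            loci=[LocusDef("L1", (1,))],
            individuals=[IndividualRecord("i1", "nowhere", "adult", 0, 0,
                                          Genotype({"L1": (1, 1)}))],
            sites=[SiteRecord("s1", 0, 0, 50)])


# -- CSV dialect -------------------------------------------------------------

def test_csv_roundtrip_with_missing(tmp_path):
    ds = StudyDataset(
        loci=[LocusDef("EE8", (100, 104)), LocusDef("EE23", (90, 92))],
        individuals=[
            IndividualRecord("a1", "s1", "adult", 1.0, 2.0,
                             Genotype({"EE8": (100, 104),
                                       "EE23": (MISSING, MISSING)})),
            IndividualRecord("a2", "s1", "seedling", 3.0, 4.0,
                             Genotype({"EE8": (104, 104), "EE23": (90, 92)})),
        ],
        sites=[SiteRecord("s1", 0, 0, 50)])
    path = tmp_path / "g.csv"
    save_genotypes(ds, path, dialect="csv")
    loci, individuals = load_genotypes(path, dialect="csv")
    assert len(individuals) == 2
    n_missing = sum(ind.genotype.is_missing(l.name)
                    for ind in individuals for l in loci)
    assert n_missing == 1
    assert individuals[0].genotype == ds.individuals[0].genotype
    assert individuals[1].stage is Stage.SEEDLING
    assert individuals[1].x == 3.0


def test_csv_duplicate_id_rejected(tmp_path):
    path = tmp_path / "g.csv"
    path.write_text(
        "individual_id,site_id,stage,x,y,L1.a1,L1.a2\n"
        "i1,s1,adult,0,0,1,2\n"
        "i1,s1,adult,0,0,1,2\n")
    with pytest.raises(ValidationError):
        load_genotypes(path, dialect="csv")


def test_csv_malformed_allele_names_line(tmp_path):
    path = tmp_path / "g.csv"
    path.write_text(
        "individual_id,site_id,stage,x,y,L1.a1,L1.a2\n"
        "i1,s1,adult,0,0,xx,2\n")
    with pytest.raises(ParseError, match="line 2"):
        load_genotypes(path, dialect="csv")


# -- GenePop dialect ---------------------------------------------------------

def test_genepop_roundtrip(tmp_path, two_site_dataset):
    gpath, mpath = tmp_path / "d.gen", tmp_path / "meta.csv"
    save_genotypes(two_site_dataset, gpath, dialect="genepop", meta_path=mpath)
    loci, individuals = load_genotypes(gpath, dialect="genepop",
                                       meta_path=mpath)
    assert [l.name for l in loci] == two_site_dataset.locus_names
    assert len(individuals) == len(two_site_dataset.individuals)
    for got, want in zip(individuals, two_site_dataset.individuals):
        assert got.id == want.id
        assert got.genotype == want.genotype
        assert got.site_id == want.site_id
        assert got.stage == want.stage
        assert got.x == pytest.approx(want.x)


def test_genepop_missing_coding(tmp_path):
    path = tmp_path / "d.gen"
    path.write_text("title\nL1\nL2\nPop\nind1 ,  000000 100102\n")
    loci, individuals = load_genotypes(path, dialect="genepop")
    assert individuals[0].genotype.is_missing("L1")
    assert individuals[0].genotype["L2"] == (100, 102)


def test_genepop_malformed_field(tmp_path):
    path = tmp_path / "d.gen"
    path.write_text("title\nL1\nPop\nind1 ,  12345\n")
    with pytest.raises(ParseError):
        load_genotypes(path, dialect="genepop")


@settings(max_examples=25, deadline=None)
@given(st.lists(
    st.tuples(st.integers(1, 99), st.integers(1, 99)), min_size=1, max_size=8))
def test_genepop_roundtrip_property(tmp_path_factory, pairs):
    tmp = tmp_path_factory.mktemp("gp")
    individuals = [
        IndividualRecord(f"i{k}", "s1", "adult", float(k), 0.0,
                         Genotype({"L1": pair}))
        for k, pair in enumerate(pairs)]
    loci = [LocusDef("L1", tuple(sorted({a for p in pairs for a in p})))]
    ds = StudyDataset(loci=loci, individuals=individuals,
                      sites=[SiteRecord("s1", 0, 0, 50)])
    g, m = tmp / "d.gen", tmp / "m.csv"
    save_genotypes(ds, g, dialect="genepop", meta_path=m)
    _, got = load_genotypes(g, dialect="genepop", meta_path=m)
    assert [i.genotype for i in got] == [i.genotype for i in individuals]


def test_synthetic_roundtrip_allele_counts(tmp_path, default_sim):
    cfg, ds, ledger = default_sim
    path = tmp_path / "g.csv"
    save_genotypes(ds, path, dialect="csv")
    loci, individuals = load_genotypes(path, dialect="csv")
    want = {}
    for ind in ds.individuals:
        for locus, pair in ind.genotype.items():
            if pair[0] != MISSING:
                for a in pair:
                    want[(locus, a)] = want.get((locus, a), 0) + 1
    got = {}
    for ind in individuals:
        for locus, pair in ind.genotype.items():
            if pair[0] != MISSING:
                for a in pair:
                    got[(locus, a)] = got.get((locus, a), 0) + 1
    assert got == want


# -- site table --------------------------------------------------------------

def test_packaged_site_table():
    sites = load_site_table(tables.packaged_sites_path())
    assert len(sites) == 9
    assert sorted(s.forest_cover for s in sites) == [19, 28, 34, 43, 50, 59,
                                                     63, 70, 83]


def test_site_table_empty_file(tmp_path):
    path = tmp_path / "s.csv"
    path.write_text("")
    assert load_site_table(path) == []


def test_site_table_duplicate_id(tmp_path):
    path = tmp_path / "s.csv"
    path.write_text("site_id,centroid_x,centroid_y,forest_cover\n"
                    "s1,0,0,50\ns1,1,1,60\n")
    with pytest.raises(ValidationError):
        load_site_table(path)


def test_site_table_cover_out_of_range(tmp_path):
    path = tmp_path / "s.csv"
    path.write_text("site_id,centroid_x,centroid_y,forest_cover\ns1,0,0,150\n")
    with pytest.raises(ValidationError):
        load_site_table(path)


def test_site_table_roundtrip(tmp_path):
    sites = [SiteRecord("a", 0, 0, 10.0), SiteRecord("b", 100, 0, 90.0)]
    path = tmp_path / "s.csv"
    save_site_table(sites, path)
    assert load_site_table(path) == sites


# -- filtering ---------------------------------------------------------------

def _dataset_with_counts(counts):
    """counts: {site: (n_adults, n_seedlings)}"""
    loci = [LocusDef("L1", (1, 2))]
    sites, individuals = [], []
    for j, (sid, (na, ns)) in enumerate(counts.items()):
        sites.append(SiteRecord(sid, float(j * 1000), 0.0, 50.0))
        for stage, n in (("adult", na), ("seedling", ns)):
            for i in range(n):
                individuals.append(IndividualRecord(
                    f"{sid}_{stage}_{i}", sid, stage, float(i), 0.0,
                    Genotype({"L1": (1, 2)})))
    return StudyDataset(loci=loci, individuals=individuals, sites=sites)


def test_filter_drops_below_threshold():
    ds = _dataset_with_counts({"ok": (10, 5), "low": (10, 4)})
    log = []
    out = filter_sites_min_count(ds, 5, log=log)
    assert [s.site_id for s in out.sites] == ["ok"]
    assert log == ["low"]
    assert all(i.site_id == "ok" for i in out.individuals)


def test_filter_identity_when_all_pass():
    ds = _dataset_with_counts({"a": (5, 5), "b": (6, 7)})
    out = filter_sites_min_count(ds, 5)
    assert out.sites == ds.sites
    assert [i.id for i in out.individuals] == [i.id for i in ds.individuals]


def test_filter_idempotent():
    ds = _dataset_with_counts({"a": (5, 5), "b": (3, 9), "c": (9, 9)})
    once = filter_sites_min_count(ds, 5)
    twice = filter_sites_min_count(once, 5)
    assert [s.site_id for s in once.sites] == [s.site_id for s in twice.sites]
    assert [i.id for i in once.individuals] == [i.id for i in twice.individuals]


def test_filter_synthetic_undersampled_site():
    cfg = SimulationConfig(n_sites=3, covers=(20.0, 50.0, 80.0),
                           adults_per_site=(10, 10, 10),
                           seedlings_per_site=(8, 3, 8),
                           n_loci=4, alleles_per_locus=4, seed=2)
    ds, _ = simulate_dataset(cfg)
    out = filter_sites_min_count(ds, 5)
    assert [s.site_id for s in out.sites] == ["s1", "s3"]
    kept = {i.id for i in out.individuals}
    assert kept == {i.id for i in ds.individuals if i.site_id != "s2"}


# -- allele frequencies ------------------------------------------------------

def test_allele_frequencies_counting():
    loci = [LocusDef("L1", (1, 2))]
    sites = [SiteRecord("s1", 0, 0, 50)]
    inds = [
        IndividualRecord("a1", "s1", "adult", 0, 0, Genotype({"L1": (1, 1)})),
        IndividualRecord("a2", "s1", "adult", 1, 0, Genotype({"L1": (1, 2)})),
        IndividualRecord("s", "s1", "seedling", 2, 0, Genotype({"L1": (2, 2)})),
    ]
    ds = StudyDataset(loci=loci, individuals=inds, sites=sites)
    f = allele_frequencies(ds, "all_adults")
    assert f.freq("L1", 1) == pytest.approx(0.75)
    assert f.freq("L1", 2) == pytest.approx(0.25)
    f_all = allele_frequencies(ds, "all_individuals")
    assert f_all.freq("L1", 1) == pytest.approx(0.5)


def test_allele_frequencies_all_missing_errors():
    loci = [LocusDef("L1", (1,))]
    sites = [SiteRecord("s1", 0, 0, 50)]
    inds = [IndividualRecord("a1", "s1", "adult", 0, 0,
                             Genotype({"L1": (MISSING, MISSING)}))]
    ds = StudyDataset(loci=loci, individuals=inds, sites=sites)
    with pytest.raises(ValidationError, match="L1"):
        allele_frequencies(ds, "all_adults")


def test_allele_frequencies_sum_and_order_invariance(default_sim):
    cfg, ds, _ = default_sim
    f = allele_frequencies(ds, "all_adults")
    for locus in f.loci:
        assert sum(f.table(locus).values()) == pytest.approx(1.0, abs=1e-9)
    shuffled = StudyDataset(loci=ds.loci,
                            individuals=list(reversed(ds.individuals)),
                            sites=ds.sites)
    g = allele_frequencies(shuffled, "all_adults")
    assert f.as_dict() == g.as_dict()


def test_synthetic_frequencies_close_to_founder():
    cfg = SimulationConfig(n_sites=2, covers=(30.0, 70.0),
                           adults_per_site=300, seedlings_per_site=5,
                           n_loci=3, alleles_per_locus=4, seed=5)
    ds, _ = simulate_dataset(cfg)
    rng = np.random.default_rng(cfg.seed)
    founder = {f"L{i+1:02d}": rng.dirichlet(np.ones(4)) for i in range(3)}
    f = allele_frequencies(ds, "all_adults")
    for i, locus in enumerate(f.loci):
        labels = [100 + 2 * j for j in range(4)]
        got = np.array([f.table(locus).get(a, 0.0) for a in labels])
        assert np.abs(got - founder[locus]).max() < 0.06


def test_packaged_count_and_geneflow_tables():
    counts = tables.load_site_counts()
    assert counts["adults"].sum() == 246
    assert counts["seedlings"].sum() == 271
    assert counts["assigned_total"].sum() == 21
    assert counts["assigned_same_landscape"].sum() == 16
    assert counts["assigned_other_landscape"].sum() == 5
    records = tables.load_geneflow_records()
    assert len(records) == 5
    assert records["distance_km"].max() == 13
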