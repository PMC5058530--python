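import numpy as np
import pytest

from palmflow.genodata import (
    AlleleFreqTable,
    Genotype,
    IndividualRecord,
    LocusDef,
    SiteRecord,
    StudyDataset,
)
from palmflow.synthetic_data import SimulationConfig, simulate_dataset


def make_individual(ident, a, b, locus="L1", site="s1", stage="adult",
                    x=0.0, y=0.0):
    return IndividualRecord(id=str(ident), site_id=site, stage=stage, x=x, y=y,
                            genotype=Genotype({locus: (a, b)}))


@pytest.fixture
def biallelic_freqs():
    return AlleleFreqTable({"L1": {1: 0.5, 2: 0.5}})


@pytest.fixture
def two_site_dataset():
    """Tiny handcrafted dataset: 2 sites, 1 locus, mixed stages."""
    loci = [LocusDef("L1", (1, 2, 3))]
    sites = [SiteRecord("s1", 0.0, 0.0, 25.0),
             SiteRecord("s2", 5000.0, 0.0, 75.0)]
    individuals = []
    k = 0
    for site, n_adult, n_seed in (("s1", 6, 6), ("s2", 6, 6)):
        for stage, n in (("adult", n_adult), ("seedling", n_seed)):
            for i in range(n):
                k += 1
                individuals.append(IndividualRecord(
                    id=f"i{k}", site_id=site, stage=stage,
                    x=float(10 * i), y=0.0,
                    genotype=Genotype({"L1": (1 + (k % 2), 2 + (k % 2))})))
    return StudyDataset(loci=loci, individuals=individuals, sites=sites)


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free simulation with all parents sampled, no cross-site flow."""
    cfg = SimulationConfig(
        n_sites=3, covers=(20.0, 50.0, 80.0), adults_per_site=20,
        seedlings_per_site=15, n_loci=10, alleles_per_locus=8,
        error_rate=0.0, prop_parents_sampled=1.0,
        cross_site_threshold_m=1e12, seed=101)
    return cfg, *simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_sim():
    cfg = SimulationConfig(
        n_sites=4, covers=(19.0, 43.0, 63.0, 83.0), adults_per_site=15,
        seedlings_per_site=12, n_loci=8, alleles_per_locus=6, seed=7)
    return cfg, *simulate_dataset(cfg)
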