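import numpy as np
import pandas as pd
import pytest

from kinselect.datamodel import make_variant_table
from kinselect import sim

#: deer-like multi-chromosome karyotype used by recovery fixtures — ten
#: 50-Mb autosomes so realized IBD/autozygosity has modest variance.
DEER_CHROMS = {f"chr{i}": 50_000_000 for i in range(1, 11)}


@pytest.fixture(scope="session")
def snp_map_10k():
    """1 SNP / 10 kb over a single 100-Mb chromosome."""
    n = 10_000
    return make_variant_table(["chr1"] * n, np.arange(1, n + 1) * 10_000)


@pytest.fixture(scope="session")
def two_pop_freqs():
    """Balding-Nichols frequencies for two subpopulations at FST 0.2."""
    cfg = sim.SimConfig(n_variants=5000, fst=0.2, seed=42)
    rng = np.random.default_rng(42)
    anc, freqs = sim.draw_subpop_frequencies(cfg, rng)
    return anc, freqs


@pytest.fixture(scope="session")
def two_pop_cohort(two_pop_freqs):
    """40 unrelated samples, 20 from each diverged subpopulation."""
    _, freqs = two_pop_freqs
    rng = np.random.default_rng(7)
    g = np.vstack(
        [sim.population_sample(freqs[0], 20, rng), sim.population_sample(freqs[1], 20, rng)]
    )
    labels = ["A"] * 20 + ["B"] * 20
    return g, labels


@pytest.fixture(scope="session")
def sib_cohort():
    """50 full-sib families in one cohort with realized-IBD truth."""
    ped = []
    for i in range(50):
        ped += sim.ped_full_sibs(f"fam{i}")
    cfg = sim.SimConfig(
        chrom_lengths=DEER_CHROMS, n_variants=10_000, pedigree=ped, seed=11
    )
    return sim.gene_drop(cfg)


@pytest.fixture(scope="session")
def demo_dataset():
    """The shipped demo scenario (bottlenecked + outbred herds + hybrids)."""
    return sim.gene_drop(sim.demo_config(seed=17))
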