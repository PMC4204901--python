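import numpy as np
import pandas as pd
import pytest

from pcx.meth_calls import MethylationTable
from pcx.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_config():
    """A small but complete study design: 4 genotypes x 2 timepoints."""
    return SimulationConfig(
        seed=0, n_genes=60, n_prc2_targets=24, genome_length=3_000_000,
        cpg_density=2.0, reads_per_sample=40_000)


@pytest.fixture(scope="session")
def cohort(tiny_config):
    return simulate_cohort(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_meth_table(rng, n=200, samples=("a",), chrom="chr1",
                      max_cov=40) -> MethylationTable:
    pos = np.sort(rng.choice(10 * n, size=n, replace=False))
    counts = {}
    for s in samples:
        cov = rng.integers(0, max_cov, size=n)
        meth = rng.binomial(cov, rng.random(n))
        counts[s] = (cov, meth)
    return MethylationTable.from_counts([chrom] * n, pos, counts)
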