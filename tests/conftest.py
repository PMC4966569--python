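import numpy as np
import pandas as pd
import pytest

from niebtools.catalog import NiebCatalog
from niebtools.core import IntervalSet


def make_catalog(records):
    """Catalog from (chrom, start, end) tuples."""
    return NiebCatalog(IntervalSet(
        pd.DataFrame(records, columns=["chrom", "start", "end"])))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_catalog():
    return make_catalog([("chr1", 1000, 1150), ("chr1", 2500, 2700),
                         ("chr1", 5000, 5100), ("chr2", 800, 950)])


@pytest.fixture
def synthetic_run(rng):
    """A small end-to-end synthetic genome with catalog and divergence data."""
    from niebtools.simulate import SyntheticTruth, generate_genomes, simulate_divergence
    truth = SyntheticTruth()
    genome, catalog = generate_genomes(truth, {"chr1": 400_000}, seed=7)
    sim = simulate_divergence(truth, genome, catalog, np.random.default_rng(8))
    return truth, genome, catalog, sim
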