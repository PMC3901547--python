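import datetime as dt

import numpy as np
import pytest

from serialabc import GenerationClock, mongola_design, punta_europa_rainfall
from serialabc.synthetic import tiny_fixture


@pytest.fixture(scope="session")
def design():
    return mongola_design()

@pytest.fixture(scope="session")
def clock(design):
    return GenerationClock(18.0, design.sample_dates[-1])

@pytest.fixture(scope="session")
def rainfall():
    return punta_europa_rainfall()

@pytest.fixture()
def rng():
    return np.random.default_rng(12345)

@pytest.fixture()
def tiny():
    return tiny_fixture()


def random_small_dataset(rng, n_groups=None):
    """A random small dataset (with occasional missing genotypes) for
    oracle comparisons."""
    from serialabc.dataset import SampleGroup, TemporalGenotypeDataset

    n_groups = n_groups or rng.integers(2, 4)
    n_loci = int(rng.integers(1, 4))
    groups = []
    for g in range(int(n_groups)):
        n = int(rng.integers(2, 8))
        geno = rng.integers(1, 8, size=(n, n_loci, 2))
        # sprinkle missing genotypes, but keep >= 2 typed individuals per
        # locus so small-sample estimators stay defined
        miss = rng.random((n, n_loci)) < 0.1
        miss[:2, :] = False
        geno[miss] = 0
        groups.append(
            SampleGroup(date=dt.date(2009, 1, 1) + dt.timedelta(days=30 * g), genotypes=geno)
        )
    return TemporalGenotypeDataset(groups=groups)
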