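import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def tiny_site_table() -> pd.DataFrame:
    """Two strains, four CpG sites with assorted coverage."""
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "pos": [3, 10, 21, 30],
            "strand": ["+"] * 4,
            "context": ["CG"] * 4,
            "b6.mc": [8, 0, 1, 3],
            "b6.cov": [10, 8, 10, 4],
            "d2.mc": [9, 0, 0, 2],
            "d2.cov": [10, 9, 10, 5],
        }
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic bundle shared across tests."""
    from cpgdm import synthio

    config = synthio.SyntheticConfig(
        density_spectrum=tuple((float(d), 12) for d in (10, 30, 60, 100)),
        n_chroms=2,
    )
    return synthio.simulate_all(config, seed=11)


@pytest.fixture(scope="session")
def small_called(small_bundle):
    from cpgdm import segmetrics

    seg = small_bundle.reference.segments
    sites = segmetrics.assign_sites_to_segments(small_bundle.site_table, seg)
    return segmetrics.add_calls(sites)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
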