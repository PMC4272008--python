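import numpy as np
import pandas as pd
import pytest

from sccnv.genome import BinMap
from sccnv.simulate import hg19_like_binmap


@pytest.fixture(scope="session")
def hg_map():
    """hg19-proportioned 6,000-bin map with centromeres and arms (seed 1)."""
    return hg19_like_binmap(6000, seed=1)


@pytest.fixture(scope="session")
def hg_map_small():
    """Coarse 1,500-bin variant for cheaper multi-sample experiments."""
    return hg19_like_binmap(1500, seed=1)


def toy_binmap(n_bins=30, bin_size=460_000, chrom="chr1", gc=0.4):
    """Uniform single-chromosome bin map for hand-built examples."""
    df = pd.DataFrame({
        "chrom": [chrom] * n_bins,
        "start": np.arange(n_bins) * bin_size,
        "end": (np.arange(n_bins) + 1) * bin_size,
        "n_mappable": 100,
        "gc": gc,
    })
    return BinMap(df, read_length=50, total_bins_requested=n_bins)


@pytest.fixture
def small_binmap():
    return toy_binmap()
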