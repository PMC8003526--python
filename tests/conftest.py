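import numpy as np
import pytest

from ctmtf.estimator import uniform_reference
from ctmtf.genome import build_genome_bins
from ctmtf.simulate import default_cell_lines


@pytest.fixture(scope="session")
def genome():
    """The full bundled hg19-like tiling (1 Mb windows, chr1-22 + chrX)."""
    return build_genome_bins()


@pytest.fixture(scope="session")
def mini_genome():
    """A small 3-chromosome tiling for fast unit tests (43 bins)."""
    sizes = {"chr1": 20_000_000, "chr2": 15_500_000, "chr19": 8_000_000}
    return build_genome_bins(sizes, window=1_000_000)


@pytest.fixture(scope="session")
def cell_lines(genome):
    return default_cell_lines(genome)


@pytest.fixture(scope="session")
def reference(genome):
    return uniform_reference(genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(20210409)
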