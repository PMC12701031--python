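import numpy as np
import pytest

from recmap.genmap import GeneticMap


@pytest.fixture
def uniform_map() -> GeneticMap:
    """11 markers at 1 Mb spacing, uniform 1 cM/Mb."""
    pos = np.arange(11) * 1_000_000 + 1
    return GeneticMap("chr1", pos, np.arange(11, dtype=float),
                      chromosome_length=10_000_001)


@pytest.fixture
def three_marker_map() -> GeneticMap:
    """Markers at 1, 1000001, 2000001 bp with cM 0, 1, 3 (rates 1 and 2)."""
    return GeneticMap("chr1", [1, 1_000_001, 2_000_001], [0.0, 1.0, 3.0])


def random_map(rng: np.random.Generator, n_markers: int = 50,
               chrom: str = "chr1", length: int = 5_000_000) -> GeneticMap:
    pos = np.unique(rng.integers(1, length, size=n_markers))
    rates = rng.gamma(0.5, 2.0, size=len(pos) - 1)
    cm = np.concatenate([[0.0], np.cumsum(rates * np.diff(pos) / 1e6)])
    return GeneticMap(chrom, pos, cm, chromosome_length=length)
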