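import numpy as np
import pytest

from meiodyn.genome_model import GenomeLayout, GenomicInterval, PeakSet
from meiodyn.synthetic_data import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def layout():
    return GenomeLayout({"chr1": 100_000, "chr2": 80_000})


@pytest.fixture(scope="session")
def bundle():
    """One full simulator bundle shared by the suite (seeded)."""
    return simulate_bundle(SimConfig(seed=11))


def random_peakset(rng: np.random.Generator, layout: GenomeLayout,
                   n: int = 30, max_width: int = 2000) -> PeakSet:
    ivs = []
    for _ in range(n):
        chrom = str(rng.choice(layout.chroms))
        w = int(rng.integers(50, max_width))
        s = int(rng.integers(0, layout[chrom] - w))
        ivs.append(GenomicInterval(chrom, s, s + w))
    return PeakSet(ivs, layout)
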