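import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hormonesig.intervals import GenomicInterval, IntervalSet
from hormonesig.simulate import GenomeLayout

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_layout():
    return GenomeLayout(["chr1", "chr2"], {"chr1": 100_000, "chr2": 80_000})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_interval_set(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=500):
    ivs = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(ivs)


def brute_force_covered(interval_set):
    """Per-base mark-up of covered positions, the merge oracle."""
    covered = {}
    for iv in interval_set:
        covered.setdefault(iv.chrom, set()).update(range(iv.start, iv.end))
    return covered
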