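import numpy as np
import pytest

from cobindscan.genomic_io import CoverageTrack, GenomeLayout, Peak


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def layout():
    return GenomeLayout({"chr1": 1_000_000, "chr2": 500_000})


def make_random_peaks(rng, n, chrom="chr1", span=1_000_000, width=400, name_prefix="p"):
    """Unsorted random peaks with distinct summits."""
    summits = rng.choice(np.arange(width, span - width), size=n, replace=False)
    peaks = []
    for i, s in enumerate(summits):
        s = int(s)
        peaks.append(
            Peak(chrom, s - width // 2, s + width // 2, s,
                 float(rng.lognormal(4, 1)), float(rng.uniform(5, 50)),
                 name=f"{name_prefix}{i}")
        )
    return peaks


def make_random_track(rng, n_runs=50, chrom="chr1", span=100_000, max_value=5.0):
    """A random piecewise-constant track with gaps."""
    bounds = np.sort(rng.choice(np.arange(1, span), size=2 * n_runs, replace=False))
    starts, ends = bounds[::2], bounds[1::2]
    values = rng.uniform(0, max_value, size=n_runs)
    return CoverageTrack({chrom: (starts, ends, values)})


def per_base_sum(track, chrom, start, end):
    """Brute-force per-base oracle for interval coverage sums."""
    total = 0.0
    starts, ends, values, _ = track._runs[chrom]
    for pos in range(start, end):
        for s, e, v in zip(starts, ends, values):
            if s <= pos < e:
                total += v
                break
    return total
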