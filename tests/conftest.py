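import numpy as np
import pytest

from entroseg.objectives import Histogram, N_BINS


def make_hist(counts) -> Histogram:
    """Histogram from a dense length-256 count array or {bin: count} mapping."""
    arr = np.zeros(N_BINS, dtype=np.int64)
    if isinstance(counts, dict):
        for b, c in counts.items():
            arr[b] = c
    else:
        c = np.asarray(counts, dtype=np.int64)
        arr[: c.size] = c
    return Histogram.from_counts(arr)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_support_hist(rng):
    """Random histogram supported on bins 0..15 (exhaustively enumerable)."""
    counts = rng.integers(1, 50, size=16)
    return make_hist(counts)
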