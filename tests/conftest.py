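import numpy as np
import pytest
from hypothesis import settings
from numpy.lib.stride_tricks import sliding_window_view

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def naive_contrast(arr: np.ndarray, window: int) -> np.ndarray:
    """Independent per-window contrast oracle: explicit neighborhoods via
    sliding windows over a symmetric-padded frame, population std / mean."""
    pad = window // 2
    padded = np.pad(np.asarray(arr, dtype=np.float64), pad, mode="symmetric")
    win = sliding_window_view(padded, (window, window))
    mean = win.mean(axis=(-1, -2))
    std = win.std(axis=(-1, -2))          # population flavor (ddof=0)
    out = np.zeros_like(mean)
    np.divide(std, mean, out=out, where=mean > 0)
    return out


@pytest.fixture(scope="session")
def naive_contrast_fn():
    return naive_contrast


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
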