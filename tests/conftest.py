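import numpy as np
import pytest

from tapddk import DisplacementCurve, RunConfig


@pytest.fixture
def config():
    return RunConfig()


def sinusoid_curve(freq_hz: float, duration: float, fs: float,
                   noise_sd: float = 0.0, seed: int = 0) -> DisplacementCurve:
    """Raw aperture oscillating at freq_hz: peaks = full opening."""
    t = np.arange(int(round(duration * fs))) / fs
    v = 50.0 * (1 - np.cos(2 * np.pi * freq_hz * t)) / 2.0
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0, noise_sd * 50.0, len(t))
        v = v - v.min()  # keep the raw curve non-negative
    return DisplacementCurve(t, v, normalized=False)


def local_maxima_oracle(values: np.ndarray) -> np.ndarray:
    """Exhaustive local-maximum scan, independent of scipy peak picking.

    Plateau-aware: a run of equal samples rising on the left and falling on
    the right counts as one maximum (its first sample).
    """
    idx = []
    n = len(values)
    i = 1
    while i < n - 1:
        if values[i] > values[i - 1]:
            j = i
            while j + 1 < n and values[j + 1] == values[j]:
                j += 1
            if j < n - 1 and values[j + 1] < values[j]:
                idx.append(i)
            i = j + 1
        else:
            i += 1
    return np.array(idx, dtype=int)
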