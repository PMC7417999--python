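import numpy as np
import pytest

from optophys.core import LfpTrace, NormalizedTrace, RawTrace, Track


def brute_force_dff(samples, sampling_rate, window=120.0):
    """Independent oracle: loop-based centered windowed-mean dF/F."""
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    half = int(round(window / 2.0 * sampling_rate))
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        f = samples[lo:hi].mean()
        out[i] = (samples[i] - f) / f
    return out


def greedy_separation(times, amplitudes, min_interval):
    """Independent oracle for the descending-amplitude spacing rule."""
    times = np.asarray(times, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    order = sorted(range(times.size), key=lambda i: (-amplitudes[i], times[i]))
    kept = []
    for i in order:
        if all(abs(times[i] - times[j]) >= min_interval for j in kept):
            kept.append(i)
    kept.sort(key=lambda i: times[i])
    return times[kept], amplitudes[kept]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_track():
    """2 cm/s straight line along x, 25 Hz, 120 s, far from any wall."""
    fs = 25.0
    t = np.arange(int(120 * fs)) / fs
    return Track(t, 2.0 * t, np.zeros_like(t), fs)


@pytest.fixture
def constant_raw_trace():
    return RawTrace(np.full(60_000, 100.0), sampling_rate=100.0)


def make_norm(samples, fs=100.0):
    return NormalizedTrace(np.asarray(samples, dtype=float), fs, 120.0)
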