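"""Bulk fluorescence normalization and calcium-transient statistics.

The baseline F for each sample is the mean of a 2-min window centered on it
(clipped at the trace edges, so the effective window shrinks near the ends);
dF/F = (x - F) / F.  Transients are strict local maxima of dF/F above a
threshold (default 5%), pruned greedily in descending amplitude order to
enforce a minimum inter-event interval (default 1 s).
"""

from __future__ import annotations

import numpy as np

from .core import (
    BinnedSeries,
    NormalizedTrace,
    RawTrace,
    TransientSet,
    bin_counts,
)
from .core import percent_of_pre as _percent_of_pre
from .errors import (
    DegenerateBaselineError,
    InvalidParameterError,
    WindowRangeError,
)

__all__ = [
    "normalize_dff",
    "sliding_baseline",
    "local_maxima",
    "detect_transients",
    "artifact_screen",
    "bin_event_rate",
    "percent_of_pre",
    "summarize_windows",
]


def sliding_baseline(trace: RawTrace, window: float = 120.0) -> np.ndarray:
    """Centered moving-window mean, window clipped to the trace extent."""
    if window <= 0:
        raise InvalidParameterError("window must be > 0")
    x = trace.samples
    n = x.size
    if n == 0:
        raise InvalidParameterError("trace must contain at least 1 sample")
    half = int(round(window / 2.0 * trace.sampling_rate))
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n)
    hi = np.clip(idx + half + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def normalize_dff(trace: RawTrace, window: float = 120.0) -> NormalizedTrace:
    """dF/F with a sliding 2-min baseline: ``(x - F) / F``."""
    baseline = sliding_baseline(trace, window)
    bad = np.flatnonzero(baseline <= 0)
    if bad.size:
        raise DegenerateBaselineError(int(bad[0]), int(bad[-1]))
    return NormalizedTrace(
        samples=(trace.samples - baseline) / baseline,
        sampling_rate=trace.sampling_rate,
        window_length=window,
        start_time=trace.start_time,
    )


def local_maxima(samples: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima (greater than both neighbours)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int)
    return np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1


def detect_transients(
    norm: NormalizedTrace,
    threshold: float = 0.05,
    min_interval: float = 1.0,
) -> TransientSet:
    """Strict local maxima of dF/F above *threshold*, >= *min_interval* apart.

    Candidates are accepted greedily in descending amplitude order (ties go
    to the earlier time); a candidate within ``min_interval`` of an already
    accepted event is discarded.  Amplitudes must exceed the threshold
    strictly.
    """
    if threshold <= 0:
        raise InvalidParameterError("threshold must be > 0")
    if min_interval < 0:
        raise InvalidParameterError("min_interval must be >= 0")
    peaks = local_maxima(norm.samples)
    amps = norm.samples[peaks]
    keep = amps > threshold
    peaks, amps = peaks[keep], amps[keep]
    times = norm.start_time + peaks / norm.sampling_rate

    # descending amplitude, earlier time wins ties
    order = np.lexsort((times, -amps))
    accepted_times: list[float] = []
    accepted_amps: list[float] = []
    for i in order:
        t = times[i]
        if all(abs(t - s) >= min_interval for s in accepted_times):
            accepted_times.append(t)
            accepted_amps.append(amps[i])
    sel = np.argsort(accepted_times)
    return TransientSet(
        event_times=np.asarray(accepted_times)[sel],
        event_amplitudes=np.asarray(accepted_amps)[sel],
        threshold=threshold,
        min_interval=min_interval,
    )


def artifact_screen(
    norm_traces: list[NormalizedTrace], threshold: float = 0.05
) -> np.ndarray:
    """Per-trace boolean: does any strict dF/F local maximum exceed *threshold*?

    Used to calibrate the motion-artifact cutoff from fluorophore-only
    control recordings.
    """
    if not norm_traces:
        raise InvalidParameterError("need at least one trace")
    flags = []
    for tr in norm_traces:
        idx = local_maxima(tr.samples)
        flags.append(bool(idx.size and np.any(tr.samples[idx] > threshold)))
    return np.asarray(flags, dtype=bool)


def bin_event_rate(
    events: TransientSet,
    session_extent: tuple[float, float],
    bin: float = 60.0,
) -> BinnedSeries:
    """Per-bin event counts converted to events/min (half-open bins)."""
    edges, counts = bin_counts(events.event_times, session_extent, bin)
    widths = np.diff(edges)
    return BinnedSeries(edges, counts / (widths / 60.0), units="events/min")


def percent_of_pre(binned: BinnedSeries, n_pre_bins: int = 30) -> BinnedSeries:
    """Normalize each bin to the mean of the first *n_pre_bins* bins (x100)."""
    return _percent_of_pre(binned, n_pre_bins)


def summarize_windows(
    binned: BinnedSeries,
    pre_window: tuple[float, float] = (600.0, 1800.0),
    post_window: tuple[float, float] = (2400.0, 3600.0),
) -> tuple[float, float]:
    """Means of the bins lying wholly inside each window (seconds).

    Defaults correspond to minutes 11-30 (pre) and 41-60 (post) of a
    60-minute session with the manipulation at minute 30.
    """
    def _mean(window):
        lo, hi = window
        if lo < binned.bin_edges[0] - 1e-9 or hi > binned.bin_edges[-1] + 1e-9:
            raise WindowRangeError(f"window {window} outside binned extent")
        sel = (binned.bin_edges[:-1] >= lo - 1e-9) & (binned.bin_edges[1:] <= hi + 1e-9)
        if not np.any(sel):
            raise WindowRangeError(f"window {window} contains no whole bin")
        return float(np.mean(binned.values[sel]))

    return _mean(pre_window), _mean(post_window)
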