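"""Open-field locomotion metrics from X/Y tracking.

"Instant velocity" over a window is the Euclidean path length accumulated in
that window divided by its duration (robust to direction changes within the
window).  Subject exclusion uses a one-sided 3-SD rule on a group metric.
"""

from __future__ import annotations

import numpy as np

from .core import BinnedSeries, Track
from .core import percent_of_pre as _percent_of_pre
from .errors import InvalidParameterError, WindowRangeError

__all__ = [
    "instant_velocity",
    "velocity_timecourse",
    "distance_moved",
    "exclude_outliers",
]

# Default sensitization windows: 14-min inter-block pause + 16 min after the
# second stimulation block, for a protocol starting at t = 0 (block 1 ends at
# 300 s, block 2 spans 1140-1440 s).
DEFAULT_DISTANCE_WINDOWS = [(300.0, 1140.0), (1440.0, 2400.0)]


def _step_lengths(track: Track) -> tuple[np.ndarray, np.ndarray]:
    """(start time, length) of each inter-sample step."""
    if len(track) < 2:
        raise InvalidParameterError("need >= 2 tracking samples")
    if np.any(np.diff(track.times) <= 0):
        raise InvalidParameterError("track times must be strictly increasing")
    d = np.hypot(np.diff(track.x), np.diff(track.y))
    return track.times[:-1], d


def instant_velocity(track: Track, window: float = 1.0) -> BinnedSeries:
    """Path length per consecutive *window*-second interval, in cm/s.

    Windows tile the track from its first timestamp; a trailing partial
    window is dropped.  Each step is assigned to the window containing its
    start time.
    """
    if window <= 0:
        raise InvalidParameterError("window must be > 0")
    starts, lengths = _step_lengths(track)
    t0 = track.times[0]
    n_windows = int(np.floor((track.times[-1] - t0) / window + 1e-9))
    if n_windows < 1:
        raise InvalidParameterError("track shorter than one window")
    which = np.floor((starts - t0) / window + 1e-9).astype(int)
    keep = which < n_windows
    sums = np.bincount(which[keep], weights=lengths[keep], minlength=n_windows)
    edges = t0 + window * np.arange(n_windows + 1)
    return BinnedSeries(edges, sums / window, units="cm/s")


def velocity_timecourse(
    velocity: BinnedSeries,
    bin: float = 60.0,
    n_pre_bins: int = 30,
) -> BinnedSeries:
    """Average the 1-s velocity series into 60-s bins, percent-of-pre."""
    if bin <= 0:
        raise InvalidParameterError("bin must be > 0")
    win = velocity.bin_edges[1] - velocity.bin_edges[0]
    per_bin = int(round(bin / win))
    if per_bin < 1:
        raise InvalidParameterError("bin must cover >= 1 velocity window")
    n_bins = velocity.n_bins // per_bin
    if n_bins < 1:
        raise InvalidParameterError("velocity series shorter than one bin")
    trimmed = velocity.values[: n_bins * per_bin].reshape(n_bins, per_bin)
    edges = velocity.bin_edges[0] + bin * np.arange(n_bins + 1)
    binned = BinnedSeries(edges, trimmed.mean(axis=1), units="cm/s")
    return _percent_of_pre(binned, n_pre_bins)


def distance_moved(
    track: Track,
    windows: list[tuple[float, float]] = None,
) -> float:
    """Euclidean path length (cm) summed over the given time windows."""
    if windows is None:
        windows = DEFAULT_DISTANCE_WINDOWS
    starts, lengths = _step_lengths(track)
    total = 0.0
    for lo, hi in windows:
        if hi <= lo:
            raise InvalidParameterError(f"window ({lo}, {hi}) is empty")
        if lo < track.times[0] - 1e-9 or hi > track.times[-1] + 1e-9:
            raise WindowRangeError(f"window ({lo}, {hi}) outside track extent")
        sel = (starts >= lo) & (starts < hi)
        total += float(np.sum(lengths[sel]))
    return total


def exclude_outliers(values) -> np.ndarray:
    """One-sided 3-SD inclusion mask for a per-subject metric.

    A subject is excluded iff its value exceeds mean + 3*SD of the *other*
    subjects (leave-one-out; sample SD).  Only high outliers are excluded.
    With zero spread among the remaining subjects a lone high value is still
    excluded; all-equal groups keep everyone.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise InvalidParameterError("need >= 3 subjects")
    include = np.ones(v.size, dtype=bool)
    for i in range(v.size):
        rest = np.delete(v, i)
        cutoff = rest.mean() + 3.0 * rest.std(ddof=1)
        if v[i] > cutoff:
            include[i] = False
    return include
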