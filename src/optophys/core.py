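"""Shared containers and small statistical helpers.

Every time series carries an explicit sampling rate and start time so that
binning and window selection can be done in seconds throughout; bins are
half-open ``[left, right)`` everywhere (an event landing exactly on an edge
belongs to the later bin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    InvalidParameterError,
    NormalizationUndefinedError,
)

__all__ = [
    "RawTrace",
    "NormalizedTrace",
    "TransientSet",
    "BinnedSeries",
    "SpikeTrain",
    "LfpTrace",
    "Track",
    "ModulationCall",
    "POTENTIATED",
    "DEPRESSED",
    "NON_MODULATED",
    "bin_counts",
    "percent_of_pre",
    "paired_modulation_test",
]

POTENTIATED = "potentiated"
DEPRESSED = "depressed"
NON_MODULATED = "non-modulated"


def _as_float_array(values) -> np.ndarray:
    return np.asarray(values, dtype=float)


@dataclass
class RawTrace:
    """Uniformly sampled raw fluorescence trace (arbitrary units)."""

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = _as_float_array(self.samples)
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be > 0")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class NormalizedTrace:
    """dF/F trace (dimensionless fraction) with the baseline window used."""

    samples: np.ndarray
    sampling_rate: float
    window_length: float
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = _as_float_array(self.samples)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate


@dataclass
class TransientSet:
    """Detected fluorescence events after threshold and spacing rules."""

    event_times: np.ndarray
    event_amplitudes: np.ndarray
    threshold: float
    min_interval: float

    def __post_init__(self):
        self.event_times = _as_float_array(self.event_times)
        self.event_amplitudes = _as_float_array(self.event_amplitudes)

    def __len__(self) -> int:
        return self.event_times.size


@dataclass
class BinnedSeries:
    """Edges + per-bin values; ``len(values) == len(bin_edges) - 1``."""

    bin_edges: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.bin_edges = _as_float_array(self.bin_edges)
        self.values = _as_float_array(self.values)
        if self.values.size != self.bin_edges.size - 1:
            raise InvalidParameterError(
                "values must have exactly one entry per bin "
                f"({self.values.size} values, {self.bin_edges.size} edges)"
            )
        if self.bin_edges.size >= 2 and not np.all(np.diff(self.bin_edges) > 0):
            raise InvalidParameterError("bin edges must be strictly increasing")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return self.values.size


@dataclass
class SpikeTrain:
    """Sorted spike timestamps for one unit."""

    unit_id: str
    spike_times: np.ndarray
    session_extent: tuple[float, float]

    def __post_init__(self):
        self.spike_times = _as_float_array(self.spike_times)
        start, end = self.session_extent
        if end <= start:
            raise InvalidParameterError("session_extent must satisfy end > start")
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) < 0):
                raise InvalidParameterError("spike_times must be sorted")
            if self.spike_times[0] < start or self.spike_times[-1] > end:
                raise InvalidParameterError("spikes outside session extent")

    def __len__(self) -> int:
        return self.spike_times.size


@dataclass
class LfpTrace:
    """Local field potential trace (µV), 1 kHz by convention."""

    samples: np.ndarray
    sampling_rate: float = 1000.0
    channel_id: str = ""
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = _as_float_array(self.samples)
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be > 0")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class Track:
    """Open-field X/Y tracking (cm)."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.times = _as_float_array(self.times)
        self.x = _as_float_array(self.x)
        self.y = _as_float_array(self.y)
        if not (self.times.size == self.x.size == self.y.size):
            raise InvalidParameterError("times, x, y must have equal lengths")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ModulationCall:
    """Per-signal potentiated/depressed/non-modulated label.

    ``label`` is non-modulated iff ``p_value >= alpha_corrected``; when
    significant, direction follows percent_change (>100% potentiated,
    <100% depressed).
    """

    signal_id: str
    p_value: float
    alpha_corrected: float
    percent_change: float
    label: str
    degenerate: bool = False  # zero-variance pairing flagged, p forced to 1

    def __post_init__(self):
        if self.label not in (POTENTIATED, DEPRESSED, NON_MODULATED):
            raise InvalidParameterError(f"unknown label {self.label!r}")


def bin_counts(
    times: np.ndarray,
    extent: tuple[float, float],
    bin_width: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Count events in half-open ``[left, right)`` bins covering *extent*.

    Returns ``(edges, counts)``.  The extent is tiled with as many whole bins
    as fit; the last bin may be truncated to end exactly at the extent's end.
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin width must be > 0")
    start, end = extent
    if end <= start:
        raise InvalidParameterError("extent must satisfy end > start")
    n_bins = int(np.ceil((end - start) / bin_width - 1e-12))
    edges = start + bin_width * np.arange(n_bins + 1)
    edges[-1] = min(edges[-1], end)
    times = _as_float_array(times)
    if times.size and (times.min() < start or times.max() >= end + 1e-12):
        raise InvalidParameterError("events outside the binning extent")
    idx = np.floor((times - start) / bin_width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return edges, counts


def percent_of_pre(binned: BinnedSeries, n_pre_bins: int = 30) -> BinnedSeries:
    """Express every bin as ``100 * value / mean(first n_pre_bins values)``."""
    if n_pre_bins < 1 or n_pre_bins > binned.n_bins:
        raise InvalidParameterError(
            f"n_pre_bins={n_pre_bins} not within 1..{binned.n_bins}"
        )
    pre_mean = float(np.mean(binned.values[:n_pre_bins]))
    if pre_mean == 0:
        raise NormalizationUndefinedError("pre-period mean is zero")
    return BinnedSeries(
        bin_edges=binned.bin_edges.copy(),
        values=100.0 * binned.values / pre_mean,
        units="% of pre",
    )


def paired_modulation_test(
    pre_values: Sequence[float],
    post_values: Sequence[float],
    *,
    alpha: float = 0.05,
    n_comparisons: int = 1,
    percent_change: float | None = None,
    signal_id: str = "",
) -> ModulationCall:
    """Two-sided paired t-test with Bonferroni-corrected alpha.

    Values are paired by index.  Direction of a significant change is taken
    from ``percent_change`` (post as % of pre; computed from the supplied
    windows when not given): >100% potentiated, <100% depressed.  A
    zero-variance identical pairing is treated as p = 1 and flagged.
    """
    pre = _as_float_array(pre_values)
    post = _as_float_array(post_values)
    if pre.size != post.size:
        raise InvalidParameterError("pre and post windows must pair by index")
    if pre.size < 2:
        raise InvalidParameterError("need at least 2 paired values")
    if n_comparisons < 1:
        raise InvalidParameterError("n_comparisons must be >= 1")
    alpha_corrected = alpha / n_comparisons

    if percent_change is None:
        pre_mean = float(np.mean(pre))
        if pre_mean == 0:
            raise NormalizationUndefinedError("pre-window mean is zero")
        percent_change = 100.0 * float(np.mean(post)) / pre_mean

    diffs = post - pre
    degenerate = False
    if np.all(diffs == diffs[0]):
        # zero-variance differences: the t statistic is undefined. Identical
        # windows are forced to p = 1 (non-modulated, flagged); a constant
        # nonzero shift is a perfectly consistent change (t -> inf).
        if diffs[0] == 0:
            p_value = 1.0
            degenerate = True
        else:
            p_value = 0.0
    else:
        p_value = float(stats.ttest_rel(post, pre).pvalue)

    if p_value < alpha_corrected:
        label = POTENTIATED if percent_change > 100.0 else DEPRESSED
    else:
        label = NON_MODULATED
    return ModulationCall(
        signal_id=signal_id,
        p_value=p_value,
        alpha_corrected=alpha_corrected,
        percent_change=float(percent_change),
        label=label,
        degenerate=degenerate,
    )
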