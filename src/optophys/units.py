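"""Firing-rate time-courses and modulation classification for sorted units.

Spike trains enter pre-sorted.  Rates are computed in 60-s bins; a unit is
classified across a manipulation with a two-sided paired t-test on matched
pre/post bins, Bonferroni-corrected, with direction taken from the
percent-of-pre rule (>100% potentiated, <100% depressed).
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .core import (
    DEPRESSED,
    NON_MODULATED,
    POTENTIATED,
    BinnedSeries,
    ModulationCall,
    SpikeTrain,
    bin_counts,
    paired_modulation_test,
)
from .core import percent_of_pre as _percent_of_pre
from .errors import InvalidParameterError, WindowRangeError

__all__ = [
    "bin_firing",
    "window_means",
    "classify_unit",
    "timecourse_percent_of_pre",
    "cohort_pie",
    "DEFAULT_TEST_WINDOW_PRE",
    "DEFAULT_TEST_WINDOW_POST",
]

# Bin-index windows (into a 60-bin, 60-minute session): minutes 11-30 of the
# pre period paired with minutes 11-30 of the post period (41-60 absolute).
DEFAULT_TEST_WINDOW_PRE = (10, 30)
DEFAULT_TEST_WINDOW_POST = (40, 60)


def bin_firing(train: SpikeTrain, bin: float = 60.0) -> BinnedSeries:
    """Per-bin spike counts converted to Hz (half-open bins)."""
    edges, counts = bin_counts(train.spike_times, train.session_extent, bin)
    widths = np.diff(edges)
    return BinnedSeries(edges, counts / widths, units="Hz")


def window_means(
    binned: BinnedSeries,
    pre_bins: tuple[int, int] = DEFAULT_TEST_WINDOW_PRE,
    post_bins: tuple[int, int] = DEFAULT_TEST_WINDOW_POST,
) -> tuple[float, float]:
    """Mean rate over two bin-index windows ``[start, stop)``."""
    for lo, hi in (pre_bins, post_bins):
        if lo < 0 or hi > binned.n_bins or hi <= lo:
            raise WindowRangeError(f"bin window ({lo}, {hi}) outside series")
    pre = float(np.mean(binned.values[pre_bins[0]:pre_bins[1]]))
    post = float(np.mean(binned.values[post_bins[0]:post_bins[1]]))
    return pre, post


def classify_unit(
    binned: BinnedSeries,
    test_window_pre: tuple[int, int] = DEFAULT_TEST_WINDOW_PRE,
    test_window_post: tuple[int, int] = DEFAULT_TEST_WINDOW_POST,
    alpha: float = 0.05,
    n_comparisons: int = 1,
    signal_id: str = "",
) -> ModulationCall:
    """Paired t-test on matched pre/post bins with Bonferroni correction.

    The two windows must contain equal numbers of bins (paired by index
    within the window).  Percent change is the post-window mean expressed as
    a percentage of the pre-window mean.
    """
    pre_lo, pre_hi = test_window_pre
    post_lo, post_hi = test_window_post
    if (pre_hi - pre_lo) != (post_hi - post_lo):
        raise InvalidParameterError("test windows must contain equal bin counts")
    pre_mean, post_mean = window_means(binned, test_window_pre, test_window_post)
    percent_change = (
        100.0 * post_mean / pre_mean if pre_mean != 0 else float("nan")
    )
    if pre_mean == 0:
        # silent unit in the pre window: fall back to the raw test direction
        percent_change = float("inf") if post_mean > 0 else 100.0
    return paired_modulation_test(
        binned.values[pre_lo:pre_hi],
        binned.values[post_lo:post_hi],
        alpha=alpha,
        n_comparisons=n_comparisons,
        percent_change=percent_change,
        signal_id=signal_id,
    )


def timecourse_percent_of_pre(
    binned: BinnedSeries, n_pre_bins: int = 30
) -> BinnedSeries:
    """Rate time-course expressed as percent of the pre-period mean."""
    return _percent_of_pre(binned, n_pre_bins)


def cohort_pie(calls: list[ModulationCall]) -> dict[str, int]:
    """Counts of potentiated / depressed / non-modulated calls."""
    counts = Counter(call.label for call in calls)
    return {
        POTENTIATED: counts.get(POTENTIATED, 0),
        DEPRESSED: counts.get(DEPRESSED, 0),
        NON_MODULATED: counts.get(NON_MODULATED, 0),
    }
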