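"""Opto-evoked LFP and spiking quantification around test pulses.

Each test pulse yields a +/-100 ms LFP snippet.  The headline amplitude is
the peak-to-peak (max - min) of the 100 ms window after pulse onset; the
100 ms before onset serves the wire-responsiveness screen.  Evoked firing
uses 25 ms OFF/ON windows around onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    BinnedSeries,
    LfpTrace,
    ModulationCall,
    SpikeTrain,
    paired_modulation_test,
)
from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    NormalizationUndefinedError,
)
from .protocols import StimSchedule

__all__ = [
    "EvokedTrialMatrix",
    "EvokedFiringResult",
    "extract_trials",
    "peak_to_peak",
    "trial_amplitudes",
    "wire_is_responsive",
    "amplitude_timecourse",
    "classify_lfp",
    "evoked_firing",
    "evoked_firing_timecourse",
    "ACTIVATED",
    "INHIBITED",
    "NOT_MODULATED",
]

ACTIVATED = "activated"
INHIBITED = "inhibited"
NOT_MODULATED = "not-modulated"

PRE = "Pre"
POST = "Post"


@dataclass
class EvokedTrialMatrix:
    """Equal-length per-pulse LFP snippets covering [-window, +window]."""

    trials: np.ndarray          # (n_trials, n_samples)
    trial_times: np.ndarray     # pulse onset times, s
    phase: np.ndarray           # "Pre" / "Post" per trial
    onset_index: int            # sample index of pulse onset within a snippet
    sampling_rate: float

    def __post_init__(self):
        self.trials = np.asarray(self.trials, dtype=float)
        self.trial_times = np.asarray(self.trial_times, dtype=float)
        self.phase = np.asarray(self.phase)
        if self.trials.ndim != 2:
            raise InvalidParameterError("trials must be a 2-D array")
        if not (len(self.trials) == len(self.trial_times) == len(self.phase)):
            raise InvalidParameterError("trials/times/phase lengths differ")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def pre_onset(self) -> np.ndarray:
        """Samples in the [-window, 0) interval, per trial."""
        return self.trials[:, : self.onset_index]

    def post_onset(self) -> np.ndarray:
        """Samples in the (0, +window] interval, per trial."""
        return self.trials[:, self.onset_index:]

    def select(self, phase: str) -> "EvokedTrialMatrix":
        mask = self.phase == phase
        return EvokedTrialMatrix(
            self.trials[mask],
            self.trial_times[mask],
            self.phase[mask],
            self.onset_index,
            self.sampling_rate,
        )


def extract_trials(
    lfp: LfpTrace,
    schedule: StimSchedule,
    manipulation_time: float,
    window: float = 0.1,
    blank: float = 0.0,
) -> EvokedTrialMatrix:
    """Cut a +/-*window* snippet around every test pulse.

    Pulses inside the schedule's protocol blocks are excluded; pulses without
    full coverage at the trace edges are dropped with a warning.  ``blank``
    zeroes the first *blank* seconds after onset (stimulation-artifact
    blanking for real recordings; defaults to none).
    """
    fs = lfp.sampling_rate
    n_side = int(round(window * fs))
    onsets = schedule.onsets
    onsets = onsets[~schedule.in_block(onsets)]

    idx = np.round((onsets - lfp.start_time) * fs).astype(int)
    ok = (idx - n_side >= 0) & (idx + n_side <= lfp.samples.size)
    n_dropped = int(np.sum(~ok))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} pulse(s) without full +/-{window * 1e3:.0f} ms coverage",
            stacklevel=2,
        )
    idx, onsets = idx[ok], onsets[ok]
    trials = np.stack([lfp.samples[i - n_side : i + n_side] for i in idx]) if idx.size \
        else np.empty((0, 2 * n_side))
    if blank > 0 and trials.size:
        trials = trials.copy()
        trials[:, n_side : n_side + int(round(blank * fs))] = 0.0
    phase = np.where(onsets < manipulation_time, PRE, POST)
    return EvokedTrialMatrix(trials, onsets, phase, n_side, fs)


def peak_to_peak(window_samples: np.ndarray) -> float:
    """Difference between the maximum and minimum deflection (>= 0)."""
    w = np.asarray(window_samples, dtype=float)
    if w.size == 0:
        raise InvalidParameterError("empty window")
    return float(np.max(w) - np.min(w))


def trial_amplitudes(trials: EvokedTrialMatrix) -> np.ndarray:
    """Per-trial peak-to-peak amplitude of the post-onset window."""
    post = trials.post_onset()
    if post.shape[1] == 0:
        raise InvalidParameterError("trials have no post-onset samples")
    return post.max(axis=1) - post.min(axis=1)


def wire_is_responsive(trials: EvokedTrialMatrix, alpha: float = 0.05) -> bool:
    """Trial-by-trial screen on Pre-phase trials.

    Paired t-test of post-onset vs pre-onset 100 ms peak-to-peak amplitudes;
    the wire is responsive iff p < alpha and the post-onset mean is larger
    (evoked responses are deflections, not suppressions).
    """
    pre_phase = trials.select(PRE)
    if pre_phase.n_trials < 2:
        raise InsufficientDataError("need >= 2 Pre-phase trials")
    before = pre_phase.pre_onset()
    after = pre_phase.post_onset()
    p2p_before = before.max(axis=1) - before.min(axis=1)
    p2p_after = after.max(axis=1) - after.min(axis=1)
    if np.all(p2p_after - p2p_before == (p2p_after - p2p_before)[0]):
        diff = (p2p_after - p2p_before)[0]
        return bool(diff > 0)
    p = float(stats.ttest_rel(p2p_after, p2p_before).pvalue)
    return bool(p < alpha and p2p_after.mean() > p2p_before.mean())


def amplitude_timecourse(
    trials: EvokedTrialMatrix, bin: float = 60.0
) -> BinnedSeries:
    """60-s binned mean amplitude as percent of the Pre-phase mean."""
    if bin <= 0:
        raise InvalidParameterError("bin must be > 0")
    amps = trial_amplitudes(trials)
    pre_mask = trials.phase == PRE
    if not np.any(pre_mask):
        raise InsufficientDataError("need >= 1 Pre-phase trial")
    pre_mean = float(np.mean(amps[pre_mask]))
    if pre_mean == 0:
        raise NormalizationUndefinedError("Pre-phase mean amplitude is zero")
    t0 = np.floor(trials.trial_times.min() / bin) * bin
    t1 = trials.trial_times.max()
    n_bins = int(np.floor((t1 - t0) / bin)) + 1
    edges = t0 + bin * np.arange(n_bins + 1)
    which = np.floor((trials.trial_times - t0) / bin).astype(int)
    sums = np.bincount(which, weights=amps, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BinnedSeries(edges, 100.0 * means / pre_mean, units="% of pre")


def _binned_amplitudes(
    trials: EvokedTrialMatrix, bin: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mean amplitude per 60-s bin for Pre and Post phases separately."""
    amps = trial_amplitudes(trials)

    def _phase_bins(phase):
        mask = trials.phase == phase
        t = trials.trial_times[mask]
        a = amps[mask]
        if t.size == 0:
            return np.array([])
        t0 = np.floor(t.min() / bin) * bin
        which = np.floor((t - t0) / bin).astype(int)
        n = which.max() + 1
        sums = np.bincount(which, weights=a, minlength=n)
        counts = np.bincount(which, minlength=n)
        keep = counts > 0
        return sums[keep] / counts[keep]

    return _phase_bins(PRE), _phase_bins(POST)


def classify_lfp(
    trials: EvokedTrialMatrix,
    alpha: float = 0.05,
    n_comparisons: int = 1,
    bin: float = 60.0,
    test_bins: tuple[int, int] = (10, 30),
    signal_id: str = "",
) -> ModulationCall:
    """Potentiated/depressed/non-modulated call on binned evoked amplitudes.

    Amplitudes are binned per phase; bins ``test_bins`` (default 11-30 of
    each phase, by index) are paired and tested exactly as unit rates are.
    Percent change is the post-phase window mean as percent of pre.
    """
    pre_bins, post_bins = _binned_amplitudes(trials, bin)
    lo, hi = test_bins
    if hi > pre_bins.size or hi > post_bins.size:
        raise InsufficientDataError(
            f"test bins ({lo}, {hi}) need >= {hi} bins per phase "
            f"(have {pre_bins.size} pre, {post_bins.size} post)"
        )
    pre_sel = pre_bins[lo:hi]
    post_sel = post_bins[lo:hi]
    pre_mean = float(np.mean(pre_sel))
    if pre_mean == 0:
        raise NormalizationUndefinedError("pre-window mean amplitude is zero")
    return paired_modulation_test(
        pre_sel,
        post_sel,
        alpha=alpha,
        n_comparisons=n_comparisons,
        percent_change=100.0 * float(np.mean(post_sel)) / pre_mean,
        signal_id=signal_id,
    )


@dataclass
class EvokedFiringResult:
    """Per-trial OFF/ON firing rates around pulses with the activation call."""

    off_rates: np.ndarray  # Hz, [-window, 0) per trial
    on_rates: np.ndarray   # Hz, [0, +window) per trial
    p_value: float
    label: str             # activated / inhibited / not-modulated


def _rates_around(
    train: SpikeTrain, onsets: np.ndarray, window: float
) -> tuple[np.ndarray, np.ndarray]:
    t = train.spike_times
    off = np.searchsorted(t, onsets) - np.searchsorted(t, onsets - window)
    on = np.searchsorted(t, onsets + window) - np.searchsorted(t, onsets)
    return off / window, on / window


def evoked_firing(
    train: SpikeTrain,
    schedule: StimSchedule,
    window: float = 0.025,
    alpha: float = 0.05,
) -> EvokedFiringResult:
    """OFF (25 ms before) vs ON (25 ms after onset) firing comparison.

    Paired t-test across trials; activated iff significant with ON > OFF,
    inhibited iff significant with ON < OFF.
    """
    if window <= 0:
        raise InvalidParameterError("window must be > 0")
    onsets = schedule.onsets[~schedule.in_block(schedule.onsets)]
    if onsets.size < 2:
        raise InsufficientDataError("need >= 2 trials")
    off, on = _rates_around(train, onsets, window)
    diffs = on - off
    if np.all(diffs == diffs[0]) and diffs[0] == 0:
        return EvokedFiringResult(off, on, 1.0, NOT_MODULATED)
    p = float(stats.ttest_rel(on, off).pvalue)
    if p < alpha:
        label = ACTIVATED if on.mean() > off.mean() else INHIBITED
    else:
        label = NOT_MODULATED
    return EvokedFiringResult(off, on, p, label)


def evoked_firing_timecourse(
    train: SpikeTrain,
    schedule: StimSchedule,
    manipulation_time: float,
    window: float = 0.025,
    bin: float = 60.0,
    alpha: float = 0.05,
    n_comparisons: int = 1,
    signal_id: str = "",
) -> tuple[BinnedSeries, ModulationCall]:
    """Evoked ON-rate time-course (percent of pre) plus a modulation call.

    The call pairs per-trial ON rates across the manipulation by
    chronological order; unequal trial counts are truncated to the common
    length with a warning.
    """
    onsets = schedule.onsets[~schedule.in_block(schedule.onsets)]
    if onsets.size < 2:
        raise InsufficientDataError("need >= 2 trials")
    _, on = _rates_around(train, onsets, window)

    pre_mask = onsets < manipulation_time
    pre_on, post_on = on[pre_mask], on[~pre_mask]
    if pre_on.size == 0 or post_on.size == 0:
        raise InsufficientDataError("need trials in both phases")
    pre_mean = float(np.mean(pre_on))
    if pre_mean == 0:
        raise NormalizationUndefinedError("pre-phase evoked rate is zero")

    t0 = np.floor(onsets.min() / bin) * bin
    n_bins = int(np.floor((onsets.max() - t0) / bin)) + 1
    edges = t0 + bin * np.arange(n_bins + 1)
    which = np.floor((onsets - t0) / bin).astype(int)
    sums = np.bincount(which, weights=on, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    timecourse = BinnedSeries(edges, 100.0 * means / pre_mean, units="% of pre")

    n = min(pre_on.size, post_on.size)
    if pre_on.size != post_on.size:
        warnings.warn(
            f"unequal trial counts ({pre_on.size} pre, {post_on.size} post); "
            f"truncating to {n}",
            stacklevel=2,
        )
    call = paired_modulation_test(
        pre_on[:n],
        post_on[:n],
        alpha=alpha,
        n_comparisons=n_comparisons,
        percent_change=100.0 * float(np.mean(post_on)) / pre_mean,
        signal_id=signal_id,
    )
    return timecourse, call
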