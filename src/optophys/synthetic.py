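"""Synthetic sessions with known ground truth for every downstream stage.

Generators are deterministic in ``(ground truth, seed)``.  The signal models
are deliberately simple:

* photometry: multiplicative double-exponential bleach x (1 + transients +
  noise), transients rise instantaneously and decay exponentially; Gaussian
  sensor noise in fractional units; optional brief motion artifacts
  (fluorophore-only mode);
* spikes: inhomogeneous Poisson via thinning, with a rate step at the
  manipulation time and an optional stimulus-locked rate bump;
* evoked LFP: 1/f^alpha Gaussian background plus a fixed kernel scaled to
  one amplitude before the manipulation and another after;
* locomotion: reflected random walk whose per-step speed is drawn around a
  pre/post target speed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import LfpTrace, RawTrace, SpikeTrain, Track
from .errors import InvalidParameterError
from .io import SessionManifest, write_spikes, write_trace, write_track
from .protocols import StimSchedule, build_test_pulses

__all__ = [
    "BleachParams",
    "PhotometryGroundTruth",
    "UnitGroundTruth",
    "EvokedGroundTruth",
    "TrackGroundTruth",
    "sample_poisson_times",
    "one_over_f_noise",
    "default_evoked_kernel",
    "generate_photometry",
    "generate_spike_train",
    "generate_evoked_lfp",
    "generate_track",
    "generate_full_session",
]


def sample_poisson_times(
    rate_hz: float, t_start: float, t_stop: float, rng: np.random.Generator
) -> np.ndarray:
    """Sorted homogeneous Poisson event times on [t_start, t_stop)."""
    if rate_hz < 0:
        raise InvalidParameterError("rate must be >= 0")
    span = t_stop - t_start
    n = rng.poisson(rate_hz * span)
    return t_start + np.sort(rng.uniform(0.0, span, size=n))


def one_over_f_noise(
    n: int, sd: float, alpha: float, rng: np.random.Generator, dt: float
) -> np.ndarray:
    """Gaussian noise spectrally shaped by 1/f^alpha, scaled to *sd*."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, dt)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-alpha / 2.0)
    shaped = np.fft.irfft(spectrum * shaping, n=n)
    s = shaped.std()
    return shaped * (sd / s) if s > 0 else shaped


# --------------------------------------------------------------------------
# photometry


@dataclass
class BleachParams:
    """Double-exponential multiplicative photobleaching decay."""

    initial: float = 100.0      # a.u.
    tau_fast: float = 600.0     # s
    tau_slow: float = 6000.0    # s
    frac_fast: float = 0.3

    def level(self, t: np.ndarray) -> np.ndarray:
        if self.initial <= 0:
            raise InvalidParameterError("bleach initial level must be > 0")
        if self.tau_fast <= 0 or self.tau_slow <= 0:
            raise InvalidParameterError("bleach time constants must be > 0")
        if not 0.0 <= self.frac_fast <= 1.0:
            raise InvalidParameterError("frac_fast must lie in [0, 1]")
        return self.initial * (
            self.frac_fast * np.exp(-t / self.tau_fast)
            + (1.0 - self.frac_fast) * np.exp(-t / self.tau_slow)
        )


@dataclass
class PhotometryGroundTruth:
    """Everything needed to synthesize (and later score) one fluorescence trace.

    ``transient_tau`` is the exponential decay constant of the transient
    kernel.  The default (0.5 s) keeps the above-threshold tail of a 10%
    transient comfortably shorter than the 1 s inter-event interval used
    downstream, so detected counts track the generative rate.
    """

    transient_times: np.ndarray = field(default_factory=lambda: np.array([]))
    transient_amplitudes: np.ndarray = field(default_factory=lambda: np.array([]))
    bleach_params: BleachParams = field(default_factory=BleachParams)
    noise_sd: float = 0.003          # fractional (dF/F units)
    artifact_times: np.ndarray = field(default_factory=lambda: np.array([]))
    sampling_rate: float = 100.0     # Hz
    duration: float = 3600.0         # s
    transient_tau: float = 0.5       # s
    artifact_amplitude: float = 0.02  # fractional dF/F
    artifact_tau: float = 0.05       # s

    def __post_init__(self):
        self.transient_times = np.asarray(self.transient_times, dtype=float)
        self.transient_amplitudes = np.asarray(self.transient_amplitudes, dtype=float)
        self.artifact_times = np.asarray(self.artifact_times, dtype=float)
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise InvalidParameterError("sampling_rate and duration must be > 0")
        if self.transient_times.size:
            if np.any(np.diff(self.transient_times) <= 0):
                raise InvalidParameterError("transient_times must be strictly increasing")
            if self.transient_times[0] < 0 or self.transient_times[-1] > self.duration:
                raise InvalidParameterError("transient_times outside [0, duration]")
        if self.transient_amplitudes.size != self.transient_times.size:
            raise InvalidParameterError("one amplitude per transient required")
        if self.noise_sd < 0 or self.transient_tau <= 0 or self.artifact_tau <= 0:
            raise InvalidParameterError("noise_sd >= 0 and taus > 0 required")

    @classmethod
    def with_poisson_transients(
        cls,
        rate_pre_per_min: float,
        rate_post_per_min: float,
        seed: int,
        amplitude: float = 0.10,
        manipulation_time: float = 1800.0,
        duration: float = 3600.0,
        **kwargs,
    ) -> "PhotometryGroundTruth":
        """Poisson transient times with a rate change at the manipulation."""
        rng = np.random.default_rng(seed)
        pre = sample_poisson_times(rate_pre_per_min / 60.0, 0.0, manipulation_time, rng)
        post = sample_poisson_times(
            rate_post_per_min / 60.0, manipulation_time, duration, rng
        )
        times = np.concatenate([pre, post])
        return cls(
            transient_times=times,
            transient_amplitudes=np.full(times.size, amplitude),
            duration=duration,
            **kwargs,
        )

    @classmethod
    def eyfp(
        cls,
        seed: int,
        artifact_rate_per_min: float = 0.5,
        duration: float = 3600.0,
        **kwargs,
    ) -> "PhotometryGroundTruth":
        """Fluorophore-only control: no transients, small motion artifacts."""
        rng = np.random.default_rng(seed)
        return cls(
            artifact_times=sample_poisson_times(
                artifact_rate_per_min / 60.0, 0.0, duration, rng
            ),
            duration=duration,
            **kwargs,
        )


def _add_exponential_bumps(
    fractional: np.ndarray,
    times: np.ndarray,
    amplitudes: np.ndarray,
    tau: float,
    fs: float,
) -> None:
    """Add instantaneous-rise / exponential-decay bumps in place."""
    n = fractional.size
    kernel_len = min(n, int(round(10 * tau * fs)) + 1)
    kernel = np.exp(-np.arange(kernel_len) / (tau * fs))
    for t0, amp in zip(times, amplitudes):
        i0 = int(np.ceil(t0 * fs - 1e-9))
        if i0 >= n:
            continue
        stop = min(n, i0 + kernel_len)
        # sub-sample alignment: decay evaluated from the true event time
        frac_offset = i0 / fs - t0
        fractional[i0:stop] += amp * np.exp(-frac_offset / tau) * kernel[: stop - i0]


def generate_photometry(
    gt: PhotometryGroundTruth, seed: int
) -> tuple[RawTrace, PhotometryGroundTruth]:
    """Synthesize ``bleach(t) * (1 + transients + artifacts) + noise``."""
    rng = np.random.default_rng(seed)
    n = int(round(gt.duration * gt.sampling_rate))
    t = np.arange(n) / gt.sampling_rate
    fractional = np.zeros(n)
    _add_exponential_bumps(
        fractional, gt.transient_times, gt.transient_amplitudes,
        gt.transient_tau, gt.sampling_rate,
    )
    if gt.artifact_times.size:
        _add_exponential_bumps(
            fractional,
            gt.artifact_times,
            np.full(gt.artifact_times.size, gt.artifact_amplitude),
            gt.artifact_tau,
            gt.sampling_rate,
        )
    if gt.noise_sd > 0:
        # multiplicative sensor noise: the dF/F noise floor stays stationary
        # as the bleach level decays
        fractional = fractional + rng.normal(0.0, gt.noise_sd, size=n)
    samples = gt.bleach_params.level(t) * (1.0 + fractional)
    return RawTrace(samples, gt.sampling_rate), gt


# --------------------------------------------------------------------------
# spikes


@dataclass
class UnitGroundTruth:
    """Rate model for one unit: a step at injection plus an optional bump."""

    base_rate: float                 # Hz
    post_multiplier: float = 1.0     # dimensionless, > 0
    injection_time: float = 1800.0   # s
    evoked_bump: tuple[float, float, float] | None = None  # (latency s, width s, added Hz)

    def __post_init__(self):
        if self.base_rate < 0:
            raise InvalidParameterError("base_rate must be >= 0")
        if self.post_multiplier <= 0:
            raise InvalidParameterError("post_multiplier must be > 0")
        if self.evoked_bump is not None:
            lat, width, added = self.evoked_bump
            if width <= 0 or added < 0 or lat < 0:
                raise InvalidParameterError("invalid evoked_bump parameters")


def generate_spike_train(
    gt: UnitGroundTruth,
    duration: float,
    seed: int,
    schedule: StimSchedule | None = None,
    unit_id: str = "unit",
) -> SpikeTrain:
    """Inhomogeneous Poisson spike train via thinning."""
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    rng = np.random.default_rng(seed)
    bump_rate = gt.evoked_bump[2] if (gt.evoked_bump and schedule is not None) else 0.0
    lam_max = gt.base_rate * max(1.0, gt.post_multiplier) + bump_rate
    if lam_max == 0:
        return SpikeTrain(unit_id, np.array([]), (0.0, duration))
    candidates = sample_poisson_times(lam_max, 0.0, duration, rng)
    rate = np.where(
        candidates >= gt.injection_time,
        gt.base_rate * gt.post_multiplier,
        gt.base_rate,
    ).astype(float)
    if bump_rate > 0:
        lat, width, added = gt.evoked_bump
        onsets = schedule.onsets
        prev = np.searchsorted(onsets, candidates, side="right") - 1
        has_prev = prev >= 0
        dt = np.where(has_prev, candidates - onsets[np.clip(prev, 0, None)], np.inf)
        rate = rate + np.where((dt >= lat) & (dt < lat + width), added, 0.0)
    keep = rng.uniform(0.0, lam_max, size=candidates.size) < rate
    return SpikeTrain(unit_id, candidates[keep], (0.0, duration))


# --------------------------------------------------------------------------
# evoked LFP


def default_evoked_kernel(sampling_rate: float = 1000.0) -> np.ndarray:
    """Biphasic 40-ms waveform with unit peak-to-peak amplitude."""
    t = np.arange(int(round(0.04 * sampling_rate))) / sampling_rate
    k = np.sin(2 * np.pi * t / 0.04)
    return k / (k.max() - k.min())


@dataclass
class EvokedGroundTruth:
    """Stimulus-locked LFP deflection whose amplitude changes at a manipulation."""

    amp_pre: float                   # µV (kernel scale before manipulation)
    amp_post: float                  # µV (after)
    manipulation_time: float = 1800.0
    kernel: np.ndarray | None = None  # waveform at sampling_rate; support <= 100 ms
    background_sd: float = 0.0       # µV
    # 1/f^alpha exponent. 1.5 keeps the within-window noise small enough that
    # per-trial peak-to-peak amplitude is an essentially unbiased estimator;
    # exponent 1 inflates small evoked amplitudes by >10%.
    background_alpha: float = 1.5
    sampling_rate: float = 1000.0

    def __post_init__(self):
        if self.amp_pre < 0 or self.amp_post < 0:
            raise InvalidParameterError("evoked amplitudes must be >= 0")
        if self.background_sd < 0:
            raise InvalidParameterError("background_sd must be >= 0")
        if self.kernel is None:
            self.kernel = default_evoked_kernel(self.sampling_rate)
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.size / self.sampling_rate > 0.1 + 1e-9:
            raise InvalidParameterError("kernel support must be <= 100 ms")


def generate_evoked_lfp(
    gt: EvokedGroundTruth,
    schedule: StimSchedule,
    duration: float,
    seed: int,
    channel_id: str = "",
) -> LfpTrace:
    """Background 1/f noise plus the kernel at every pulse onset."""
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    if len(schedule) and schedule.extent > duration + 1e-9:
        raise InvalidParameterError("schedule extends beyond the trace duration")
    if len(schedule) >= 2:
        min_gap = float(np.min(np.diff(schedule.onsets)))
        if gt.kernel.size / gt.sampling_rate > min_gap + 1e-9:
            raise InvalidParameterError(
                "kernel longer than the inter-pulse interval"
            )
    rng = np.random.default_rng(seed)
    fs = gt.sampling_rate
    n = int(round(duration * fs))
    samples = one_over_f_noise(n, gt.background_sd, gt.background_alpha, rng, 1.0 / fs)
    klen = gt.kernel.size
    for onset in schedule.onsets:
        i0 = int(round(onset * fs))
        if i0 >= n:
            continue
        amp = gt.amp_pre if onset < gt.manipulation_time else gt.amp_post
        stop = min(n, i0 + klen)
        samples[i0:stop] += amp * gt.kernel[: stop - i0]
    return LfpTrace(samples, fs, channel_id=channel_id)


# --------------------------------------------------------------------------
# locomotion


@dataclass
class TrackGroundTruth:
    """Reflected random walk with a speed change at the manipulation time."""

    speed_pre: float                 # cm/s
    speed_post: float                # cm/s
    arena: tuple[float, float] = (30.0, 30.0)  # cm
    sampling_rate: float = 25.0      # Hz
    manipulation_time: float | None = 1800.0
    speed_jitter: float = 0.25       # fractional SD of per-step speed
    heading_sd: float = 0.6          # rad per sqrt(s) of heading diffusion

    def __post_init__(self):
        if self.speed_pre < 0 or self.speed_post < 0:
            raise InvalidParameterError("speeds must be >= 0")
        if self.arena[0] <= 0 or self.arena[1] <= 0:
            raise InvalidParameterError("arena dimensions must be > 0")
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be > 0")


def _reflect(p: float, lo: float, hi: float) -> tuple[float, bool]:
    span = hi - lo
    q = (p - lo) % (2 * span)
    reflected = q > span
    return lo + (2 * span - q if reflected else q), reflected


def generate_track(gt: TrackGroundTruth, duration: float, seed: int) -> Track:
    """Billiard-reflected random walk; step speed drawn around the phase target.

    Headings mirror off the walls so the walk does not linger against a
    boundary (which would shorten the recorded path relative to the drawn
    step lengths).
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    rng = np.random.default_rng(seed)
    fs = gt.sampling_rate
    dt = 1.0 / fs
    n = int(round(duration * fs))
    times = np.arange(n) / fs
    switch = gt.manipulation_time if gt.manipulation_time is not None else np.inf
    target = np.where(times[:-1] < switch, gt.speed_pre, gt.speed_post)
    if gt.speed_jitter > 0:
        speeds = np.maximum(
            0.0, rng.normal(target, gt.speed_jitter * np.maximum(target, 0.0))
        )
    else:
        speeds = target.astype(float)
    if gt.heading_sd > 0:
        dheading = rng.normal(0.0, gt.heading_sd * np.sqrt(dt), size=n - 1)
    else:
        dheading = np.zeros(n - 1)
    steps = speeds * dt
    w, h = gt.arena
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = w / 2.0, h / 2.0
    heading = 0.0
    for i in range(n - 1):
        heading += dheading[i]
        px = x[i] + steps[i] * np.cos(heading)
        py = y[i] + steps[i] * np.sin(heading)
        x[i + 1], rx = _reflect(px, 0.0, w)
        y[i + 1], ry = _reflect(py, 0.0, h)
        if rx:
            heading = np.pi - heading
        if ry:
            heading = -heading
    return Track(times, x, y, fs)


# --------------------------------------------------------------------------
# whole sessions


def _gt_to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _gt_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_gt_to_jsonable(v) for v in obj]
    return obj


def generate_full_session(
    out_dir: str | Path,
    seed: int,
    duration: float = 3600.0,
    manipulation_time: float = 1800.0,
    photometry_gt: PhotometryGroundTruth | None = None,
    unit_gts: list[UnitGroundTruth] | None = None,
    evoked_gt: EvokedGroundTruth | None = None,
    track_gt: TrackGroundTruth | None = None,
    schedule: StimSchedule | None = None,
) -> SessionManifest:
    """Generate a complete synthetic session and write it as plain text.

    Ground truth is always emitted alongside the signals so recovery tests
    read truth only from the session directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    if photometry_gt is None:
        photometry_gt = PhotometryGroundTruth.with_poisson_transients(
            rate_pre_per_min=3.0,
            rate_post_per_min=6.0,
            seed=int(rng.integers(2**31)),
            manipulation_time=manipulation_time,
            duration=duration,
        )
    if unit_gts is None:
        unit_gts = [
            UnitGroundTruth(5.0, 2.0, manipulation_time),
            UnitGroundTruth(5.0, 0.5, manipulation_time),
            UnitGroundTruth(5.0, 1.0, manipulation_time),
        ]
    if schedule is None:
        schedule = build_test_pulses(duration)
    if evoked_gt is None:
        evoked_gt = EvokedGroundTruth(
            amp_pre=50.0, amp_post=75.0,
            manipulation_time=manipulation_time, background_sd=10.0,
        )
    if track_gt is None:
        track_gt = TrackGroundTruth(
            speed_pre=2.0, speed_post=6.0, manipulation_time=manipulation_time
        )

    manifest = SessionManifest(
        session_id=f"synthetic-{seed}",
        duration=duration,
        manipulation_time=manipulation_time,
        schedule_file="schedule.csv",
        ground_truth_file="ground_truth.json",
    )
    truth: dict = {"seed": seed}

    trace, _ = generate_photometry(photometry_gt, int(rng.integers(2**31)))
    write_trace(out_dir / "photometry.csv", trace.samples, trace.times)
    manifest.signals["photometry"] = "photometry.csv"
    manifest.sampling_rates["photometry"] = photometry_gt.sampling_rate
    truth["photometry"] = _gt_to_jsonable(asdict(photometry_gt))

    truth["units"] = []
    for i, ugt in enumerate(unit_gts):
        train = generate_spike_train(
            ugt, duration, int(rng.integers(2**31)),
            schedule=schedule, unit_id=f"unit{i}",
        )
        fname = f"unit{i}.csv"
        write_spikes(out_dir / fname, train.spike_times)
        manifest.signals[f"unit{i}"] = fname
        truth["units"].append(_gt_to_jsonable(asdict(ugt)))

    schedule.to_files(out_dir / "schedule.csv")
    lfp = generate_evoked_lfp(
        evoked_gt, schedule, duration, int(rng.integers(2**31)), channel_id="ch0"
    )
    write_trace(out_dir / "lfp.csv", lfp.samples, lfp.times)
    manifest.signals["lfp"] = "lfp.csv"
    manifest.sampling_rates["lfp"] = evoked_gt.sampling_rate
    gt_dict = asdict(evoked_gt)
    truth["evoked"] = _gt_to_jsonable(gt_dict)

    track = generate_track(track_gt, duration, int(rng.integers(2**31)))
    write_track(out_dir / "track.csv", track)
    manifest.signals["track"] = "track.csv"
    manifest.sampling_rates["track"] = track_gt.sampling_rate
    truth["track"] = _gt_to_jsonable(asdict(track_gt))

    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    manifest.save(out_dir / "manifest.json")
    return manifest
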