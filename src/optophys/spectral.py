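"""Bartlett-tapered averaged power spectra and five-band power tables.

Spectra are Welch-style averages of Bartlett (triangular) tapered segments
with 50% overlap by default.  The segment length is derived from the target
frequency grid: 512 values spanning 0-100 Hz, i.e. a spacing of 100/512 Hz
(~0.1953 Hz; 5120-sample segments at 1 kHz).  Power is reported as percent
of the total within 0-100 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import LfpTrace
from .errors import InsufficientDataError, InvalidParameterError

__all__ = [
    "BANDS",
    "PowerSpectrum",
    "BandPowerTable",
    "welch_psd",
    "power_spectrum",
    "band_powers",
    "average_by_group",
]

#: Frequency bands (Hz); half-open [lo, hi) except the last, closed at 100.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 10.0),
    "beta": (10.0, 30.0),
    "low_gamma": (30.0, 80.0),
    "high_gamma": (80.0, 100.0),
}

N_FREQ_VALUES = 512
F_MAX = 100.0


@dataclass
class PowerSpectrum:
    """Percent-of-total power on a fixed 0-100 Hz grid."""

    frequencies: np.ndarray
    power: np.ndarray  # percent, sums to 100

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.size != self.power.size:
            raise InvalidParameterError("frequencies/power length mismatch")


@dataclass
class BandPowerTable:
    """Per-band share of total power (percent)."""

    shares: dict[str, float]

    def total(self) -> float:
        return float(sum(self.shares.values()))


def _segment_length(sampling_rate: float) -> int:
    # spacing of F_MAX / N_FREQ_VALUES Hz requires fs / nperseg = spacing
    return int(round(sampling_rate * N_FREQ_VALUES / F_MAX))


def welch_psd(
    lfp: LfpTrace,
    nperseg: int | None = None,
    overlap: float | int = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Bartlett-tapered averaged periodogram over the full 0-Nyquist range.

    *overlap* < 1 is interpreted as a fraction of the segment length;
    an integer >= 1 as an absolute number of overlapping samples.
    """
    if nperseg is None:
        nperseg = _segment_length(lfp.sampling_rate)
    if lfp.samples.size < nperseg:
        raise InsufficientDataError(
            f"trace shorter than one segment ({lfp.samples.size} < {nperseg})"
        )
    if isinstance(overlap, float) and overlap < 1:
        noverlap = int(round(overlap * nperseg))
    else:
        noverlap = int(overlap)
    if not 0 <= noverlap < nperseg:
        raise InvalidParameterError("overlap must leave a positive hop")
    freqs, psd = sps.welch(
        lfp.samples,
        fs=lfp.sampling_rate,
        window="bartlett",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
    )
    return freqs, psd


def power_spectrum(
    lfp: LfpTrace,
    nperseg: int | None = None,
    overlap: float | int = 0.5,
) -> PowerSpectrum:
    """Percent-of-total spectrum on 512 frequency values spanning 0-100 Hz."""
    freqs, psd = welch_psd(lfp, nperseg=nperseg, overlap=overlap)
    in_range = freqs < F_MAX - 1e-9
    freqs, psd = freqs[in_range], psd[in_range]
    if freqs.size != N_FREQ_VALUES and lfp.sampling_rate >= 2 * F_MAX:
        # only possible if a custom nperseg broke the grid contract
        freqs, psd = freqs[:N_FREQ_VALUES], psd[:N_FREQ_VALUES]
    total = float(np.sum(psd))
    if total == 0:
        raise InvalidParameterError("zero total power in 0-100 Hz")
    return PowerSpectrum(freqs, 100.0 * psd / total)


def band_powers(spec: PowerSpectrum) -> BandPowerTable:
    """Sum percent power into the five canonical bands."""
    if spec.frequencies[-1] > F_MAX + 1e-9:
        raise InvalidParameterError("spectrum extends beyond 100 Hz")
    shares = {}
    for name, (lo, hi) in BANDS.items():
        if hi >= F_MAX:  # top band closed at 100 Hz
            sel = (spec.frequencies >= lo) & (spec.frequencies <= hi)
        else:
            sel = (spec.frequencies >= lo) & (spec.frequencies < hi)
        shares[name] = float(np.sum(spec.power[sel]))
    return BandPowerTable(shares)


def average_by_group(
    spectra: list[PowerSpectrum],
    subjects: list[str],
    groups: list[str] | None = None,
) -> dict[str, PowerSpectrum]:
    """Average electrode spectra within subject, then subjects within group.

    Each subject carries equal weight in its group mean regardless of how
    many electrodes it contributes.
    """
    if not spectra:
        raise InvalidParameterError("need at least one spectrum")
    if len(subjects) != len(spectra):
        raise InvalidParameterError("one subject label per spectrum required")
    if groups is None:
        groups = ["all"] * len(spectra)
    if len(groups) != len(spectra):
        raise InvalidParameterError("one group label per spectrum required")
    grid = spectra[0].frequencies
    for s in spectra[1:]:
        if s.frequencies.size != grid.size or not np.allclose(s.frequencies, grid):
            raise InvalidParameterError("mismatched frequency grids")

    by_subject: dict[tuple[str, str], list[np.ndarray]] = {}
    for spec, subj, grp in zip(spectra, subjects, groups):
        by_subject.setdefault((grp, subj), []).append(spec.power)
    by_group: dict[str, list[np.ndarray]] = {}
    for (grp, _subj), powers in by_subject.items():
        by_group.setdefault(grp, []).append(np.mean(powers, axis=0))
    return {
        grp: PowerSpectrum(grid.copy(), np.mean(subject_means, axis=0))
        for grp, subject_means in by_group.items()
    }
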