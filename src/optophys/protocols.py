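"""Stimulation schedules: sparse test pulses and the LFS/TBS/HFS protocols.

All builders place the first pulse at t = 0 of the protocol epoch; absolute
placement within a session is handled by ``shift``.  Pulse width defaults to
15 ms for every protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "StimSchedule",
    "build_test_pulses",
    "build_lfs",
    "build_tbs",
    "build_hfs",
    "read_schedule",
]

PULSE_WIDTH = 0.015  # seconds


@dataclass
class StimSchedule:
    """Ordered pulse onsets (s) plus pulse width and optional block spans."""

    onsets: np.ndarray
    pulse_width: float
    protocol_name: str = ""
    block_boundaries: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.pulse_width <= 0:
            raise InvalidParameterError("pulse_width must be > 0")
        if self.onsets.size >= 2:
            gaps = np.diff(self.onsets)
            if np.any(gaps <= 0):
                raise InvalidParameterError("onsets must be strictly increasing")
            if np.any(gaps < self.pulse_width - 1e-12):
                raise InvalidParameterError(
                    "consecutive onsets closer than one pulse width"
                )
        blocks = sorted(self.block_boundaries)
        for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
            if e0 > s1:
                raise InvalidParameterError("block boundaries overlap")
        for s0, e0 in blocks:
            if e0 <= s0:
                raise InvalidParameterError("block end must exceed block start")

    def __len__(self) -> int:
        return self.onsets.size

    @property
    def extent(self) -> float:
        """Time of the end of the last pulse."""
        return float(self.onsets[-1] + self.pulse_width) if len(self) else 0.0

    def shift(self, offset: float) -> "StimSchedule":
        """Return a copy translated by *offset* seconds."""
        return replace(
            self,
            onsets=self.onsets + offset,
            block_boundaries=[(s + offset, e + offset) for s, e in self.block_boundaries],
        )

    def in_block(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask: which of *times* fall inside a protocol block."""
        times = np.asarray(times, dtype=float)
        mask = np.zeros(times.shape, dtype=bool)
        for s, e in self.block_boundaries:
            mask |= (times >= s) & (times < e)
        return mask

    # -- serialization: CSV of (onset_s, width_s) plus a JSON header ---------

    def to_files(self, csv_path: str | Path, json_path: str | Path | None = None):
        csv_path = Path(csv_path)
        if json_path is None:
            json_path = csv_path.with_suffix(".json")
        pd.DataFrame(
            {"onset_s": self.onsets, "width_s": self.pulse_width}
        ).to_csv(csv_path, index=False)
        header = {
            "protocol_name": self.protocol_name,
            "pulse_width_s": self.pulse_width,
            "block_boundaries": [list(b) for b in self.block_boundaries],
        }
        Path(json_path).write_text(json.dumps(header, indent=2))


def read_schedule(csv_path: str | Path, json_path: str | Path | None = None) -> StimSchedule:
    csv_path = Path(csv_path)
    if json_path is None:
        json_path = csv_path.with_suffix(".json")
    df = pd.read_csv(csv_path)
    header = json.loads(Path(json_path).read_text())
    return StimSchedule(
        onsets=df["onset_s"].to_numpy(),
        pulse_width=float(header["pulse_width_s"]),
        protocol_name=header.get("protocol_name", ""),
        block_boundaries=[tuple(b) for b in header.get("block_boundaries", [])],
    )


def build_test_pulses(duration: float, pulse_width: float = PULSE_WIDTH) -> StimSchedule:
    """0.2 Hz test pulses: one onset every 5 s starting at t = 0."""
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    onsets = np.arange(0.0, duration, 5.0)
    return StimSchedule(onsets, pulse_width, protocol_name="test_pulses")


def build_lfs(pulse_width: float = PULSE_WIDTH) -> StimSchedule:
    """Low-frequency stimulation: 5 Hz pulses for 15 min (4500 pulses)."""
    onsets = np.arange(0.0, 900.0, 0.2)
    return StimSchedule(onsets, pulse_width, protocol_name="lfs")


def build_tbs(
    pulse_width: float = PULSE_WIDTH, repetition_interval: float = 10.0
) -> StimSchedule:
    """Theta-burst stimulation.

    10 repetitions x 10 trains x 4 pulses = 400 pulses.  Within a train the
    4 pulses run at 50 Hz (20 ms apart); train onsets within a repetition
    follow theta frequency (every 1/10.5 s).  The interval between repetition
    onsets is a convention (default 10 s) chosen so repetitions never overlap.
    """
    if repetition_interval <= 10 / 10.5:
        raise InvalidParameterError("repetition_interval too short: repetitions overlap")
    train_offsets = np.arange(10) / 10.5
    pulse_offsets = np.arange(4) * 0.02
    onsets = (
        repetition_interval * np.arange(10)[:, None, None]
        + train_offsets[None, :, None]
        + pulse_offsets[None, None, :]
    ).ravel()
    return StimSchedule(np.sort(onsets), pulse_width, protocol_name="tbs")


def build_hfs(pulse_width: float = PULSE_WIDTH) -> StimSchedule:
    """High-frequency stimulation: two 5-min 60 Hz blocks, 14 min apart.

    36,000 discrete pulse onsets total; ``block_boundaries`` records the two
    stimulation blocks so trial extraction can exclude them.
    """
    period = 1.0 / 60.0
    block1 = np.arange(0, 18000) * period          # [0, 300) s
    block2 = 1140.0 + np.arange(0, 18000) * period  # [1140, 1440) s
    return StimSchedule(
        np.concatenate([block1, block2]),
        pulse_width,
        protocol_name="hfs",
        block_boundaries=[(0.0, 300.0), (1140.0, 1440.0)],
    )
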