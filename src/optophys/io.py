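"""Plain-text session I/O: columnar CSV signals plus a JSON manifest.

Traces are ``time_s,value`` CSV; spike trains and pulse schedules are one
timestamp per row; tracks are ``time_s,x_cm,y_cm``.  A session directory is
tied together by ``manifest.json``.  ``bundle_hdf5`` optionally packs a
whole session into one HDF5 file.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import LfpTrace, RawTrace, SpikeTrain, Track
from .errors import InvalidParameterError

__all__ = [
    "SessionManifest",
    "write_trace",
    "read_raw_trace",
    "read_lfp_trace",
    "write_spikes",
    "read_spikes",
    "write_track",
    "read_track",
    "bundle_hdf5",
]


@dataclass
class SessionManifest:
    """Describes one recording session's files and analysis parameters."""

    session_id: str
    duration: float
    manipulation_time: float
    signals: dict[str, str] = field(default_factory=dict)  # name -> filename
    sampling_rates: dict[str, float] = field(default_factory=dict)
    schedule_file: str | None = None
    pre_window: tuple[float, float] = (600.0, 1800.0)
    post_window: tuple[float, float] = (2400.0, 3600.0)
    ground_truth_file: str | None = None

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SessionManifest":
        data = json.loads(Path(path).read_text())
        data["pre_window"] = tuple(data["pre_window"])
        data["post_window"] = tuple(data["post_window"])
        return cls(**data)


def write_trace(path: str | Path, samples, times) -> None:
    pd.DataFrame({"time_s": times, "value": samples}).to_csv(path, index=False)


def _read_trace(path: str | Path) -> tuple[np.ndarray, float, float]:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise InvalidParameterError(f"{path}: trace needs >= 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise InvalidParameterError(f"{path}: non-uniform sampling")
    return df["value"].to_numpy(dtype=float), 1.0 / dt[0], float(t[0])


def read_raw_trace(path: str | Path) -> RawTrace:
    samples, fs, t0 = _read_trace(path)
    return RawTrace(samples, fs, start_time=t0)


def read_lfp_trace(path: str | Path, channel_id: str = "") -> LfpTrace:
    samples, fs, t0 = _read_trace(path)
    return LfpTrace(samples, fs, channel_id=channel_id, start_time=t0)


def write_spikes(path: str | Path, spike_times) -> None:
    pd.DataFrame({"time_s": np.asarray(spike_times, dtype=float)}).to_csv(
        path, index=False
    )


def read_spikes(
    path: str | Path, unit_id: str, session_extent: tuple[float, float]
) -> SpikeTrain:
    df = pd.read_csv(path)
    return SpikeTrain(unit_id, df["time_s"].to_numpy(dtype=float), session_extent)


def write_track(path: str | Path, track: Track) -> None:
    pd.DataFrame(
        {"time_s": track.times, "x_cm": track.x, "y_cm": track.y}
    ).to_csv(path, index=False)


def read_track(path: str | Path) -> Track:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    fs = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 0.0
    return Track(t, df["x_cm"].to_numpy(float), df["y_cm"].to_numpy(float), fs)


def bundle_hdf5(session_dir: str | Path, out_path: str | Path) -> None:
    """Pack every CSV signal referenced by a session manifest into HDF5."""
    session_dir = Path(session_dir)
    manifest = SessionManifest.load(session_dir / "manifest.json")
    with h5py.File(out_path, "w") as h5:
        h5.attrs["session_id"] = manifest.session_id
        h5.attrs["manipulation_time"] = manifest.manipulation_time
        h5.attrs["duration"] = manifest.duration
        for name, fname in manifest.signals.items():
            df = pd.read_csv(session_dir / fname)
            grp = h5.create_group(name)
            for col in df.columns:
                grp.create_dataset(col, data=df[col].to_numpy())
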