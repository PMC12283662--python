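"""Domain types and on-disk trial format for multimodal strength-assessment recordings.

A *trial* is one shoulder-flexion repetition recorded simultaneously on two
streams: three-channel surface EMG over the deltoid fascicles (nominally
10 kHz) and a six-axis IMU (triaxial accelerometer + gyroscope, nominally
100 Hz), labelled with a manual-muscle-testing (MMT) strength grade in
[2, 5].

On disk a trial is a directory with three plain-text files::

    trial_dir/
        emg.csv    # t, ch1, ch2, ch3
        imu.csv    # t, ax, ay, az, gx, gy, gz [, pitch, roll, yaw]
        meta.yaml  # subject_id, trial_id, grade, fs_emg, fs_imu, acc_units, ...

Canonical units: acceleration in g, angular velocity in deg/s, angles in
degrees, time in seconds on a clock shared by both streams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EMG_CHANNELS",
    "EmgTrial",
    "ImuTrial",
    "TrialRecord",
    "AlignedTrial",
    "FormatError",
    "DataError",
    "LabelError",
    "AlignmentError",
    "read_trial",
    "write_trial",
    "align_streams",
    "MIN_OVERLAP_S",
]

#: Fixed channel order for the three deltoid fascicles.
EMG_CHANNELS = ("anterior_deltoid", "middle_deltoid", "posterior_deltoid")

#: Shortest usable overlap between the sEMG and IMU streams, in seconds.
#: One flexion takes seconds; anything shorter indicates a clock fault.
MIN_OVERLAP_S = 0.5


class FormatError(ValueError):
    """A trial file violates the documented layout (e.g. wrong channel count)."""


class DataError(ValueError):
    """A trial file contains non-numeric or NaN samples."""


class LabelError(ValueError):
    """The strength-grade label is outside the supported range [2, 5]."""


class AlignmentError(ValueError):
    """The two streams do not share a usable time overlap."""


@dataclass
class EmgTrial:
    """Three-channel surface-EMG recording.

    Attributes
    ----------
    subject_id, trial_id : str
        Identifiers shared with the paired IMU stream.
    fs_emg : float
        Sampling rate in Hz (nominally 10000).
    channels : tuple of str
        Muscle labels in fixed order (anterior, middle, posterior deltoid).
    samples : ndarray, shape (n, 3)
        Amplitudes in arbitrary units (zero-mean after acquisition).
    t0 : float
        Start time in seconds on the shared clock.
    """

    subject_id: str
    trial_id: str
    fs_emg: float
    samples: np.ndarray
    t0: float = 0.0
    channels: tuple = EMG_CHANNELS

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_emg <= 0:
            raise FormatError(f"fs_emg must be positive, got {self.fs_emg}")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise FormatError(
                f"sEMG requires exactly 3 channels, got shape {self.samples.shape}"
            )
        if len(self.channels) != 3:
            raise FormatError("exactly 3 channel labels required")
        if not np.isfinite(self.samples).all():
            raise DataError("sEMG samples contain NaN/inf")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs_emg

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs_emg


@dataclass
class ImuTrial:
    """Six-axis IMU recording (plus optional device-reported Euler angles).

    acc is in g, gyro in deg/s, euler_device (pitch, roll, yaw) in degrees.
    """

    subject_id: str
    trial_id: str
    fs_imu: float
    acc: np.ndarray
    gyro: np.ndarray
    euler_device: np.ndarray | None = None
    acc_units: str = "g"
    t0: float = 0.0

    def __post_init__(self):
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.fs_imu <= 0:
            raise FormatError(f"fs_imu must be positive, got {self.fs_imu}")
        for name, arr in (("acc", self.acc), ("gyro", self.gyro)):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise FormatError(f"{name} must be (n, 3), got {arr.shape}")
        if self.acc.shape[0] != self.gyro.shape[0]:
            raise FormatError("acc and gyro must have the same length")
        if not (np.isfinite(self.acc).all() and np.isfinite(self.gyro).all()):
            raise DataError("IMU samples contain NaN/inf")
        if self.euler_device is not None:
            self.euler_device = np.asarray(self.euler_device, dtype=float)
            if self.euler_device.shape != (self.acc.shape[0], 3):
                raise FormatError("euler_device must be (n, 3) matching acc/gyro")
        if self.acc_units not in ("g", "m/s^2"):
            raise FormatError(f"unknown acc_units {self.acc_units!r}")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs_imu

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def to_canonical(self) -> "ImuTrial":
        """Return a copy with acceleration in g (the canonical unit)."""
        if self.acc_units == "g":
            return self
        out = dataclasses.replace(self, acc=self.acc / 9.80665, acc_units="g")
        return out


@dataclass
class TrialRecord:
    """One labelled trial: paired sEMG + IMU streams and the MMT grade."""

    emg: EmgTrial
    imu: ImuTrial
    grade: float
    usable: bool = True

    def __post_init__(self):
        if not (2.0 <= self.grade <= 5.0):
            raise LabelError(f"grade must lie in [2, 5], got {self.grade}")
        if (self.emg.subject_id, self.emg.trial_id) != (
            self.imu.subject_id,
            self.imu.trial_id,
        ):
            raise FormatError("emg and imu identifiers disagree")


@dataclass
class AlignedTrial:
    """A trial with the overlap window of its two streams resolved."""

    emg: EmgTrial
    imu: ImuTrial
    overlap_window: tuple = field(default=(0.0, 0.0))

    def __post_init__(self):
        t_start, t_end = self.overlap_window
        if t_end <= t_start:
            raise AlignmentError("overlap window must have positive length")


# ---------------------------------------------------------------------------
# On-disk format
# ---------------------------------------------------------------------------

def write_trial(record: TrialRecord, path: str | Path) -> Path:
    """Write a trial to `path` as emg.csv + imu.csv + meta.yaml.

    Inverse of :func:`read_trial` on canonical-unit records.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    emg, imu = record.emg, record.imu

    emg_df = pd.DataFrame(
        {
            "t": emg.times,
            "ch1": emg.samples[:, 0],
            "ch2": emg.samples[:, 1],
            "ch3": emg.samples[:, 2],
        }
    )
    emg_df.to_csv(path / "emg.csv", index=False, float_format="%.17g")

    t_imu = imu.t0 + np.arange(imu.n_samples) / imu.fs_imu
    cols = {
        "t": t_imu,
        "ax": imu.acc[:, 0],
        "ay": imu.acc[:, 1],
        "az": imu.acc[:, 2],
        "gx": imu.gyro[:, 0],
        "gy": imu.gyro[:, 1],
        "gz": imu.gyro[:, 2],
    }
    if imu.euler_device is not None:
        cols["pitch"] = imu.euler_device[:, 0]
        cols["roll"] = imu.euler_device[:, 1]
        cols["yaw"] = imu.euler_device[:, 2]
    pd.DataFrame(cols).to_csv(path / "imu.csv", index=False, float_format="%.17g")

    meta = {
        "subject_id": emg.subject_id,
        "trial_id": emg.trial_id,
        "grade": float(record.grade),
        "usable": bool(record.usable),
        "fs_emg": float(emg.fs_emg),
        "fs_imu": float(imu.fs_imu),
        "acc_units": imu.acc_units,
        "t0_emg": float(emg.t0),
        "t0_imu": float(imu.t0),
        "channels": list(emg.channels),
    }
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def read_trial(path: str | Path) -> TrialRecord:
    """Load a trial directory written by :func:`write_trial`.

    Units are converted to canonical form (acceleration in g).

    Raises
    ------
    FormatError
        Missing file or channel, or malformed layout.
    DataError
        NaN or non-numeric samples.
    LabelError
        Grade outside [2, 5].
    """
    path = Path(path)
    for fname in ("emg.csv", "imu.csv", "meta.yaml"):
        if not (path / fname).exists():
            raise FormatError(f"trial directory {path} is missing {fname}")

    with open(path / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    for key in ("subject_id", "trial_id", "grade", "fs_emg", "fs_imu"):
        if key not in meta:
            raise FormatError(f"meta.yaml missing required key {key!r}")

    try:
        emg_df = pd.read_csv(path / "emg.csv", float_precision="round_trip")
        imu_df = pd.read_csv(path / "imu.csv", float_precision="round_trip")
    except ValueError as exc:  # pragma: no cover - pandas parse failure
        raise DataError(f"could not parse trial CSVs: {exc}") from exc

    emg_cols = ["ch1", "ch2", "ch3"]
    if not all(c in emg_df.columns for c in emg_cols):
        raise FormatError(
            f"emg.csv must contain columns {emg_cols}, got {list(emg_df.columns)}"
        )
    imu_cols = ["ax", "ay", "az", "gx", "gy", "gz"]
    if not all(c in imu_df.columns for c in imu_cols):
        raise FormatError(
            f"imu.csv must contain columns {imu_cols}, got {list(imu_df.columns)}"
        )

    emg_samples = emg_df[emg_cols].to_numpy(dtype=float)
    if not np.isfinite(emg_samples).all():
        raise DataError("emg.csv contains NaN or non-numeric samples")
    acc = imu_df[["ax", "ay", "az"]].to_numpy(dtype=float)
    gyro = imu_df[["gx", "gy", "gz"]].to_numpy(dtype=float)
    if not (np.isfinite(acc).all() and np.isfinite(gyro).all()):
        raise DataError("imu.csv contains NaN or non-numeric samples")

    euler = None
    if all(c in imu_df.columns for c in ("pitch", "roll", "yaw")):
        euler = imu_df[["pitch", "roll", "yaw"]].to_numpy(dtype=float)

    grade = float(meta["grade"])
    if not (2.0 <= grade <= 5.0):
        raise LabelError(f"grade {grade} outside [2, 5] in {path}")

    emg = EmgTrial(
        subject_id=str(meta["subject_id"]),
        trial_id=str(meta["trial_id"]),
        fs_emg=float(meta["fs_emg"]),
        samples=emg_samples,
        t0=float(meta.get("t0_emg", emg_df["t"].iloc[0] if "t" in emg_df else 0.0)),
        channels=tuple(meta.get("channels", EMG_CHANNELS)),
    )
    imu = ImuTrial(
        subject_id=str(meta["subject_id"]),
        trial_id=str(meta["trial_id"]),
        fs_imu=float(meta["fs_imu"]),
        acc=acc,
        gyro=gyro,
        euler_device=euler,
        acc_units=str(meta.get("acc_units", "g")),
        t0=float(meta.get("t0_imu", imu_df["t"].iloc[0] if "t" in imu_df else 0.0)),
    ).to_canonical()

    return TrialRecord(emg=emg, imu=imu, grade=grade, usable=bool(meta.get("usable", True)))


# ---------------------------------------------------------------------------
# Temporal alignment
# ---------------------------------------------------------------------------

def align_streams(emg: EmgTrial, imu: ImuTrial, min_overlap: float = MIN_OVERLAP_S) -> AlignedTrial:
    """Intersect the time spans of the two streams on the shared clock.

    The overlap window is ``[max(t0s), min(end times)]``. Trials whose
    overlap is shorter than `min_overlap` (default 0.5 s) are rejected —
    a flexion takes seconds, so a sub-half-second overlap implies a clock
    fault rather than a short movement.
    """
    t_start = max(emg.t0, imu.t0)
    t_end = min(emg.t_end, imu.t_end)
    if t_end - t_start < min_overlap:
        raise AlignmentError(
            f"stream overlap [{t_start}, {t_end}] shorter than {min_overlap} s"
        )
    return AlignedTrial(emg=emg, imu=imu, overlap_window=(t_start, t_end))
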