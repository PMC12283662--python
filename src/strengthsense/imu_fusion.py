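"""Complementary-filter orientation fusion and per-trial kinematic scalars.

The accelerometer gives absolute (gravity-referenced) inclination that is
noisy during motion; the gyroscope gives smooth angular rates that drift
when integrated. A first-order complementary filter blends the two with a
fusion coefficient K (default 0.4):

    roll  <- K * (roll_prev  + wx * dt) + (1 - K) * roll_acc
    pitch <- K * (pitch_prev + wy * dt) + (1 - K) * pitch_acc
    yaw   <- yaw_prev + wz * dt                      (gyro-only)

Yaw has no gravity reference (and no magnetometer here), so it is pure
gyro integration and drifts slowly. Axes follow the sensor convention:
rotation about X is roll, about Y pitch, about Z yaw, with X mounted
anteriorly on the upper arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_types import ImuTrial

__all__ = [
    "FusionConfig",
    "OrientationSeries",
    "ImuFeatureSet",
    "IMU_FEATURE_NAMES",
    "accel_angles",
    "complementary_filter",
    "fuse_trial",
    "imu_scalarize",
]

#: Canonical order of the nine IMU scalar features.
IMU_FEATURE_NAMES = (
    "gyro_x",
    "gyro_y",
    "gyro_z",
    "acc_x",
    "acc_y",
    "acc_z",
    "pitch",
    "roll",
    "yaw",
)


@dataclass(frozen=True)
class FusionConfig:
    """Complementary-filter parameters.

    K : fusion coefficient in [0, 1]; K=0 trusts the accelerometer only,
        K=1 integrates the gyro only. Default 0.4.
    initial_angles : (roll, pitch, yaw) in degrees at t=0.
    use_device_angles : when True and the trial carries device-reported
        Euler angles, those are used verbatim instead of re-fusing.
    """

    K: float = 0.4
    initial_angles: tuple = (0.0, 0.0, 0.0)
    use_device_angles: bool = False

    def __post_init__(self):
        if not (0.0 <= self.K <= 1.0):
            raise ValueError(f"K must lie in [0, 1], got {self.K}")


@dataclass
class OrientationSeries:
    """Fused roll/pitch/yaw time series in degrees at the IMU rate."""

    roll: np.ndarray
    pitch: np.ndarray
    yaw: np.ndarray
    fs: float

    def __post_init__(self):
        for name in ("roll", "pitch", "yaw"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} series contains non-finite values")
            setattr(self, name, arr)
        if not (len(self.roll) == len(self.pitch) == len(self.yaw)):
            raise ValueError("roll/pitch/yaw must share a length")


@dataclass(frozen=True)
class ImuFeatureSet:
    """Nine per-trial kinematic scalars (peak absolute values)."""

    gyro_x: float
    gyro_y: float
    gyro_z: float
    acc_x: float
    acc_y: float
    acc_z: float
    pitch: float
    roll: float
    yaw: float

    def as_row(self) -> dict:
        return {name: getattr(self, name) for name in IMU_FEATURE_NAMES}


def accel_angles(acc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inclination angles from the gravity direction, in degrees.

    roll_acc  = atan2(a_y, a_z)
    pitch_acc = atan2(-a_x, sqrt(a_y^2 + a_z^2))

    With the sensor at rest and gravity along +Z this gives (0, 0); a pure
    pitch rotation theta maps the measured gravity vector to
    (-sin(theta), 0, cos(theta)) and is recovered exactly.

    Raises on a zero acceleration vector (the inclination is undefined).
    """
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2 or acc.shape[1] != 3:
        raise ValueError(f"acc must be (n, 3), got {acc.shape}")
    norms = np.linalg.norm(acc, axis=1)
    if np.any(norms == 0.0):
        bad = int(np.argmax(norms == 0.0))
        raise ValueError(f"zero acceleration vector at sample {bad}: angle undefined")
    ax, ay, az = acc[:, 0], acc[:, 1], acc[:, 2]
    roll_acc = np.degrees(np.arctan2(ay, az))
    pitch_acc = np.degrees(np.arctan2(-ax, np.hypot(ay, az)))
    return roll_acc, pitch_acc


def complementary_filter(
    gyro: np.ndarray,
    roll_acc: np.ndarray,
    pitch_acc: np.ndarray,
    dt: float,
    cfg: FusionConfig = FusionConfig(),
) -> OrientationSeries:
    """Fuse gyro rates with accelerometer inclination into roll/pitch/yaw.

    Per step, roll and pitch are the K-weighted blend of the propagated
    previous estimate (prev + omega*dt) and the accelerometer angle; yaw
    is pure gyro integration. All angles in degrees, rates in deg/s.
    """
    gyro = np.asarray(gyro, dtype=float)
    roll_acc = np.asarray(roll_acc, dtype=float)
    pitch_acc = np.asarray(pitch_acc, dtype=float)
    if gyro.ndim != 2 or gyro.shape[1] != 3:
        raise ValueError(f"gyro must be (n, 3), got {gyro.shape}")
    n = gyro.shape[0]
    if len(roll_acc) != n or len(pitch_acc) != n:
        raise ValueError("gyro and accelerometer-angle series must share a length")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")

    K = cfg.K
    roll = np.empty(n)
    pitch = np.empty(n)
    yaw = np.empty(n)
    r, p, y = cfg.initial_angles
    for i in range(n):
        r = K * (r + gyro[i, 0] * dt) + (1.0 - K) * roll_acc[i]
        p = K * (p + gyro[i, 1] * dt) + (1.0 - K) * pitch_acc[i]
        y = y + gyro[i, 2] * dt
        roll[i], pitch[i], yaw[i] = r, p, y
    return OrientationSeries(roll=roll, pitch=pitch, yaw=yaw, fs=1.0 / dt)


def fuse_trial(imu: ImuTrial, cfg: FusionConfig = FusionConfig()) -> OrientationSeries:
    """Orientation series for a whole IMU trial.

    Uses device-reported Euler angles verbatim when the config asks for it
    and the trial carries them; otherwise re-fuses from raw acc/gyro.
    """
    if cfg.use_device_angles and imu.euler_device is not None:
        e = imu.euler_device  # columns: pitch, roll, yaw
        return OrientationSeries(roll=e[:, 1], pitch=e[:, 0], yaw=e[:, 2], fs=imu.fs_imu)
    roll_acc, pitch_acc = accel_angles(imu.acc)
    return complementary_filter(imu.gyro, roll_acc, pitch_acc, dt=1.0 / imu.fs_imu, cfg=cfg)


def _wrap_deg(a: float) -> float:
    """Wrap an angle magnitude into [-180, 180]."""
    return float((a + 180.0) % 360.0 - 180.0)


def imu_scalarize(
    acc: np.ndarray, gyro: np.ndarray, orient: OrientationSeries
) -> ImuFeatureSet:
    """Reduce each of the nine kinematic channels to a per-trial scalar.

    Accelerometer and gyro channels: peak absolute value over the trial.
    Euler angles: peak absolute excursion from the trial's initial angle —
    muscle strength relates to how far (and fast) the limb travels, so the
    peak captures the discriminative extreme.
    """
    acc = np.asarray(acc, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    if acc.size == 0 or gyro.size == 0 or len(orient.roll) == 0:
        raise ValueError("cannot scalarize empty series")

    def peak(v):
        return float(np.max(np.abs(v)))

    def excursion(v):
        return _wrap_deg(np.max(np.abs(v - v[0])))

    return ImuFeatureSet(
        gyro_x=peak(gyro[:, 0]),
        gyro_y=peak(gyro[:, 1]),
        gyro_z=peak(gyro[:, 2]),
        acc_x=peak(acc[:, 0]),
        acc_y=peak(acc[:, 1]),
        acc_z=peak(acc[:, 2]),
        pitch=excursion(orient.pitch),
        roll=excursion(orient.roll),
        yaw=excursion(orient.yaw),
    )
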