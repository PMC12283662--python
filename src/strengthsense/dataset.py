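"""Assemble the n x 21 feature table, min-max normalize, and partition it.

Each usable trial contributes one row of 21 features: the four sEMG
features (RMS, iEMG, MAV, MF) for each of the three deltoid channels,
plus nine IMU kinematic scalars (peak |gyro| and |acc| per axis, peak
pitch/roll/yaw excursion). The MMT grade is the regression target.

Normalization is the min-max map ``x' = (x - min) / (max - min)`` fitted
per column. By default it is fitted on the training partition only and
then applied to the test partition (whose values may fall outside [0, 1]);
fitting on all data leaks test information and can be requested explicitly
with ``norm_on_all``.
"""

from __future__ import annotations

import dataclasses as _dc
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emg_features import emg_feature_set, EMG_FEATURE_NAMES
from .imu_fusion import (
    FusionConfig,
    IMU_FEATURE_NAMES,
    fuse_trial,
    imu_scalarize,
)
from .io_types import TrialRecord, align_streams
from .preprocess import SgConfig, sg_denoise

__all__ = [
    "FeatureTable",
    "NormState",
    "SplitSpec",
    "FEATURE_COLUMNS",
    "extract_features",
    "assemble",
    "fit_norm",
    "apply_norm",
    "split",
    "kfold",
]

#: Canonical 21-column order: 3 muscles x 4 sEMG features, then 9 IMU scalars.
_MUSCLES = ("anterior_deltoid", "middle_deltoid", "posterior_deltoid")
FEATURE_COLUMNS = tuple(
    f"{m}_{f}" for m in _MUSCLES for f in EMG_FEATURE_NAMES
) + IMU_FEATURE_NAMES


@dataclass
class FeatureTable:
    """n x 21 feature matrix with grade labels and subject ids."""

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray
    column_names: tuple = FEATURE_COLUMNS

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.column_names):
            raise ValueError(
                f"X must have {len(self.column_names)} columns, got {self.X.shape}"
            )
        if not np.isfinite(self.X).all():
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise ValueError(
                f"non-finite feature at row {bad[0]}, column {self.column_names[bad[1]]}"
            )
        if len(self.y) != self.X.shape[0] or len(self.subject_ids) != self.X.shape[0]:
            raise ValueError("X, y and subject_ids must share n rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def take(self, idx) -> "FeatureTable":
        return FeatureTable(
            X=self.X[idx],
            y=self.y[idx],
            subject_ids=self.subject_ids[idx],
            column_names=self.column_names,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.column_names))
        df.insert(0, "subject_id", self.subject_ids)
        df["grade"] = self.y
        return df


@dataclass(frozen=True)
class NormState:
    """Per-column min and max from the fitting partition."""

    mins: np.ndarray
    maxs: np.ndarray
    column_names: tuple = FEATURE_COLUMNS

    def to_dict(self) -> dict:
        return {
            name: {"min": float(lo), "max": float(hi)}
            for name, lo, hi in zip(self.column_names, self.mins, self.maxs)
        }


@dataclass(frozen=True)
class SplitSpec:
    """Train fraction, RNG seed and fold count for partitioning."""

    train_fraction: float = 0.7
    seed: int = 0
    folds: int = 5

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def extract_features(
    record: TrialRecord,
    sg_cfg: SgConfig = SgConfig(),
    fusion_cfg: FusionConfig = FusionConfig(),
) -> dict:
    """Run one trial through alignment, denoising, and both feature banks.

    Returns the 21-feature row as an ordered dict keyed by FEATURE_COLUMNS.
    """
    aligned = align_streams(record.emg, record.imu)
    t0, t1 = aligned.overlap_window

    emg = record.emg
    i0 = int(np.ceil((t0 - emg.t0) * emg.fs_emg))
    i1 = int(np.floor((t1 - emg.t0) * emg.fs_emg))
    emg_win = emg.samples[i0 : i1 + 1]
    emg_cut = _dc.replace(emg, samples=emg_win, t0=emg.t0 + i0 / emg.fs_emg)
    denoised = sg_denoise(emg_cut, sg_cfg)
    emg_feats = emg_feature_set(denoised)

    imu = record.imu
    j0 = int(np.ceil((t0 - imu.t0) * imu.fs_imu))
    j1 = int(np.floor((t1 - imu.t0) * imu.fs_imu))
    sl = slice(j0, j1 + 1)
    imu_cut = _dc.replace(
        imu,
        acc=imu.acc[sl],
        gyro=imu.gyro[sl],
        euler_device=None if imu.euler_device is None else imu.euler_device[sl],
        t0=imu.t0 + j0 / imu.fs_imu,
    )
    orient = fuse_trial(imu_cut, fusion_cfg)
    imu_feats = imu_scalarize(imu_cut.acc, imu_cut.gyro, orient)

    row = emg_feats.as_row(emg.channels)
    row.update(imu_feats.as_row())
    return {name: row[name] for name in FEATURE_COLUMNS}


def assemble(
    trials: list,
    sg_cfg: SgConfig = SgConfig(),
    fusion_cfg: FusionConfig = FusionConfig(),
) -> FeatureTable:
    """Build the feature table from processed trials, dropping unusable ones.

    Raises if the list is empty or a feature comes out non-finite (the
    error names the offending trial and column).
    """
    usable = [t for t in trials if t.usable]
    if not usable:
        raise ValueError("no usable trials to assemble")
    rows, ys, sids = [], [], []
    for rec in usable:
        row = extract_features(rec, sg_cfg, fusion_cfg)
        for name, val in row.items():
            if not np.isfinite(val):
                raise ValueError(
                    f"non-finite feature {name} in trial "
                    f"{rec.emg.subject_id}/{rec.emg.trial_id}"
                )
        rows.append([row[name] for name in FEATURE_COLUMNS])
        ys.append(rec.grade)
        sids.append(rec.emg.subject_id)
    return FeatureTable(X=np.array(rows), y=np.array(ys), subject_ids=np.array(sids))


def fit_norm(X_train: np.ndarray, column_names=FEATURE_COLUMNS) -> NormState:
    """Per-column min and max of the fitting partition."""
    X_train = np.asarray(X_train, dtype=float)
    return NormState(
        mins=X_train.min(axis=0), maxs=X_train.max(axis=0), column_names=tuple(column_names)
    )


def apply_norm(X: np.ndarray, state: NormState) -> np.ndarray:
    """Min-max transform ``(x - min) / (max - min)`` columnwise.

    Degenerate columns (max == min) map to 0. Values outside the fitted
    range extrapolate linearly (test values may leave [0, 1]).
    """
    X = np.asarray(X, dtype=float)
    span = state.maxs - state.mins
    out = np.zeros_like(X)
    ok = span > 0
    out[:, ok] = (X[:, ok] - state.mins[ok]) / span[ok]
    if not ok.all():
        degenerate = [state.column_names[i] for i in np.flatnonzero(~ok)]
        warnings.warn(f"degenerate (constant) columns mapped to 0: {degenerate}")
    return out


def split(table: FeatureTable, spec: SplitSpec) -> tuple[FeatureTable, FeatureTable]:
    """Seeded 7:3 (by default) row split.

    The train size is ``floor(train_fraction * n)``; rows are shuffled
    with the spec seed, so identical seeds give identical partitions.
    """
    if table.n < 10:
        raise ValueError(f"need at least 10 rows to split, got {table.n}")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(table.n)
    n_train = int(np.floor(spec.train_fraction * table.n))
    return table.take(perm[:n_train]), table.take(perm[n_train:])


def kfold(n: int, spec: SplitSpec) -> list[np.ndarray]:
    """Disjoint, exhaustive, seeded k-fold partition of ``range(n)``.

    Returns a list of ``spec.folds`` index arrays. Sizes differ by at most
    one (n = 145, k = 5 gives five folds of 29).
    """
    if n < spec.folds:
        raise ValueError(f"cannot make {spec.folds} folds from {n} rows")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, spec.folds)]
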