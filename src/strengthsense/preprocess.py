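"""Savitzky-Golay denoising of sEMG and rule-based channel quality control.

The Savitzky-Golay filter fits a low-order polynomial to each sliding
window by least squares and takes the fitted value at the window centre,
which suppresses broadband noise while preserving waveform morphology
(peak structure, slope continuity) — the property that makes it a common
choice for sEMG. Defaults: window of 51 samples, cubic polynomial.

Quality control mirrors standard bench practice: a channel fails if its
low-frequency baseline wanders too far or if mains interference dominates
the spectrum. QC is report-only here; dropping failed channels is a
pipeline-level policy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_types import EmgTrial

__all__ = ["SgConfig", "QcConfig", "ChannelQc", "QcReport", "sg_denoise", "qc_channels"]


@dataclass(frozen=True)
class SgConfig:
    """Savitzky-Golay parameters: odd window length (samples) and polynomial order."""

    window_length: int = 51
    polyorder: int = 3

    def __post_init__(self):
        if self.window_length % 2 != 1 or self.window_length < 3:
            raise ValueError("window_length must be an odd integer >= 3")
        if not (0 <= self.polyorder < self.window_length):
            raise ValueError("polyorder must satisfy 0 <= polyorder < window_length")


@dataclass(frozen=True)
class QcConfig:
    """Channel-quality thresholds.

    drift_max_frac : baseline drift limit as a fraction of channel RMS.
    drift_max_abs : absolute drift limit in amplitude units; overrides the
        fractional rule when set.
    powerline_ratio_max : max fraction of power within ±1 Hz of mains.
    powerline_hz : mains frequency (50 Hz default; switch to 60 where applicable).
    """

    drift_max_frac: float = 0.2
    drift_max_abs: float | None = None
    powerline_ratio_max: float = 0.2
    powerline_hz: float = 50.0


@dataclass(frozen=True)
class ChannelQc:
    channel: str
    baseline_drift: float
    powerline_ratio: float
    passed: bool


@dataclass(frozen=True)
class QcReport:
    channels: tuple

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.channels)

    def to_dict(self) -> dict:
        return {
            c.channel: {
                "baseline_drift": c.baseline_drift,
                "powerline_ratio": c.powerline_ratio,
                "passed": c.passed,
            }
            for c in self.channels
        }


def sg_denoise(trial: EmgTrial, cfg: SgConfig = SgConfig()) -> EmgTrial:
    """Apply per-channel Savitzky-Golay smoothing; output length equals input.

    Edges are handled by mirror padding: the signal is reflected (without
    repeating the edge sample) by (window_length - 1) / 2 samples on each
    side, so every output sample is a genuine centred window fit.
    """
    if trial.n_samples < cfg.window_length:
        raise ValueError(
            f"signal length {trial.n_samples} shorter than window {cfg.window_length}"
        )
    smoothed = signal.savgol_filter(
        trial.samples,
        window_length=cfg.window_length,
        polyorder=cfg.polyorder,
        axis=0,
        mode="mirror",
    )
    return dataclasses.replace(trial, samples=smoothed)


def _baseline_drift(x: np.ndarray, fs: float) -> float:
    """Peak-to-peak range of the sub-1 Hz baseline trend.

    The signal is first block-mean decimated to ~20 Hz, then low-passed at
    1 Hz (2nd-order Butterworth, zero phase). Filtering at the decimated
    rate keeps the normalized cutoff well away from zero, where IIR
    filters lose numerical reliability at sEMG sampling rates.
    """
    block = max(1, int(round(fs / 20.0)))
    nb = len(x) // block
    xm = x[: nb * block].reshape(nb, block).mean(axis=1)
    fs_dec = fs / block
    if fs_dec <= 2.0 or nb < 10:
        trend = xm
    else:
        sos = signal.butter(2, 1.0, btype="low", fs=fs_dec, output="sos")
        trend = signal.sosfiltfilt(sos, xm, padlen=nb - 1)
    return float(np.ptp(trend))


def _powerline_ratio(x: np.ndarray, fs: float, f0: float) -> float:
    """Fraction of spectral power within f0 ± 1 Hz (periodogram estimate)."""
    freqs, psd = signal.periodogram(x, fs=fs)
    total = float(np.sum(psd))
    if total <= 0.0:
        return 0.0
    band = (freqs >= f0 - 1.0) & (freqs <= f0 + 1.0)
    return float(np.sum(psd[band]) / total)


def qc_channels(trial: EmgTrial, cfg: QcConfig = QcConfig()) -> QcReport:
    """Assess each sEMG channel for baseline drift and mains interference.

    A channel passes iff its baseline drift is below ``drift_max_frac`` of
    the channel RMS and the mains-band power fraction is below
    ``powerline_ratio_max``. Requires at least one second of signal so the
    sub-1 Hz trend is estimable.
    """
    if trial.duration < 1.0:
        raise ValueError("QC requires a trial of at least 1 s")
    reports = []
    for j, name in enumerate(trial.channels):
        x = trial.samples[:, j]
        drift = _baseline_drift(x, trial.fs_emg)
        ratio = _powerline_ratio(x, trial.fs_emg, cfg.powerline_hz)
        rms = float(np.sqrt(np.mean(x**2)))
        if cfg.drift_max_abs is not None:
            drift_limit = cfg.drift_max_abs
        else:
            drift_limit = cfg.drift_max_frac * rms
        passed = (drift < drift_limit or rms == 0.0) and ratio < cfg.powerline_ratio_max
        reports.append(
            ChannelQc(channel=name, baseline_drift=drift, powerline_ratio=ratio, passed=passed)
        )
    return QcReport(channels=tuple(reports))
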