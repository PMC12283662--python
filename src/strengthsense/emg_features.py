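"""Time- and frequency-domain sEMG features: RMS, iEMG, MAV and median frequency.

Per channel over the trial's active window:

* ``RMS  = sqrt(mean(x_i^2))`` — signal energy; grows with recruitment.
* ``MAV  = mean(|x_i|)`` — rectified mean amplitude.
* ``iEMG = sum(|x_i|) / fs`` — rectangular-rule integral of the rectified
  signal, i.e. cumulative area under the curve; satisfies
  ``iEMG = MAV * duration`` by construction.
* ``MF`` — the median frequency: the frequency splitting the power
  spectral density into equal-power halves, estimated from a Welch
  periodogram with linear interpolation inside the crossing bin. MF falls
  with fatigue and shifts with contraction intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_types import EmgTrial

__all__ = [
    "EmgFeatureSet",
    "compute_rms",
    "compute_mav",
    "compute_iemg",
    "compute_mf",
    "emg_feature_set",
    "EMG_FEATURE_NAMES",
]

#: Per-channel feature order used throughout the feature table.
EMG_FEATURE_NAMES = ("rms", "iemg", "mav", "mf")


@dataclass(frozen=True)
class EmgFeatureSet:
    """Four scalar features for each of the three channels.

    Keys of each dict are channel labels. Units: rms/mav in amplitude
    units, iemg in amplitude*seconds, mf in Hz.
    """

    rms: dict
    iemg: dict
    mav: dict
    mf: dict

    def as_row(self, channels) -> dict:
        """Flatten to ``{channel}_{feature}: value`` in canonical order."""
        row = {}
        for ch in channels:
            for feat in EMG_FEATURE_NAMES:
                row[f"{ch}_{feat}"] = getattr(self, feat)[ch]
        return row


def compute_rms(x: np.ndarray) -> float:
    """Root mean square amplitude, sqrt((1/N) * sum x_i^2)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("RMS undefined for an empty vector")
    return float(np.sqrt(np.mean(x**2)))


def compute_mav(x: np.ndarray) -> float:
    """Mean absolute value, (1/N) * sum |x_i|."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("MAV undefined for an empty vector")
    return float(np.mean(np.abs(x)))


def compute_iemg(x: np.ndarray, fs: float) -> float:
    """Integrated EMG: rectangular-rule integral of the rectified signal.

    ``sum |x_i| * (1/fs)``, in amplitude*seconds. Equals MAV times the
    window duration.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("iEMG undefined for an empty vector")
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    return float(np.sum(np.abs(x)) / fs)


def compute_mf(
    x: np.ndarray,
    fs: float,
    nperseg: int | None = None,
) -> float:
    """Median frequency of the power spectrum, in Hz.

    The PSD is estimated by Welch's method (Hann taper, 50% overlap,
    segment length ``min(N, 4096)`` unless overridden). The median
    frequency is the point where the cumulative PSD reaches half the
    total power, located by linear interpolation inside the crossing
    frequency bin.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValueError("median frequency requires at least 16 samples")
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    if not np.any(x):
        raise ValueError("median frequency undefined for an all-zero signal")

    if nperseg is None:
        nperseg = min(x.size, 4096)
    freqs, psd = signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    cum = np.cumsum(psd)
    total = cum[-1]
    if total <= 0:
        raise ValueError("median frequency undefined: zero total power")
    half = total / 2.0
    # Each bin's power is spread uniformly over its frequency cell
    # [f_k - df/2, f_k + df/2]; the crossing is interpolated inside the cell.
    df = freqs[1] - freqs[0]
    k = int(np.searchsorted(cum, half))
    below = cum[k - 1] if k > 0 else 0.0
    frac = (half - below) / psd[k]
    f_left = max(freqs[k] - df / 2.0, 0.0)
    return float(min(f_left + frac * df, freqs[k] + df / 2.0))


def emg_feature_set(trial: EmgTrial, nperseg: int | None = None) -> EmgFeatureSet:
    """Compute all four features for each channel of a (denoised) trial."""
    rms, iemg, mav, mf = {}, {}, {}, {}
    for j, ch in enumerate(trial.channels):
        x = trial.samples[:, j]
        rms[ch] = compute_rms(x)
        iemg[ch] = compute_iemg(x, trial.fs_emg)
        mav[ch] = compute_mav(x)
        mf[ch] = compute_mf(x, trial.fs_emg, nperseg=nperseg)
    return EmgFeatureSet(rms=rms, iemg=iemg, mav=mav, mf=mf)
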