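"""Classical time-domain feature battery for sEMG and ECG.

sEMG features: root mean square (RMS), integrated EMG (iEMG, sum of
rectified amplitudes), zero-crossing count (ZC, sum of absolute sign
differences, so each crossing contributes 2), and average rectified value
(ARV).  ECG features: mean RR interval, low-frequency (0.04-0.15 Hz) power
of the RR tachogram, and the LF/HF ratio against the standard 0.15-0.4 Hz
high-frequency band.  These are the inputs of the KNN/SVM baseline
classifiers and of the per-state correlation analysis that motivates
fusing the two modalities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import interpolate, signal as sps

from .synthgen import PairedRecord, RawRecord

__all__ = [
    "ecg_mean",
    "rms",
    "iemg",
    "zc",
    "arv",
    "lf_power",
    "rr_from_record",
    "feature_vector",
    "feature_table",
    "correlation_matrix",
]

FEATURE_COLUMNS = [
    "ecg_mean",
    "semg_rms",
    "semg_iemg",
    "semg_zc",
    "semg_arv",
    "ecg_lf",
    "ecg_lf_hf",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


def _as1d(y) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty input")
    return y


def ecg_mean(rr) -> float:
    """Mean RR interval in seconds: (1/M) * sum(RR_i)."""
    rr = _as1d(rr)
    if np.any(rr <= 0):
        raise ValueError("RR intervals must be positive")
    return float(np.mean(rr))


def rms(y) -> float:
    """Root mean square sqrt((1/N) * sum(y_n^2))."""
    return float(np.sqrt(np.mean(_as1d(y) ** 2)))


def iemg(y) -> float:
    """Integrated EMG: sum of rectified amplitudes sum(|y_n|)."""
    return float(np.sum(np.abs(_as1d(y))))


def zc(y, deadband: float = 0.0) -> int:
    """Zero-crossing statistic: sum_n |sign(y_n) - sign(y_{n-1})|.

    Each sign flip contributes 2 (the absolute difference of the signs);
    samples within ``deadband`` of zero are treated as zero.
    """
    y = _as1d(y)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    if deadband > 0:
        y = np.where(np.abs(y) <= deadband, 0.0, y)
    s = np.sign(y)
    return int(np.sum(np.abs(np.diff(s))))


def arv(y, fs: float | None = None) -> float:
    """Average rectified value (1/N) * sum(|y_n|), the discrete (1/T)int|y|dt."""
    y = _as1d(y)
    return float(np.mean(np.abs(y)))


def lf_power(
    rr_times,
    rr_values,
    fs_resample: float = 4.0,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
) -> tuple[float, float]:
    """LF power and LF/HF ratio of the RR tachogram.

    The unevenly sampled tachogram (``rr_times`` in s, ``rr_values`` in s)
    is cubic-interpolated onto a uniform 4 Hz grid, its power spectral
    density estimated by Welch's method, and band powers integrated over
    the LF and HF bands.  Returns ``(lf, lf/hf)``; an HF power of zero
    yields ``inf`` for the ratio.
    """
    t = _as1d(rr_times)
    v = _as1d(rr_values)
    if len(t) != len(v):
        raise ValueError("rr_times and rr_values must have equal length")
    if len(t) < 30:
        raise ValueError("need >= 30 RR intervals for the 0.04 Hz band")
    cs = interpolate.CubicSpline(t, v)
    grid = np.arange(t[0], t[-1], 1.0 / fs_resample)
    even = cs(grid)
    even = even - even.mean()
    nperseg = min(len(even), 256)
    f, psd = sps.welch(even, fs=fs_resample, nperseg=nperseg)

    def band(lohi):
        lo, hi = lohi
        mask = (f >= lo) & (f < hi)
        return float(np.trapezoid(psd[mask], f[mask])) if mask.sum() > 1 else 0.0

    lf = band(lf_band)
    hf = band(hf_band)
    ratio = float("inf") if hf == 0 else lf / hf
    return lf, ratio


def rr_from_record(record: RawRecord, min_peak_frac: float = 0.5):
    """(times, intervals) of the RR series, from ground truth or peak detection.

    Uses the generator's ``rr_intervals_s`` metadata when present; otherwise
    detects R peaks with :func:`scipy.signal.find_peaks` at half the signal
    maximum with a 0.25 s refractory distance.
    """
    if "rr_intervals_s" in record.meta:
        rr = np.asarray(record.meta["rr_intervals_s"], dtype=float)
        t0 = np.asarray(record.meta["beat_times_s"], dtype=float)[: len(rr)]
        return t0, rr
    x = record.samples
    peaks, _ = sps.find_peaks(
        x, height=min_peak_frac * x.max(), distance=int(0.25 * record.fs)
    )
    if len(peaks) < 2:
        raise ValueError("fewer than 2 R peaks detected")
    times = peaks / record.fs
    return times[:-1], np.diff(times)


def feature_vector(pair: PairedRecord, with_spectral: bool = True) -> dict:
    """All scalar features for one paired record, keyed by column name."""
    y = pair.semg.samples
    t_rr, rr = rr_from_record(pair.ecg)
    feats = {
        "ecg_mean": ecg_mean(rr),
        "semg_rms": rms(y),
        "semg_iemg": iemg(y),
        "semg_zc": float(zc(y)),
        "semg_arv": arv(y),
    }
    if with_spectral and len(rr) >= 30:
        lf, ratio = lf_power(t_rr, rr)
        feats["ecg_lf"] = lf
        feats["ecg_lf_hf"] = ratio
    else:
        feats["ecg_lf"] = np.nan
        feats["ecg_lf_hf"] = np.nan
    feats["state"] = pair.state
    return feats


def feature_table(pairs: list[PairedRecord]) -> pd.DataFrame:
    """Feature DataFrame with one row per record (columns fixed + 'state')."""
    rows = [feature_vector(p) for p in pairs]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS + ["state"])


def correlation_matrix(table: pd.DataFrame, state: int) -> pd.DataFrame:
    """Per-state Pearson correlation matrix of the feature columns.

    Zero-variance features yield NaN rows/columns (undefined correlation);
    the diagonal is forced to exactly 1 for well-defined features.
    """
    sub = table[table["state"] == state]
    if len(sub) < 3:
        raise ValueError("need >= 3 records for a correlation matrix")
    cols = [c for c in FEATURE_COLUMNS if c in sub.columns]
    data = sub[cols].dropna(axis=1, how="all")
    corr = data.corr(method="pearson")
    defined = data.std() > 0
    for c in corr.columns:
        if defined.get(c, False):
            corr.loc[c, c] = 1.0
        else:
            corr.loc[c, :] = np.nan
            corr.loc[:, c] = np.nan
    return corr
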