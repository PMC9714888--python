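"""Signal conditioning and single-period extraction.

Pipeline for both modalities: filter (third-order Butterworth low-pass for
ECG; second-order 60-160 Hz band-stop for sEMG, the anti-interference
stage of the acquisition chain), amplify, optionally wavelet-denoise,
segment into periods (R-peak to R-peak for ECG, contraction cycle for
sEMG), average the periods into one representative single-period waveform,
and normalise its length by cyclically repeating it until a fixed sequence
length L (default 800) is reached.  Cyclic repetition keeps the waveform's
morphology intact — tail zero-padding would inject a spurious flat segment
and resampling would distort the period's time scale.

All filters are applied zero-phase (forward-backward), which preserves the
timing of morphological landmarks at the cost of doubling the effective
filter order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy import signal as sps

from .synthgen import RawRecord

__all__ = [
    "FilterSpec",
    "PeriodSeries",
    "butter_lowpass",
    "bandstop_semg",
    "apply_gain",
    "wavelet_denoise",
    "detect_semg_onsets",
    "segment_periods",
    "period_average",
    "normalize_length",
    "record_to_period_series",
]

DEFAULT_L = 800


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter design: low-pass (one cutoff) or band-stop (two)."""

    kind: str  # "lowpass" | "bandstop" | "bandpass"
    order: int
    cutoffs: tuple[float, ...]
    fs: float

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "bandstop", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        nyq = self.fs / 2
        if any(not (0 < c < nyq) for c in self.cutoffs):
            raise ValueError(f"cutoffs {self.cutoffs} must lie in (0, {nyq})")
        n_expected = 1 if self.kind == "lowpass" else 2
        if len(self.cutoffs) != n_expected:
            raise ValueError(f"{self.kind} needs {n_expected} cutoff(s)")
        if n_expected == 2 and not self.cutoffs[0] < self.cutoffs[1]:
            raise ValueError(f"{self.kind} needs low < high")

    def sos(self) -> np.ndarray:
        wn = self.cutoffs[0] if self.kind == "lowpass" else list(self.cutoffs)
        return sps.butter(self.order, wn, btype=self.kind, fs=self.fs, output="sos")


@dataclass
class PeriodSeries:
    """A length-normalised single-period sequence, the classifier input unit.

    ``values[:source_period_len]`` is the segmented-and-averaged period;
    the remainder is the cyclic repetition that pads it out to length L.
    """

    values: np.ndarray
    source_period_len: int
    modality: str
    state: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        L = len(self.values)
        if not 1 <= self.source_period_len <= L:
            raise ValueError(
                f"source_period_len {self.source_period_len} outside [1, {L}]"
            )


def _filtfilt(record: RawRecord, spec: FilterSpec) -> RawRecord:
    filtered = sps.sosfiltfilt(spec.sos(), record.samples)
    return replace(record, samples=filtered)


def butter_lowpass(record: RawRecord, order: int = 3, cutoff_hz: float = 40.0) -> RawRecord:
    """Zero-phase third-order Butterworth low-pass (ECG conditioning).

    The 40 Hz default keeps the standard monitoring ECG band; the order is
    the acquisition chain's stated design.
    """
    spec = FilterSpec("lowpass", order, (cutoff_hz,), record.fs)
    return _filtfilt(record, spec)


def bandstop_semg(
    record: RawRecord,
    order: int = 2,
    edges: tuple[float, float] = (60.0, 160.0),
    interpret_as_bandpass: bool = False,
) -> RawRecord:
    """Zero-phase band-stop over ``edges`` (default 60-160 Hz) for sEMG.

    Digital (bilinear) realisation of the acquisition chain's second-order
    analog stop-band stage against electromagnetic interference.  The
    stop-band reading of the two printed corner frequencies is unusual for
    sEMG; ``interpret_as_bandpass=True`` switches to treating them as a
    pass band instead.
    """
    kind = "bandpass" if interpret_as_bandpass else "bandstop"
    spec = FilterSpec(kind, order, tuple(edges), record.fs)
    return _filtfilt(record, spec)


def apply_gain(
    record: RawRecord, pre_gain: float = 5.0, post_gain: float = 318.0
) -> tuple[RawRecord, float]:
    """Scale by the two-stage amplification; returns (record, total gain).

    Defaults mirror an instrumentation pre-amplifier gain of 5 followed by
    a 318x main stage, i.e. a total gain of 1590.
    """
    if pre_gain <= 0 or post_gain <= 0:
        raise ValueError("gains must be > 0")
    total = pre_gain * post_gain
    return replace(record, samples=record.samples * total), total


def wavelet_denoise(
    record: RawRecord,
    family: str = "db4",
    level: int = 4,
    threshold: float | None = None,
) -> RawRecord:
    """Discrete-wavelet denoising: decompose, soft-threshold details, rebuild.

    ``threshold=None`` uses the universal threshold sigma*sqrt(2*log N)
    with sigma estimated from the finest detail level via the median
    absolute deviation.  ``threshold=0`` reduces to perfect reconstruction.
    """
    x = record.samples
    max_level = pywt.dwt_max_level(len(x), pywt.Wavelet(family).dec_len)
    if level < 1 or level > max_level:
        raise ValueError(f"level {level} infeasible for length {len(x)} (max {max_level})")
    coeffs = pywt.wavedec(x, family, level=level)
    if threshold is None:
        sigma = np.median(np.abs(coeffs[-1])) / 0.6745 if len(coeffs[-1]) else 0.0
        threshold = sigma * np.sqrt(2 * np.log(max(len(x), 2)))
    if threshold > 0:
        denoised = [coeffs[0]] + [
            pywt.threshold(c, threshold, mode="soft") for c in coeffs[1:]
        ]
    else:
        denoised = coeffs  # zero threshold: plain perfect reconstruction
    rec = pywt.waverec(denoised, family)[: len(x)]
    return replace(record, samples=rec)


def detect_semg_onsets(
    record: RawRecord,
    threshold_frac: float = 0.2,
    hysteresis_frac: float = 0.1,
    smooth_s: float = 0.05,
) -> np.ndarray:
    """Contraction-cycle onsets from the smoothed rectified envelope.

    Rising crossings of ``threshold_frac * max(envelope)`` with a lower
    release level at ``hysteresis_frac`` to suppress chatter.  For
    continuous (non-burst) activity the envelope may never release, so
    when fewer than two onsets are found the thresholds fall back to the
    envelope mean with a release level one third of a standard deviation
    below it, marking one onset per modulation cycle.  Used when no
    ground-truth markers accompany the record.
    """
    env = np.abs(record.samples)
    width = max(int(round(smooth_s * record.fs)), 1)
    kernel = np.ones(width) / width
    env = np.convolve(env, kernel, mode="same")

    def crossings(hi, lo):
        onsets = []
        armed = True
        for i, v in enumerate(env):
            if armed and v >= hi:
                onsets.append(i)
                armed = False
            elif not armed and v < lo:
                armed = True
        return onsets

    onsets = crossings(threshold_frac * env.max(), hysteresis_frac * env.max())
    if len(onsets) < 2:
        onsets = crossings(env.mean(), env.mean() - env.std() / 3.0)
    return np.asarray(onsets, dtype=int)


def segment_periods(record: RawRecord, markers) -> list[np.ndarray]:
    """Split the signal at the given strictly-increasing marker indices.

    Markers are R-peak indices for ECG or contraction onsets for sEMG;
    with k markers the k-1 between-marker segments are returned.
    """
    markers = np.asarray(markers, dtype=int)
    if len(markers) < 2:
        raise ValueError("need at least 2 markers to form a segment")
    if np.any(np.diff(markers) <= 0):
        raise ValueError("markers must be strictly increasing")
    if markers[0] < 0 or markers[-1] > len(record.samples):
        raise ValueError("markers outside the record")
    return [record.samples[a:b] for a, b in zip(markers[:-1], markers[1:])]


def period_average(segments: list[np.ndarray]) -> np.ndarray:
    """Average periods: resample each to the median length, pointwise mean."""
    if len(segments) == 0:
        raise ValueError("no segments to average")
    lengths = [len(s) for s in segments]
    if min(lengths) < 1:
        raise ValueError("empty segment")
    target = int(np.median(lengths))
    resampled = [
        s if len(s) == target else _resample_linear(np.asarray(s, float), target)
        for s in segments
    ]
    return np.mean(resampled, axis=0)


def _resample_linear(seg: np.ndarray, target: int) -> np.ndarray:
    old = np.linspace(0.0, 1.0, num=len(seg))
    new = np.linspace(0.0, 1.0, num=target)
    return np.interp(new, old, seg)


def normalize_length(
    period: np.ndarray,
    L: int = DEFAULT_L,
    modality: str = "sEMG",
    state: int = -1,
) -> PeriodSeries:
    """Cyclically repeat a single period out to exactly L samples.

    The sequence length L must accommodate at least one full period; the
    last repetition is truncated, so ``values[i] == period[i % len(period)]``.
    """
    period = np.asarray(period, dtype=float)
    p = len(period)
    if p < 1:
        raise ValueError("empty period")
    if p > L:
        raise ValueError(f"period length {p} exceeds sequence length {L}")
    reps = int(np.ceil(L / p))
    values = np.tile(period, reps)[:L]
    return PeriodSeries(values=values, source_period_len=p, modality=modality, state=state)


def record_to_period_series(
    record: RawRecord,
    L: int = DEFAULT_L,
    markers=None,
    denoise: bool = False,
) -> PeriodSeries:
    """Full per-record pipeline: filter, segment, average, length-normalise.

    Ground-truth markers from the generator metadata are used when present;
    otherwise sEMG onsets are detected from the rectified envelope (ECG
    requires explicit markers or ``r_peaks`` metadata).
    """
    if record.modality == "ECG":
        filtered = butter_lowpass(record)
        if markers is None:
            markers = record.meta.get("r_peaks")
        if markers is None:
            raise ValueError("ECG record needs R-peak markers")
    elif record.modality == "sEMG":
        filtered = bandstop_semg(record)
        if markers is None:
            markers = record.meta.get("cycle_onsets")
        if markers is None:
            markers = detect_semg_onsets(filtered)
    else:
        raise ValueError(f"unknown modality {record.modality!r}")

    if denoise:
        filtered = wavelet_denoise(filtered)

    # average only periods that fit within L after resampling
    segments = segment_periods(filtered, markers)
    period = period_average(segments)
    if len(period) > L:
        period = _resample_linear(period, L)
    return normalize_length(period, L=L, modality=record.modality, state=record.state)
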