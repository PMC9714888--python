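"""Seedable synthetic sEMG / ECG generator.

Emulates the feature-level structure observed in fatiguing exercise:
sEMG amplitude features (RMS, iEMG, ARV) rise and the zero-crossing count
falls as the muscle tires, while the mean RR interval of the ECG shortens.
The waveform models are deliberately simple:

* sEMG — Gaussian white noise band-pass filtered to a state-dependent
  passband (the upper edge drops with fatigue, pulling the zero-crossing
  rate down), modulated by a periodic contraction envelope and scaled to a
  state-dependent target RMS.
* ECG — a fixed sum-of-Gaussians PQRST template placed on an RR point
  process whose mean shortens with fatigue, with sinusoidal low-frequency
  modulation of the RR series.  Ground-truth R-peak positions and RR
  intervals are kept as metadata so period segmentation can be tested
  against a known answer.

Every output is a pure function of (arguments, seed): per-record seeds are
derived from the master seed with ``derive_seed(master, record_index,
modality_code)`` via :class:`numpy.random.SeedSequence`, so any single
record can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .states import STATES, STATE_NAMES, check_state

__all__ = [
    "SynthConfig",
    "RawRecord",
    "PairedRecord",
    "derive_seed",
    "generate_semg",
    "generate_ecg",
    "generate_dataset",
    "write_record",
    "read_record",
    "write_dataset",
]

# PQRST template: (offset from R in s, amplitude, Gaussian width in s)
_PQRST = (
    (-0.20, 0.12, 0.025),   # P
    (-0.05, -0.15, 0.010),  # Q
    (0.00, 1.00, 0.011),    # R
    (0.05, -0.20, 0.010),   # S
    (0.30, 0.30, 0.040),    # T
)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    The state maps are keyed by the fatigue label in {-1, 0, 1}.  Defaults
    are sized so that the three classes are separable by a classifier:
    RMS ratio 1 : 1.4 : 2.0 across relaxed/transition/fatigue, sEMG
    passband upper edge falling 350 -> 250 -> 150 Hz, and mean RR interval
    0.85 s -> 0.75 s -> 0.65 s.
    """

    duration_s: float = 30.0
    fs_semg: float = 1000.0
    fs_ecg: float = 250.0
    semg_rms_by_state: dict[int, float] = field(
        default_factory=lambda: {-1: 1.0, 0: 1.4, 1: 2.0}
    )
    semg_band_by_state: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {-1: (20.0, 350.0), 0: (20.0, 250.0), 1: (20.0, 150.0)}
    )
    rr_mean_by_state: dict[int, float] = field(
        default_factory=lambda: {-1: 0.85, 0: 0.75, 1: 0.65}
    )
    rr_sd: float = 0.025
    lf_mod_hz: float = 0.1
    lf_mod_depth_s: float = 0.05
    semg_cycle_s: float = 0.8
    semg_env_depth: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.fs_semg <= 0 or self.fs_ecg <= 0:
            raise ValueError("sampling rates must be > 0")
        rms = [self.semg_rms_by_state[s] for s in STATES]
        if not (rms[0] < rms[1] < rms[2]):
            raise ValueError(
                "semg_rms_by_state must be strictly increasing relaxed->fatigue"
            )
        rr = [self.rr_mean_by_state[s] for s in STATES]
        if not (rr[0] > rr[1] > rr[2]):
            raise ValueError(
                "rr_mean_by_state must be strictly decreasing relaxed->fatigue"
            )
        highs = [self.semg_band_by_state[s][1] for s in STATES]
        if not (highs[0] > highs[1] > highs[2]):
            raise ValueError(
                "sEMG passband upper edge must be strictly decreasing with fatigue"
            )


@dataclass
class RawRecord:
    """One modality's sampled signal plus labelling metadata.

    ``meta`` carries generator ground truth: ``r_peaks`` (sample indices)
    and ``rr_intervals_s`` for ECG, ``cycle_onsets`` for sEMG.
    """

    samples: np.ndarray
    fs: float
    modality: str  # "sEMG" | "ECG"
    state: int
    subject_id: str = "synth"
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        check_state(self.state)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class PairedRecord:
    """Synchronously labelled sEMG + ECG pair for one record."""

    semg: RawRecord
    ecg: RawRecord
    state: int


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic per-record seed from a master seed and an index key."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_semg(
    state: int, config: SynthConfig | None = None, seed: int | None = None
) -> RawRecord:
    """Generate one synthetic sEMG record for the given fatigue state."""
    config = config or SynthConfig()
    check_state(state)
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)

    fs = config.fs_semg
    n = round(config.duration_s * fs)
    low, high = config.semg_band_by_state[state]
    if not (0 < low < high < fs / 2):
        raise ValueError(f"degenerate sEMG passband ({low}, {high}) at fs={fs}")

    x = rng.standard_normal(n)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x)

    t = np.arange(n) / fs
    env = 1.0 + config.semg_env_depth * np.sin(2 * np.pi * t / config.semg_cycle_s)
    x = x * env

    target = config.semg_rms_by_state[state]
    emp = float(np.sqrt(np.mean(x**2)))
    x = np.zeros(n) if target == 0 or emp == 0 else x * (target / emp)

    period = round(config.semg_cycle_s * fs)
    onsets = np.arange(0, n, period, dtype=int)
    return RawRecord(
        samples=x,
        fs=fs,
        modality="sEMG",
        state=state,
        seed=seed,
        meta={"cycle_onsets": onsets.tolist()},
    )


def generate_ecg(
    state: int, config: SynthConfig | None = None, seed: int | None = None
) -> RawRecord:
    """Generate one synthetic ECG record with ground-truth R peaks."""
    config = config or SynthConfig()
    check_state(state)
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)

    rr_mean = config.rr_mean_by_state[state]
    if not rr_mean > 3 * config.rr_sd:
        raise ValueError(
            f"rr_mean ({rr_mean}) must exceed 3*rr_sd ({3 * config.rr_sd})"
        )

    fs = config.fs_ecg
    n = round(config.duration_s * fs)
    t_grid = np.arange(n) / fs

    beat_times: list[float] = []
    rr_list: list[float] = []
    t = rr_mean / 2.0
    while t < config.duration_s:
        beat_times.append(t)
        rr = (
            rr_mean
            + config.lf_mod_depth_s * np.sin(2 * np.pi * config.lf_mod_hz * t)
            + rng.normal(0.0, config.rr_sd)
        )
        if rr <= 0:
            raise ValueError("drew a non-positive RR interval; reduce rr_sd")
        rr_list.append(rr)
        t += rr

    x = np.zeros(n)
    for bt in beat_times:
        for off, amp, width in _PQRST:
            x += amp * np.exp(-0.5 * ((t_grid - bt - off) / width) ** 2)

    r_peaks = [int(round(bt * fs)) for bt in beat_times]
    # RR intervals between consecutive beats actually placed in the record
    rr_between = list(np.diff(beat_times))
    return RawRecord(
        samples=x,
        fs=fs,
        modality="ECG",
        state=state,
        seed=seed,
        meta={
            "r_peaks": r_peaks,
            "beat_times_s": [float(b) for b in beat_times],
            "rr_intervals_s": [float(r) for r in rr_between],
        },
    )


def generate_dataset(
    n_per_state: int, config: SynthConfig | None = None, seed: int | None = None
) -> list[PairedRecord]:
    """Generate a class-balanced list of paired (sEMG, ECG) records.

    Records carry distinct seeds derived from the master seed by record
    index and modality, so the dataset is reproducible record-by-record.
    """
    config = config or SynthConfig()
    if n_per_state < 1:
        raise ValueError("n_per_state must be >= 1")
    master = config.seed if seed is None else int(seed)

    pairs: list[PairedRecord] = []
    idx = 0
    for state in STATES:
        for _ in range(n_per_state):
            semg = generate_semg(state, config, seed=derive_seed(master, idx, 0))
            ecg = generate_ecg(state, config, seed=derive_seed(master, idx, 1))
            sid = f"synth{idx:05d}"
            semg.subject_id = ecg.subject_id = sid
            pairs.append(PairedRecord(semg=semg, ecg=ecg, state=state))
            idx += 1
    return pairs


# ---------------------------------------------------------------------------
# Plain-text persistence: CSV (time_s, value) + JSON sidecar per record.


def write_record(record: RawRecord, basepath: str | Path) -> tuple[Path, Path]:
    basepath = Path(basepath)
    csv_path = basepath.with_suffix(".csv")
    json_path = basepath.with_suffix(".json")
    arr = np.column_stack([record.time_s, record.samples])
    np.savetxt(csv_path, arr, delimiter=",", header="time_s,value", comments="")
    sidecar = {
        "fs": record.fs,
        "modality": record.modality,
        "state": record.state,
        "subject_id": record.subject_id,
        "seed": record.seed,
        "meta": record.meta,
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def read_record(basepath: str | Path) -> RawRecord:
    basepath = Path(basepath)
    arr = np.loadtxt(basepath.with_suffix(".csv"), delimiter=",", skiprows=1)
    sidecar = json.loads(basepath.with_suffix(".json").read_text())
    return RawRecord(
        samples=arr[:, 1],
        fs=sidecar["fs"],
        modality=sidecar["modality"],
        state=sidecar["state"],
        subject_id=sidecar["subject_id"],
        seed=sidecar["seed"],
        meta=sidecar.get("meta", {}),
    )


def write_dataset(pairs: list[PairedRecord], outdir: str | Path) -> Path:
    """Write all records plus a manifest.json listing them."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, pair in enumerate(pairs):
        base_semg = outdir / f"rec{i:05d}_semg"
        base_ecg = outdir / f"rec{i:05d}_ecg"
        write_record(pair.semg, base_semg)
        write_record(pair.ecg, base_ecg)
        entries.append(
            {
                "index": i,
                "state": pair.state,
                "state_name": STATE_NAMES[pair.state],
                "semg": base_semg.name,
                "ecg": base_ecg.name,
            }
        )
    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps({"records": entries}, indent=1))
    return manifest
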