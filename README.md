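# myofuse

Recognising exercise-induced muscle fatigue from **surface EMG and ECG
time series**, fused at the decision level.

Muscle fatigue monitoring matters for athletic training, rehabilitation
and wearable devices, but classifiers built on a handful of scalar sEMG
features are fragile: the classical time-domain indices are strongly
inter-correlated and their single-modality models transfer poorly across
individuals.  `myofuse` implements an alternative pipeline for
researchers in physiological signal processing:

1. each record is reduced to a **single-period waveform** of fixed length
   L = 800 (filtering → periodic segmentation → period averaging →
   cyclic-repeat length normalisation);
2. one **temporal convolutional network (TCN)** per modality classifies
   the period into three fatigue states (relaxed −1, transition 0,
   fatigue 1).  The network stacks residual blocks of dilated causal
   convolutions (5-tap kernels, dilation ladder [1, 2, 4, 8, 16, 32, 64],
   32- then 64-filter stages), with receptive field
   RF = 1 + (k−1)·Σdᵢ = 509 for one stage and 1017 for two — wider than
   the whole input;
3. the two softmax outputs are fused by **Dempster–Shafer evidence
   theory**: credibility discounting m({s}) = c·pₛ, m(Θ) = 1 − c with
   default credibilities sEMG 0.591 / ECG 0.409, then Dempster's rule
   m₁₂(A) ∝ Σ_{B∩C=A} m₁(B)m₂(C) with conflict normalisation 1/(1−K).

The package also provides the classical feature battery (RMS, iEMG, ZC,
ARV, mean RR, LF and LF/HF of the RR tachogram) with KNN/SVM baselines,
per-class precision/recall/F-score = 2PR/(P+R) under stratified 10-fold
cross-validation, and a **seedable synthetic sEMG/ECG generator** that
emulates the feature-level signatures of fatigue (rising RMS/iEMG/ARV,
falling zero-crossing count, shortening RR interval), so the entire
pipeline is testable without any recording hardware.  The TCN — forward,
backward and Adam — is implemented directly in NumPy; training is exactly
reproducible from one integer seed.

## Worked example

```python
import numpy as np
from myofuse import synthgen, features, tcn, fusion

# 30 labelled sEMG+ECG pairs (10 per state), reproducible from one seed
pairs = synthgen.generate_dataset(10, seed=0)
table = features.feature_table(pairs)
print(table.groupby("state")[["semg_rms", "semg_zc", "ecg_mean"]].mean().round(3))
```

```
       semg_rms  semg_zc  ecg_mean
state
-1          1.0  22893.4     0.848
 0          1.4  16869.2     0.749
 1          2.0  10668.0     0.646
```

The group means show the encoded fatigue signatures: sEMG amplitude
rises (RMS 1.0 → 2.0), the zero-crossing count falls (the sEMG band
narrows), and the mean RR interval shortens (heart rate climbs) from
relaxed to fatigued.

```python
print(tcn.receptive_field(5, [1, 2, 4, 8, 16, 32, 64]))   # 509
print(tcn.build_model(tcn.NetConfig()).receptive_field)   # 1017

# decision fusion: sEMG says fatigue, ECG leans transition
p_semg = tcn.StateProbabilities(p={-1: 0.10, 0: 0.25, 1: 0.65})
p_ecg  = tcn.StateProbabilities(p={-1: 0.20, 0: 0.45, 1: 0.35})
state, conf, m = fusion.fuse_probabilities(p_semg, p_ecg)
print(state, round(conf, 3), round(m.theta, 3))   # 1 0.403 0.286
```

The fused verdict follows the more credible sEMG evidence (fatigue,
combined mass 0.403) while 0.286 of the mass remains on the full frame —
the residual ignorance after discounting both classifiers.

An end-to-end comparison of all nine models (per-modality KNN/SVM/TCN
and the three fused variants) on synthetic data:

```bash
myofuse --seed 1 --out-dir out experiment --n-per-state 30 --epochs 3
```

writes `out/comparison.csv` (model × state × precision/recall/F-score)
and `out/report.json` (per-fold detail).  Other subcommands — `synth`,
`preprocess`, `features`, `train-tcn`, `fuse`, `evaluate` — expose the
individual pipeline stages.

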