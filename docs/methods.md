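# Methods

## Problem and model

`myofuse` classifies the fatigue state of an exercising muscle — relaxed
(-1), transition (0), fatigue (1) on the RPE self-report scale — from two
synchronously recorded biosignals: surface electromyography (sEMG) over
the active muscle and the electrocardiogram (ECG).  Rather than fitting a
classifier to hand-picked scalar features, the primary model feeds the
*morphology* of one signal period into a temporal convolutional network
(TCN), one network per modality, and merges the two decisions with
Dempster-Shafer (D-S) evidence fusion.

### Single-period inputs

Each record is reduced to one representative period of fixed length
L = 800 samples:

1. **Filtering.**  ECG: zero-phase third-order Butterworth low-pass
   (default cutoff 40 Hz — the monitoring-band choice; configurable).
   sEMG: zero-phase second-order Butterworth band-stop over 60–160 Hz,
   the digital (bilinear) realisation of the acquisition chain's analog
   interference filter.  Zero-phase (forward-backward) application
   preserves the timing of waveform landmarks and doubles the effective
   order; we accept that trade deliberately, since period *shape* is the
   classifier input.  Note the 60–160 Hz stop band removes a sizeable part
   of the sEMG energy band; it is implemented as specified by the
   acquisition design rather than as standard sEMG practice (20–450 Hz
   band-pass plus mains notch), and both edges are configurable.
2. **Optional wavelet denoising** (db4, level 4, soft universal
   threshold, all configurable).
3. **Periodic segmentation** at R peaks (ECG) or contraction-cycle onsets
   (sEMG), then **period averaging**: segments are linearly resampled to
   the median segment length and averaged pointwise.
4. **Length normalisation**: the averaged period is repeated cyclically
   until L samples are reached, the last repetition truncated.  Cyclic
   repetition (not zero padding, not resampling) keeps amplitude and
   spectral content intact, which matters because both carry the fatigue
   signal.

For synthetic data the segmentation markers are generator ground truth.
For real sEMG without markers an envelope detector is provided: rising
crossings of 20% of the smoothed rectified envelope's maximum with a 10%
release level; when activity is continuous and the envelope never
releases, the detector falls back to mean-crossings of the envelope (one
onset per modulation cycle).

### The temporal convolutional classifier

The network is a stack of residual blocks of dilated causal 1-D
convolutions.  A causal convolution's output at time t uses inputs at
times ≤ t only (left zero-padding of (k−1)·d samples); dilation d inserts
gaps between the k kernel taps so the span grows exponentially up the
stack.  With constant kernel size k the receptive field after a ladder of
dilations is

    RF = 1 + (k − 1) · Σᵢ dᵢ.

Defaults follow the reference architecture: 5-tap kernels, stride 1,
dilation ladder [1, 2, 4, 8, 16, 32, 64], ladder run twice — a front
stage of 32 filters and a back stage of 64.  Schedule-level accounting
(one convolution per dilation level) gives RF = 509 for one stage and
1017 for two, which covers the entire 800-sample input.  Each residual
block actually applies *two* weight-normalised convolutions at its
dilation (each followed by ReLU and spatial dropout, rate 0.05), so the
exact causal span of a block is obtained from the per-conv-layer list
[d, d] with the same formula; the model reports the schedule-level figure
and the test suite verifies the per-layer span empirically.  Block output
is o = σ(F(x) + x) with a 1×1 convolution projecting the shortcut when
channel widths differ.  The head is a global average pool over time and a
dense softmax over the three states — chosen to keep the parameter count
independent of L.

The network, its gradients and the Adam optimiser are implemented
directly in NumPy (im2col + GEMM convolutions, float32): the package is
self-contained, every arithmetic step is visible to the test suite, and
training is exactly reproducible from one integer seed (weight
initialisation, shuffling, dropout masks and the validation split all
derive from it).

Two stabilisers proved necessary for a 14-block unnormalised residual
stack and are on by default: the second convolution of each block opens
with its weight-norm gain at 0.1 of the data-independent value, so blocks
start near the identity; and inputs are standardised by *global* scalars
(training-set mean and standard deviation, stored on the model).
Per-sample standardisation would be wrong here: amplitude differences
between records are the main fatigue cue.

Training: Adam (learning rate 2·10⁻³, batch 32, ≤ 50 epochs).  The rate
is set at 2·10⁻³ rather than the more customary 1·10⁻³ because the small
synthetic problems this package targets converge in a handful of epochs
at the higher rate and are insensitive to the difference in final
accuracy.  Early stopping uses a 10% validation split with patience 3;
training also halts once the epoch's running training accuracy reaches
`stop_train_acc` (default 0.98).

### Decision fusion

Each modality's softmax vector p is discounted into a basic probability
assignment with that modality's credibility c: m({s}) = c·pₛ on the three
singletons and m(Θ) = 1 − c on the full frame.  The two bodies of
evidence combine by Dempster's rule,

    m(A) = Σ_{B∩C=A} m₁(B)m₂(C) / (1 − K),   K = Σ_{B∩C=∅} m₁(B)m₂(C),

and the decision is the singleton of maximal combined mass (ties break to
the first state in canonical order and are flagged; K ≥ 1 − 10⁻¹² is
treated as total conflict and raised).  Because discounting always leaves
mass on Θ when c < 1, total conflict cannot occur for credibilities in
(0, 1).  Default credibilities are sEMG 0.591 / ECG 0.409, the
cross-validated reliability weights of the two modality classifiers;
`estimate_credibility` re-derives weights from a fresh accuracy pair by
normalisation (cᵢ = accᵢ/Σacc), the rule consistent with the defaults
summing to one.  Focal elements are restricted to singletons plus Θ — a
softmax head provides no evidence for composite hypotheses.

### Feature battery and baselines

For the comparison arm the classical time-domain features are computed
per record: RMS, iEMG = Σ|yₙ| (the rectified sum — the universal iEMG
definition, consistent with ARV), zero-crossing statistic
Σ|sign(yₙ) − sign(yₙ₋₁)| (each crossing contributes 2; an optional
amplitude deadband defaults to 0), ARV, mean RR interval, and the LF
(0.04–0.15 Hz) power and LF/HF ratio of the RR tachogram (HF band
0.15–0.40 Hz, the standard HRV convention; tachogram cubic-interpolated
to a uniform 4 Hz grid, Welch PSD, band powers by trapezoidal
integration).  KNN (k = 5) and RBF-SVM (C = 1) baselines run on
standardised features under stratified 10-fold cross-validation; the
summary accuracy is the mean of the ten fold accuracies, and per-class
precision/recall/F-score come from the pooled out-of-fold predictions.
Precision is TP/(TP+FP) and recall TP/(TP+FN); the misprinted
TP/(TP+TN) variant is exposed as `precision_as_printed` for audit only.

## Synthetic data generator

No public dataset accompanies the method, so the package ships a seedable
generator that emulates the *feature-level* structure of fatiguing
exercise, at these defaults (all overridable):

| quantity | relaxed | transition | fatigue |
|---|---|---|---|
| sEMG target RMS (a.u.) | 1.0 | 1.4 | 2.0 |
| sEMG passband (Hz) | 20–350 | 20–250 | 20–150 |
| mean RR (s) | 0.85 | 0.75 | 0.65 |

sEMG is Gaussian white noise band-passed to the state's band (4th-order
Butterworth, zero-phase), modulated by a 0.8 s contraction-cycle envelope
(depth 0.3) and rescaled to the target RMS.  The falling upper band edge
drives the zero-crossing count down with fatigue; the rising RMS drives
iEMG/ARV up.  ECG is a fixed sum-of-Gaussians PQRST template placed on an
RR point process: RR = mean + 0.05·sin(2π·0.1 Hz·t) + N(0, 0.025²) s.
The modulation depth and jitter are typical HRV magnitudes and are
balanced so the 0.1 Hz component is resolvable in the LF band (LF/HF > 1
by construction).  Records default to 30 s — long enough for ≥ 30 RR
intervals, the minimum for the 0.04 Hz band.  Ground-truth R-peak
positions, RR intervals and cycle onsets ride along as metadata.

Per-record seeds derive from the master seed by
`SeedSequence([master, record_index, modality_code])`, so any record is
reproducible in isolation and datasets are balanced by construction.

What the generator does *not* emulate: motor-unit action potentials,
motion artifacts, electrode noise, ECG artifact leakage into sEMG,
inter-subject variability, or any coupling between the two channels
beyond the shared label.  Consequently, passing recovery tests show that
the pipeline extracts and fuses the encoded class structure correctly —
they say nothing about accuracy on human recordings, and the reference
cohort percentages are documentation context only, never test targets.

## Experiment harness and problem sizes

`run_experiment` reproduces the 9-model comparison (ECG/sEMG × KNN/SVM/
TCN plus the three fused variants) at synthetic scale: default 30 records
per state and 3 training epochs — sized so the complete pipeline runs in
minutes on one CPU; both knobs scale up in `ExperimentConfig`.  Feature
baselines use full 10-fold CV; the two TCNs use a single stratified 70/30
train/test split, since ten network fits per modality would multiply
runtime roughly tenfold without exercising any additional code path.
Fused-TCN credibilities are estimated from the modality TCNs'
training-split accuracies; fused KNN/SVM use out-of-fold probabilities
(SVM margins mapped through a softmax) and CV-accuracy credibilities.
The test suite's recovery checks train the default network on 300
periods per class, and the property and oracle tests run at n ≤ 1000.

## Numerical choices and edge cases

* Mass-function normalisation tolerance 10⁻⁹; conflict cut-off
  K ≥ 1 − 10⁻¹².
* F-score is 0 by convention when precision + recall = 0; one-vs-rest
  counts with empty positive sets report precision/recall 0.
* Fold splitting is stratified with near-equal sizes (differ by ≤ 1).
* `normalize_length` rejects periods longer than L (L must hold at least
  one full period); length-L inputs pass through unchanged (idempotent).
* Zero-amplitude sEMG targets yield exactly-zero signals; a wavelet
  threshold of 0 reduces to perfect reconstruction.
* Weight-norm kernels guard the norm with a 10⁻¹² floor; softmax
  cross-entropy clips probabilities at 10⁻¹².
* ReLU subgradient at 0 is taken as 0.

## Known limitations

* The TCN is CPU-only and sized for desk-scale experiments; wall-clock
  cost grows linearly in records × epochs × L.
* The 60–160 Hz sEMG stop band follows the stated acquisition design, not
  common sEMG practice; treat it as a configurable historical choice.
* The envelope-based sEMG onset detector assumes either burst activity or
  periodic amplitude modulation; arrhythmic contraction patterns need
  external markers.
* Credibility estimation by accuracy normalisation is one defensible rule
  among several; the defaults (0.591/0.409) are fixed reference values.
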