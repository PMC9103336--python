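# Methods

This note documents the models, procedures and numerical choices behind
`fecgsqi`, a package for assessing the signal quality of non-invasive
foetal ECG (NI-FECG) recordings.

## Problem setting

An NI-FECG recording consists of one maternal chest lead (M) and three
abdominal leads (A1–A3), sampled at 1 kHz. Each abdominal lead carries a
mixture of the maternal ECG, a much weaker foetal ECG, and noise
(baseline wander, mains interference, broadband sensor and muscle
noise). A recording is *good* when the foetal heart rate (FHR) can be
read off at least one abdominal lead, and *bad* otherwise — the same
binary judgement a technician makes during a screening session. The
package automates that judgement two ways: a spectrogram CNN that
classifies 2.5 s multi-channel segments directly, and a classical
benchmark built on 45 signal-quality indices (SQIs).

## Synthetic data generator

Real NI-FECG corpora with quality labels are scarce and typically
private, so the package ships a generator that emulates the statistical
structure of such a corpus and provides ground truth (exact maternal and
foetal R-peak positions, known foetal SNR) that no real dataset offers.

**Beat morphology.** Each beat is a sum of five Gaussian lobes (P, Q, R,
S, T) on a beat-phase axis spanning 2π per cardiac cycle, in the style
of the standard dynamical ECG simulator. The foetal template is the
maternal one with the Q/R/S widths halved (`qrs_width_scale = 0.5`),
reflecting the shorter foetal depolarization. Lobe amplitudes are scaled
so a rendered R peak is ≈ 1 signal unit.

**Beat trains.** RR intervals are the nominal `60/rate` seconds with
multiplicative Gaussian jitter (σ = `rr_jitter_frac`, default 0.03,
truncated at 3σ) — enough variability to avoid perfectly periodic
spectra without modelling full heart-rate dynamics.

**Mixture model.** Channel M is the maternal render plus a small sensor
noise floor and no foetal content. Each abdominal channel is

    A_i = m_i · mecg + f_i · fecg + baseline + powerline + broadband,

with per-channel gains (defaults: maternal 0.5/0.4/0.6, foetal
0.15/0.25/0.2 before rescaling, i.e. foetal R ≈ 0.1–0.4 × maternal R),
a 0.3 Hz sinusoidal baseline (amplitude 0.1), a 50 Hz mains tone
(amplitude 0.05 ≈ 5 % of the maternal R peak) and Gaussian noise
(σ = 0.02). Random phases and noise come from named RNG streams spawned
from one integer seed, so recordings are bit-reproducible.

**SNR calibration and labels.** The foetal SNR of a channel is the power
ratio of the foetal component to the summed *non-maternal* noise. The
maternal component is deliberately excluded from the denominator: the
clinical quality judgement concerns FECG visibility, and the maternal
ECG is a structured signal that template subtraction removes, not noise.
All foetal gains are rescaled by a common factor so the best abdominal
channel achieves the configured target SNR exactly. The label is a pure
threshold function: good iff target SNR ≥ 3 dB. Dataset generation
draws per-class SNRs from disjoint intervals (good [6, 18] dB, bad
[−12, 0] dB), FHR uniform in [110, 160] bpm and MHR in [65, 95] bpm, so
no synthetic recording is borderline — mirroring a labelling procedure
that discarded recordings of inconsistent quality.

**What the generator does not emulate:** foetal movement and electrode
repositioning within a recording, uterine-contraction artefacts,
vernix-caseosa attenuation, twin pregnancies, and the non-linear
projection of the maternal ECG onto the abdomen (the generator uses one
maternal waveform with per-channel scalar gains). Consequently, passing
tests demonstrate that the pipeline's machinery is correct and that it
separates the *modelled* quality axis (foetal SNR); they do not certify
performance on real abdominal recordings.

## Preprocessing

Per channel, in order:

1. **Normalization** to [−1, 1]: `x̄ = 2 (x − x_min)/(x_max − x_min) − 1`.
   The output attains −1 and +1 exactly; a constant channel (dead
   electrode) raises a hard error rather than silently producing zeros.
2. **Bandpass**: causal single-pass 3rd-order Butterworth, 3–100 Hz.
   Zero-phase filtering is deliberately not used — it would double the
   effective order, and phase delay is irrelevant to image
   classification. One decade below the low edge the response is
   ≈ 60 dB down; one octave above the high edge ≈ 21 dB (the physical
   roll-off of an order-3 design).
3. **Segmentation**: 2.5 s windows, 0.1 s overlap (stride 2.4 s). At
   typical rates a window holds 4–6 foetal and 3–5 maternal R peaks —
   enough to judge measurability of the heart rate.
4. **Spectrogram**: 80-point Hamming-window magnitude STFT. The one-sided
   spectrum minus the DC bin gives 40 rows (12.5–500 Hz); DC is dropped
   because the 3 Hz high-pass has already emptied it. With hop 20 and
   centered framing a 2500-sample segment yields exactly 126 frames
   (⌊2500/20⌋ + 1). A left-aligned hop-25 variant (97 frames) is
   available behind `hop=25, centered=False`; the default was chosen to
   reproduce the 40 × 126 output geometry exactly, which a 25-sample
   hop cannot. Magnitudes (linear, not log) are min–max rescaled per
   image to [0, 128] and kept continuous; an all-zero input maps to the
   all-zero image. The per-image rescale makes images exactly invariant
   to positive amplitude scaling of the segment.

## QRS detection

Five detector families with deliberately different detection functions:

- `maxsearch` — rate-constrained local-maximum search on the smoothed
  energy envelope, seeded by the dominant RR from autocorrelation;
- `jqrs` — QRS-band energy with an adaptive threshold and search-back
  for gaps longer than 1.66 × the median RR;
- `pan_tompkins` — derivative → squaring → moving-window integration
  with dual adaptive (signal/noise) thresholds and search-back;
- `gqrs` — data-driven matched filter: a beat template averaged from
  the strongest candidate beats, normalized cross-correlation, adaptive
  threshold;
- `wqrs` — curve-length transform over a 130 ms window with trend
  removal and threshold crossing.

All detections are snapped to the nearest local |x| maximum and pruned
to a refractory period (200 ms maternal, 150 ms foetal; RR priors
50–110 and 100–180 bpm respectively). The families are *not* numerical
replicas of the WFDB implementations of the same names: what matters
for the detector-agreement features (bSQI) is behavioural diversity
under noise, and for annotation-based features accuracy on clean
signals (F1 ≥ 0.95 against generator truth across 60–160 bpm).

Annotation matching is greedy nearest-pair within ±50 ms, one-to-one,
ties toward the earlier reference beat; it guarantees TP + FP = |test|
and TP + FN = |reference|.

## Maternal-ECG cancellation (TSpca)

Template subtraction with principal components: 500 ms windows centered
on each maternal R peak are stacked, mean-centered per window, and
decomposed by SVD; each window is reconstructed from the top 2
components and subtracted in place. Overlapping windows (maternal rate
above ~120 bpm) are truncated at the midpoints between adjacent beats;
edge windows are truncated at the signal boundaries; samples outside
every window pass through unchanged. The per-window mean is not
restored — the bandpass has already removed the baseline. The window
length, component count and per-channel (rather than stacked-channel)
processing are this package's choices; they are exposed in
`TspcaConfig`. On perfectly periodic maternal-only input the residual
RMS is below 5 % of the input RMS; residual power is non-increasing in
the number of components (a property of the SVD truncation).

## The 45 SQI features

Ten detector-independent features are computed once per segment on the
extracted foetal signal of the best abdominal channel: stdSQI, sSQI
(skewness), kSQI (non-excess kurtosis), pSQI (1 − ratio of 5–15 Hz to
5–45 Hz power), basSQI (0–3 Hz over 0–100 Hz power), mxSQI (residual
energy around maternal R positions, inverted), mpSQIa/b (power at the
first five / all [0.5, 10] Hz harmonics of the maternal rate relative to
[0.5, 100] Hz), and mcSQIa/b (mean magnitude-squared coherence, chest
vs extracted and raw abdominal vs extracted). Ten bSQI features give
the F1 agreement of each unordered pair of the five detectors, and five
per-detector features (iSQI, rSQI, cSQI, xSQI, miSQI) complete
10 + 10 + 25 = 45. The layout is versioned (`fecgsqi-45-v1`) since
other partitions of the same feature families into 45 slots exist.

Choices worth noting:

- the "best" channel is the abdominal channel whose extracted signal
  maximizes xSQI under the Pan–Tompkins foetal detector;
- xSQI is defined here as E_in/(E_in + E_out) with E_in the mean squared
  amplitude inside ±50 ms beat windows — it satisfies the [0, 1] range
  law and the "beat extravagance" semantics;
- rSQI counts beat-to-beat heart-rate outliers (> 30 bpm from the
  median) over the number of RR intervals;
- mpSQI is reported as the raw harmonic-power ratio; whether strong
  maternal-harmonic content in a residual is good or bad is left to the
  classifier rather than baked into the feature's sign;
- every feature outside the three time-domain moments lies in [0, 1];
  degenerate inputs (too few beats, zero power) map to a sentinel 0 so
  classical models need no imputation, with a quality mask recording
  extraction failures.

## The spectrogram CNN

One convolutional path per channel (four paths, or three in the
abdominal-only variant). Each path stacks three residual blocks — two
3×3 stride-1 Conv2D layers, each followed by batch normalization, with a
1×1-convolution (batch-normalized) bypass summed into the block output
before the final ReLU — followed by a 24-unit fully connected layer.
The per-path outputs are concatenated into a single sigmoid unit: the
probability that the segment is of good quality. Default block widths
are (16, 32, 64); the `REDUCED_ARCH` preset uses (8, 16, 32) with 2×2
max pooling after each block, which shrinks the dense layer ~100-fold
and is the recommended configuration for CPU-bound work. Input pixels
are divided by 128 before the first convolution.

Training minimizes binary cross-entropy (computed on logits for
stability) with Adam at learning rate 5·10⁻⁴, batch size 28. After
every epoch the model is scored by validation AUC; the weights kept are
those of the best epoch, earliest epoch on ties. Weight initialization
is fan-in-scaled Gaussian, fully seeded; training is deterministic
given the seed.

The network lives on a compact numpy engine (`fecgsqi.nn`): stride-1
same-padding convolutions computed as per-kernel-offset GEMMs
accumulated in place via BLAS `sgemm` on contiguous buffers (chosen
after profiling — it avoids the large strided writes that dominate
im2col on a single core), batch normalization with running statistics,
2×2 max pooling with tie-splitting gradients, and Adam. Every layer's
gradients are tested against independent references (scipy correlations
and float64 closed forms).

## Evaluation protocol

Nested stratified cross-validation: an outer K-fold loop (default 10)
holds out a test fold; the remaining data enter an inner K-fold loop
(default 5) used purely for model selection — for the CNN, one training
run per inner fold with the best-validation-AUC weights winning; for
classical learners, a grid search scored by inner-CV mean AUC followed
by a refit on the full outer-training set. The selected model is
evaluated once on the held-out fold. Repetitions re-randomize the folds.
Aggregates are mean ± sample standard deviation (ddof = 1) over all
outer evaluations. The positive class is *good*.

Stratification is at segment level by default, matching a protocol that
partitions segments directly; because segments of one recording are
correlated, this flatters generalization estimates, so a
`grouping="recording"` mode keeps all segments of a recording in one
fold (grouped stratification) for honest estimates.

Classical baselines: Gaussian Naive Bayes, linear and RBF SVMs
(standardized features, margins mapped through a logistic so 0.5 is the
decision boundary), and random forests (raw features). Default grids:
SVM C ∈ {0.1, 1, 10, 100}, RBF γ ∈ {10⁻³, 10⁻², 10⁻¹, scale}; RF
trees ∈ {100, 300}, depth ∈ {∞, 10, 20}, min-leaf ∈ {1, 5}; NB variance
smoothing ∈ {10⁻⁹, 10⁻⁷, 10⁻⁵}.

Recording-level decisions use majority voting over segment predictions;
an exact tie resolves to *bad*, since rejecting a borderline recording
and re-recording is cheaper than accepting a useless one. False
positives and negatives are also reported per minute of data
(`fp/minutes`, `fn/minutes`).

## Problem sizes used by the test suite

The repository's end-to-end checks run on desk-scale versions of the
study conditions: 100 synthetic recordings (50 good / 50 bad, disjoint
SNR intervals) of 12.5 s each → 500 segments. Classical models are
evaluated on all 500 segments with a 2-fold outer / 2-fold inner nested
CV; the CNN (reduced preset, 20 epochs) on a 2-segments-per-recording
subset of 200 images with the same fold counts. These sizes keep the
default suite within ordinary CI budgets while leaving the protocol
itself — nested selection, stratification, best-epoch weights —
identical to the full-scale configuration (10 outer / 5 inner folds,
200 epochs), which remains the default of the library API.

## Known limitations

- The generator's linear mixing and single maternal projection make the
  synthetic separation task easier than real data; reported synthetic
  AUCs are upper bounds on realism.
- At few epochs the CNN's ranking (AUC) converges before its output
  calibration; 0.5-threshold accuracies lag AUC in short trainings.
- The classical SQI formulas re-derived from one-line descriptions
  (cSQI, xSQI, mpSQI, mcSQI) follow the documented definitions in this
  note; other implementations of the same names may differ in detail.
- WFDB container support is not provided; recordings travel as CSV with
  a sampling-rate header plus plain-text annotation files.
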