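# fecgsqi

Signal-quality assessment for non-invasive foetal electrocardiography
(NI-FECG).

Recording a foetal ECG through electrodes on the maternal abdomen is
cheap and safe, but the foetal component is weak and often drowned out
by the maternal ECG, baseline wander, mains interference and movement
artefacts. In practice a technician inspects every recording to decide
whether the foetal heart rate (FHR) is measurable — a labour-intensive
step this package automates. Given a four-channel recording (one
maternal chest lead *M*, three abdominal leads *A1–A3*, 1 kHz), it
classifies 2.5 s segments as **good** (FHR measurable) or **bad**, and
aggregates segment decisions into a recording-level verdict by majority
vote.

Two classifier families are provided, plus everything needed to train
and evaluate them without any external data:

- **`fecgsqi.cnn`** — a four-path residual CNN operating on per-channel
  spectrogram images. Each channel is normalized to [−1, 1] via
  x̄ = 2(x − x_min)/(x_max − x_min) − 1, bandpassed (3rd-order
  Butterworth, 3–100 Hz), segmented (2.5 s windows, 0.1 s overlap) and
  rendered as an 80-point Hamming STFT image of 40 × 126 pixels in
  [0, 128]. Each path stacks three residual Conv2D pairs with 1×1
  bypasses, batch norm and ReLU, then an FC-24 layer; the concatenated
  paths feed a single sigmoid output ŷ. Training is Adam (lr 5·10⁻⁴)
  on binary cross-entropy, keeping the weights of the epoch with the
  best validation AUC. The network runs on a compact, fully-tested
  numpy engine — no deep-learning framework required.
- **`fecgsqi.sqi`** — the classical benchmark: a 45-dimensional vector
  of signal-quality indices (statistical moments, band-power ratios
  such as pSQI and basSQI, detector-agreement bSQI over five QRS
  detectors, heart-rate regularity rSQI, morphology conformity cSQI,
  maternal-residual indices mxSQI/mpSQI/mcSQI/miSQI) computed from the
  TSpca-extracted foetal signal, fed to Naive Bayes, linear/RBF SVM or
  random-forest baselines with grid search.
- **`fecgsqi.synth`** — a seeded generator of labelled four-channel
  recordings (Gaussian-lobe ECG morphology, controllable foetal SNR,
  known R-peak ground truth) that emulates a screening corpus.
- **`fecgsqi.evaluation`** — nested stratified cross-validation
  (outer test folds, inner model-selection folds), standard metrics,
  per-minute false-event rates and majority voting.

## Worked example

Run the bundled end-to-end pipeline — synthesize a labelled corpus,
preprocess it, compute the 45 SQI features, and evaluate a random
forest with nested cross-validation:

```sh
$ fecgsqi run --learner rf --seed 1 --out-dir demo-out
rf: AUC 0.958 ± 0.038, accuracy 0.875, majority-vote accuracy 0.950
```

The run generated 20 recordings (10 good / 10 bad, 10 s each, 80
segments). The line reports the mean ± standard deviation of the AUC
over the outer test folds (0.958: the model ranks a random good segment
above a random bad one ~96 % of the time), the segment-level accuracy
at the 0.5 threshold, and the fraction of recordings whose label the
segment-majority vote recovered (19 of 20). `demo-out/summary.json`
holds the full record — confusion totals, per-minute false-positive and
false-negative rates, per-recording votes, the config hash and seed.

The same from Python, with the CNN instead:

```python
import numpy as np
from fecgsqi.pipeline import prepare_dataset
from fecgsqi.evaluation import FoldSpec, nested_cv
from fecgsqi.cnn import REDUCED_ARCH, TrainConfig

recs, segments, images, labels, groups = prepare_dataset(
    {"n_good": 10, "n_bad": 10, "duration_s": 10.0, "seed": 1})
result = nested_cv(images, labels, "cnn",
                   FoldSpec(outer_k=2, inner_k=2, seed=0),
                   arch=REDUCED_ARCH,
                   train_config=TrainConfig(epochs=20, seed=0))
print(result.aggregate()["auc"])
```

Other stages are exposed individually (`fecgsqi synth`, `preprocess`,
`qrs`, `extract`, `features`, `benchmark`) — see `fecgsqi --help`.

## Layout

```
src/fecgsqi/
  synth.py        labelled synthetic NI-FECG generator
  preprocess.py   normalize / bandpass / segment / spectrogram
  qrs.py          five QRS detectors + annotation matching
  extract.py      TSpca maternal-ECG cancellation
  sqi.py          45 classical SQI features
  nn.py, cnn.py   numpy NN engine and the four-path residual CNN
  benchmark.py    NB / SVM / RF baselines with grid search
  evaluation.py   nested stratified CV, metrics, majority voting
  io.py, cli.py, pipeline.py
docs/methods.md   models, assumptions, parameter choices, limitations
```
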