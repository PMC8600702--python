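# fus2net

A tested re-implementation of **Fus2Net**, a multi-branch residual-fusion
convolutional neural network for classifying breast-ultrasound (BUS)
lesion images as benign or malignant — together with everything needed to
exercise it without clinical data: a seeded synthetic speckle-phantom
generator, the published preprocessing pipeline, stratified k-fold
training, and ROC/confusion evaluation.

## Who this is for

Researchers in ultrasound computer-aided diagnosis who want a
reproducible, dependency-light reference of the Fus2Net architecture and
training protocol: the exact layer geometry is machine-checked against
the published 27-row parameter table, and every numerical component
(convolution gradients, AUC, stratification) is verified against
independent oracles in the test suite. The network engine is pure NumPy,
so nothing beyond the scientific Python stack is required.

## The model

Input 299×299 images (three-channel by default) pass through:

* a stem of three 3×3 convolutions (32/s2 valid, 32/s1 valid, 64/s1
  same), each with batch norm + ReLU;
* **Block 1**: three two-branch fusion modules — max-pool ∥ conv (→160
  ch), a 1×1/3×3 branch ∥ a 1×1/7×1/1×7/3×3 branch (→192 ch), avg-pool ∥
  conv (→384 ch) — each fused by channel concatenation;
* **Block 2**: three conv branches (→32, 32, 64 ch) concatenated to 128,
  projected by a linear 1×1 convolution to 384, multiplied by a residual
  scale γ = 0.1 and added back to the block input, then BN + ReLU;
* a head: average-pool to 4×4×384 → flatten (6144) → dense(128, L2 0.05)
  → dropout 0.5 → dense(2) → softmax.

Training follows the published protocol: stratified ten-fold
cross-validation, batch size 16, 53 epochs per fold, Adam/RMSprop/SGD at
default settings, softmax cross-entropy. Evaluation reports accuracy,
sensitivity, specificity, precision (malignant positive) and ROC/AUC.

## Worked example

Check the built network against the published layer table:

```python
from fus2net import (build_fus2net, Fus2NetConfig, conformance_check,
                     reference_table, metrics, ConfusionCounts)

model = build_fus2net(Fus2NetConfig(seed=0))
report = conformance_check(model, reference_table())
print("rows matched:", sum(o.match for o in report.outcomes), "/", len(report.outcomes))
print("total parameters:", report.total_params)
```

prints

```
rows matched: 27 / 27
total parameters: 1534962
```

meaning every layer's input/output shape matches the published table
(with its three internally inconsistent cells corrected, see
`docs/methods.md`), and the network holds ~1.53 M parameters including
batch-norm statistics. Metrics work directly on confusion counts — for a
hypothetical 100-image held-out set with 44 true positives, 48 true
negatives, 2 false positives and 6 false negatives:

```python
r = metrics(ConfusionCounts(tp=44, tn=48, fp=2, fn=6))
print(r.accuracy, r.sensitivity, r.specificity, r.precision)
```

```
0.92 0.88 0.96 0.9565217391304348
```

i.e. 92 % of images classified correctly, 88 % of malignant lesions
caught (sensitivity), 96 % of benign lesions recognized (specificity).

The same workflow is available from the shell:

```bash
fus2net generate --out data --n-benign 30 --n-malignant 30 \
                 --height 96 --width 96 --seed 7
fus2net check-arch --report conformance.json
fus2net train --data data --out run --folds 2 --epochs 12 \
              --input-size 96 --no-reg --seed 0
fus2net evaluate --data holdout --out eval --input-size 96
```

`generate` writes a `benign/`/`malignant/` PNG layout with a CSV
manifest; `train` writes per-fold metrics (`cv_results.json`) and
per-epoch histories; every command leaves a `run_record.json` with the
resolved configuration and seeds beside its artifacts.

## Synthetic phantoms

Real BUS images are not redistributable, so `fus2net.phantom` generates
B-mode-like phantoms: multiplicative speckle over a smooth background
with one hypoechoic lesion per image. Benign lesions have smooth
elliptical margins; malignant lesions carry radial roughness and
spicules. The margin statistic perimeter²/area separates the classes by a
wide margin, so the phantoms carry exactly the kind of signal —
morphology, not intensity — that the network is meant to learn.

## Layout

```
src/fus2net/
  phantom.py      seeded synthetic-phantom generator
  preprocess.py   balancing, bilinear resize, standardization, augmentation
  arch.py         layer table, shape oracle, builder, conformance
  nn/             pure-NumPy layers, DAG container, optimizers
  training.py     stratified k-fold harness
  evaluation.py   confusion/metrics/ROC/AUC
  cli.py          fus2net generate|preprocess|check-arch|train|evaluate
tests/            unit, property and acceptance suites
docs/methods.md   model, assumptions, parameter choices, limitations
```
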