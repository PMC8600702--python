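# Methods

## Problem and model

`fus2net` implements a two-class (benign vs. malignant) classifier for
B-mode breast-ultrasound (BUS) lesion images built around a multi-branch
fusion CNN. The network has four parts:

1. **Stem** — three 3×3 convolutions: 32 filters at stride 2 (valid
   padding), 32 at stride 1 (valid), 64 at stride 1 (same). Each
   convolution is followed by batch normalization and ReLU.
2. **Block 1** — three two-branch fusion modules whose branch outputs are
   channel-concatenated. Module 1: 3×3/stride-2 max-pooling ∥ 96-filter
   3×3/stride-2 convolution (→160 channels). Module 2: {1×1, 64; 3×3
   valid, 96} ∥ {1×1, 64; 7×1, 64; 1×7, 64; 3×3 valid, 96} (→192
   channels). Module 3: 3×3/stride-2 average pooling ∥ 192-filter
   3×3/stride-2 convolution (→384 channels). The asymmetric 7×1/1×7 pair
   deepens the network and adds nonlinearity at low parameter cost; the
   pooling branches regularize.
3. **Block 2 (scaled residual)** — three convolutional branches
   {1×1, 32} ∥ {1×1, 32; 3×3, 32} ∥ {1×1, 32; 3×3, 48; 3×3, 64}, all with
   same padding, concatenated to 128 channels, projected back to 384 by a
   linear 1×1 convolution, multiplied by a residual scale γ, and added
   elementwise to the block input, followed by BN + ReLU. The scaled
   shortcut (γ ≪ 1) stabilizes training of the deep fused trunk.
4. **Head** — average pooling to a 4×4 map, flatten (6144), a dense layer
   of width `fc1_width` with L2-regularized kernel, dropout, and a final
   2-neuron dense layer read out through a softmax. Training minimizes
   2-class softmax cross-entropy.

With a 299×299×3 input the layer geometry reproduces the published
27-row parameter table exactly; `fus2net.arch.reference_table()` encodes
that table declaratively and `conformance_check` verifies the built
network against it row by row. Three printed cells of the table are
internally inconsistent and are corrected (and flagged in the table's
`note` fields): the input channel counts of the second and third stem
convolutions (printed 3, necessarily 32), the duplicated "module 2"
section heading (the second occurrence is module 3), and the final
average-pooling row (printed stride 1 with no window, which cannot map
35→4; implemented as an 8×8/stride-8 valid pool, the unique standard
pooling reproducing the printed 4×4×384 output). Padding is not printed
anywhere; it is inferred per row as valid wherever the printed spatial
size shrinks and same wherever it is preserved.

Two independent routes to every shape are kept deliberately separate:
`infer_shape` is closed-form arithmetic over the declarative row
(valid: ⌊(n−f)/s⌋+1, same: ⌈n/s⌉), while the conformance registry records
the actual tensor shapes produced by executing the built network. Tests
and the acceptance script require the two routes to agree.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `input_size` | 299 px | network input side; other sizes re-derive the geometry |
| `channels` | 3 | three-channel (replicated-gray) or single-channel input |
| `residual_scale` γ | 0.1 | multiplier on the Block 2 branch before the add; the customary range for scaled residuals is 0.1–0.3, and the value is not recoverable from the published table |
| `fc1_width` | 128 | width of the first dense layer (not published) |
| `dropout_rate` | 0.5 | dropout after the first dense layer |
| `l2_factor` | 0.05 | L2 penalty on the first dense kernel (convention: `l2·Σw²`) |
| optimizer | adam | Adam/RMSprop/SGD at conventional defaults (lr 0.001/0.001/0.01) |
| `batch_size` | 16 | mini-batch size |
| `epochs_per_fold` | 53 | fixed epoch budget per fold, no early stopping |
| `k_folds` | 10 | stratified cross-validation folds |

Batch normalization uses momentum 0.9 for its running statistics, chosen
so that inference statistics are well calibrated within the short
(tens-of-steps-per-epoch) schedules this package is exercised at; the
epsilon is 1e−3. Weights are initialized from a truncated normal with
fan-in scaling (std √(2/fan_in), resampled beyond 2σ), biases at zero;
all initialization, shuffling, dropout and augmentation draws are seeded.

The engine underneath (`fus2net.nn`) is a compact pure-NumPy
implementation: im2col/GEMM convolution, window pooling, batch norm,
dense, dropout, concat/add, and Adam/RMSprop/SGD. Every backward pass is
verified against central finite differences in the test suite; max-pool
and ReLU checks use inputs spaced away from their kink points, where the
one-sided derivative makes finite differences uninformative.

## Preprocessing

Order: class balancing → bilinear resize → (training-time augmentation) →
per-image standardization, with standardization always the last step
before the network.

* **Balancing** oversamples the minority class by flipping `n_select`
  randomly chosen images horizontally and vertically (two new samples per
  selection). With the clinical split (646/306) and `n_select=170` the
  classes balance exactly at 646 each. By default balancing runs inside
  each cross-validation fold's training split only, so a mirror of a
  held-out image can never be trained on; `balance_mode="paper"`
  reproduces the published order (balance once, before splitting).
* **Resize** is bilinear with half-pixel-center alignment (the common
  image-library convention); a worked 2×2→3×3 example in the tests pins
  the convention down. Values stay in [0, 255] because bilinear weights
  are convex.
* **Standardization** is x* = (x − μ)/σ with μ, σ the mean and
  *population* standard deviation over all pixels and channels of the
  single image; a constant image maps to zeros. Per-image (rather than
  dataset-wide) statistics were chosen because the transform is defined
  on a single image; the operation is idempotent.
* **Augmentation** draws rotation (±20°), shift (±10 % of the frame),
  shear (±0.2), multiplicative brightness ([0.8, 1.2]) and
  horizontal/vertical flips per image per batch; magnitudes are
  configurable because the published account names the transform families
  but not their ranges. Resampling is bilinear with nearest-edge fill
  (avoiding artificial dark borders in speckle images); augmentation is
  applied on the fly to training batches only.
* **Channel modes**: one→three replicates the gray plane; three→one
  averages channels with round-half-even to the nearest integer.

## Synthetic phantoms

No public stand-in exists for the clinical images, so the package ships a
seeded phantom generator. Each phantom is a smooth echogenic background
(vertical gain ramp plus large-scale filtered noise around gray level
130) modulated by correlated multiplicative speckle (Gaussian field,
correlation length ≈ 1.2 px, amplitude `speckle_scale` = 0.25), with one
hypoechoic lesion (echo drop 45–60 %) whose support is an ellipse (aspect
0.6–1.0, random orientation, radius 10–24 % of the frame at defaults).
The class contrast is margin morphology: benign margins are smooth
ellipses; malignant margins multiply the radius by a low-order Fourier
roughness term plus 4–9 narrow Gaussian spicules, both scaled by
`malignant_boundary_roughness` (0.18 at clinical resolution). Setting the
roughness to zero collapses both classes onto the same boundary model.

The scale-free margin statistic perimeter²/area (4π for a disc), measured
on the generated masks by marching-squares contour tracing, separates the
classes essentially perfectly at default settings — the generator's
contract is that a trivial threshold classifier exceeds 80 % accuracy, so
any learning failure in the smoke tests indicts the pipeline, not the
data. In the reduced-resolution helper (`small_config`) the roughness
amplitude is raised to 0.35 because spicules that span 4–10 px at the
clinical 775×580 frame become sub-pixel once the lesion radius drops
below ~25 px; the larger amplitude preserves the same morphological
contrast after downscaling rather than easing the task.

What the phantoms do **not** model: beamforming geometry, attenuation,
acoustic shadowing/enhancement behind lesions, heterogeneous parenchyma,
calcifications, probe pressure artifacts, or annotation overlays. Passing
the learnability tests therefore shows the pipeline can extract a
shape-borne class signal end to end — it says nothing about clinical
performance on real BUS images.

## Training and evaluation

Stratified k-fold assignment is delegated to scikit-learn's
`StratifiedKFold` (shuffled, seeded), which guarantees per-fold class
counts within one of the global proportion; a round-robin dealing
fallback covers the degenerate case of classes smaller than k (e.g.
leave-one-out). Each fold trains a freshly initialized model for the full
epoch budget; batches are reshuffled every epoch with the fold seed and
the last partial batch is kept. The 53-epoch setting is a fixed stopping
budget, not an early-stopping criterion.

Evaluation takes malignant as the positive class: accuracy
(TP+TN)/total, sensitivity TP/(TP+FN), specificity TN/(FP+TN), precision
TP/(TP+FP). Hard labels use the argmax (equivalently a 0.5 threshold on
the malignant probability). Ratios with zero denominators are reported as
NaN and listed in `EvalResult.undefined` rather than zero-filled, so
degenerate folds remain visible. ROC curves and AUC are computed by
threshold sweep via scikit-learn; ties count one half, and the tests hold
the AUC to the all-pairs brute-force definition within 1e−12 and to the
trapezoid area under the returned curve within 1e−9.

## Problem sizes used by the test suite

The clinical experiment (1052 images at 775×580, tenfold, 53 epochs) is
GPU-scale; the package's own verification runs at sizes a single CPU
handles comfortably, as a deliberate design choice:

* architecture conformance at the full 299×299 geometry (exact, seconds);
* counting arithmetic (646 balance, 952/100 split, 64–65 stratification)
  at full counts but reduced frames, since only counts enter;
* the learnability run on 200 phantoms at a 96×96 variant of the
  architecture, 2 folds × 12 epochs, light augmentation
  (rotation ±15°, shift ±5 %, shear ±0.1), no dropout/L2 — the contrast
  between regularized and unregularized runs is exercised structurally
  elsewhere. Pooled held-out accuracy is tested against chance with a
  one-sided binomial test at p < 0.01 (with the shipped seeds the run
  scores around 150/200).

## Known limitations

* The engine is CPU-only NumPy; full-scale (299×299, tenfold, 53-epoch)
  training is possible but slow, and no GPU path is provided.
* The residual scale, first-dense width and final pooling parameters are
  not recoverable from the published description; all three are exposed
  as configuration with documented defaults.
* Phantom realism is deliberately minimal (see above); reported phantom
  metrics do not transfer to clinical data.
* `balance_mode="paper"` reproduces the published balance-before-split
  order, which permits flip-leakage across folds; it exists for
  procedural fidelity and is off by default.
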