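# Methods

## The model and its assumptions

The classifier operates on single maFLIM pixels: three fluorescence decay
channels (collagen, NADH, FAD emission bands) sampled at 0.25 ns, inverted,
zero-padded to 300 samples each and concatenated into a 900-vector normalized
to sum to 100. Working at pixel level turns a small cohort into millions of
training samples; the price is that pixels from one patient are highly
correlated, which is exactly the nuisance structure the contrastive stage is
designed to remove.

**Contrastive stage.** Within a batch, each class's anchor is its mean
embedding and each patient's mean embedding acts as a positive for its own
class and a negative for the others. Minimizing the clustering term and
maximizing the separation term shapes an embedding in which class membership,
not patient identity, determines position. Both terms are squared Euclidean
norms of vector differences; the adaptive weights are treated as constants
during backpropagation (no gradient flows through the weighting). Anchors are
pixel-weighted class means — with unequal pixels per patient this differs
from the patient-weighted mean; the pixel-weighted reading matches "mean
embedding of the class within the batch" and makes the anchor the exact mean
of its class's pixels.

The loss attaches at a structural tap: the fourth encoder layer's output
after batch normalization, before the ReLU. Batch normalization here is load-
bearing, not cosmetic — the separation term is unbounded on an unconstrained
embedding, and the 2-D arcs experiments show it diverging by many orders of
magnitude without it, while with it the embedding scale is pinned and the
term saturates.

**Multitask stage.** The two heads consume the post-activation bottleneck
(the activation is treated as part of the layer). Cross-entropies are
sample-weighted by scikit-learn "balanced" class weights of the training
distribution, with the weighted-mean reduction (unit weights give the plain
mean). The consistency regularizer formalizes "contradictory predictions" by
selection-with-stop-gradient: for ground-truth malignant pixels that the
diagnosis head calls malignant, a cross-entropy pushes the delineation head
toward "lesion"; for ground-truth healthy pixels that the delineation head
calls healthy, a cross-entropy pushes the diagnosis head toward its benign
side. Selection is by argmax and does not backpropagate through the selecting
head; the loss averages over contributing pixels and is zero when none
contribute. `L_reg` enters the total unweighted. The encoder keeps training
during this stage (joint fine-tuning); a `freeze_encoder` flag exposes the
alternative.

## Tunable parameters

| parameter | default | role |
|---|---|---|
| pre-training lr / batch / epochs | 1e-5 / 512 / 10 | Adam on the contrastive loss |
| gradient clip | 0.25 | global-norm clip, pre-training only |
| multitask lr / batch / epochs | 1e-5 / 256 / 5 | Adam on `L_MT` |
| α₀ | 1.0 | base clustering weight; α = α₀(1 − clamp(S,0,1)), updated once per epoch |
| ε | 1e-8 | floor on squared anchor distances in β (coincident-mean guard) |
| dropout p | 0.5 | head regularization |
| median filter window | 3×3 | spatial SNR improvement, borders clipped so size is preserved |
| SNR threshold | 2.0 | pixel mask: peak amplitude / tail-noise SD of the weakest channel |
| per-channel padded length | 300 | fixes the 900-d input |
| monitoring subsample | 10,000 px | silhouette estimate for α updates and dev selection |

Checkpoint selection: stage 1 takes the epoch with the highest development
silhouette; stage 2 the epoch with the highest development mean of the two
tasks' pixel-level balanced accuracies (diagnosis alone in single-task
ablations). The development criterion choices are ours; only "best model
based on the development set" is prescribed.

Silhouette monitoring uses the **batch-normalized embedding** (batch
statistics, running estimates untouched): that is the representation the
contrastive loss operates on, and the only well-defined one at
initialization, where the running estimates still hold their arbitrary (0, 1)
defaults.

## Synthetic data: what it emulates, what it does not

`simulate_cohort` produces one lesion and one healthy 160×160 image per
patient (desk-scale studies use smaller planes), three biexponential channel
decays per pixel at 0.25 ns with additive Gaussian noise, stored
negative-going so the preprocessing inversion is meaningful. Class structure:
malignant lesions get NADH/FAD-channel lifetimes shortened by the class
effect (the direction associated with a decreased optical redox ratio);
benign lesions get longer collagen/NADH lifetimes (structural remodeling);
healthy tissue is the baseline. A lognormal patient factor multiplies all of
a patient's lifetimes identically in both images — the inter-patient nuisance
the contrastive loss must overcome. Magnitudes are configuration knobs, not
claims about real tissue.

Not emulated: instrument-response convolution (explicitly not needed by the
method), spatial lesion structure within an image (pixels of an image are
exchangeable), day-to-day calibration drift (calibration factors default to
1), diagnosis-dependent anatomical-site effects, and realistic photon
statistics (noise is additive Gaussian, not Poisson). Passing tests therefore
demonstrate that the machinery recovers planted class structure under
patient-level nuisance — not clinical performance. The headline clinical
numbers (e.g. diagnosis sensitivity 82.08 %, specificity 75.92 %) belong to a
private dataset and are out of reach here by construction.

## Scaled-down study conditions

Desk-scale experiments must fit minutes, not GPU-days. The recovery study
uses 8+8 patients with 32×32 images (≈33k pixels), the default 900-d input
and a 900-128-64-32-16 encoder, and raises both learning rates from 1e-5 to
1e-3: the full-scale protocol takes ~66,000 pre-training steps (3.4 M pixels,
batch 512, 10 epochs) while the desk-scale cohort yields ~430, so the larger
rate keeps total parameter travel comparable; epochs, batch sizes and the
clip threshold stay at their defaults. Held-out predictions are pooled over a
truncated fold rotation (4 of 8 runs for the signal case; all 8 for the
chance-level control, whose estimate needs more images). The arcs demo trains
full-batch (300–450 points) for 400 steps at lr 1e-2.

## Numerical choices and degenerate inputs

- Squared distances in β are floored at ε = 1e-8; tail-noise SDs in the SNR
  statistic at machine epsilon, with the ratio capped at 1e6.
- Exact 50/50 pixel votes assign the image to the positive (lesion/malignant)
  class — the clinically conservative tie-break.
- Metrics with zero denominators are reported as absent (`None`), never as 0.
- Singleton silhouette clusters score 0; "next nearest cluster" minimizes the
  mean distance B (the standard definition).
- Single-class batches contribute no separation term (logged warning);
  classes absent from a batch are simply omitted from both sums.
- A pixel whose calibrated total signal is non-positive cannot be
  sum-normalized and raises a degenerate-pixel error; fully masked images
  yield empty datasets and are skipped with a warning at evaluation.
- Cross-validation with fewer than 4 folds degrades gracefully (1 dev fold at
  3; train = dev in 2-fold smoke configurations, which exist for orchestration
  tests only).
- All randomness flows from explicit seeds through `numpy` generators;
  weights use He-uniform initialization; BN momentum 0.1, eps 1e-5; float32
  forward/backward with float64 loss arithmetic.

## Open design points resolved here

- **3-class arcs construction**: the third class is the upper arc of an
  independently sampled moons pair translated by (2, 0), preserving the
  interleaved geometry; the original study does not describe its 3-class
  variant, so this is a stand-in, not a reconstruction.
- **Encoder widths**: the printed totals (4 layers, 630,814 parameters) admit
  several integer solutions; we use the canonical halving taper 900-512-256-
  128-16 with heads 16-21-14-2 and fail fast if the count drifts.
- **Patient-level folds**: splits assign whole patients (both images) to a
  fold; splitting a patient's images across train/test would leak patient
  identity into evaluation.
- **SNR statistic**: peak absolute amplitude over all channels divided by the
  tail-noise SD of the weakest channel — an explicit, testable stand-in where
  only "low-SNR pixels were masked" is prescribed.

## Known limitations

Training is CPU-bound NumPy; full-scale cohorts (67 patients at 160×160×3×
~250 samples) need streaming I/O (`iter_cohort` + the HDF5 container) and
hours of compute. The chance-level control is an estimate from a finite image
set: pooled over 16 held-out lesion images its sampling band is roughly ±0.1
even when the classifier is exactly at chance. The consistency loss is one
formalization of the described penalty; alternatives (symmetric KL between
heads, soft selection) were not explored.
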