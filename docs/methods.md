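# Methods

`btc` implements a complete three-class brain-tumor classification
pipeline for T1-contrast-enhanced MRI slices — enhancement,
segmentation, feature extraction, ensemble classification, evaluation —
at desk scale, with a synthetic phantom generator standing in for real
MRI collections.  This note records the models, the parameters that
matter, and the design choices made where the design was genuinely
open.

## Synthetic phantoms

Real three-class collections pair each slice with a tumor mask and one
of three diagnoses (meningioma, glioma, pituitary).  The generator
emulates the features the pipeline actually exploits:

* an axis-aligned elliptical "brain" (semi-axes ≈ 0.42/0.35 of the
  image side, ±5% jitter) at intensity ≈ 0.43 on a 0.05 background,
  with mild smooth texture;
* one bright lesion per image (base intensity drawn from 0.72–0.90 —
  deliberately overlapping across classes so raw brightness alone
  cannot classify; a test enforces that a tumor-mean threshold stays
  near chance);
* class-conditional geometry: **pituitary** — small (scale 0.16–0.24 of
  the minor semi-axis), compact, centred low on the midline (row offset
  0.38–0.55 of the vertical semi-axis, |col offset| ≤ 0.12);
  **meningioma** — smooth ellipse attached to the periphery (centre at
  72–85% of the boundary radius); **glioma** — large (0.32–0.46),
  boundary perturbed by random radial harmonics (orders 2–5, amplitudes
  4–10% of the radius), with internal multiplicative texture;
* a smooth multiplicative bias field (default amplitude 0.15) and
  additive Gaussian noise (default σ = 0.02 on the [0,1] scale).

Defaults: 64×64 pixels, 100 images per class for evaluation runs.
Everything derives from a single integer seed (per-image seeds spawn
from a `SeedSequence`), so identical calls are bit-identical.

**What the phantoms do not model:** skull/CSF anatomy, multi-sequence
MRI, partial-volume effects, scanner-specific noise spectra, 3-D
structure, or inter-patient anatomy. Passing tests show the pipeline's
machinery is correct and that it separates classes whose differences
are geometric and textural; they do not certify performance on real
MRI.

Preprocessing follows the standard recipe: min–max normalization to
[0, 1] (a constant image maps to zeros with a warning rather than
dividing by zero), and 4× augmentation — the original, one rotation
with the angle drawn from {90°, 180°, 270°}, a horizontal flip and a
vertical flip.  Grid-aligned rotations are exact (no interpolation);
arbitrary angles are available (bilinear for pixels,
nearest-neighbour for masks so they stay binary).  3,064 inputs
therefore become exactly 12,256.

## AGSW guided filter

The enhancement stage is a guided filter whose window weights are
anisotropic Gaussian side windows.  Output is locally linear in a
guidance image Y: `Z_i = a_k Y_i + b_k` within the window centred at
k.  Coefficients minimise the weighted ridge loss
`Σ w_i (a_k Y_i + b_k − p_i)² + ε a_k²`, giving

    a_k = Cov_w(Y, p) / (Var_w(Y) + ε),   b_k = E_w[p] − a_k E_w[Y].

A `literal` loss variant inserts an extra `+a_k` in the residual
(equivalent to shifting Y by one unit); it shares the gain and differs
only by −a_k in the bias, and exists purely as a fidelity switch — the
`standard` form is the default because the extra term contradicts the
filter's own output model.

*Weight bank.* For each orientation θ ∈ {0°, 45°, 90°, 135°} an
anisotropic Gaussian (σ_major = 2.0 along θ, σ_minor = 0.8 across,
window half-width r = 4) is restricted to nine side windows — full,
four halves, four quadrants — and renormalized to unit sum.  Per pixel
and orientation, the side window with the minimal weighted
reconstruction error is selected (ties to the fixed order full, L, R,
U, D, NW, NE, SW, SE); near an edge a one-sided window fits without
straddling it, which is what preserves edges.  One subtlety the tests
pin down: because each side-window mask is renormalized, the *centre*
pixel of an isolated impulse is actually best fit by the full window;
the one-sided windows win at the impulse's neighbours, which is where
straddling would blur.

*Aggregation.* The selected per-window coefficients are averaged into
per-pixel fields with the mask values as weights, over all covering
windows and orientations (`ā_i = Σ w_k(i−k) a_k / ξ`); borders are
replicate-padded so the normalizer ξ is never zero.  The output
`Z = ā·Y + b̄` is kept unclipped for downstream math and clipped to
[0, 1] for display.

*Guidance.* Y = (1−λ)·norm(image) + λ·norm(|∇image|) with λ = 0.3 and
central-difference gradients; a constant image (zero gradient) is
passed through unchanged, since min–max normalizing a constant is
degenerate.  ε defaults to 1e−3.  None of r, θ-set, σ, λ, ε have
canonical values; all are config keys.

*Morphological cleanup.* Otsu threshold → binary opening (disk,
radius 3) → hole filling → largest connected component → multiply.
Empty foreground falls back to the full-image mask with a warning.
The operation is idempotent on the phantoms (tested).

## Segmentation

A U-Net whose encoder stages are residual blocks followed by
squeeze-and-excitation (SE) recalibration: global average pool per
channel, FC to C/r (r = 4) with ReLU, FC back to C with sigmoid,
channelwise multiply.  The decoder mirrors with nearest-neighbour
upsampling, a 3×3 convolution and skip concatenation; a 1×1 sigmoid
head emits per-pixel lesion probability (binarized at 0.5).

The default is deliberately scaled down: depth 3, base 8 channels,
≈ 143k parameters — small enough to train in ~1.5 minutes on one CPU
while reaching Dice ≥ 0.8 on phantoms.  A full-scale SE-ResNet-101
style encoder (stage multiplicities 3/4/23/3) is constructible via
`full_scale=True` but deliberately not exercised by the tests.

Training: Dice loss plus **positive-weighted** binary cross-entropy
(lesion pixels weighted ×10, the order of the background/lesion pixel
ratio), Adagrad at learning rate 0.003, batch size 4, 70/30
train/test split, best-test-Dice checkpoint returned.  The positive
weighting is load-bearing: with unweighted BCE the optimizer can
drive the network into the all-background solution on some seeds
(saturated sigmoid, flat loss, Dice 0), and Adagrad's decaying
effective step cannot escape; weighting the rare class removes that
attractor.  The 1-pixel additive smoothing in the soft Dice keeps the
loss defined for empty masks.

ROI extraction crops the predicted mask's bounding box expanded by a
4-pixel margin, clips to the image, and resizes to 64×64 (bilinear,
anti-aliased).  An empty prediction falls back to the full image with
a warning, so downstream stages always receive an input.

## Feature extraction

The trunk composes: a 3×3 stem (8 channels) + 2×2 max pool → two
dense blocks (2 stages each, growth rate 4; each stage is a 3×3
convolution + ReLU on the concatenation of everything before it, so a
block maps g0 → g0 + N·g channels) each followed by a transition (1×1
convolution + 2×2 average pool) → a four-branch multiscale block
(1×1; 1×1→3×3; 1×1→5×5; 3×3 stride-1 max pool→1×1; widths 8/8/8/8,
concatenated to 32 channels at 8×8) → attention refinement → global
average pool → a 32-dim feature vector.

Attention refinement runs two blocks in parallel on the 8×8×32 map
and combines them:

* **Self-attention** over spatial positions: the map is flattened to
  Y×D (Y = 64), and per head i, `Q_i = F W_i^Q + e^Q` (same for K, V),
  `head_i = softmax(Q_i K_i^T / C_k) V_i`; heads (default h = 4,
  C_k = C_v = D/h) are concatenated and projected back to D.  The
  logits are divided by **C_k itself**, not √C_k — kept as the primary
  form with `divide_by_sqrt_Ck` as a config switch.  The output
  projection is dimensioned (h·C_v)×D, the only shape for a
  position-shared projection.
* **Spatial attention**: cross-channel average and max pooling →
  concat (H×W×2) → ReLU → 1×1 convolution to one channel → sigmoid →
  broadcast multiply.  σ is sigmoid and ψ is ReLU throughout.
* **Aggregation**: elementwise addition (a concat + 1×1-conv variant is
  available by config).
* **Channel attention**: global max pool per channel → 1×1 conv to
  Ĉ = max(1, round(C/8)) + ReLU → 1×1 conv to C + sigmoid →
  channelwise multiply.

Every gating block (SE, spatial, channel) only rescales by factors in
(0, 1): shapes and signs are invariants, and each block is tested
against an independent scalar-loop oracle at 1e−6.

The trunk is trained end-to-end with a small softmax classification
head (dropout 0.5) that is discarded after training; only the pooled
feature vector feeds the ensemble.  To keep evaluation honest, the
representation-learning sample is a *separate* phantom draw (fresh
seeds) — the extractor never sees the images it later featurizes, so
cross-validated accuracy carries no transductive leakage.  Training
defaults: Adagrad, learning rate 0.003, batch 32; 100 epochs at full
scale, 15 in the desk-scale pipeline (enough on phantoms).

## Ensemble classification

Members: random forest (200 trees), RBF-kernel SVM (C = 1) with
Platt-style sigmoid calibration for probabilities, and k-NN (k = 5,
distance weighting) — all scikit-learn, all seeded.  The soft vote is
the weighted mean of member probability matrices (rows re-sum to 1);
the prediction is the argmax with exact ties broken to the lowest
class index and logged.  Normalizing the sum to a mean leaves the
argmax unchanged and makes the output a genuine distribution.

Evaluation uses stratified 5-fold cross-validation: every sample is
tested exactly once; a class with fewer than k members triggers a
warning and an unstratified fallback.  When augmented copies are
present they carry their source index as a group: groups never split
across folds and only original images are scored, so augmentation
cannot leak across the train/test boundary or inflate the test set.

## Metrics

For an n×n confusion matrix (rows actual, columns predicted), each
class is scored one-vs-rest: TP = C[c,c], FN = row − TP, FP = column −
TP, TN = total − TP − FN − FP, then accuracy, specificity,
sensitivity, precision and F1 by their standard formulas.  Conventions
worth stating:

* the headline "overall accuracy" of a report is the **macro average
  of per-class accuracies**; trace/total is reported separately as the
  fold accuracy (for the shipped reference matrix these are 0.9967 and
  0.9951);
* zero-denominator metrics return 0 with a degeneracy flag instead of
  raising;
* summaries round half-up to 4 decimal places;
* ROC curves are one-vs-rest threshold sweeps with trapezoidal areas
  (scikit-learn), cross-checked in tests against an exhaustive
  pairwise-ranking (Mann–Whitney) computation.

The package ships `data/reference_confusion.csv`, the published
reference confusion matrix for the three-class problem (3,064
samples); `btc reproduce-reference` recomputes its full metric table
and exits nonzero on any 4-dp mismatch.

## Numerical core

No deep-learning framework is used: `btc.nn` is a small reverse-mode
autodiff engine over numpy — tensors record their tape, `conv2d` is
im2col plus one BLAS matmul per pass, pooling/upsampling/softmax/
losses have hand-derived backwards, all verified against central
finite differences.  Networks train in float32 for speed; the
functional surfaces used by the oracle tests run in float64 (the
guided-filter oracle agreement is at 1e−10, attention oracles at
1e−6).  After a backward pass the engine breaks the closure↔node
reference cycles so large activations free immediately by reference
counting — relevant when training under tight memory.

Reproducibility plumbing: a single master seed fans out to per-stage
seeds via `SeedSequence([master, crc32(stage_name)])`; the run
manifest records the config hash, per-stage seeds and timings, and
every artifact path.  Two runs with the same config and seed produce
identical confusion matrices.

## Problem sizes

The shipped desk-scale configuration — the one the tests and the
acceptance script exercise — uses 300 evaluation phantoms (100 per
class) at 64×64, a segmenter trained on a separate 60-phantom sample
for 15 epochs, a feature extractor trained on another 60-phantom
sample for 15 epochs, and 5-fold CV; one full run takes roughly two
minutes on a single CPU and reaches macro accuracy ≈ 0.95 with
segmentation Dice ≈ 0.9.  Full-scale settings (60 segmentation
epochs, 100 feature epochs, SE-ResNet-101-style encoder, 3,064-image
datasets with 4× augmentation) remain expressible through the same
configs.

## Known limitations

* Phantom realism is intentionally minimal (see above); accuracy
  numbers on phantoms say nothing quantitative about real MRI.
* The 70/30 segmentation split and the later 5-fold CV operate on
  disjoint phantom samples, so their interaction on a shared real
  dataset is not modelled.
* The attention-logit scaling `1/C_k` (as adopted) damps attention for
  wide heads; the √C_k switch exists but is not the default.
* Adagrad's monotonically decaying step can stall long runs; at the
  shipped epoch counts this is not reached.
* The CLI stores model weights as `.npz` plus a JSON descriptor; there
  is no cross-version checkpoint compatibility promise.
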