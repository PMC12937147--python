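# Methods

## Problem and model

The package classifies a breast as benign or malignant from its two standard
mammographic projections — craniocaudal (CC) and mediolateral oblique (MLO) —
processed jointly. The network is a dual-branch convolutional classifier with
adaptive cross-view fusion:

1. **View-specific residual branches.** Each view (256×256×1 by default) passes
   through three residual blocks with 32, 64 and 128 filters. A block is
   conv3×3 → batch norm → ReLU → maxpool2×2, added to a shortcut. Because the
   block halves the spatial size and changes the channel count, a literal
   identity shortcut is impossible; the shortcut is a 1×1 stride-2 projection
   convolution (the standard down-sampling residual form). The branch shape
   ladder is 256×256×1 → 128×128×32 → 64×64×64 → 32×32×128, and the two
   branches share architecture but not weights.
2. **Gated cross-view fusion.** Per view, a 1×1 convolution plus sigmoid
   produces a gate map g_v the same shape as the feature map (32×32×128);
   the fused map is `F = g_MLO ⊙ F_MLO + g_CC ⊙ F_CC`. Gates are
   full-resolution and full-channel because the elementwise product pairs
   them with same-shaped features; a spatial-only (single-channel) gate is
   available as a config option. The ablation baseline replaces gating with
   channel concatenation followed by a 1×1 reduction back to 128 channels so
   that all downstream stages are shape-invariant across fusion modes.
3. **Multi-head self-attention.** The 1024 spatial positions of the fused map
   are treated as tokens with 128-channel embeddings; four heads compute
   scaled dot-product attention with d_k = 128/4 = 32, the head outputs are
   concatenated and projected back to 128 channels. A residual skip is added
   before the per-token layer normalisation (standard transformer practice;
   toggleable via `mhsa_residual`). No positional encoding is used.
4. **Spatial attention.** Channel-wise mean and max maps are concatenated
   (H×W×2), passed through a 7×7 same-padded convolution and a sigmoid to give
   a single-channel map M_s that multiplicatively reweights the features. The
   map is computed from the self-attention output (the pipeline order); the
   `spatial_map_from_fused` flag instead derives M_s from the pre-attention
   fused map.
5. **Head.** Global average pooling (128-vector) → dense 64 + ReLU →
   dropout 0.5 (training only) → dense 1 + sigmoid = malignancy probability.

Training minimises inverse-class-frequency–weighted binary cross-entropy

    L = -(1/N) Σ_i w_{y_i} [ y_i log p_i + (1-y_i) log(1-p_i) ],
    w_c = N / (2 N_c),

with Adam at 1e-4, batch size 16, learning rate ×0.1 after a five-epoch
validation-loss plateau, early stopping on validation loss (patience 10 —
the plateau patience is part of the published recipe, the stopping patience
is this package's choice), at most 100 epochs. Probabilities entering the log
terms are clamped to [1e-7, 1-1e-7].

## Numerical engine

The network, including the backward pass, runs on a compact numpy
reverse-mode autodiff core (`mammofusion.nn`): a define-by-run tape whose ops
(GEMM-based im2col convolution, maxpool with argmax routing, batch/layer
norm, softmax, elementwise ops) each register a gradient closure. Arrays are
float32 NHWC. Gradients of every op are verified against central finite
differences in the test suite; the convolution forward is additionally
checked against `scipy.ndimage.correlate`. Weight init is He-normal for
convolutions and Glorot-uniform for dense layers, all drawn from a single
seeded `numpy.random.Generator`, so inference and restarted training are
bit-reproducible.

## Preprocessing

Per view: orientation normalisation (right-laterality images are flipped so
the chest wall is always the left edge — this makes the pectoral-corner
heuristic view-invariant), Otsu breast extraction (256-bin between-class
variance scan; the largest connected foreground component is kept and cropped
to its bounding box), MLO-only pectoral suppression, CLAHE (clip limit 2.0,
8×8 tiles — standard defaults, exposed in config), bilinear resize to
256×256, rescale to [0, 1]. CC and MLO records are paired by (case id,
laterality); unpaired views are excluded and cross-laterality pairing is
never performed.

The pectoral estimator thresholds the brightest intensity class in the
upper-posterior quadrant (a second Otsu pass within the first pass's bright
class, falling back to the first threshold when that class is homogeneous),
keeps the connected component touching the corner, fits a straight line to
its lower boundary and zeroes everything above-left of the line. When no
component touches the corner the image is returned unchanged with a logged
warning, which also makes the operation idempotent. This is a deliberately
simple, replaceable stand-in for a published pectoral-removal algorithm that
is only cited, not described, in the source method.

CLAHE is implemented directly (clipped per-tile histograms with uniform
excess redistribution; bilinear blending of per-tile lookup tables) on the
8-bit [0, 255] convention, so that at each tile center the mapping equals the
tile's own equalisation — the property the tests exercise.

Whether contrast enhancement precedes or follows pectoral removal is an open
choice; this package removes the pectoral wedge first so the enhancement
never amplifies wedge-boundary artefacts.

## Augmentation

Training pairs are expanded by the original, a horizontal flip, and one
rotation per angle in (45°, 90°, 135°, 180°, 234°, 270°) — exactly 8 outputs
per input, applied identically to both views. The transforms are not
composed (flip × rotation would give 14×). The 234° angle is kept verbatim
as the default (it is plausibly a transposed 225°, but fidelity wins) and is
configurable. Non-right-angle rotations keep the 256×256 frame (rotation
about the center, bilinear sampling, zero fill); right angles and flips are
exact array reorderings and preserve the intensity histogram. Samples tagged
as held-out are refused by the augmentation entry point — test data is never
augmented, and splits precede augmentation.

## Synthetic phantoms

The generator renders paired CC/MLO phantoms: a half-elliptical breast on
the chest-wall edge (geometry jittered per case; right-laterality cases
mirrored), a bright triangular pectoral wedge in MLO views only, smooth
within-breast texture, additive Gaussian noise, and lesions whose boundary
irregularity encodes the class. Malignant lesions (1–3 per case by default)
have radial boundaries perturbed by random-phase harmonics with amplitude
0.35; benign cases show, with probability 0.5, a single smooth blob at 55 %
contrast with amplitude 0.05. Lesions are placed at the same breast-relative
coordinates in both views, displaced in the MLO rendering by at most the
configured jitter (default 1.5 % of image size). `view_asymmetry` attenuates
the lesion contrast in one view (fixed or per-case random) to emulate cases
whose diagnostic signal is concentrated in a single projection. Every record
carries ground-truth mask channels (breast, pectoral, lesion), used by tests
as oracles for the Otsu, pectoral-removal and Grad-CAM stages.

Intensities are 8-bit-like floats in [0, 255] (tissue 110, pectoral 185,
malignant lesion +70, texture SD 18, noise SD 6 by default). The phantoms
make no attempt at radiographic texture realism or BI-RADS taxonomy: passing
tests demonstrate that the pipeline's machinery works end-to-end and that
the architecture can learn a lesion-morphology signal, not that the model
would perform at any particular level on clinical FFDM data.

## Evaluation

Confusion-based metrics (sensitivity, specificity, accuracy, precision, F1,
classification error rate = 1 − accuracy) at decision threshold 0.5;
undefined ratios (zero denominators) are reported as missing rather than
zero so they cannot distort fold means. ROC by threshold sweep with
trapezoidal AUC (ties collapse into one step); Cohen's kappa from the
confusion marginals. Cross-validation aggregates interpolate each fold's TPR
onto a fixed 101-point FPR grid and report the pointwise mean curve with a
±1 SD band plus mean AUC ± SD across folds.

## Grad-CAM

For a chosen spatial stage (default: the spatial-attention-refined map, the
last stage with spatial extent before pooling), channel weights are the
globally averaged gradients of the pre-sigmoid logit with respect to the
stage activations; the map is ReLU of the weighted channel sum, bilinearly
upsampled to the input resolution and min-max normalised. Zero-gradient or
non-positive maps are flagged degenerate and returned as all-zero. Overlays
alpha-blend a jet colormap at 0.4 over the grayscale input (red = high).

## Problem sizes used by the test and acceptance runs

The suite runs on a single CPU with a numpy training loop, so the learning
checks use scaled-down renderings chosen once:

* **Tiny overfit:** 32 pairs (16/16), phantoms at 128 px preprocessed to
  64×64 input, full model, 45 epochs; reaches 100 % training accuracy around
  epoch 30.
* **Ablation ordering:** 40 cases with per-case random view asymmetry
  (attenuation 0.85), 48×48 input, 2-fold CV, right-angle + flip
  augmentation of the training folds, 18 epochs, three seeds.
* **Cross-validated study (acceptance script):** 30 cases, 48×48 input,
  5-fold CV, 15 epochs.

The architecture shape checks run at the full 256×256 input. Checks that are
counting- or arithmetic-based (augmentation factors, metric oracles) are
size-independent by construction.

## Known limitations

* The numpy engine is single-threaded and memory-bound; it is suitable for
  the desk-scale studies above, not for full-resolution training on
  thousands of mammograms.
* The pectoral estimator assumes an approximately straight wedge boundary
  touching the image corner; strongly curved or low-contrast pectoral
  margins on real FFDM would need the published algorithm it stands in for.
* Phantom results do not transfer to clinical performance claims; the
  generator exists to exercise and verify the pipeline.
* At desk scale the ablation ordering between the four fusion/attention
  variants is noisy: with tens of training pairs the attention stages'
  extra parameters are not reliably beneficial, whereas the published
  ordering was measured on thousands of images.
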