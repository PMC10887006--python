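# Methods

## Model

`neurofuse` classifies paired, co-registered CE-T1WI / T2-Flair axial
slices into three tumor types (GBM, SBM, PCNSL). Two weight-independent
encoders with identical topology process the two modalities: a 3×3 stem
convolution, then three stages of [5-layer dense block → 1×1 transition →
2×2 average pooling]. Every dense layer is BatchNorm → ReLU → 3×3
convolution emitting `growth_rate` channels and receives the concatenation
of the block input and all previous layer outputs. With a 240×240 input the
per-stage grids are 120², 60² and 30²; the default transition widths
(32, 64, 128) make the deepest feature 30×30×128.

Fusion happens at all three scales. At each scale the two modality features
are first projected to a common width by a shared 1×1 convolution, then
merged pixel-wise by a convex combination whose weights derive from each
modality's *activity level*: the channel-wise L1 norm, smoothed by a
(2r+1)² box sum with the divisor held fixed at (2r+1)² (zero padding, so
border pixels are down-weighted rather than renormalised; this follows the
printed formula of the fusion rule rather than a partial-window average).
Where the weight denominator falls below 1e-8 — all modalities inactive —
the weights fall back to the uniform 1/K and carry no gradient. The three
per-scale fused maps are resized bilinearly to the 30×30 grid and averaged;
a "last-scale-only" path is available by calling the fusion with a single
scale. The published architecture fuses the three scales but does not state
how they combine; averaging preserves the stated 30×30×128 fused geometry
while using all scales.

Channel-then-spatial multiplicative attention (a sigmoid bottleneck over the
spatially pooled descriptor, then a sigmoid over a 3×3 convolution of the
channel-mean map) is applied separately to the two deep modality features
and to the fused map. The exact attention formulation is not specified in
the source description ("spatial-channel self-attention"); this sequential
gating is the standard lightweight realisation, and `attention: off`
disables it for ablations. The three gated 30×30 blocks are concatenated
(3×128 = 384 channels), flattened and passed through two fully connected
layers (hidden width 256 by default) and a softmax.

The training loss is the mean over slices of the categorical cross-entropy
−Σ_l y_l log p_l; probabilities are clamped at 1e-12 inside the log.
Network inputs in [0, 255] are divided by 255 at the first layer.

## Preprocessing

Raw volumes are assumed co-registered (deformable registration is an
upstream prerequisite, as is skull stripping; the brain mask is an input).
The chain is: resample CE-T1WI onto the T2-Flair grid (linear
interpolation, zero fill outside the moving volume); clip intensities to
[μ−3σ, μ+3σ] where μ and σ are the mean and *population* standard
deviation over the whole volume (per modality; a constant volume is
returned unchanged); crop each slice to the smallest axis-aligned square
containing the brain mask's bounding box, centred on it, shifted to stay
inside the image where possible and zero-padded where not; resize
bilinearly to 240×240; min-max map to [0, 255] (constant slices map to
zero). Masks are resized with nearest-neighbour interpolation.

## Synthetic phantom study

No clinical data ships with the package; the `synthetic` module generates
seeded co-registered two-modality slice stacks that caricature the three
phenotypes:

| phenotype | modality 1 (enhancing) | modality 2 (edema) |
|-----------|------------------------|--------------------|
| GBM-like  | bright ring (2.2×bg), dark core (0.45×bg) | moderate halo, 1.5× lesion radius |
| SBM-like  | compact bright nodule (2.25×bg, 0.55× radius) | broad halo, 2.6× radius |
| PCNSL-like| homogeneous bright mass (1.95×bg) | thin halo, 1.3× radius |

against an elliptical "brain" of intensity 100 at native 128×128 resolution
(exercising the resize path), with per-patient jitter of lesion position
(±10% of the image), radius (±20%) and contrast (±10%), a spherical-cap
radius profile across 3–8 tumor slices, 1–2 lesion-free slices per patient
(so tumor-slice filtering is exercised), and additive Gaussian noise
(SD 6 by default, against a lesion/background contrast of ~100). Mean
lesion brightness is similar across classes on modality 1, so ring vs.
homogeneous discrimination requires spatial features and SBM discrimination
leans on the second modality — the encoders and the fusion path both carry
real signal.

The per-slice lesion mask uses whole-lesion semantics: the focal
abnormality *union* its hyperintense halo, the usual whole-tumor convention
in brain-lesion segmentation. The masks select the "slices containing the
tumor" for training and patient aggregation and define the in/out regions
of the Grad-CAM localization measurement; they are never model inputs.

What the phantoms do **not** emulate: scanner physics (k-space, bias
fields, coil profiles), anatomy (gyri, ventricles, skull), registration
error, class-imbalanced cohorts, or intra-class heterogeneity beyond the
jitter above. Passing the end-to-end study therefore shows that the
pipeline is wired correctly and can recover class structure that matches
its assumptions — not that it reaches clinical accuracy.

## Training and evaluation protocol

Library defaults follow the reference recipe: Adam, learning rate 1e-4,
weight decay 1e-5 (classic L2 folded into the gradient), 100 epochs,
5-fold patient-level stratified cross-validation. Batch size defaults
to 16 (unstated in the source; a common choice). Folds are seeded: within
each class, patients are shuffled and dealt so per-class fold sizes differ
by at most one, extras going to the currently smallest folds, which also
keeps total fold sizes maximally even. Per-fold models are re-initialised
with fold-derived seeds.

A patient's prediction is the element-wise mean of the slice
probabilities; the label is its argmax. Per-class Youden-optimal ROC
cutoffs (ties broken toward higher specificity) are reported alongside but
do not override the argmax — the source is ambiguous on this point, and
argmax keeps the three-class rule coherent. Metrics: accuracy; macro
one-vs-rest PPV, sensitivity, specificity, F1; macro one-vs-rest
trapezoidal AUC on patient probabilities (the multiclass AUC scheme is
unstated in the source; macro one-vs-rest assumed). NRI is the categorical
form on predicted labels, P(new right, ref wrong) − P(new wrong, ref
right), because the risk-threshold variant needs formulas that are not
available. Grad-CAM weights are spatial means of the class-logit gradient
at the chosen feature layer (`fusion`, `t1ce` or `flair`; post-attention);
the rectified weighted sum is upsampled to 240×240 and min-max normalised.

## The scaled study

The end-to-end experiment in the test suite and acceptance script uses a
90-patient cohort (30 per class; ~500 tumor slices), the reduced-width
configuration `small_config()` (stem 3, growth 3, stage widths 6/10/12,
hidden 32 — same topology, same 240→30 geometry), and 4 epochs of Adam at
learning rate 1e-3, batch 8, with fold 0 of a stratified 5-fold split held
out (18 patients). The larger learning rate and short schedule suit the
narrow model and the phantoms' strong class structure: training loss
plateaus within two epochs. The determinism check runs a miniature
pipeline (2 patients per class, 1 epoch) twice and requires byte-identical
metric reports.

## Numerical choices

* The tensor engine is a numpy reverse-mode autodiff core; the dense
  blocks run as one fused numba operation over a shared channel buffer
  with a hand-derived backward, and the 3×3 convolutions use compiled
  loops. All gradients are validated against central finite differences
  (float64, tiny models); the whole-model check uses a directional
  derivative along the analytic gradient, after nudging parameters off the
  zero init — at exactly zero bias/shift the stem's ReLU zeros sit on the
  kink, where a central difference measures the subgradient average rather
  than the one-sided derivative.
* Bilinear resizing uses half-pixel centres with edge clamping, expressed
  as dense 1-D interpolation matrices so the adjoint is exact.
* BatchNorm: eps 1e-5, momentum 0.1, population batch statistics, running
  stats at evaluation.
* Model weights: He-normal initialisation, seeded; float32 by default,
  float64 available for gradient checks.
* [0, 255] normalisation clips round-off so the contract holds exactly;
  σ = 0 volumes and constant slices short-circuit to the identity / zeros.

## Limitations

* 2D slices only; no 3D context beyond patient-level averaging.
* The numpy/numba engine is single-threaded and CPU-bound: the default
  width at 240×240 is practical for inference and geometry checks, while
  training experiments use the reduced width.
* The phantom study bounds what the tests can claim about clinical data
  (see above); reported phantom metrics are not estimates of clinical
  performance.
* NRI is the categorical approximation; AUC averaging is macro one-vs-rest
  by assumption.
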