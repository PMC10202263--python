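# Methods

`genscreen` implements a two-stage screening method for scoliosis-like
spinal curvature on frontal radiographs and exercises it end to end on a
synthetic phantom simulator. This note records the model, the knobs that
matter, and the design decisions taken where the design was genuinely open.

## The method

**Stage 1 — generative training on diseased images only.** A style-based
GAN (mapping network Z→W, synthesis network W→image) is trained exclusively
on radiographs *with* curvature at or above the diagnostic threshold. The
rationale: even severely scoliotic spines contain locally normal segments,
so a generator fit to the diseased distribution still spans near-normal
appearance, while concentrating its latent variation on the disease axis.
Training uses the non-saturating logistic loss with lazy R1 regularization
on the discriminator (coefficient γ = 6.5536, applied every 16 steps and
scaled by the interval), Adam with learning rate 0.002 and betas (0, 0.99)
for both networks, and differentiable discriminator-input augmentation
(brightness/contrast jitter, small integer translations). Horizontal flips
and cutout are deliberately excluded: curve direction (dextro vs levo) is a
clinical signal and occlusions are not a plausible radiograph corruption.
Checkpoints are recorded on a fixed interval and the one with the lowest
Fréchet distance between real and generated feature embeddings is selected.

**Stage 2 — inversion features and linear probing.** A query image `x` is
embedded by solving

    w* = argmin_w  || G(w) − x ||²  ( + λ · noise regularizer )

with the generator frozen, by Adam on a single W-space vector (not the
per-layer W+ extension) for a fixed iteration count (default 1000;
initialization at the mean W over 1000 mapped z draws; learning rate 0.1
with 5% warm-up and a 25% cosine ramp-down; best-so-far latent kept). The
optimized `w*` is the feature. A projection head — an MLP with 1–3 affine
layers, 512 ReLU hidden units, a 1-dimensional sigmoid output, and no batch
normalization — is trained on the latents with binary cross-entropy,
full-batch Adam at learning rate 0.001 for exactly 200 epochs on a 1:1
balanced downstream split.

**Screening evaluation.** AUROC (equal to the Mann–Whitney statistic) with
a stratified-bootstrap percentile 95% CI; the operating threshold is the
largest `t` with sensitivity(score ≥ t) ≥ 0.9 — the screening convention of
pinning sensitivity and reading specificity/PPV/NPV off the resulting
confusion table. The decision rule is inclusive (`score ≥ t`), which
matters when scores tie at the threshold. Reconstruction quality is
reported as RMSE and PSNR on the 8-bit (0–255) scale and SSIM with the
standard constants (K1=0.01, K2=0.03, 7×7 uniform window, scikit-image's
default), compared between groups with Welch or paired t-tests.

## The synthetic phantom

Real screening radiographs are hospital data and are not distributed with
this package; the simulator generates the study's data conditions instead.
Each phantom is a torso (soft-edged ellipse), six symmetric rib arcs, and a
column of 16 super-Gaussian vertebral bodies laid along a parametric
centerline. The centerline's lateral offset is a sum of one or two
sinusoidal terms in normalized height with controllable apex positions; the
ground-truth Cobb angle is the maximum pairwise angle between centerline
tangents (computed densely, i.e. landmark-free), and amplitudes are solved
by bisection so a requested severity is hit to within ±0.05°. Curve
direction is levo (left-convex) with probability 0.125, matching the
clinical estimate that 10–15% of adolescent scoliosis curves are
left-convex. Optional quadratic-Bézier bright curves emulate external
device lines (catheters, monitor wires) — the false-positive confounders of
real chest films — behind an `artifact_prob` stress knob that defaults off.

Dataset recipes mirror the two-stage design: a diseased-only upstream split
(severity uniform on 20–45°), a 1:1 balanced downstream split, and an
imbalanced test split. Normals draw severity from 0–9°; the 10–19°
borderline band is deliberately left empty by default (borderline cases are
a stress setting, not the base condition). The diagnostic threshold is 20°.

What the phantom does *not* emulate: projection physics, exposure and
positioning variability, anatomy beyond the spine band and ribs, age/sex
differences, or real curve taxonomies beyond apex position and count.
Passing tests therefore demonstrate that the pipeline's machinery works and
that its qualitative claims (normals embed into a diseased-only manifold;
latents carry the disease signal; the dominant latent direction acts as a
curvature axis) reproduce under controlled conditions — not that the
clinical performance numbers transfer.

## Problem sizes (micro profile)

The package's default experiment is sized for a single CPU: 32×32 phantoms,
192 upstream images, 128+128 downstream, 40+120 test; generator/discriminator
channel plan `min(256/res, 48)` with 64-dimensional Z and W; 1000 training
steps at batch 16; FID from a fixed seeded random-convnet embedding (used
only to *rank* checkpoints of a run, where a pretrained embedding adds
nothing at this scale); inversion at 150 iterations for dataset-scale work.
At these sizes the GAN trains in minutes and the full pipeline, inversion
included, completes in about ten. A 512×512 profile with the full 1000
inversion iterations is configuration, not code: every size above is a
config field.

## Numerical and design choices

- **Autodiff.** The models run on a small in-repo reverse-mode tensor
  engine (NumPy) whose vector-Jacobian products are themselves graph
  expressions, so the R1 gradient penalty's double backward is exact; this
  is verified against analytic forms in the tests. Convolution is im2col
  plus a closed family of three BLAS-backed bilinear primitives.
- **Modulated convolutions** use weight demodulation; the generator has no
  per-layer noise inputs, so the inversion's noise-regularization weight
  defaults to 0 (the hook remains for generators that carry noise maps).
- **Preprocessing order** is spacing correction → CLAHE → pad → resize →
  channel stacking. CLAHE runs before padding so the zero border cannot
  distort tile histograms. CLAHE quantizes to 8 bits first; the clip limit
  uses the per-bin convention (2.0 with an (8,8) tile grid) and is mapped
  to scikit-image's normalized parameter as `clip/nbins`. Padding is
  centered and zero-valued so the spine stays centered; resampling is
  bilinear.
- **Spacing correction** resamples the denser axis down to the coarser
  spacing (mm-isotropic pixels), preserving the physical aspect ratio that
  naive resizing would distort — and with it the apparent Cobb angle.
- **Probe standardization.** Latents are z-scored per dimension on the
  training rows before probing (toggleable). Rationale: full-batch Adam at
  the fixed small learning rate is scale-sensitive; standardization makes
  the 200-epoch budget reliably sufficient.
- **Fixed-sensitivity threshold.** With P positives, the threshold is the
  ⌈0.9·P⌉-th largest positive score; any higher observed threshold provably
  violates the target (tightness is property-tested). A target of 0 is
  rejected rather than mapped to a degenerate threshold.
- **CI method.** Stratified bootstrap percentile (2.5/97.5) with 2000
  replicates by default; resamples are drawn within class so every
  replicate has both classes.
- **FID** clamps small negative values (eigen-noise of the matrix square
  root) to zero; ties in checkpoint selection resolve to the earliest
  iteration.
- **SeFa directions** come from the first style-affine layer only (the
  single-layer variant); multi-layer aggregation is out of scope. Traversal
  at α=0 is the identity by construction (same code path). Which of the
  leading directions carries the curvature axis varies with the training
  seed; the tested claim is that one of the top three does, monotonically
  sweeping a lateral-deviation score of the rendered spine for most
  starting latents.
- **Inversion batching.** Images are inverted jointly in batches; because
  the loss decouples per image and Adam is diagonal, per-image trajectories
  are independent of batch composition, and latent tables are
  order-invariant (rows sorted by image id).
- **Training-unit convention.** Training length is counted in optimizer
  steps (per-network updates), with checkpoint selection by FID across the
  recorded series.

## Known limitations

- The reduced architecture (2-layer mapping, one modulated conv per
  resolution, no noise inputs, no style mixing, no lazy path-length
  regularization) preserves the Z→W→image contract but not the capacity of
  a full style-based generator; at the micro scale, synthetic AUROC
  saturates near 1.0 and says nothing about real-data AUROC.
- The random-convnet FID embedding ranks checkpoints within a run but its
  absolute values are not comparable to Inception-based FID.
- Discriminator augmentation uses a fixed probability, not the adaptive
  controller of ADA-style training.
- Bootstrap CIs undercover slightly at very small test sizes; the coverage
  property is tested at n=2000 scores.
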