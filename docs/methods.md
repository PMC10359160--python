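# Methods

## Model

The generator is a 3D U-Net: `levels` resolution scales (default 7, as in
the full-fidelity configuration), one 3×3×3 convolution + per-channel
normalization + activation per scale (leaky-ReLU 0.2 in the encoder, ReLU in
the decoder), average-pool downsampling, nearest-neighbor upsampling, and
skip connections by channel concatenation. The output head is a small-init
(σ = 0.01) convolution to 3 channels with no final activation, scaled by a
fixed `velocity_scale_mm` (default 10) so the raw network output is an
unbounded stationary velocity field in millimetres. Patch sides must be
divisible by 2^(levels−1) with at least 2 voxels at the bottom scale.

The raw output is interpreted as a **stationary velocity field** v and
exponentiated by scaling and squaring: u₀ = v/2ⁿ, then n self-compositions
uₖ₊₁(p) = uₖ(p) + uₖ(p + uₖ(p)) with trilinear interpolation (default
n = 7). For smooth velocities of the magnitudes encountered here this
construction keeps det(I + ∇u) > 0 everywhere — the property tests verify
zero folding for random smooth fields up to 25 mm amplitude on the default
grid. Displacements use the pull-back convention: the warped image at p
samples the source at p + u(p), with replicate boundary handling so no air
is injected at the volume edge.

The discriminator is a conditional convolutional encoder on the 2-channel
(source, candidate) pair producing a patchwise logit map; real pairs are
(source, target), fake pairs (source, warped source). The adversarial
objective is the vanilla binary cross-entropy of the conditional GAN
formulation the architecture follows.

### Loss terms and weights

All reconstruction losses are computed on the HU intensity scale, so the
printed soft-contrast window (a = 500, b = 500, c = 3000) applies literally:

* image similarity: mean |warped − target| (HU);
* contrast fidelity: mean |SC(warped) − SC(target)| with
  SC(I) = c/(1+exp(−(I−a)/b)); its slope bound fid ≤ c/(4b) · L1 is
  verified as a property;
* curvature smoothness: mean over interior voxels of Σⱼ‖Δvⱼ‖², with Δ the
  6-neighbor spacing-aware Laplacian. Affine fields are annihilated exactly;
  any discretization scale is absorbed by λ3;
* weights default to λ1 = λ2 = 100, λ3 = 1 — the reconstruction-dominant
  weighting conventional for paired image-to-image adversarial models. With
  these, the adversarial term contributes a small fraction of the gradient
  signal, which matches the intent of deformation recovery with adversarial
  regularization. All three are exposed in `TrainConfig`.

The full objective is differentiated end-to-end through integration and
warping: the trilinear sampler is differentiable with respect to both the
sampled field and the sampling displacement. Because no deep-learning
framework is assumed, `planct.nn` implements a small tape-based reverse-mode
autodiff on numpy arrays with numba-compiled convolution and grid-sampling
kernels; every op is validated against central-difference numerical
gradients to ~1e-6.

Optimization uses Adam (β₁ = 0.5, β₂ = 0.999), one discriminator step and
one generator step per sampled patch, batch size 1 (the practical setting at
volumetric patch sizes; per-channel normalization computed from the current
sample is then identical to batch normalization and deterministic). Training
aborts with a diagnostic state dump if any loss term becomes non-finite.

### Inference

Full-volume synthesis tiles the normalized input with 50%-overlap patches,
blends the predicted velocities with a cosine window (with a small floor so
edge voxels keep nonzero weight), integrates the blended velocity once
globally, and warps the original-intensity input. Output voxels are convex
combinations of input voxels — the synthesized scan cannot hallucinate HU
values, which the tests check voxelwise against the local 8-corner
interpolation hull.

## Preprocessing

Body segmentation thresholds at −300 HU, keeps the largest 3D connected
component, applies a radius-2 morphological closing (erosion with
outside-as-foreground so structures reaching the volume border are not
shaved), and fills holes per axial slice (lungs are interior holes at this
threshold). Couch removal sets everything outside the body mask to
−1000 HU; a geometric couch model can be digitally re-added for downstream
dose calculation. Network inputs are affinely mapped from [−1000, 1000] HU
to [−1, 1].

## Synthetic phantom cohort

Each case renders a body (elliptic cylinder, 40 HU), two lung ellipsoids
(−750 HU) cut below a paraboloid diaphragm dome, a spherical tumor (60 HU,
default 9 mm radius ≈ 3 cc), a bony spine cylinder (700 HU), and a couch
band (200 HU) — curved for the diagnostic state, flat for the planning
state. Geometry is expressed relative to a 240 mm reference field of view
(96³ at 2.5 mm) and scales linearly with grid extent, so 48³ desk-scale
grids contain the same anatomy. Interfaces are softened with a σ = 0.7 voxel
Gaussian to emulate partial volume.

The ground-truth deformation is analytic and C¹: a superior-directed
pull-back offset around the diaphragm dome (Gaussian decay, default peak
15 mm — the planning-state anatomy appears shifted inferiorly, enlarging the
lungs, consistent with breath-hold acquisition) plus a radial contraction of
sampling positions about the body axis (default 3% contour expansion). Both
modes are windowed to zero at the volume border and near the spine axis
(rigid spine). The planning volume and its masks are produced by warping the
clean diagnostic volume with this field; independent Gaussian noise
(σ = 20 HU) is then added to each state, so the pair is never related by an
exact intensity identity. Cohorts jitter body size, lung size, tumor radius
(calibrated so a 15-case default draw has a median GTV volume near 3.1 cc),
diaphragm displacement (10–20 mm) and contour change (2–4%), with per-case
seeds `base_seed + index`.

What the phantom does *not* emulate: airway/vessel trees, cardiac and
respiratory motion phases, metal/beam-hardening artifacts, couch deflection,
and true inter-patient anatomical variability. Passing tests therefore
demonstrate that the pipeline recovers smooth, large-scale setup differences
under controlled conditions — not clinical-grade performance on patient
data.

## Evaluation

RASSD is the RMS HU difference; Dice is 2|X∩Y|/(|X|+|Y|) (both-empty
defined as 1, one-empty as 0); the Hausdorff distance is the exact symmetric
max-min Euclidean distance between surface voxel sets (foreground voxels
with a 6-neighbor background face), spacing-aware, in mm. Body metrics are
restricted to the z-slice interval where both body masks are nonempty;
RASSD for lungs/GTV is averaged over the union of the two structure masks.
Folding is the fraction of interior voxels with det(I + ∇u) ≤ 0, computed by
central differences (one-sided at borders, which are excluded from the
statistic). All three metrics are tested against independent brute-force
oracles.

## Problem sizes and numerical choices

The desk-scale profile used by the test-suite experiments runs 48³ volumes,
5 U-Net levels with base width 4 (capped at 32), a 3-layer discriminator,
5 integration steps inside the training loss (7 at inference), and learning
rates 2e-3 (G) / 2e-4 (D). The parameter-recovery experiment trains on 8
jittered pairs for 30 epochs and evaluates 2 held-out cases; across five
seeded replicates it improves held-out lung Dice in every replicate (mean
0.92 → 0.97) and more than halves the body-masked L1 versus the unwarped
baseline (mean 70 → 33 HU). The 128³/7-level configuration
remains the default `TrainConfig` for full-fidelity use.

Ties and degenerate inputs: identity resampling and zero-displacement
warping are exact (short-circuited); oblique NIfTI affines are rejected
rather than resliced; empty evaluation regions raise rather than return 0;
the linear-velocity integrator closed form (e^a − 1)x is only asserted where
the flow stays inside the domain, since replicate clamping governs
trajectories that exit.

## Limitations

Registration to obtain ground truth for *real* scan pairs is out of scope —
the package consumes externally produced alignments in the same NIfTI DVF
format, and the phantom supplies analytic truth for all tests. Velocities
are stationary (no time-varying integration); inverse fields are not
computed explicitly. The numpy/numba backend targets single-CPU
reproducibility, not large-scale training throughput.
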