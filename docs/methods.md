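# Methods

`multiatlas` implements a classical multi-atlas segmentation pipeline for
small skull-base structures (the motivating target is the foramen ovale, a
few-mm canal used as a puncture target in trigeminal interventions), plus a
synthetic phantom cohort that stands in for clinical CT data. This note
records the models, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Pipeline model

Segmentation of a fixed image F from an atlas set {(Aⱼ, Lⱼ)} of gray
volumes with expert labels proceeds in three steps:

1. **Atlas selection.** Every atlas gray volume is resampled onto F's grid
   (identity alignment, linear interpolation) and scored by normalized
   cross-correlation over the voxels inside both domains,

       NCC = Σ(F−F̄)(A−Ā) / √(Σ(F−F̄)² Σ(A−Ā)²) ∈ [−1, 1].

   The top k = 10 atlases are kept. NCC's invariance to positive linear
   intensity rescaling makes the ranking robust to scanner calibration
   differences. (A commonly reprinted typeset variant of this formula
   multiplies the two centered *sums* in the numerator; that expression is
   identically near zero and not bounded by ±1 — we implement the standard
   product-of-deviations form, which is the quantity the robustness
   argument actually requires.)

2. **Registration.** Each selected atlas is aligned to F by a
   multiresolution affine stage followed by a multiresolution cubic
   B-spline free-form deformation (FFD). The fixed→moving map composes as
   `affine(ffd(x))`, so the FFD's control grid lives on the fixed domain.
   Both stages maximize sampled normalized mutual information (Studholme
   form, (H₁+H₂)/H₁₂) over a fresh random draw of 2000 fixed voxels per
   iteration, binned into a 32×32 joint histogram with per-level min–max
   intensity scaling. Labels are propagated with nearest-neighbor
   interpolation; gray warps default to third-order (cubic B-spline)
   interpolation.

3. **Fusion.** The k propagated labels are combined by one of:
   * **MV** — foreground iff strictly more than half vote foreground; an
     even split is background (conservative for a puncture target).
   * **STAPLE** — binary EM estimating a consensus posterior W and
     per-atlas sensitivity/specificity (p, q); initialization
     p = q = 0.9999, fixed foreground prior π (default: the stack's mean
     foreground fraction), E-step products in log space, p and q clamped
     to [1e−5, 1−1e−5], convergence at mean |ΔW| < 1e−6 or 50 iterations,
     consensus W ≥ 0.5. EM statistics are restricted to the union of atlas
     foregrounds dilated by 10 voxels (Euclidean distance transform):
     with a few-hundred-voxel structure in a 64³ volume, whole-volume
     statistics pin every specificity at ≈1 and erase the rater weighting.
     Configurable (`roi_dilation_vox=None` uses the full volume).
   * **SIMPLE** — start from MV; each round, score every retained atlas by
     Dice against the current estimate, discard those below
     mean − α·std (worst first, never below `min_keep=3`), re-fuse the
     remainder by MV; stop when nothing is discarded or after
     `max_rounds=5`. Default α = 2: only clear outliers are dropped. An
     earlier default of α = 1 discards near-average members of homogeneous
     committees every round, which measurably *hurts* the fused result
     (committee shrinkage); α = 2 keeps benign stacks intact while still
     rejecting gross failures (an inverted atlas is dropped in round 1).
     `alpha=inf` reduces SIMPLE to plain MV exactly.

Evaluation reports Dice overlap, the 95% Hausdorff distance and the
average symmetric surface distance. Surfaces are the foreground voxels
with a 6-connected background (or out-of-bounds) neighbor; distances are
Euclidean between voxel centers in physical mm (no sub-voxel meshing).
HD95 pools both directions' nearest-neighbor distances and takes a single
95th percentile (linear interpolation); a per-direction max-of-percentiles
variant is available via `hd95(..., pooled=False)`. ASD divides the summed
nearest-neighbor distances of both surfaces by the total surface count.
Identical empty masks score Dice 1 (with a warning); an empty prediction
against nonempty truth yields Dice 0 and NaN distances flagged
`empty_prediction` rather than an exception, so batch runs proceed.

## FFD transform

The deformation at a point with per-axis control-cell offset u ∈ [0,1) is
the tensor product over the 4×4×4 surrounding control displacements with
the uniform cubic B-spline weights

    B0 = (1−u)³/6,  B1 = (3u³−6u²+4)/6,  B2 = (−3u³+3u²+3u+1)/6,  B3 = u³/6,

with support indices i = ⌊x/δ⌋ − 1 per axis. The production evaluator runs
scipy's spline interpolation over the control-coefficient grid
(`map_coordinates(order=3, prefilter=False)`), which is algebraically the
same sum; the explicit triple-loop tensor product is kept in the test
suite as the independent oracle (agreement ≲1e−15). Control grids are
constructed with one spare cell beyond each domain face so every domain
point carries full cubic support; evaluation outside the supported region
is a `DomainError`, not extrapolation.

## Optimizer

Both stages use stochastic gradient ascent with the decaying gain
a/(A+t+1)^α (α = 0.602; a = 3, A = 30 for the affine stage, whose
finite-difference gradient is low-noise and tolerates the larger gain;
a = 2, A = 20 for the FFD stage) on a *normalized* gradient direction:

* **Affine (12 parameters).** Central finite differences with step
  0.4 mm, all parameters evaluated on the *same* sample draw per
  iteration. Pairing the ±ε evaluations on common samples cancels the
  sampling noise, so each difference measures the macroscopic metric
  slope. The 9 linear-part parameters are scaled by the fixed-domain
  radius so all 12 share mm units; the rotation center is the image
  center. The 24 perturbed evaluations are batched through one
  interpolation call.
* **FFD (3 × thousands of parameters).** Analytic gradient: the
  moving-intensity axis of the joint histogram uses a linear Parzen
  window, making sampled NMI differentiable in each sample's moving
  value; the chain rule through the moving image's spatial gradient and
  each sample's 64 tensor-product support weights yields the full
  control-grid gradient in one pass (a bincount scatter). Two variance
  controls matter in practice: the spatial gradient is taken on a
  1-voxel-smoothed copy of the moving image (acquisition noise otherwise
  dominates the gradient in flat regions), and a momentum average
  (β = 0.95) accumulates the per-draw gradients — the per-draw analytic
  gradient is unbiased but has sub-unity signal-to-noise.

Each stage runs coarse→fine over a Gaussian pyramid (smooth with
σ = factor/2 voxels, decimate by the factor, default 2; level counts
clamped so no axis drops below 4 voxels). The FFD grid spacing halves per
level down to the configured finest spacing (default 5 mm), each level
seeded by evaluating the previous level's FFD at the new control points.
At the end of every level the optimized parameters are kept only if they
do not score worse than the level's starting parameters under a
fixed-seed, double-size NMI evaluation — a cheap monotonicity safeguard
against late-iteration stochastic drift. With a fixed `rng_seed` the
whole registration is bit-reproducible.

Presets: `paper` (4×1000 affine, 5×3000 FFD iterations, 5 mm grid — the
full clinical-CT parameterization, ~tens of minutes per case) and `desk`
(2×150 affine, 3×200 FFD, 5 mm grid), the default, sized so that a full
20-atlas/10-test phantom benchmark runs in roughly ten minutes on one
CPU core. On the 64³ phantoms the desk preset recovers a known 4/−3/2 mm
translation to ≲0.05 mm, a 5° rotation to within ~0.5°, and removes
≈55–70% of the mean displacement error of random 3 mm FFDs (measured over the bony anatomy, where
intensity actually constrains the deformation; displacements inside
homogeneous regions are not identifiable from intensity and are excluded
from that statistic).

## Phantom

The synthetic cohort emulates the skull-base geometry at small scale: a
64³ volume at 0.5 mm isotropic spacing holds an ellipsoidal bone shell
(radii 12/10/9 mm, 3 mm thick, ≈1400 intensity) over soft tissue (≈40) in
air (≈−1000), pierced by two oblique cylindrical canals (radius 1.5 mm,
±6 mm lateral, tilted 20°) whose removed-bone voxels are the left/right
truth labels (a few hundred voxels each — the clinical structure's scale).
Acquisition is modeled as additive Gaussian noise (σ = 30) followed by
slight Gaussian smoothing (0.4 mm), in that order. Cohort members apply an
independent random FFD (10 mm control grid, i.i.d. uniform ±3 mm — kept
below 0.4× the grid spacing so the warp stays well-behaved) to the
noise-free base, then fresh noise and smoothing; truth labels ride the
same warp (nearest neighbor) and are regenerated under a fresh sub-seed
(logged) in the rare case a warped canal breaks into multiple 6-connected
components. Everything is a pure function of spec + seed.

What the phantom does **not** model: real skull anatomy and its
asymmetries, CT physics (beam hardening, streak artifacts, partial
volume beyond linear interpolation), scanner-dependent intensity curves,
and expert-rater label disagreement. Passing the cohort benchmark
therefore validates the pipeline machinery and the relative behavior of
the fusion methods under controlled misalignment — not clinical accuracy
on patient CT.

## Benchmark design

`run_benchmark` registers each (test case, selected atlas) pair exactly
once and reuses the propagated labels for all three fusion methods, so
MV/STAPLE/SIMPLE are compared on identical inputs; selection and
registration use only gray volumes and are shared between the left and
right structures. On the default seeded cohort the observed ordering is
STAPLE > MV ≈ SIMPLE in mean Dice, with STAPLE also best on HD95 and ASD —
the performance-weighted consensus beats unweighted voting when the
propagated labels vary in quality, and SIMPLE's outlier rejection rarely
triggers on a benign cohort (as intended; it exists to reject gross
registration failures).

## Degenerate inputs and numerical edges

* Constant images: NCC raises a degenerate-input error (zero variance);
  NMI of a constant image returns 1 (zero marginal entropy).
* Metric sampling requires ≥20% of samples inside the moving domain
  during optimization (≥50% for the public `nmi`); below that an
  `OverlapError` is raised rather than optimizing a vacuous histogram.
* Non-finite metric or gradient values abort with an
  `OptimizationError` carrying the level/iteration.
* Label files must be exactly {0, 1}; anything else is a validation
  error listing the offending values — no silent thresholding.
* Geometry is validated everywhere: positive spacing, orthonormal
  direction (|det| = 1 within 1e−6), grid identity checks before any
  voxel-wise comparison.

## Known limitations

* The FFD control grid is axis-aligned in world space; volumes with
  non-identity direction matrices are supported for I/O and resampling,
  but registration quality has only been exercised on axis-aligned data.
* The registration is not diffeomorphic or inverse-consistent; large
  deformations can fold.
* STAPLE here is the binary, spatially-uniform-prior variant; no
  multi-class or locally-weighted fusion.
* Sampled-NMI gradients make the optimizer stochastic; accuracy is
  bounded by the late-iteration gain (~0.05 mm at desk settings), not by
  machine precision.
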