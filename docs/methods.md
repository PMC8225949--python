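# Methods

`osteoadapt` simulates and inversely fits the mechanoregulated adaptation of
cortical bone as observed in longitudinal micro-CT of a loaded long-bone
diaphysis (the in-vivo mouse tibial loading model is the motivating system).
This note records the model, its assumptions, the synthetic data used to
exercise it, and the numerical choices made where the design was open.

## Forward model

One forward step maps a calibrated gray-value volume at time *t* to a pseudo
micro-CT volume at *t* + 2 weeks (one scan interval):

1. **Segmentation.** A global threshold midway between the background and
   bone peaks of the gray-value histogram binarizes the volume. Peaks are
   the two most prominent local maxima of a moving-average-smoothed
   histogram (window 5 bins); unimodal histograms raise an error instructing
   an explicit threshold. Pipelines that evolve an image repeatedly compute
   the threshold once on the baseline and reuse it, because remodeling can
   add a third histogram mode (freshly deposited, fully mineralized tissue)
   that would destabilize re-estimation.
2. **Micro-FE.** Every bone voxel becomes an 8-node hexahedral element
   (edge = voxel spacing, default 10.4 µm) with homogeneous isotropic
   elasticity, E = 14.8 GPa, ν = 0.3. Floating islands are dropped; a mask
   with no connected path between the end slices is an error. Boundary
   conditions emulate axial compression of the diaphysis: the proximal
   slice's nodes are fully constrained, and the distal bone surface is
   kinematically coupled — rotation suppressed — to a reference carrying the
   total load. Three load cases are built in: physiological
   (0.01355·BW N/g superior–inferior plus 0.00289·BW N/g
   posterior–anterior, BW in grams; the medial–lateral component is
   negligible), a nominal 12 N passive axial peak, and their superposition.
3. **Stimulus.** The per-element strain energy density (SED, Pa) is the
   8-point Gauss average of ½ εᵀCε. Bone voxels take their element SED;
   background voxels face-adjacent to the periosteal or endosteal surface
   take the mean SED of their face-adjacent bone neighbors. This one-voxel
   rim is the apposition front: it is how bone can form outside the current
   surface.
4. **Mechanostat.** Tissue mineral density changes linearly with the
   stimulus excess, with no lazy zone:
   ΔTMD = τ_a (U − U_thr) for U ≥ U_thr, −τ_r (U_thr − U) otherwise, in
   mg/cc per 2-week step. TMD is clamped to [0, 1200] mgHA/cc (the
   calibration wedge ceiling; configurable). The update applies to every
   voxel in the stimulus support, not only surface voxels.
5. **Pseudo-CT.** Updated TMD is converted back to gray values through the
   inverse calibration. A voxel whose new gray value crosses the
   segmentation threshold changes bone/background status at the *next*
   step's binarization; no element is removed mid-step.

An optional box-mean smoothing of the stimulus before the law is available
but off by default.

## Inverse problem

The three parameters (τ_a, τ_r, U_thr) are estimated from one scan interval
by matching per-section changes in volumetric second moments. The cropped
length is split into 10 contiguous near-equal sections (1 = distal); for
each section and each direction (medial–lateral, anterior–posterior) the
voxel-volume-weighted second moment about the section's centroidal axis is
computed from the binarized volume, and the objective is

J(θ) = Σ_{s,d} w_{s,d} (ΔI_pred − ΔI_exp)², w_{s,d} = 1/max(ΔI_exp², ε),

with ε = (median |ΔI_exp|)². The floor makes the objective scale-free across
sections while capping the weight of sections whose experimental change is
accidentally tiny; with a much smaller floor those near-zero terms dominate
by orders of magnitude and their single-voxel granularity makes the
landscape effectively un-optimizable. If every experimental change is zero
the raw squared error is used.

**Why not gradient-based SQP.** The predicted moments come from a binarized
volume, so J is piecewise constant: between voxel flips all finite
differences vanish, and below the flip spacing a quasi-Newton step sees a
flat function. The fit therefore uses a deterministic global-then-local
strategy: a seeded Latin-hypercube presample of the bounded box (default
512 points), Nelder–Mead descents from the best points, then "zoom" rounds
that re-sample shrinking boxes (half-widths 0.1 and 0.02 in normalized
coordinates) around the best distinct local solutions. All randomness comes
from the single seed; identical inputs give identical results.

**Cutoff coordinates.** The search runs in (U_thr, log d_a, log d_r) with
d_a = m_a/τ_a and d_r = m_r/τ_r, where m_a and m_r are the TMD margins a
background or bone voxel must gain or lose to cross the segmentation
threshold (estimated from the gray levels on either side of it). A voxel
flips when its stimulus passes U_thr + d_a or U_thr − d_r, so these
coordinates align the staircase structure of J with the search axes; in raw
(rate, threshold) coordinates the minimum lies in a narrow curved valley.

**Identifiability.** For a noiseless two-level image (all bone at one gray
value, all background at another) the binarized moments depend on θ *only*
through the two flip cutoffs — an exact one-parameter degeneracy, so the
rates cannot be recovered no matter the optimizer. Partial mineralization
at the surfaces (present in real scans through partial-volume voxels, and
in phantom experiments after a burn-in of forward steps) breaks the
degeneracy by giving voxels individual flip margins. Even then the rates
are the softer directions; the threshold is the tightly identified
parameter. The fit caches the baseline stimulus map — within one fit the
baseline, load and material are fixed, so the expensive micro-FE stage runs
once and each objective evaluation costs only a mechanostat update and a
morphometry pass (~10 ms on the test phantoms).

A Gauss–Newton linearization at the optimum provides approximate standard
errors; because of the staircase they are order-of-magnitude figures only
and are labeled as such in `summary()`.

## Validation metrics

Surface voxels (union over the two time points, plus voxels whose
bone/background status changed) are classified apposition/resorption/
unchanged by the sign of their TMD change (threshold `min_delta`, default 0;
status transitions override), and tagged periosteal or endosteal. Two
overlap ratios are reported per state and surface: spatial match
(normalized by the predicted count) and prediction accuracy (normalized by
the experimental count). Undefined ratios are NaN, never 0 or 1. Both
whole-bone and per-section values are emitted; section values weighted by
their denominators aggregate exactly to the whole-bone value.

Densitometrics follow standard micro-CT conventions: BV from the bone mask,
TV from a per-slice fill of everything enclosed by the periosteal outline,
BMC = Σ TMD·V_vox, BMD = BMC/TV, per region.

## Synthetic phantoms

The phantom is a hollow elliptical (default circular) cortical tube with a
bimodal gray-value histogram, generated pre-aligned. Voxel membership is
decided by the voxel center (no partial-volume antialiasing), which makes
voxel-count and second-moment oracles exact. The default calibration maps
background TMD 0 → gray 40 and bone TMD 640 mgHA/cc → gray 200, threshold
120. Noise is additive Gaussian in gray values, clamped to
[0, gray(1200)] = [0, 340]; at the default noise levels the background mode
sits ~8σ from the clamp, so the noise is effectively unbiased. All
randomness is reproducible from the stored seed.

Standard geometries:

* **standard tube** — outer radius 14 voxels, inner 8, ≥100 slices. The
  voxelization error of the annulus second moment oscillates with the
  radius in voxels; 14/8 sits at −0.8% from the closed form
  L·(π/4)(R_o⁴−R_i⁴), which keeps the 2% oracle comfortable (12/7, for
  comparison, reaches −2.6%).
* **small tube** — outer 10, inner 6, 60 slices; used for the parameter-
  recovery experiments where many forward solves are needed.

**Scale.** The phantom cross-section (~0.02 mm²) is ~25× smaller than a
mouse tibia's cortical cross-section, so the same loads produce SED values
~60× larger than organ scale, and physically equivalent remodeling rates
are correspondingly smaller. The recovery experiments use ground truth
(τ_a = 0.15, τ_r = 0.2 mg/cc·Pa⁻¹·(2 wk)⁻¹, U_thr = 6000 Pa) under the
physiological load at BW = 22 g, which places the setpoint near the 40th
percentile of the stimulus so remodeling is two-sided, and two burn-in
steps before the fit pair for the identifiability reason above.

What the phantom does **not** emulate: trabecular architecture, growth-plate
geometry, scanner physics (beam hardening, rings), registration error, and
partial-volume blur. Passing tests on phantoms therefore demonstrate the
correctness of the algorithmic chain and the recoverability of parameters
under ideal imaging, not performance on real scans.

## Numerical choices

* **Solver.** Constraints are eliminated exactly (no penalties): fixed
  degrees of freedom are removed and coupled ones condensed onto three
  master translations, so the rigid-coupling contract (identical
  translations on the coupled surface) holds to machine precision. Reduced
  systems ≤ 12 000 unknowns use a sparse direct factorization; larger ones
  a Jacobi-preconditioned conjugate gradient to relative residual 1e-8.
  Typical desk-scale solves: 50k unknowns ≈ 2–4 s, 213k ≈ 40 s on one CPU.
* **Verification BCs.** Two extra boundary-condition variants exist solely
  for closed-form checks: a uniform-traction column (the exact uniaxial
  solution lies in the trilinear space, so displacement and SED match
  F·L/(E·A) and σ²/2E to solver precision) and a free-tip cantilever (mean
  tip deflection vs F·L³/(3EI); at length ≈ 7 diameters shear deformation
  contributes ~2%, within the 5% oracle). The pipeline default remains the
  coupled configuration.
* **Signs and axes.** Arrays are indexed (z, y, x) with slice 0 the most
  distal; the compressive superior–inferior load points from the distal
  coupling toward the constrained proximal end (+z in index space). SED is
  quadratic in the displacements, so no downstream quantity depends on this
  sign choice.
* **Connectivity.** Exterior/medullary background is decided per slice with
  4-connectivity; surface adjacency uses 6-connectivity in 3D. A bone voxel
  adjacent to both exterior and cavity is labeled periosteal
  (deterministic tie-break).
* **Centroid alignment** uses integer-voxel shifts only (rounded), because
  superposition precedes bitwise voxel comparisons that need a common grid.
* **Degenerate inputs.** Empty sections raise by default; inside the fit
  objective they contribute zero moments (no bone, no bending resistance),
  which slopes the objective back toward feasible parameters instead of a
  flat penalty plateau. FE failures inside the objective return a large
  finite penalty so the search survives.
* **Section partition.** Remainder slices go to the most distal sections;
  lengths differ by at most one slice.

## Known limitations

* Rates and threshold trade off strongly when remodeling is one-sided or
  the baseline has no partial-mineralization voxels; only the threshold is
  then meaningfully recoverable.
* Under image noise the staircase objective develops spurious local minima
  that can capture the search for some noise realizations and search seeds:
  on noiseless self-generated pairs the fit reliably reaches the exact
  global minimum, but noisy-data recovery errors scatter by a few percent
  to a few tens of percent depending on the seed, so noise-robustness
  statements should be read per-realization, not as guarantees.
* The per-section moment objective is insensitive to density changes that
  do not move the binarized surface (it "does not optimize TMD changes").
* Single material, linear kinematics, no lazy zone, no poroelastic or
  fluid-flow stimuli; the time step equals the scan interval (2 weeks),
  with optional sub-stepping off by default.
* Rigid registration is out of scope: inputs are assumed pre-aligned up to
  an integer-voxel centroid shift.
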