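# Methods

## Motion estimation

Motion is estimated per sub-cellular patch, not per cell: the annotated
contour's bounding box is tiled with non-overlapping squares of side
`patch_px` (default 13 px = 8.3 µm at 0.64 µm/px), and a patch is kept
iff its center lies inside the contour polygon and its bounds inside the
image. For each retained patch and consecutive frame pair, the integer
displacement maximizing the zero-mean normalized cross-correlation
(Pearson correlation on pixels) between the patch and the equally sized
shifted window in the next frame is taken, over the Euclidean disk
|d| ≤ r with r = ceil(v_max·Δt/(60·px)) (16 px at defaults, from the
120 µm/hr bound). Normalization makes the match invariant to
multiplicative intensity changes; frames are replicate-padded by r so
boundary patches search complete windows.

Numerical choices:

- **Integer displacements only.** The measures are built around
  quantized motion; the 15 µm/hr motile floor (≈ 2 px/frame) exists
  because one-pixel steps quantize the angle too coarsely. Sub-pixel
  refinement would change the estimator class without changing any
  measure materially.
- **Tie-break** among equally correlated displacements: smaller squared
  magnitude first (bias toward "no motion" under ambiguity), then
  smaller velocity angle in [0°, 360°) with (0, 0) first. This total
  order makes the matcher bit-reproducible and lets tests compare it
  against an exhaustive oracle exactly.
- **Quality gates.** A zero-variance (flat) patch, and any match whose
  correlation peak is below 0.5, is recorded as (0, 0) and non-motile.
  The peak-height gate is the standard particle-image-velocimetry
  defense against spurious peaks: a signal-free patch correlated
  against ~800 candidate windows reaches ≈ 0.3 by chance, while a
  genuinely tracking patch sits near 0.9. Gated observations count in
  the motile-fraction denominator, like sub-threshold ones.
- **Angle convention.** Image coordinates are x-right/y-down; velocity
  angles are reported counter-clockwise from +x after flipping y, and
  the conversion happens in exactly one place
  (`motion.displacement_to_velocity`).

## Measures

All measures pool motile (patch, frame-pair) observations with equal
weight ("across all patches over time"); per-frame means enter only the
temporal profiles. Angular alignment folds the velocity-vs-radial
difference into [0°, 90°], so apically and basally directed radial
motion both score 0 and uniform motion averages 45. Direction classes
split at 90° from the outward radial direction, with the boundary
assigned basal (a fixed, measure-zero choice). B/A counts observations,
not tracks. Undefined values (empty subsets, zero apical count) are NaN
in memory and `NA` in CSV. Temporal variance is the sample (n−1)
variance over frame pairs with at least one motile observation; the
trend slope is the least-squares slope against frame index. Rings have
equal width (fitted radius / 5) measured from the fitted circle center;
patches beyond the fitted radius but inside the contour join ring 5.
Radial angles use the manually annotated center, while size and rings
use the fitted circle — both definitions stay intact when the two
centers disagree. Circle fitting is the algebraic (Kåsa) least-squares
fit, closed-form and exact on true circles; degenerate (collinear)
contours are rejected.

## Cohort statistics

Two-sided nonparametric tests throughout: Wilcoxon rank-sum
(Mann-Whitney, exact for small tie-free samples, midranks with tie
correction otherwise) between cohorts, Wilcoxon signed-rank for paired
measures on the same rosettes, Pearson correlation with the t-transform
p-value, ordinary least-squares fits. "Signed distances" to a reference
fit are vertical residuals y − (a·x + b); positive RS residuals mean
less radial organization than the reference group predicts at that
rosette size. No multiple-testing correction is applied.

## Synthetic data generator

The generator produces the statistical structure the analysis assumes,
with full ground truth, so parameter recovery is testable end to end.

**Geometry and texture.** Nuclei are placed by dart-throwing inside the
annulus between the lumen (default 12 px) and the rosette radius
(default 60 px ≈ 77 µm diameter), with an anisotropic exclusion zone —
elongated radially (14 px), tight tangentially (8 px) — matching the
packing of elongated, radially oriented nuclei in a pseudostratified
epithelium; placement saturates, so the realized count can be below
`n_nuclei`. Each nucleus is rendered as a fixed constellation of 18
small Gaussian granules (σ ≈ 0.8–1.6 px, amplitudes 0.4–1.6× the
per-nucleus brightness) placed uniformly in a radially elongated
ellipse (7 × 4.5 px semi-axes). The constellation design is
load-bearing: normalized cross-correlation is brightness-invariant, so
smooth identical blobs are mutually indistinguishable within the 16 px
search radius, and granule clouds tighter than their granule size blur
into exactly such blobs. Frames add independent Gaussian pixel noise
(sd 0.02 against unit-amplitude nuclei).

**Dynamics.** Each nucleus lives on a fixed ray through the center. A
contiguous angular wedge of nuclei (sized to realize `motile_fraction`
to the nearest nucleus) migrates; the rest are static — non-migrating
cells cluster spatially in real cultures, and a contiguous static
domain minimizes the moving/static texture interfaces that patches
cannot resolve. Motile nuclei migrate in phase: an apical leg at
`apical_speed_um_hr` down to a per-cycle excursion amplitude (drawn
uniformly from 10–16 px, with an early turnaround if the innermost
nucleus reaches the center), then a basal return at `basal_speed_um_hr`.
Angular noise is a bounded tangential wobble shared by the cohort, with
the radial step scaled so each step's magnitude equals the configured
speed exactly. Phase coherence freezes the relative geometry in polar
coordinates: nuclei never collide and patch content translates rigidly,
which is the matcher's core assumption — and the two-dimensional
stand-in for the third dimension in which a real epithelium resolves
counter-migrating nuclei. Because the basal return of an excursion is
slower than its apical leg, basally directed observations outnumber
apical ones by v_apical/v_basal (≈ 1.10 at the default speeds) — the
emergent basal-to-apical ratio, consistent with the mild basal excess
and the ≈1.1 apical/basal speed fold seen in rosette recordings. An
`antiphase_fraction` sub-wedge migrating in counter-phase pulls B/A
toward 1; the perturbation presets use it. In `random_motion` mode
(the non-rosette control) every motile nucleus instead takes an
independent uniformly random direction each frame, with sparse
placement and isotropic texture — elongated radial texture would bias
estimated directions along its own axis, and independent wanderers must
be sparse enough not to collide.

**Presets.** `e_rg`/`m_rg` encode the early- and mid-stage cohorts
(motile fractions 0.6/0.3; apical/basal speeds 38.81/35.27 and
30.25/27.12 µm/hr; angular noise 35°/50°). `control` equals `e_rg`;
`blebbistatin_like` keeps speed but degrades organization (60°) and
outward bias (antiphase 0.45); `cytochalasin_like` additionally lowers
motility (0.45) and speed (28/26 µm/hr).

**What the generator does not emulate.** Photobleaching, focus drift,
mitosis and apoptosis, cytoplasmic (as opposed to nuclear) reporter
texture, 3-D stratification and its projection artifacts, and
asynchronous per-cell migration. Passing recovery tests therefore
demonstrates that the pipeline measures what it claims on data obeying
its assumptions — not that those assumptions hold for any particular
recording. Two known degradations are deliberate and realistic: tracking
weakens near the lumen, where radial rays converge (inner rings score
worse, as in real rosettes), and at the motile/static wedge interface.

## Problem sizes and benchmark conditions

Recovery benchmarks run one 75-px-radius rosette (≈ 104 patches) for 50
frames per stage; the random-motion baseline runs 60 frames on the
default geometry (≈ 2900 motile observations). Cohort comparisons use twenty 160-px
movies per group (radii 35–55 px, 25 frames each). Measured behavior at
these sizes: motile fractions read back within ±0.035 of the set
0.6/0.3 across seeds; apical/basal speeds within ≈ +3 to +5 µm/hr of the
configured values (residual inflation from boundary-patch mismatches,
within the 7.68 µm/hr one-pixel quantization step); the random-motion
Radial Score within 45.2 ± 0.7°. The quantization step itself bounds any
speed at `max_speed` + one step (122.9 µm/hr at defaults).

## Known limitations

- Displacements are integers; speeds are multiples of 7.68 µm/hr at the
  default calibration, and per-observation speeds are biased high by a
  few µm/hr where patches straddle texture boundaries.
- The B/A ratio of the wave model is pinned near the speed ratio; it
  cannot exceed it, unlike individual recordings with stronger basal
  excess.
- Annotations are trusted as given; there is no drift correction or
  contour tracking over time (contours are assumed stable across the
  recording).
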