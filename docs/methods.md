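# Methods

`mtasym` measures *directional left-to-right asymmetry* of paired
subcortical structures (hippocampus and amygdala) and tests whether that
asymmetry differs between clinical groups. This note documents the model,
the numerical choices, and what the synthetic validation does and does not
establish.

## Shape asymmetry model

Each participant contributes a left and a right binary segmentation. The
right shape is reflected across the sagittal (left–right) axis so both
hemispheres live in a single shape space; asymmetry then becomes an
ordinary shape difference between two shapes of the same participant.

**Grooming.** Binary masks are antialiased (Gaussian smoothing of the 0/1
indicator; `smoothing_iterations` passes at 0.4 voxel each, implemented as
one pass at 0.4·√n voxels since Gaussians compose), resampled to a common
isotropic grid (default 1.0 mm, trilinear), converted to a signed Euclidean
distance transform (negative inside; sub-voxel refinement of the interface
band from the antialiased values and their gradient), and blurred mildly
(default σ = 0.5 mm) for numerical stability. Masks that are empty,
fragmented, or vanish during grooming are rejected with a logged reason —
the automated stand-in for visual quality control. The antialias width was
chosen so the 0.5-level volume of a 10 mm sphere changes by < 2%.

**Alignment.** All groomed shapes (left and flipped-right, all
participants) are rigidly aligned — rotation and translation only, *no
scaling*, because size asymmetry is signal here; head size is handled
statistically via the TIV covariate instead. Alignment is an iterative
closest-surface Procrustes: each moved surface point is matched to its foot
point on the reference surface, obtained by projecting through the
reference signed-distance field and its gradient (this avoids the
tangential sliding that makes nearest-neighbour ICP under-rotate smooth
shapes), and the pose is re-solved with the Kabsch algorithm. Sweeps stop
when the mean point movement falls below 10⁻³ mm (at most 100 sweeps;
non-convergence yields a warning and the best iterate). A Besl–McKay-style
geometric extrapolation accelerates the linear tail of convergence. On
analytic test shapes the aligner recovers a 5 mm translation to < 0.01 mm
and a 10° rotation to < 0.2°.

**Template and correspondence points.** The template surface is the zero
iso-surface (marching cubes) of the voxel-wise mean of all aligned signed
distance fields. M template points (512 for the hippocampus, 256 for the
smaller amygdala; configurable) are chosen from the template vertices by
greedy farthest-point sampling — deterministic (start at the
lexicographically smallest vertex, ties to the lowest index) and
near-uniform (max nearest-neighbour gap < 3× the mean gap). Outward unit
normals are the normalized positive gradient of the mean field.
Correspondence is by deterministic normal-line projection: template point k
is moved to the zero crossing of the subject's distance field nearest to
the template surface along the template normal (search window ±10 mm,
sampling step 0.25 voxel, linear interpolation of the crossing). Points
with no crossing fall back to the globally nearest surface point and are
counted; a subject with > 5% fallbacks is flagged for QC. This
template-projection scheme replaces entropy-based particle optimization:
it preserves the analysis contract (M corresponded points + per-point
normals, shared across all subjects and sides) while being reproducible
and directly testable.

**Asymmetry.** At each template point k,

  a(k) = (x_left(k) − x_rightflipped(k)) · n(k)   [mm]

with n(k) the outward template normal — positive where the left surface
lies outside the mirrored right surface (left locally larger), negative
where the left is locally smaller. Normals live on the template (one
shared frame), not on individual subjects, so a(k) is comparable across
participants. The volume-asymmetry index is (L − R)/(L + R), dimensionless
in [−1, 1]; volumes are computed from the groomed masks (thresholded
antialiased grids), with raw voxel-count volumes reported alongside.

## Point-wise inference

For each comparison and each point, ordinary least squares relates a(k) to
a group indicator plus covariates: age, sex (0/1), total intracranial
volume, and — when both groups are cognitively impaired — dementia
severity (CDR-global, used as a continuous covariate). A sensitivity mode
appends MRI field strength and voxel volume to every design. Rows with any
missing covariate are excluded; the group coefficient is tested two-sided
with n − p − 1 degrees of freedom. Rank-deficient designs drop collinear
covariate columns with a warning; points with zero residual variance
report p = 1 and are flagged rather than dropped, keeping the family size
fixed. The per-point fit is a vectorized closed-form solve (one matrix
solve per comparison for all M points); it is verified against
`statsmodels.OLS` to 10⁻¹⁰ in the tests.

The six default comparisons are AD_Epi vs AD_NoEpi, nonAD_Epi vs
nonAD_NoEpi, and each of the four impaired groups vs HC. All p-values of
one structure — M points × 6 comparisons, i.e. 3072 (hippocampus) or 1536
(amygdala) tests — are pooled into a *single* Benjamini–Hochberg step-up
correction; significance is q < 0.05, two-sided. Per-comparison pooling is
available behind a flag but non-default. Sign labels follow the standard
rendering convention: `left_larger` (green) for a positive adjusted group
difference in left-minus-right asymmetry, `left_smaller` (purple) for
negative. A one-group mode (covariates centred, intercept tested) measures
the baseline hemispheric asymmetry of healthy controls.

Volume asymmetry is compared with an unadjusted two-sample t-test plus a
covariate-adjusted linear model, mirroring the point-wise designs.

## Matching

Control cohorts are built by 1:k (default k = 5) fixed-ratio *optimal*
propensity matching: a logistic model (IRLS; ridge 10⁻⁴ fallback under
separation) of case status on age/sex(/dementia type) gives propensity
scores; each case is replicated k times and the assignment minimizing the
**total** |logit-propensity| distance is solved exactly as a minimum-cost
bipartite matching, without replacement, no caliper, lexicographic
tie-breaking. Standardized mean differences before/after matching are
reported per covariate. On every instance small enough for exhaustive
search, the assignment cost equals the brute-force minimum.

## Synthetic cohorts

The generator emulates the study conditions without any clinical data:

* **Base shapes.** The hippocampus is a curved ellipsoid (full axes
  40 × 15 × 12 mm, bend 0.4 rad applied as a volume-preserving quadratic
  shear; the long-axis parameter t splits head / body / tail thirds); the
  amygdala is an 18 × 14 × 12 mm ellipsoid with lateral/medial halves.
  Both are voxelized from approximate signed-distance functions on a 1 mm
  grid sized to the structure plus a 4 mm margin.
* **Baseline hemispheric asymmetry**: a uniform 0.1 mm inward offset of
  the left surface, reproducing the normative "left slightly smaller than
  right".
* **Group effects**: localized inward Gaussian displacement (height =
  amplitude in mm, width σ = 4 mm, truncated at 3σ) of one side's surface,
  centred on a named region, applied only to the configured groups.
  Amplitude 0 reproduces the null generator exactly.
* **Noise**: i.i.d. Gaussian surface displacement smoothed at 2 mm and
  rescaled to σ = 0.5 mm by default, added to the implicit function before
  thresholding, so masks stay connected.
* **Covariates**: age ~ N(71, 14²) truncated to [40, 95]; sex female with
  p = 0.556; TIV ~ N(1.4 × 10⁶, (1.2 × 10⁵)²) mm³ with +10% for males (so
  the TIV adjuster has something real to adjust); CDR-global 0 for HC and
  {0.5, 1, 2} with probabilities {0.6, 0.3, 0.1} otherwise; field strength
  {1.5, 3} T; voxel volume {0.8, 1.0, 1.2} mm³. Default group sizes follow
  the emulated study (35/28/183/137/320).
* A fixed seed determines every mask and covariate byte-for-byte.

What the generator does *not* emulate: MRI intensities, partial-volume and
segmentation-boundary noise, anatomically realistic subfield geometry,
scanner site effects, or any coupling between covariates and shape beyond
TIV/sex. Passing tests therefore demonstrate that the pipeline recovers
known geometric ground truth under controlled conditions — not that the
effect sizes are clinically calibrated (no published effect sizes in mm
exist to calibrate against).

## Validation studies and problem sizes

* **Mirror null** (exactness): 40 participants, zero baseline/noise/effect,
  1 mm grid, M = 512. Left masks are exact reflections of right masks, and
  the pipeline returns |a(k)| < 0.25 voxel everywhere (in practice ~10⁻⁶
  mm) and zero significant points.
* **False-discovery control**: 200 replicate null cohorts (n = 20/group,
  noise 0.5 mm, baseline 0.1 mm), hippocampus at 1.25 mm voxels with
  M = 128 — a reduced problem size chosen to keep the replicated study at
  desk scale; FDR control is a property of the statistics, not of the grid
  resolution. Mean false-discovery proportion over the pooled family must
  stay within the BH level plus two Monte-Carlo standard errors.
* **Localization & sign**: a 2 mm left-hippocampal-head effect in one group
  (n = 30/group, noise 0.5 mm, M = 512) must place ≥ 80% of significant
  points in the ground-truth head third with the `left_smaller` sign.
  Because a pooled FDR family tolerates ~5% false discoveries of arbitrary
  sign, the strict all-points sign condition is asserted where the
  ground-truth displacement is material (≥ 0.5 mm).
* **Matching optimality**: 100 random instances (≤ 6 cases, ≤ 12 controls,
  k ∈ {1, 2}) against an exact dynamic-programming enumeration.

## Numerical choices and degenerate inputs

* Signed distances: negative inside, by convention; flipped-sign inputs
  are rejected by the normal-orientation invariant.
* Antialias σ = 0.4 voxel/iteration, 3 iterations; isotropic respacing
  1.0 mm; blur σ = 0.5 mm. These are declared defaults, not values
  inferred from data.
* Correspondence step 0.25 voxel; search radius 10 mm; crossings chosen
  nearest the template surface; ties in farthest-point sampling broken by
  vertex index.
* Alignment surface clouds are subsampled to ≤ 500 points per shape.
* Zero-variance points: p = 1, flagged (conservative; family size fixed).
* Single-voxel or fragmented masks: rejected at grooming with a QC record;
  a participant missing either side is excluded from that structure.
* Propensity models with perfect separation: ridge-penalized IRLS
  (λ = 10⁻⁴) with a logged warning.

## Known limitations

* Template-projection correspondence is first-order: under very large or
  highly non-convex deformations the normal line may cross the subject
  surface at a non-homologous location; the fallback counter and QC flags
  surface such cases.
* Rigid alignment to a reference subject (the first key in sort order)
  rather than to a group-wise optimal frame; the mean-field template is
  built after alignment, so a pathological reference would bias the
  template. Synthetic cohorts share a canonical pose, and real cohorts
  should be roughly pre-oriented (as atlas-space segmentations are).
* The asymmetry statistic sees only left–right differences: bilaterally
  symmetric atrophy is invisible by design.
* Cross-sectional analysis only; no longitudinal or mixed-effects models.
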