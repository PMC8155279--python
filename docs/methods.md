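# Methods

This note documents the models, conventions and numerical choices behind
`pdmci`, and what the synthetic-data generator does and does not emulate.

## Cognitive subtyping

Raw scores are z-transformed against a normative mean/SD per test,
sign-flipped for time and error scores so negative z always means worse
performance.  The failure boundary is the standard-normal 5th-percentile
quantile, taken *inclusively*: z ≤ −1.645 fails.  A domain is impaired
with at least two failed tests, or one failed test when the domain has a
single test.  Verbal episodic memory follows the HVLT-R interpretation
model: an encoding/storage deficit (delayed recall **and** recognition
discrimination failed — the material was never stored) marks the domain
impaired; a retrieval deficit (recall failed, recognition preserved) does
not.  The same −1.645 cutoff is reused for each HVLT-R parameter; where a
normative table is percentile-based rather than mean/SD, callers can pass
the 5th-percentile raw cutoff as `norm_mean` with `norm_sd = 1` after
differencing, or pre-compute z externally.  Subjects with any missing
test are excluded with a warning, never imputed.

The four labels form a 2×2 over the frontal axis (attention/WM or
executive impaired) and the posterior axis (visuospatial, memory or
language impaired): PD-NC (neither), PD-FS (frontal only), PD-PC
(posterior only), PD-MS (both).  The ordinal coding used for feature
selection and correlations is PD-NC = 0, PD-FS = 1, PD-PC = 2, PD-MS = 3,
a severity gradient; it is configurable.

## Permutation inference

All group comparisons on imaging measures use Freedman–Lane permutation:
the response is regressed on the nuisance block (intercept + age, sex,
education, center; sex and center as 0/1 indicators), reduced-model
residuals are permuted and added back to the reduced-model fit, and the
full-model statistic is recomputed.  The statistic is the Pillai trace of
the group effect converted to a pseudo-F; for a univariate response this
is exactly the ANCOVA F.  The choice of multivariate statistic is
immaterial under permutation but is fixed and reported.  p-values use the
(1 + exceedances)/(1 + n_perm) estimator, so p > 0 always; when n! ≤
n_perm (n ≤ 7 at the default 10,000) the full permutation group is
enumerated instead and the estimator is the exact exceedance fraction.
Families of tests that share subjects (vertices of one structure,
segments of one tract/metric) share one permutation schedule.  A constant
response returns statistic 0 and p = 1; a group smaller than the number
of covariates + 1 raises a degenerate-design error.

FDR is Benjamini–Hochberg step-up, applied per family: all vertices of
one structure, all segments of one (tract, metric), all retained texture
features, all pairwise post hocs of one omnibus test, the five cognitive
domains of one correlation row.  No cross-family correction is applied,
mirroring per-structure/per-tract reporting.  The interaction of the two
correction levels is the literal reading: FDR is applied to the
permutation p-values.

Partial Spearman correlations rank-transform both variables *and* the
covariates (average ranks for ties), residualize on the covariates by
least squares and Pearson-correlate the residuals; the p-value uses the
t approximation with n − 2 − k degrees of freedom.  With no covariates
this reduces exactly to ordinary Spearman rho.

## Texture

GLCMs accumulate ordered voxel pairs over all 26 offsets of the 3-D
Chebyshev-1 neighbourhood at distance 1 voxel into a single matrix per
structure (symmetric by construction since opposite offsets are both
included), normalized once at the end.  A pair counts only when both
endpoints are inside the mask; no padding value is invented.  Gray levels
are quantized into 32 equal-width bins between the in-mask min and max
(configurable, reported in output metadata).  Entropy is in bits;
kurtosis is the Pearson standardized fourth moment (normal = 3), chosen
because "lower kurtosis" statements need a stated convention; sum
variance is centered on sum average (modern convention, not Haralick's
original sum-entropy centering).  Feature selection correlates each
(structure, feature) with the ordinal subtype code and retains raw
p < 0.05; retained features then enter the permutation group test with
FDR across the retained set.

## Shape

Meshes are corresponded by contract (same vertex count and triangulation
across subjects; the generator provides this by construction).  Size is
removed by scaling each subject about its centroid with the **cube root**
of (reference ICV / subject ICV) — volumes scale with length cubed; a
linear mode is available.  Alignment is rigid generalized Procrustes
(rotation + translation, no scaling step, since size is handled by ICV):
template initialized from the first subject, alternating rigid fits
(Kabsch, with reflection guard) and template re-averaging until the
template moves < 10⁻⁶ mm RMS or 100 iterations; the result is invariant
(as a shape) to rigid pre-transforms of any subject.  The vertex-wise
test uses the 3-D coordinate triple by default; a scalar
normal-projection response is available.  Deformation fields point from
the second group's mean to the first group's mean, signed against the
outward normal of the overall mean mesh.

A caveat documented here because it is visible in simulations: a strictly
local group difference leaks slightly into all vertices after rigid
alignment (the rotations/translations partially compensate the local
displacement — about 0.14 mm of whole-mesh shift per 1 mm of displacement
on a 100-of-1002-vertex patch).  This is inherent to alignment-based
shape analysis, not an implementation artifact; with the default
generator noise it stays below detectability while planted patches are
recovered at ≥ 80% precision.

## Tractometry

Profiles resample every streamline to S equidistant arc-length nodes
(default: one node per millimeter of bundle-core length when streamlines
are given; fixed S = 100 for synthetic profiles so subjects are
comparable), sample the scalar map by trilinear interpolation, and
average across streamlines with Gaussian weights in the distance to the
core node, bandwidth equal to the node-wise RMS streamline spread.
Out-of-map nodes are masked; a node with no valid contribution
invalidates the subject for that tract rather than being interpolated.
Segment-wise inference is univariate per metric; only runs of ≥ 5
consecutive FDR-significant segments are reported, and post hocs compare
subject-level means over a cluster's segments.  Profile orientation is a
per-tract convention recorded with the data; profiles must be flipped to
convention before group analysis.

## Synthetic data generator

`gen_cohort` inverts the subtyping rules: it draws an impairment pattern
per subject (Bernoulli per domain with per-subtype marginal
probabilities, resampled until consistent with the planted subtype), then
draws test z-scores from truncated normals — failed: N(−2.2, 0.3)
truncated ≤ −1.65; passed: N(0, 0.8) truncated > −1.64 — so the
classification rule fires exactly as planted with no boundary flakiness,
and back-transforms to raw scores through the normative table.  Default
composition is 41/16/25/32 (PD-NC/FS/PC/MS); the default marginals encode
the reported impairment frequencies (executive 94% of PD-FS, visuospatial
68% of PD-PC, executive and visuospatial co-impaired in ~78% of PD-MS,
encoding/storage deficits in ~32% of the posterior groups).  Only the
marginals are constrained; the joint pattern (independent draws plus a
consistency resample) is a documented choice.  Ten percent of
memory-unimpaired subjects receive a retrieval deficit and 12% of
unimpaired multi-test domains a single stray failure, for realism without
affecting labels.  Covariates follow per-group demographics (age ≈ 63–67
± 8 y, male fraction 0.53–0.94, education 10–15 ± 3 y, two-center mix).

Meshes are ellipsoids (12 × 8 × 6 mm radii) sampled on a frequency-10
geodesic icosphere (10·f² + 2 = 1002 vertices) — correspondence by
construction, standing in for a spherical-harmonic parameterization
without reimplementing it.  Each subject adds a smooth random field
(vertex noise passed through 3 neighbor-averaging rounds, SD 0.3 mm per
coordinate), scales with the cube root of a lognormal ICV (mean 1.5×10⁶
mm³, σ = 0.08) and receives a random rigid transform (≤ 10°, ≤ 5 mm)
that the pipeline must undo.  Three averaging rounds keep the field's
correlation length short: with much smoother fields, chance group-level
blobs become large enough for the BH cascade to drag them past the
threshold once a true patch is present, which would spoil localization —
a generator design constraint, not a tuning of the test.

Texture volumes are smoothed Gaussian fields (σ = 1.2 voxels) inside an
ellipsoid mask with subject-level intensity offset/scale jitter; a
planted kurtosis reduction blends the marginal toward a light-tailed
uniform through the rank-preserving map y = (1−w)z + w√12(Φ(z)−½),
preserving mean and SD exactly (blend 0.5 lowers Pearson kurtosis from
≈ 3.0 to ≈ 2.2, about 3.5 between-subject SDs).  Because this changes the
whole marginal, co-dependent GLCM features of the same structure
(entropy, variance, IDM…) shift too; specificity of recovery is
therefore asserted at the structure level.

Tract profiles are a smooth population baseline (FA ≈ 0.4–0.5, MD ≈
7×10⁻⁴ mm²/s) plus a subject offset (0.4 × within-SD), three random
low-frequency harmonics (≈ 0.33 ×) and independent segment noise
(0.67 ×); FA is clipped to [0, 1].  Segment noise dominates by design: an
offset-dominated decomposition makes all segments' p-values nearly
perfectly dependent, so whole-profile chance differences masquerade as
long significant runs and the replicate-wise false-cluster rate exceeds
the nominal level the generator is contracted to meet.  Planted effects
shift affected groups by `size` × within-SD over a segment interval (FA
down, MD up); the documented default is 1.5 SD over 15 segments.

What the generator does **not** emulate: MRI physics (bias fields,
partial volume, scanner noise spectra), segmentation error, true
anatomical shape variability, crossing-fiber effects on FA, or the
unknown real effect sizes.  Passing recovery tests therefore demonstrates
the statistical machinery's correctness and power at the documented
synthetic conditions, not clinical sensitivity.

## Problem sizes and defaults

Defaults follow the study conditions: n_perm = 10,000 (exhaustive below
that when possible), FDR α = 0.05, cluster rule ≥ 5, z-cutoff −1.645,
32 gray levels, 1002 vertices, S = 100 segments, cohort 114.  The test
suite runs the heavier simulations at reduced permutation counts
(300–500) and 20–50 replicates — sizes chosen so the binomial tolerance
of each calibration/recovery claim is respected; every such size is
stated in the test that uses it.

## Known limitations

- The subtyping boundary inclusion (z exactly −1.645 counts as failed)
  and the HVLT-R thresholds reuse of the −1.645 cutoff are documented
  operationalizations; alternative conventions change labels only for
  boundary cases.
- Rigid-GPA leakage (above) slightly delocalizes strictly local effects.
- The pipeline never imputes: subjects missing a modality are dropped
  from that modality's analysis only.
- `pingouin`/`statsmodels` offer partial correlations and MANOVA; they
  are used as cross-checks in the test suite where applicable, while the
  permutation machinery here is purpose-built (they do not provide
  Freedman–Lane MANCOVA with shared schedules).
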