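# Methods

This note records the models, numerical choices and deliberate simplifications
behind the package, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the phantom-based tests do and do not
demonstrate about real data.

## Geometry and voxelization dialect

Streamlines are handled in world millimetres throughout (TCK convention; TRK
voxel-space offsets are converted on read). A voxel grid is an array shape
plus an invertible index→world affine; a world point belongs to the voxel its
continuous index rounds to (nearest-centre rule, half-open bounds, 0-based
indices).

A bundle's voxel set is computed by **point membership after mandatory
resampling** to a step of half the smallest voxel dimension: a voxel counts
as traversed when it contains at least one resampled point. This matches
common tractometry practice and is directly checkable against an exhaustive
per-point enumeration oracle, at the cost of occasionally missing voxels a
segment merely grazes. The tests document the behaviour: from half-voxel
steps on, further refinement only *adds* grazing voxels (set containment)
and the additions stay within a few percent of the set. Exact ray–voxel
traversal could be added later as an alternative dialect; the provenance
JSON records which dialect produced a table.

Lesion–tract "intersection" is defined on the voxel lattice of the lesion
mask, not on continuous geometry, because lesions arrive as voxel masks.
The lesion-load denominator is the brain-mask voxel volume (the most direct
reading of "normalized by head size"); an externally estimated intracranial
volume can be substituted by supplying it as the brain mask.

A streamline is *lesioned* when at least one of its resampled points maps to
a lesion voxel. Lesionometry is reported in two sampling modes, because the
natural definitions differ and both are defensible: `portion` averages only
the points lying inside lesion voxels, `full` averages the entire length of
every lesioned streamline. Both are always computed; no mode is declared
canonical. When a subject has no lesioned streamline in a bundle the value
is missing (NaN) and stays missing through the statistics — it is never
imputed as 0, which would conflate "no lesion" with "zero microstructure".

## Microstructure models

**Diffusion tensor.** Fitted per voxel to the low b-value shell (plus b = 0)
by iteratively weighted least squares on the log-signal: an ordinary
log-linear fit initializes the seven coefficients (ln S0 and the six tensor
elements), then each pass reweights with the squared predicted signal — the
first-order variance model for log-transformed data. Defaults: 2 reweighting
passes, convergence tolerance 1e-10 on the largest coefficient change.
Non-positive signals are clamped to 1e-10 and the voxel is flagged in a QC
mask rather than silently fitted. Scalars follow the standard eigenvalue
formulas (MD, RD, FA with FA := 0 for an all-zero tensor); eigenvalues are
reported in non-increasing order and negative ones are flagged, not clipped.

**Spherical harmonics.** A real, even-order, orthonormal basis (flagged
`descoteaux07`; m<0 ↦ √2·Im Y, m=0 ↦ Re Y, m>0 ↦ √2·Re Y with Condon–
Shortley phase) fitted by least squares; the fit refuses under-determined
systems. RISHℓ = Σₘ c²ₗₘ is invariant to rotations of the gradient frame and
to the choice among orthonormal real conventions, which the tests verify to
1e-6 relative. AFD is the fODF's integral over the sphere, c₀₀√(4π);
constrained spherical deconvolution itself is out of scope — fODF
coefficients are consumed from files or generated by the phantom. Whether an
upstream tool's "total AFD" uses a different normalization constant must be
checked against its basis convention; the convention identifier is carried
on every coefficient map for this purpose.

**NuFO.** fODF peaks are local maxima on a subdivided-icosahedron
tessellation (642 vertices, ≥ the 362 the sampling argument requires),
thresholded at 0.1 of the voxel's maximum amplitude, greedily merged within
25° and with antipodes counted once. Threshold and separation have no
canonical published values; both are exposed as arguments. The tessellation
search cannot resolve crossings below roughly the vertex spacing (~8°),
which is far below the separation default.

## The phantom

The phantom exists to make every downstream number checkable, not to look
like a brain. One subject is an isotropic grid (default 40³ voxels at 2 mm,
matching a typical 2 mm acquisition), straight-tube bundles of 2000
streamlines each (the streamline count used per segmented bundle in the kind
of study this package supports), ellipsoidal lesions, and per-voxel metric
maps that are constant at tissue baselines outside lesions and multiplied by
fixed factors inside (FA ×0.6, AFD ×0.55, RISH0 ×0.7, RISH2 ×0.5, NuFO ×0.8
down; MD ×1.6, RD ×1.8 up — the direction of demyelination-like damage).
Optional Gaussian map noise has sd proportional to each metric's baseline so
that metrics spanning four orders of magnitude are perturbed comparably.

Bundle streamlines are the resampled centerline translated by a constant
lateral offset drawn from an isotropic Gaussian (sd = dispersion, default
1 mm) in the perpendicular plane, clipped to the tube radius. Zero dispersion
therefore collapses the bundle onto its centerline exactly, and all points
provably lie within the tube — properties the geometric oracles rely on.
DWI signals follow a single-tensor forward model (S = S0·exp(−b gᵀDg),
cylindrically symmetric about the local tangent inside bundles, isotropic
outside) with Rician noise as the magnitude of complex Gaussian noise and a
plain-Gaussian option for analytic checks.

Cohorts are two groups (defaults 24 impaired / 16 unimpaired, IQ ~ N(110,
11²), education ~ N(14, 3²)) with cognitive scores linearly coupled to one
named measure plus covariate terms and Gaussian residuals. Every generator
is a pure function of (spec, seed), with one RNG stream per subject derived
from (seed, subject index) so cohorts are reproducible under any generation
order. Ellipsoidal lesions are a tractable stand-in, not a claim about
lesion morphology; likewise straight tubes ignore crossing-fibre anatomy,
curvature and partial-volume effects. Passing tests therefore demonstrate
correctness of the measures' *semantics* and the statistics' *calibration*,
not robustness to real segmentation or registration error.

## Factors

Per bundle, the seven metric means are reduced on complete-case rows by PCA
of the correlation matrix. Components are retained at eigenvalue > 1;
loadings (eigenvector × √eigenvalue) below 0.3 absolute are suppressed for
reporting only — scores always use the full first eigenvector. Scores are
standardized to mean 0, sd 1 (ddof = 1) and oriented so RISH0 loads
positively ("higher = healthier"); when RISH0 is absent the largest loading
is made positive. Adequacy is checked with KMO (flagged below 0.7) and
Bartlett's sphericity test; failures, singular correlation matrices and a
second retained component are recorded as warnings on the model rather than
errors, since a phantom or small pilot can legitimately trip them. No
rotation is applied and only component 1 is scored.

## Statistics

**Bayesian correlation screening.** The Bayes factor integrates the exact
sampling density of the Pearson r (Hotelling's hypergeometric form) against
a stretched-beta prior on ρ with scale 1 — i.e. uniform on (−1, 1) — and is
reported in the null-over-alternative orientation (values < 1 favour the
alternative; the default inclusion threshold is 0.2). Different software
ships different default priors, so BF values are comparable across packages
only up to prior choice; the prior scale is an argument, and the tests pin
this implementation against an independent exact implementation (pingouin)
to 1e-6 relative. No multiple-testing correction is applied beyond the BF
screen, and the report says so explicitly.

**ANCOVA.** Linear model with group dummies and covariates; each term's F is
a full-versus-reduced comparison (Type-III style, appropriate for unbalanced
groups), partial η² = SS_effect/(SS_effect + SS_error), and the model's R²
is reported as its partial η². Homogeneity of regression slopes is checked
by refitting with a group × focal-covariate interaction. Levene's test
(centre = mean) on the dependent variable by group and the maximum absolute
pairwise covariate correlation (flagged at 0.8) accompany every model.
Constant covariates are dropped with a warning, which reduces the model to
a one-way ANOVA exactly. All models are complete-case per analysis, with the
missing count reported.

**Group tests** compute both pooled and Welch t; the reported variant is
chosen by Levene's test at α = 0.05. Effect sizes are Cohen's d (pooled sd)
and Hedges' g = d·(1 − 3/(4N − 9)).

**Power.** The t-test sample size inverts the noncentral-t power function
(ncp = d√(n/2), df = 2n − 2) over integer n; the correlation sample size
inverts the power of the ρ = 0 test computed from the exact distribution of
r (critical value from the null t-transform), with a Fisher-z approximation
available for comparison. Both routines are inverse-consistent (power(n) ≥
target > power(n − 1)) and Monte-Carlo-verified at 10⁵ replicates in the
acceptance script.

**Screening pipeline.** Per task: a baseline ANCOVA (group + IQ + education)
establishes the group effect; every measure is screened by Bayesian
correlation on pairwise-complete data; survivors are added one at a time as
the focal covariate. A survivor is a *unique predictor* when its term is
significant, and *attenuates* the group difference when a significant
baseline group effect loses significance once the measure is included. Tasks
with no survivor are reported as "no further analyses".

## Problem sizes and determinism

The default phantom (40³ grid, 2000 streamlines per bundle) runs a full
subject in about a second; the test suite uses 14³–40³ grids and 30–2000
streamlines, chosen so each oracle comparison stays exhaustive. The
end-to-end cohort controls run 100 seeds of the 40-subject screening stage.
Every random draw flows from explicit seeds; the pipeline writes identical
report bytes across reruns of the same config.

## Known limitations

- Point-membership voxelization slightly undercounts grazed voxels relative
  to exact traversal (documented dialect, see above).
- The screening BF is prior-dependent; only its orientation, monotonicity
  and exact-density construction are guaranteed, not agreement with any
  particular closed-source default.
- Bundle segmentation, lesion delineation, registration, denoising and CSD
  are all upstream: the package consumes their outputs and checks geometric
  consistency (hard error on affine mismatch) but cannot detect upstream
  misregistration.
- The phantom's group contrast enters only through lesion burden; real
  cohorts have correlated covariates, heteroscedastic scores and
  non-ellipsoidal lesions.
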