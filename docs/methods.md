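# Methods

`subgrowth` implements the statistical machinery used to chart longitudinal
growth of infant subcortical structures over the first 27 postnatal months
(ages 0–810 days; 1 month = 30 days throughout): penalized-spline mixed-model
growth trajectories and their derivatives, stratified-bootstrap inference on
interval growth rates, vertex-wise surface-area expansion maps with
high-/low-growth region detection, and mixed-model associations between
morphometry and behavioral scores. Because the motivating data are
access-controlled, the package ships a synthetic cohort generator with known
ground truth; every downstream stage is validated by parameter recovery
against that truth.

## Growth-trajectory model

For subject *i* with scans at ages *t* (days), a structure volume (or a
vertex's local surface area) *y<sub>i</sub>(t)* is modelled as

    y_i(t) = s_i + b * T_i(t) + f(t) + D(t) * g_i + a_i + e_i(t)

with site fixed effects *s<sub>i</sub>* (first level as reference), a scalar
coefficient *b* on the per-scan intracranial volume *T<sub>i</sub>(t)*, a
penalized cubic-spline age smooth *f(t)*, an optional sex-specific smooth
deviation *D(t)·g<sub>i</sub>* plus a sex main effect (male indicator
*g<sub>i</sub>*), a subject random intercept
*a<sub>i</sub> ~ N(0, σ<sub>a</sub>²)* and iid Gaussian noise. The no-sex
variant drops *D(t)* and the sex main effect; it is the model used per
vertex.

**Basis and penalty.** Smooths use cubic B-splines with interior knots at
quantiles of the observed ages (basis dimension K = 10 for *f*, 5 for *D* by
default; both configurable). The curvature penalty is the sum of squared
*second divided differences* of the coefficients at the Greville abscissae.
With unequal knot spacing the divided-difference form (rather than plain
index differences) is what makes the penalty null space exactly the
functions {1, t}, so the heavy-smoothing limit of the fit is the straight
line through the data — a property several tests rely on. Each smooth
carries a sum-to-zero constraint (QR reparametrization) for identifiability
against the intercept, and is then rotated to the natural parametrization:
null-space columns become unpenalized fixed effects, range-space columns
carry an identity penalty with one smoothing parameter per smooth.

**Estimation.** The Gaussian likelihood is handled exactly (no Laplace
approximation is needed): for fixed smoothing parameters λ and variance
ratio r = σ²/σ<sub>a</sub>², the spline coefficients and fixed effects solve
a penalized least-squares system, and σ² is profiled in closed form. λ and r
are chosen by maximizing the profiled marginal likelihood (ML, following the
convention of selecting smoothness by marginal likelihood; REML is a flag —
the parameter-recovery analyses use REML for the variance components, since
ML shows the expected O(p/n) downward bias in σ<sub>a</sub>²). All
quantities are computed from per-subject sufficient statistics
(W<sub>s</sub>'W<sub>s</sub>, W<sub>s</sub>'1, W<sub>s</sub>'y, …), which
makes one criterion evaluation O(S·q²) for S subjects and q coefficients,
and makes a subject-bootstrap refit a weighted re-sum of the same
statistics.

The optimizer is L-BFGS-B on (log λ, log r) with three dispersed restarts,
a Nelder–Mead polish, and a projected-gradient convergence check so that
boundary optima (λ → 0 for interpolating data, λ → ∞ for linear truth,
r → ∞ for no subject effect) are accepted as converged. A numerically
perfect fit (zero-noise data) is detected by the penalized residual sum of
squares falling below 10⁻¹² of the response's scale.

**Population curves.** Predictions average the site effects with the
observed site frequencies, set the ICV covariate to the cohort mean
ICV-versus-age curve, and are reported per sex or pooled (sexes mixed at
the observed male fraction). The ICV reference curve is fitted with the
model's own spline basis, subject random intercepts, and a *tiny fixed
ridge* instead of selected smoothing: the ICV age trend is strong, so the
basis is fully identified, and avoiding smoothing selection keeps the
reference free of shrinkage bias and makes its bootstrap (below) exact at
fixed penalty. An earlier design — binned ICV means with linear
interpolation — was abandoned: the end-segment slopes between sparse noisy
bins explode when extended to the span edges, and interpolation kinks break
the analytic-derivative/finite-difference agreement.

Derivatives are analytic (basis-derivative times coefficients, times 30
days/month); confidence bands are ±1.96 pointwise SE from the coefficient
covariance σ²(C'C + P)⁻¹; birth-normalized curves Y(t)/Y(0) get a delta-
method band. The standard reporting grid is monthly ages {0, …, 24} months
(the fitting span remains 0–810 days).

## Interval growth rates and the stratified bootstrap

The population growth rate over an interval is [Y(t₂) − Y(t₁)]/Y(t₁) on the
fitted curve, over the nine reporting intervals 0–3, 3–6, 6–9, 9–12, 12–18,
18–24, 0–6, 0–12 and 0–24 months. Uncertainty comes from a stratified
bootstrap for longitudinal data: whole subjects are resampled with
replacement — all scans of a drawn subject move together — within strata
that preserve the design margins. The default stratification is site ×
number-of-scans category {1, 2, 3+} (configurable); the exact stratification
of the original analysis is not documented, and this choice preserves both
margins the design controls. Each replicate is refit with the point
estimate's smoothing parameters and variance ratio held fixed (a
`refit_lambda` flag re-optimizes them per replicate; slower and closer to
full uncertainty), and — importantly — the ICV reference curve is itself
re-estimated from the resampled subjects, because a substantial share of
the population curve flows through the ICV coefficient. Pooled replicate
curves mix the sexes at each replicate's own male fraction.

Significance per table cell uses Z = |Y(t₂) − Y(t₁)| / SD[Y(t₂) − Y(t₁)]
with the moment (not percentile) bootstrap SD, two-sided normal p-values,
and Bonferroni correction over all cells of the table (structures ×
hemispheres... × sexes × intervals as assembled).

**Calibration caveat.** Under a flat-growth null the Z-test is well
calibrated for the five interior intervals (empirical type-I ≈ 0.03–0.07 at
α = 0.05) but anti-conservative (~0.14) for intervals anchored at 0 months:
the day-0 prediction sits at the span boundary where scans are sparse, so
its leverage is extreme, the bootstrap SD estimate is noisy, and
smoothing-parameter selection couples to the estimate. Growth claims for
birth-anchored intervals should therefore be read with caution; the
calibration analyses in the test suite evaluate the interior intervals.

Pointwise sex differences are tested the same way (bootstrap Z on the
male-minus-female fitted difference at each grid age). The asymmetry index
is AI(t) = (L − R)/((L + R)/2), positive leftward.

## Vertex-wise surface expansion

Inputs are per-scan triangle meshes with vertex-to-vertex correspondence
(identical triangle lists). The local area of a vertex is one third of the
area of each incident triangle (barycentric allocation), so vertex areas sum
exactly to the mesh area. Each vertex's local-area series is fitted with the
no-sex model (shared basis and design across vertices; smoothing parameter
and variance ratio selected per vertex), and the monthly relative expansion
rate is (dA/dt)/A(t) per month, evaluated on the monthly grid.

High-/low-growth regions at a month: candidates are the top and bottom 20%
of vertices by point rate (stable tie-break by vertex index; exactly
⌈qV⌉ per side for distinct rates). Each candidate is tested against the
cross-vertex *median* of point rates (recomputed per month) with
t = (rate − median)/SD_boot, where SD_boot is the bootstrap SD of that
vertex's rate and the reference distribution is t with B − 1 degrees of
freedom; Benjamini–Hochberg FDR runs across the tested vertices of the
structure at that month. The bootstrap SD already estimates the sampling SD
of the point rate, so it is *not* divided by √B — doing so (as a literal
one-sample t-test on the replicates would) inflates |t| by ~√B and destroys
the FDR control that the uniform-growth null simulations verify. Vertices
whose fit fails are masked out of all maps and tests.

## Behavior associations

Each association is a random-intercept linear mixed model

    score ~ age + sex + site + income + edu + ICV + predictor + (1 | subject)

fit by REML, with every covariate and the predictor standardized to zero
mean and unit variance; the predictor is the log volume-to-ICV ratio of a
structure or the local area of one vertex. Significance uses Satterthwaite's
approximation: df = 2φ²/Var(φ̂) with φ = Var(β̂) as a function of the two
variance components, the gradient and the REML observed information
evaluated numerically on the log-variance scale. (The implementation
reproduces `lmerTest` to all printed digits on shared data.) When the
random-intercept variance collapses to the boundary the model falls back to
OLS with df = n − p, which also covers the no-repeats design exactly.
Benjamini–Hochberg FDR is applied within each score across the six
structures by default (pooling all 36 cells is a flag). All 36
structure × score cells are fitted. The Model-6-style vertex analysis
includes the by-subject random intercept by default, with
`random_intercept=False` available for the fixed-effects-only form.
Confirmed structures are re-tested jointly with a Wald F-test of the added
log ratios against the covariates-only null (ML fits, F(q, n − p)
reference). Behavioral visits in separate tables are joined to scans by
nearest age within a 45-day window (configurable).

Note on scales: the generator plants behavior effects per SD of the
*age-adjusted* log ratio (scores are age-normed, so an effect on the raw
ratio's developmental trend would be absorbed by the age covariate). The
fitted standardized coefficient is per SD of the *raw* ratio and is
therefore larger than the planted value by the ratio of raw to age-adjusted
predictor SD; recovery is assessed by detection and sign, and the dedicated
recovery simulations plant effects directly on the model's predictor.

## Synthetic cohort: what it emulates, and what it does not

Defaults mirror the emulated study design: 231 subjects, two sites (50/50),
sexes at 54.5% female, scans-per-subject distribution {1: 0.55, 2: 0.33,
3: 0.08, 4: 0.04} (45% with ≥2 scans, 12% with ≥3), ages 0–810 days drawn
from a mixture with a neonatal component (15% uniform over the first 90
days), a dense 3–15-month component (60% triangular with mode at 9 months)
and a full-span uniform component (25%).

Growth truth per hemisphere: log-saturating curves V(t) = a + b·log(1 + t/c)
for thalamus, caudate, putamen, pallidum and hippocampus — birth volumes and
0–24-month growth fractions chosen to match the reported qualitative
pattern (pallidum fastest early, thalamus plateauing, caudate/putamen
roughly doubling) — and a linear curve for the amygdala. Males accrue a
structure-specific fractional surplus of the growth (largest for thalamus,
putamen, pallidum, hippocampus); sites differ by ±1% of the birth volume;
ICV grows log-saturatingly from 450 to ~1100 cm³ with a 4.5% between-subject
scale factor, and each structure co-grows with the subject's ICV deviation
(κ = 0.5·V₀/ICV₀). Residual noise SD and subject-intercept SD both default
to 60 mm³ — deliberately comparable scales, calibrated once at design time
by pilot Monte-Carlo so that population-curve recovery error is dominated
by noise rather than unmodelled heterogeneity, and frozen.

Meshes are mildly ellipsoidal icospheres whose per-vertex radial scale
follows the structure's area growth (V(t)/V(0))^(2/3), with planted
high-growth (2×) and low-growth (0.3×) angular caps of 10% of vertices
each. The planted multiplier is tapered smoothly (cosine ramp over about
two edge lengths) at the cap rims: an abrupt rim creates "cliff" triangles
whose increasing tilt — not growth — dominates their area change and leaks
spuriously high rates into the rim's neighborhood on *both* caps. The truth
patch is recorded as the vertices at half boost or more.

Behavior scores are Mullen-style standardized scores (mean ≈ 50): household
covariates, planted structure effects (thalamus→RL +3.5, thalamus→EL +3.0,
caudate→FM +2.0, putamen→FM +2.2 score units per SD of age-adjusted
ratio), a subject intercept (SD 3) and noise (SD 5); ELC is the mean of FM,
VR, RL and EL, so planted effects induce real ELC associations, and the
shared ICV denominator correlates the log ratios across structures —
marginal association tables are expected to show such indirect cells.

Not emulated: anatomy (shapes are deformed spheres), the real study's visit
schedule, realistic between-subject variance (real subcortical volumes vary
far more between subjects than the 60 mm³ intercept), missing data,
age-dependent measurement noise, and site-specific covariance. Passing
recovery tests therefore demonstrates correctness of the estimators and
calibration of the inference under the stated conditions, not robustness to
every feature of real infant MRI data.

## Problem sizes used in validation

The test suite and the acceptance script size their simulations to run on a
single CPU in minutes, as the package's own validation budget: 200 cohorts
of 150 subjects for parameter recovery; 200 flat-truth cohorts of 200
subjects with B = 200 bootstrap replicates for calibration (the study-scale
analysis default is B = 1000); one 642-vertex mesh cohort (~150 scans) for
patch recovery plus 100 42-vertex cohorts for FDR control; 300 null and 60
effect simulations for the association machinery. The acceptance script
runs the full pipeline at the default study size (231 subjects, 162-vertex
meshes, B = 500).

## Known limitations

* Birth-anchored growth intervals are anti-conservative (see above).
* Bootstrap replicates reuse the point estimate's smoothing parameters by
  default; `refit_lambda` narrows but does not remove the resulting slight
  undercoverage at span edges.
* The per-vertex tests treat the cross-vertex median as fixed; with very
  few vertices its sampling noise is ignored.
* Site enters additively only (no site × age interaction), and residuals
  are assumed uncorrelated within subject beyond the random intercept.
* No growth-peak estimation or extrapolation beyond the fitted span.
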