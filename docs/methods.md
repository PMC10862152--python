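# Methods

## The scientific question and its formalisation

Let V₁…V₁₀ be the volumes of the ten lower-leg muscle groups of one
child. Growth is *synchronous* (isometric) if every muscle keeps a
constant share of the total: over any growth interval all muscles
experience the same relative volume increase. On the log scale this
means all pairwise scaling exponents are 1: for any pair (j, k) the
points (log Vⱼ, log Vₖ) scatter around a line of slope 1, and the
leading principal axis of the 10-dimensional log-volume covariance Σ
points along c = (1, …, 1)/√10.

Both log-volumes of a pair carry biological and measurement variation,
so the pairwise line is fitted as a model II **major axis** — the first
principal axis of the 2×2 covariance — rather than by ordinary
regression of one muscle on the other:

    b = (s_y² − s_x² + √((s_y² − s_x²)² + 4 s_xy²)) / (2 s_xy).

All slopes, tests and p-values are invariant to the base of the
logarithm and to multiplying raw volumes by positive constants; both
invariances are property-tested.

## Inference

**Pairwise slope test and CI.** For a hypothesised slope b₀ the data
are rotated to the hypothesised axis orientation: u = y − b₀x,
v = x + b₀y. Under bivariate normality with true axis at angle
atan b₀, u and v are uncorrelated, so r = corr(u, v) with
t = r√((n−2)/(1−r²)) on n−2 df is an *exact* small-sample test (its
empirical size at n = 50 is 0.05 to Monte-Carlo precision). The
confidence interval is the classical angle interval
θ̂ ± ½·arcsin(q), q² = 4F(level; 1, n−2)(s_x²s_y² − s_xy²) /
((n−2)((s_y²−s_x²)² + 4s_xy²)), which inverts the rotated-scores test
exactly (cov(u, v) = R·sin 2(θ₀ − θ̂) with the determinant invariant
under rotation); the inversion is asserted in the tests. The 45
pairwise tests of slope = 1 are Holm-adjusted and reported as the
descriptive "concordance of slope pairs" surface.

**Joint isometry test.** H₀: the leading eigenvector of Σ is c. The
statistic is the classical leading-eigenvector quadratic form

    X² = (n−1)·(λ₁·cᵀS⁻¹c + cᵀSc/λ₁ − 2),

λ₁ the leading sample eigenvalue, asymptotically χ²(p−1) under H₀ and
exactly 0 when c is an exact sample eigenvector. The χ² reference is
however markedly anti-conservative at cohort-scale sample sizes: under
exact multivariate normality with p = 10 it rejects a true null at
rate ≈ 0.11 for n = 100 and ≈ 0.17 for n = 50, converging only around
n ≈ 400. The reported p-value therefore calibrates the same statistic
by parametric bootstrap: Gaussian samples are drawn from the
H₀-restricted covariance S₀ = (cᵀSc)·ccᵀ + (I − ccᵀ)S(I − ccᵀ) (the
observed covariance with its variance along c made an exact
eigenvalue), and p = (1 + #{X²* ≥ X²})/(B + 1). The calibrated test
holds its empirical size at 0.048 in the conditions above. The χ²
p-value is always reported alongside (`p_chi2`); the p-value floor is
1/(B+1), so B is chosen to resolve below any threshold being quoted
(pipeline default B = 4999 → floor 2×10⁻⁴). Degeneracies are flagged,
never silently passed: exact collinearity, singular covariance (the
most collinear column pair is named), and near-multiplicity of the
leading eigenvalue (ratio > 0.95).

Strata are boys and girls separately, pooled across ages within the
stratum; the sensitivity analysis repeats everything restricted to age
≥ 5 years (excluding the infants). Absolute volumes enter the isometry
machinery; relative volumes are used only for the descriptive trend
curves.

## Trend curves

Absolute volume (untransformed) and log relative volume
(log (V_m / ΣV)) are smoothed against age and tibia length per sex by
penalized cubic regression splines: a K = 10 cubic B-spline basis with
quantile-placed interior knots and a second-order difference penalty,
β̂ = argmin ‖y − Bβ‖² + λ‖D₂β‖². D₂ takes second *divided* differences
across the Greville abscissae, normalized by their mean spacing, so its
null space is exactly the straight lines in x even on non-uniform
knots: λ → ∞ recovers the OLS line, and the fit at fixed λ is
invariant to affine rescaling of the predictor. λ is selected by GCV,
n·RSS/(n − γ·edf)², over a 61-point log grid spanning 10⁻⁴–10⁸, with
effective-df inflation γ = 1.4: plain GCV occasionally undersmooths,
which on a truly flat response shows up as spurious boundary
excursions; mild inflation suppresses this at negligible cost to
curved signals (the sin-recovery RMSE is unchanged to three decimals).

Each fitted log-relative-volume curve carries a descriptive constancy
flag: total rise/fall ≤ 0.05 log-units counts as constant. The
rise/fall is evaluated at the observed predictor values, not on the
plotting grid, because the cohort has no data between 0.3 and 5 years
and a spline's excursion across that unsupported gap says nothing
about the children. No hypothesis test is attached to the curves — the
inferential claim about synchrony rests on the isometry test. Flat
curves are only *detectably* flat at scale: with residual
volume CV ≈ 15%, a max-over-40-curves excursion below 0.05 needs on
the order of 500 children per band; at n ≈ 200 total the noise floor
of the curves exceeds the tolerance, which the test suite demonstrates
at large n only.

## The synthetic cohort generator

No participant-level data are publicly deposited, so the package ships
a generator whose defaults reproduce the structure the analysis
expects, calibrated to the embedded normative summary (per-group
means/SDs of 10 muscle volumes, tibia/fibula length, age, body mass
and height for 4–43 children per sex × band; bands [0, 0.3), [5, 7.5),
[7.5, 10), [10, 12.5), [12.5, 15) years, half-open).

**Band-wise mode (calibrated).** Within a group every positive
variable is log-normal with moment-matched parameters
(σ² = ln(1 + s²/μ²), m = ln μ − σ²/2). Two refinements make the draws
behave like growth data while preserving the group moments:

* *age interpolation* — the log-mean varies linearly in age between
  contiguous band midpoints (slopes are never taken across the
  unscanned 0.3–5 y gap); the residual log-SD is shrunk by the
  variance the trend explains and an exact-mean correction
  (sinh u / u) keeps E[V] at the calibrated mean. Verified: group
  means within 0.5% and SDs within 3% of the calibration targets at
  n = 10⁴ per band;
* *shared size factor* — within a participant all log-scale residuals
  load 0.85 on one latent standard normal (between-variable log
  correlation ≈ 0.72), expressing that bigger children have uniformly
  bigger muscles and longer bones. Marginal moments are untouched.
  Without this correlation the major-axis analysis has little to work
  with and the generator would not resemble volumetric data, where
  between-muscle correlations of this order are universal.

The within-group distributional shape (log-normal) and the correlation
level are modelling choices — the calibration table constrains only
means and SDs.

**Allometric mode (structural truth).** log V_m = a_m + b_m·log S +
ε_m with latent size S = tibia length (a linear-in-age growth curve,
≈ 10 cm at birth to ≈ 40 cm at 15 y, with 4% log-normal noise),
ε_m ~ N(0, σ_m²) independent, σ_m = 0.15 by default, and intercepts
anchored so volumes match the reference means at tibia 26.1 cm for any
exponent choice. The *synchronous* preset (all b_m equal, equal σ_m)
generates the isometric null exactly: the population covariance is
b²σ_S²·11ᵀ + σ²I whose leading eigenvector is the isometric direction.
Equal residual SDs are part of the null construction — with unequal
σ_m and a shared exponent the leading eigenvector is perturbed away
from c, and the test is *correct* to reject. The *asynchronous* preset
spreads exponents evenly over [0.7, 1.3]; pairwise major-axis slopes
then estimate the exponent ratios b_k/b_j (consistent because the
residual variance is equal on both axes), recovered with bias ≈ 0.01
at n = 200 over the full age range. Motion-artefact flags are
Bernoulli(2/210) by default, mirroring the QC exclusion rate.

What the generator does **not** emulate: MRI intensities, segmentation
error, secular trends, within-family clustering, or any longitudinal
structure. Passing tests on synthetic cohorts show that the
statistical machinery does what it claims under the stated model, not
that the biological conclusion holds for any real cohort.

## Morphometry

Volume is voxel count × voxel volume (mm³ → cm³); voxel i covers
[i, i+1)·spacing so centers sit at (i + ½)·spacing, making
grid-aligned phantom volumes exact and general shapes accurate to
< 2% at 1 mm spacing for ≥ 20 mm structures. Bone length is the
max − min of the label's voxel-center projections (physical mm) on the
leading eigenvector of their covariance — the point-cloud version of
"longest extent along the first principal component" — and is
rotation-invariant within one voxel diagonal. Relative volume divides
by the sum over the 10 muscle groups only; bones never enter the
denominator. Summaries use the n−1 SD and report one-row strata with
an explicit undefined-SD flag; ages falling in no band go to an
explicit "unbinned" bucket. TSURAE (LG+MG+SOL) and TOTAL are always
derived, never stored.

A deliberate simplification: volumes come from voxel counts, not from
a reconstructed triangulated surface. Phantom validation bounds the
discrepancy (< 2% at 1 mm), and surface meshing is a non-goal.

## Problem sizes and reproducibility

Simulation studies in the shipped tests use 1000 replicates at n = 100
for the size study (bootstrap B = 299 per replicate), 10⁴ replicates
for the exact pairwise test, and 60 replicates at n = 200 for
recovery/power — sizes at which Monte-Carlo error is well inside the
asserted brackets. All randomness flows through explicitly seeded
`numpy.random.Generator`s; a fixed seed reproduces every cohort
bitwise and every pipeline output byte-identically (asserted in the
tests). Every pipeline artifact records the seed and a SHA-256 config
fingerprint.

## Known limitations

* The joint-test bootstrap assumes Gaussian log-volumes under the
  null; heavy-tailed deviations are not covered.
* The band-wise generator's age interpolation is piecewise linear in
  log-mean; real growth curvature within a 2.5-year band is ignored.
* At printed group sizes the over-5 sensitivity stratum (n ≈ 117) has
  finite power: rare cohort draws yield sensitivity p-values in the
  0.001–0.01 range rather than below 0.001.
* Cross-sectional only: nothing here estimates an individual child's
  growth trajectory.
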