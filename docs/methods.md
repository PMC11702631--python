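# Methods

This note documents the models, conventions and numerical choices behind
`cogmorph`, in the spirit of a statistical package's methods appendix. The
package analyses vertex-wise cortical morphometry–cognition associations on
synthetic spherical surfaces; everything below is the package's own account of
what it computes and why.

## Surface substrate

Each hemisphere is a full icosphere: a regular icosahedron subdivided `s`
times by edge midpoints and projected to a sphere of radius 100 mm (the
FreeSurfer spherical-registration convention, which makes millimetre FWHM
values meaningful). Vertex counts follow 10·4^s + 2 per hemisphere. The right
hemisphere is the exact reflection of the left through the x = 0 plane with
face winding reversed, so vertex `i` on the left corresponds to `i + n` on
the right; all mirror operations (medial-wall masks, paired parcellations,
conjugate spin rotations) reduce to this index shift and are exact rather
than approximate. The default analysis mesh is ico4 (2562 vertices per
hemisphere): large enough for genuine spatial structure, small enough that
the full pipeline and its tests run in minutes on one CPU.

The medial wall — the non-cortical part of a real surface model — is emulated
as a polar cap: the `cap_fraction` (default 0.05) of vertices nearest a pole
direction is flagged `cortex_mask = False`, symmetrically in both
hemispheres. Masked vertices are kept in-band (values NaN, never zero-filled)
so every map stays length-aligned with the mesh.

Parcellations are built by farthest-point seeding on the left-hemisphere
cortex under graph-geodesic (Dijkstra) distance followed by geodesic-Voronoi
assignment, then mirrored, giving left/right paired regions in the manner of
the Desikan–Killiany atlas. 34 regions per hemisphere is the default.

## Surface smoothing

Gaussian smoothing at a given FWHM is implemented as explicit Euler steps of
the heat equation on the cortex subgraph: σ = FWHM/√(8 ln 2), diffusion time
t = σ²/2, time scaled by the squared mean edge length. The operator is the
symmetric combinatorial Laplacian restricted to valid (cortex ∩ map-mask)
vertices, so

- constants are fixed points and the mean over the smoothed set is preserved
  to round-off,
- smoothing is exactly linear,
- masked vertices neither contribute nor receive mass (mask-aware boundary
  handling at the medial wall — a choice this package makes explicitly, since
  surface-analysis tools rarely document it),
- the step size is capped at min(ℓ̄²/8, 0.5/max-degree · ℓ̄²), keeping the
  per-step diffusion length under half the mean edge length and inside the
  explicit-Euler stability region.

Exact equivalence with a geodesic Gaussian is *not* claimed; the contract is
the invariant set above plus monotone variance reduction, which the tests
check directly.

## Synthetic data generator

The generator plays the role of three adult cohorts and a stack of
neurobiological profile maps. What it emulates:

- **Effect fields.** Smooth zero-mean fields (white noise diffused at 20 mm
  FWHM) rescaled so the maximum |β| equals the requested amplitude exactly.
  Defaults: 0.15 for g, 0.15 for age, 0.10 for sex, all inside a ±0.2
  envelope chosen to match the magnitudes reported for standardized
  vertex-wise effects in large adult cohorts. Residual SD is 1 per vertex, so
  planted fields are approximately on the standardized-β scale (attenuation
  by the factor 1/√(1+β²) ≤ 1.02 is negligible at these amplitudes).
- **Between-cohort heterogeneity.** Each cohort adds an independent smooth
  deviation field scaled by τ (default 0.02) to its g-effect field, giving
  the random-effects model real τ² to estimate rather than a token.
- **Cognitive battery.** A positive-manifold one-factor model: g ~ N(0,1),
  test_j = λ_j g + √(1−λ_j²) ε. The three default cohorts (n = 2000/800/400;
  ages 64±7.6, 59±10, 73±0.7; 10/5/13 tests with loadings 0.4–0.8) emulate a
  large biobank, a mid-size population study and a small narrow-age birth
  cohort at desk scale.
- **Covariates.** Age and sex enter the morphometry model with their own
  effect fields; three continuous head-position nuisances (coefficient 0.01,
  a free parameter — real data gives no generative statement for this
  confound), a categorical site, and an optional cognition–MRI time lag for
  the birth-cohort analogue.
- **Profile maps.** Mixtures of `n_latent` smooth, mutually orthogonal,
  unit-SD spatial patterns plus white vertex noise. With unit-norm loading
  rows, noise SD √((1−share)/share) fixes the signal share of variance
  (default 0.6 across 33 maps and 4 patterns).

What it does not emulate: scanner- or site-specific artefacts beyond a mean
shift, missing data, non-Gaussian test distributions, kinship structure, the
LBC1936-style within-domain residual covariances, and any geometric
irregularity of a real cortical sheet (the icosphere is regular; real meshes
have variable vertex density). Passing tests therefore demonstrate the
*statistical machinery* — estimator correctness, calibration, recovery under
the stated generative model — not robustness to real-data pathologies.

A 4-SD outlier rule is provided (`apply_outlier_rule`), applied per variable
rather than per subject, matching quality-control practice for biobank-scale
structure volumes.

## Latent g

`fit_one_factor` minimizes the ML discrepancy
F = ln|Σ̂| + tr(SΣ̂⁻¹) − ln|S| − p over (Λ, Ψ) for a single factor with unit
variance, on the sample *correlation* matrix (batteries mix scales; the fit
is then invariant to affine rescaling of any test). The loadings are profiled
out analytically — for fixed Ψ the optimal Λ comes from the leading eigenpair
of Ψ^{-1/2} S Ψ^{-1/2} — and the concentrated objective is minimized over
log ψ by L-BFGS-B with the conventional start ψ_j = (1 − 1/(2p)) / (S⁻¹)_jj.
Uniquenesses are bounded below at 0.005; hitting the bound flags a Heywood
case. Fit indices use the independence baseline (Σ_b = I, so F_b = −ln|S|):
T = (n−1)F, CFI with the max(·,0) clamps, TLI, RMSEA = √(max(T−df,0)/(df(n−1)))
reported missing when df = 0, and SRMR as the RMS of the lower-triangle
(including diagonal) residual correlations.

Scores default to the regression (Thomson) estimator ŝ = z Σ̂⁻¹Λ (Bartlett
available), rescaled to unit sample variance. Orientation: the mean loading
is forced positive, so higher scores mean better performance on a
positive-manifold battery. Because the correlation matrix is invariant to
reversing every test, a fully reversed battery yields the same loadings and
*flipped* scores — the estimator cannot know the tests' polarity; callers
own test direction.

A note on attainable score quality: the regression-score correlation with
the true factor is bounded by √(ρ/(1+ρ)) with ρ = Σ λ_j²/ψ_j. Six tests at
λ = 0.6 cap at 0.878; the default batteries (loadings up to 0.8) cap near
0.92, which is why score–truth correlations ≥ 0.9 are a meaningful but
passable bar.

## Vertex models

One design matrix per cohort, all vertices solved at once:
z(measure_v) ~ z(predictor) + covariates, with continuous covariates z-scored
within cohort (n−1 SD), sex as a 0/1 indicator (so its β is an SD-unit group
contrast, positive = larger in males), and site as indicator contrasts. With
no covariates the standardized β equals the Pearson correlation (tested to
1e-10). Rank deficiency raises an error naming the collinear columns. A
`standardize=False` mode reports raw OLS slopes; it exists because the
noise-free exact-recovery contract lives on the raw-slope scale — a
zero-residual vertex has standardized β = ±1 by definition.

Global associations run the same model on the cortex-aggregated measure (sum
for volume and surface area, mean for thickness/curvature/sulcal depth).
Allometric scaling is the per-vertex slope of ln(vertex area) on ln(total
area) — slope 1 is isometry — with no covariates by default and an optional
age/sex adjustment.

The model direction (vertex measure as outcome, cognition as predictor)
follows surface-GLM convention; with both sides standardized the coefficient
is symmetric in the two variables anyway. Whether nuisance covariates are
z-scored is exposed but defaults to yes.

## Meta-analysis

Per vertex, k cohort estimates are pooled under β_i ~ N(μ, SE_i² + τ²).
τ² estimators:

- **DL** (closed form): Q = Σw(β_i − β_FE)², C = Σw − Σw²/Σw,
  τ² = max(0, (Q − k + 1)/C), kept as the exactly-testable oracle;
- **REML** (default, matching mainstream meta-analysis software): Fisher
  scoring on the restricted likelihood, tolerance 1e-8, 100 iterations,
  DL start, vectorized over vertices via batched 2×2 linear algebra. The
  implementation was validated against an independent reference value frozen
  into the test suite.

Moderator meta-regression (cohort mean age is the motivating moderator) uses
the same REML machinery with design [1, z(moderator)] and a Wald z-test on
the slope; it requires k ≥ 3 for one moderator. With k = 3 the z-test is
anticonservative — the calibration test asserts a rejection rate in
[0.01, 0.12] at α = .05 rather than pretending exactness. Both the
uncorrected α < .05 convention and a per-map FDR variant of moderator
significance are computed, since either convention is defensible.

BH FDR is applied per (predictor, measure) map over cortex vertices, NaNs
passed through without counting toward the family. Log-Q maps use the
natural log (forced by the reference value ln 0.05 = −2.9957), clamped below
at a configurable floor because FDR Q values underflow in well-powered maps.

## Spin tests

Null distributions for spatial correlations must preserve spatial
autocorrelation; the spin test does this by rigid rotation of the sphere.
Uniform (Haar) rotations are drawn as the sign-corrected QR factor of a
Gaussian 3×3 matrix, with det forced to +1; the rotation-angle density
(1−cos θ)/π is verified by a goodness-of-fit test. The left hemisphere gets
R, the right its mirror conjugate M R M (M = diag(−1,1,1)); on the mirrored
mesh this makes the right permutation the index image of the left's, exactly.
Each vertex's permuted source is the nearest rotated vertex (Euclidean on
the sphere, ties to the lowest index); sources on the medial wall become
missing and are dropped pairwise per spin (the "original parcellation"
variant — the mask-swapping alternative is a config flag away in principle
but not the default).

The association map is the spun map; the profile map stays fixed. The
p-value is two-sided on |r| with the +1 correction,
p = (1 + #{|r_null| ≥ |r_obs|})/(n_spins + 1), guaranteeing p ∈ (0,1] and a
minimum of 1/(n_spins+1). p is invariant to affine transforms of either map.
Within-region correlations are plain Pearson r per paired region (left+right
vertices pooled, regions under 10 valid vertices flagged); they carry no
spin p — their value is exposing heterogeneity that cancels in the
cortex-wide r, which the ±1 piecewise construction in the tests makes exact.

## Profile PCA

Maps are stacked on the vertices valid in *all* maps and column-standardized
(so the PCA is of the correlation matrix; forced by mixing maps with
arbitrary units). Eigenstructure comes from the SVD of the standardized
matrix; loadings are reported in the √eigenvalue metric — the loading of map
m on component c is corr(map_m, score_c) — so |loading| < 0.3 thresholds are
meaningful. Sign convention: the largest-|loading| entry of each component is
positive.

Varimax maximizes the summed variance of squared loadings by iterative
pairwise planar rotations (the classical closed-form angle per pair), Kaiser
row-normalization on by default, convergence when a full sweep gains < 1e-10.
The criterion is non-decreasing by construction and the rotation matrix is
orthogonal, so communalities are preserved. A 0.01°-grid search over the
rotation angle serves as the brute-force oracle in the k = 2 tests.

Component scores after rotation are regression scores from the rotated
loadings, rescaled to unit SD; on a noise-free rank-k stack they reconstruct
the standardized data exactly. Tucker's congruence φ = Σab/√(Σa²Σb²) matches
components across solutions. The metabolism helper takes exactly three maps
(blood flow, oxygen and glucose metabolism in the motivating use) and
orients PC1 so all loadings are positive — higher scores mean higher
metabolic activity; negating every input therefore flips the score map,
which is the only behaviour consistent with that convention.

The category contrast (`category_abs_r_test`) Welch-tests |r| of
within-receptor map pairs against pairs among non-receptor maps. "Pairs among
all non-receptor maps" is the default grouping; a within-category-only
variant is available, since the natural-language description of the contrast
admits both readings.

## Pipeline and reproducibility

`run_pipeline` executes mesh → truth → cohorts → latent g → vertex GLMs →
meta-analysis → profiles → spins → PCA, writing delimited tables, JSON
summaries, and curv maps per stage. Every stage seed derives from the master
seed via `numpy.random.SeedSequence.spawn`, so a config reproduces a run
bit-for-bit; stage failures abort with the stage name while keeping partial
outputs on disk. The default configuration (ico4, three cohorts totalling
3200 subjects, five measures, 500 spins, 33 profiles) completes in about a
minute on one CPU; tests use ico2–ico3 and the acceptance checks ico4.

Problem sizes throughout (ico4 rather than a 164k template, hundreds of
spins rather than 10000, thousands of subjects rather than tens of
thousands) are the package's chosen desk-scale study conditions; all
calibration statements hold at those sizes with Monte-Carlo tolerances
stated in the tests.

## Known limitations

- The icosphere is geometrically regular; conclusions about smoothing and
  spin calibration transfer to real, irregular meshes only approximately.
- Single-factor g only; hierarchical/bifactor batteries (and within-domain
  residual covariances) are not modelled, in the generator or the fitter.
- Complete cases only; no FIML for missing test scores.
- The spin test inherits its usual blind spot: it corrects for global, not
  spatially varying, autocorrelation.
- Meta-regression inference at k = 3 cohorts is anticonservative (documented
  and calibrated, not corrected — no Knapp–Hartung adjustment).
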