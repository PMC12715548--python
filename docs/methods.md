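# Methods

This note documents the models, estimators, numerical choices and study
conditions implemented in factorscape, and what the synthetic experiments do
and do not establish about real data.

## Morphometric similarity (MIND)

Each cortical region is modeled as a multivariate distribution of its
vertices' morphometric features.  Features are standardized per subject
across the pooled vertex set (mean 0, variance 1) before any divergence is
estimated; this is required to mix incommensurate units (mm, mm², unitless
curvature) and a zero-variance feature is treated as an input error.  The
z-normalization of the finished matrix is likewise per subject (lower
triangle z-scored, mirrored; diagonal excluded from statistics and set to
the maximum z for display).  Whether standardization should instead be done
across a cohort is left configurable; per subject is the default because the
similarity matrix is a within-subject object.

Two divergence estimators are provided:

* **Gaussian (closed form).** Each region is fitted with a multivariate
  Gaussian; `KL(P‖Q) = ½[tr(Σ₂⁻¹Σ₁) + (μ₂−μ₁)ᵀΣ₂⁻¹(μ₂−μ₁) − F +
  ln(det Σ₂/det Σ₁)]` via Cholesky factorizations.  Exact under the model;
  used as the oracle in tests and as the fast path.
* **k-NN (nonparametric, default, k=3).** The Wang–Kulkarni–Verdú
  density-ratio form `(F/n)Σᵢ ln(ν_k(i)/ρ_k(i)) + ln(m/(n−1))`, with ρ_k the
  within-sample and ν_k the cross-sample k-th-neighbor distances (cKDTree).
  The estimator can go slightly negative at finite n and is clamped at 0.
  Zero distances from duplicate vertices are replaced by the smallest
  positive observed distance × 1e-6, which keeps the estimate finite and
  deterministic.

The pairwise divergence is symmetrized as the arithmetic mean of the two
directions, keeping `MIND = 1/(1+D)` in (0, 1] with diagonal exactly 1.

The k-NN estimator's finite-sample bias depends on pair geometry: it is small
(|bias| < 0.13 nats at n = 2000 for KL up to ~3) for mean shifts combined
with equal-or-wider target covariances — the regime standardized morphometric
features produce — but it underestimates substantially when the target
distribution is much *narrower* than the source (measured ≈ −0.66 nats at a
true KL of 0.77 for a half-width isotropic target).  The estimator benchmark
therefore spans KL ∈ [0, 3] in the generator-matched geometry, and analyses
should not rely on absolute k-NN divergences across strongly
variance-shrinking comparisons; ranks (and hence MIND recovery) are far more
robust than absolute values.

## Functional connectivity

FC is the Pearson correlation of regional time series (diagonal 1).  Multi-run
data are combined by Fisher r-to-z transforming each run and averaging in z
space (kind `fc_z`); the diagonal (z = ∞) is excluded and set to 0, since no
downstream statistic uses it, and off-diagonal |r| within 1e-12 of 1 is
clipped to 1−1e-7 with a warning.  Healthy-control comparison patterns are
plain element-wise group averages.  Patient matrices enter the factorization
as raw correlations, without control-based normalization.

## Latent factor model

Each signed matrix becomes a count document over 2E words (E lower-triangle
edges × {positive, negative} channel): `pos = round(s·max(x,0))`,
`neg = round(s·max(−x,0))`, with half-away-from-zero rounding for platform
stability.  The count scale s trades discretization error against document
size; fitted loadings are insensitive to it (mean absolute loading change
< 0.05 between s=10 and s=20 on the reference synthetic cohort).  The default
is s=10 for z-scaled matrices; raw correlation matrices (entries ≪ 1) use a
larger scale (60 in the demo pipeline) so documents keep enough counts.
An optional per-edge cohort z-scoring exists for parity with
control-normalized variants but defaults off.

Inference is batch variational EM for smoothed LDA with symmetric priors
α = 50/K on document–factor proportions and η = 0.01 on factor–word
distributions (standard topic-model practice).  Per-document Dirichlet
parameters are warm-started across outer iterations, the topic update's
sufficient statistics are recomputed from the final document parameters of
each E-step, and the bound is evaluated with the word-assignment term at its
conditional optimum — together these make the tracked ELBO exactly
coordinate-ascent monotone, which the test suite enforces to 1e-6.
Convergence is declared at relative ELBO change < 1e-5 (max 200 iterations);
5 random restarts are fitted and the best final bound wins.  Everything is
deterministic given the seed.  Factor count K is fixed by configuration
(3 throughout the reference analyses); no model selection is attempted.

Label switching is handled by Hungarian assignment maximizing total
lower-triangle correlation between matched signed matrices — exact for this
objective at any K, so no separate exhaustive search is kept.

## Characterization statistics

* Factor correspondence and structure–function coupling: Pearson r between
  lower-triangle vectors (canonical row-major i>j order), two-sided p.
* Behavior: pairwise-complete Pearson r of each loading column with each
  scale; cells with < 3 complete pairs are flagged, not computed.  P-values
  are two-sided and uncorrected (reference reporting style; thresholds are
  quoted at p < .005).
* Factor summary vector: first principal component of the R×R matrix treated
  as R region-observations (column-centered), sign-fixed to correlate
  nonnegatively with row means.  Region-rows orientation was chosen because
  the summary must live in region space to be comparable with receptor maps.
* Receptor regression: OLS of the (standardized) summary vector on all 19
  standardized maps jointly — one model per factor, read as "the regression
  weight of each transmitter".  The grammatically possible alternative
  (19 separate simple regressions) is available via the same design matrix
  machinery but is not the default.  Collinear map sets (condition number
  > 1e8) are rejected with the offending pair named.

## Spin permutation null

Spatially autocorrelated maps make parametric regression p-values
anti-conservative, so inference uses an empirical null: each permutation
draws a uniform random 3-D rotation, applies it to the left hemisphere and
its x-mirror to the right, and uniquely reassigns rotated parcels to original
parcels within each hemisphere.  Unique assignment (each parcel used once)
keeps every spun map an exact permutation of the original — value multiset
and approximate spatial structure preserved, alignment with predictors
destroyed.  The default assignment minimizes total reassignment distance
(Hungarian); a greedy ascending-distance variant is kept for large R.  The
permutation is applied to the response vector rather than the 19 predictor
maps — equivalent under a common rotation of one map set, and 19× cheaper.
Two-sided empirical p-values use the add-one rule, so the floor is
1/(n_perm+1); Benjamini–Hochberg q-values across transmitters are reported
alongside raw p (conservative extra column; the reference analyses report
raw spin p only).  Default n_perm = 1000 for analyses, 500 in the
calibration experiments, 300 in the demo.

## Synthetic cohort generator

The generator emulates the *statistical* structure of the study inputs, not
MRI physics:

* **Parcellation:** quasi-uniform Fibonacci lattices per hemisphere on the
  unit sphere, independently rotated about x by a seeded angle.  Quasi-uniform
  spacing matters: spin nulls are only faithful when rotated parcels land
  near original ones.
* **Factors:** K signed symmetric matrices with ~`edge_density` (default
  0.3) of lower-triangle edges active, mostly disjoint supports, mixed signs;
  draws are rejected until all pairwise |r| < 0.5 so the truth is
  identifiable.
* **Subjects:** `Σ_k loading_k·factor_k` + symmetric Gaussian noise, with
  Dirichlet(0.5) loadings — sparse enough that subjects have distinct
  dominant factors, as observed in real loading simplices.
* **Vertex clouds:** region Gaussians with mean `separation·z_r` and
  covariance `I + separation·(A_rA_rᵀ/2F)`; the closed-form symmetrized-KL
  matrix between the true Gaussians is returned as the recovery target, and
  `separation = 0` collapses every region onto one Gaussian (zero truth).
* **Time series:** multivariate Gaussian draws whose population correlation
  equals a prescribed PSD target (eigen square root; non-PSD targets rejected
  naming the offending eigenvalue).
* **Receptor maps:** i.i.d. parcel noise smoothed `round(smoothness)` times
  over the 6-nearest-neighbor sphere graph, then column-standardized.  One
  smoothing pass yields nearest-neighbor correlation ≈ 0.6–0.8, comparable to
  parcellated cortical maps; the receptor-study conditions below use two
  passes (NN correlation ≈ 0.85).
* **Behavior:** `score = loadings·effectsᵀ + noise`, with a helper that
  converts a target population correlation into the required noise SD.

What passing recovery tests does **not** show: robustness to site effects,
head motion, registration error, non-Gaussian vertex distributions, or
model misspecification of the linear mixture — none of which the generator
emulates.  The linear-mixture-plus-noise subject model is an assumption made
for testability, not a claim about the biological generative process.

## Study conditions for the reference experiments

Problem sizes were chosen once so the whole suite runs comfortably on one
CPU: divergence-estimator checks at 5-D, n up to 5000; MIND recovery at
R=20 with 500 vertices/region; LDA recovery at K=3, N=100, R=20,
Dirichlet α=0.5, noise SD 0.05; behavior dissociation at N=150, population
r≈0.3, 100 cohorts; demo pipeline at R=20, N=60.

The spin-test studies use R=100 parcels, 19 maps and 500 spins per dataset.
Two details matter for validity at parcel resolution.  First, small rotations
(≲ half the parcel spacing) reassign every parcel to itself; the identity
arrangement is already represented by the add-one rule, so identity
permutations are discarded and redrawn — without this the p-value floor is
unattainable and the null double-counts the observed configuration.  Second,
the unique reassignment slightly roughens spun maps; with the response field
smoother than the predictor maps (three vs two smoothing passes — PCA
summaries aggregate over the whole matrix and are smoother than single maps)
the per-transmitter type-I rate is calibrated (measured mean ≈ 0.045 at
α = 0.05 across three independent 200-dataset replications).  The power
study plants one map in the response and uses single-pass smoothing: under
heavier smoothing the 19 predictors become strongly collinear (variance
inflation ≈ 5), the null betas' tails widen, and even a perfectly planted
map cannot reach the permutation floor in the *joint* model — a property of
the joint reading of the regression, not of the spin null; the per-map
simple-regression variant does not share it.

## Known limitations

* The two-channel count construction inherits unknown constants (scale,
  rounding) from the antecedent framework; acceptance is via ground-truth
  recovery, not byte-level replication of restricted-data results.
* The demo pipeline factorizes mixture matrices directly on the MIND side
  (standing for z-normed MIND), because no generative model links factor
  mixtures back to per-vertex Gaussians; the MIND estimation stage is instead
  validated separately against closed-form truth.  The FC side is end-to-end
  (time series → correlation → factorization).
* Joint 19-predictor regression with strongly collinear maps inflates null
  beta variance; with very smooth maps at small R a planted map's spin p may
  sit above the theoretical floor.  This is a property of the joint-model
  reading of the regression, not of the spin null.
* Spin nulls assume hemispherically mirrored, sphere-mappable parcels;
  subcortical structures are out of scope.
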