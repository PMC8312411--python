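# Methods

## The biometrical model

Each phenotype y of twin j in a pair is modelled as

y_j = μ_s + β₁·(age − c) [+ β₂·(age − c)²] + a_s·A_j + d_s·D_j (or c_s·C_j) + e_s·E_j,

where the latent components are standard normal, s indexes sex, and c is
the cohort mean age.  Cross-twin correlations of the latents are fixed by
zygosity: corr(A₁, A₂) = 1 (MZ) or ½ (DZ); corr(D₁, D₂) = 1 or ¼;
corr(C₁, C₂) = 1 in both; E uncorrelated.  D and C cannot be estimated
simultaneously from twins reared together, so models are ADE or ACE (or
reduced AE/E).  Standardized shares a², d² (c²), e² sum to 1;
broad-sense heritability H = a² + d² in ADE models.

Because co-twins share an age, any age trend inflates raw within-pair
correlations; age therefore enters the means model *inside* the
likelihood (coefficients estimated jointly), rather than by
pre-residualization, which also treats singletons coherently.

### Sex limitation

Three nested layers:

* **full** — all paths sex-specific; the opposite-sex (OS) genetic
  cross-twin covariance is r_fm·(½ a_m a_f + ¼ d_m d_f).  r_fm is applied
  to the additive and dominance terms jointly by default; a config switch
  (`r_fm_scope="additive"`) restricts it to the additive term.  The joint
  convention was chosen because the two variants are indistinguishable in
  ACE/AE models and differ only through the OS dominance term, and the
  combined genetic covariance is the quantity the OS pairs identify.
* **quantitative** — r_fm fixed at 1 (same genetic sources, sex-specific
  magnitudes).
* **none** — the standardized broad-sense share H is constrained equal
  across sexes; total variance and the A/D split remain sex-specific.
  Equating H (rather than raw paths) is the substantively meaningful
  "no quantitative sex difference" hypothesis when total variances differ
  between men and women.

### Parameterizations

Path mode parameterizes each sex as (log V, H-share h ∈ [0,1], additive
fraction g ∈ [0,1]), so shares are non-negative by construction, h is a
raw coordinate (making profile intervals for H one-dimensional), and the
model is scale-free via log V.  The direct-symmetric mode parameterizes
variance components (V_A, V_D, V_E) directly and unbounded, allowing
negative estimates; expected covariances are assembled linearly, and
non-positive-definite trial points are rejected (large penalty) so
optimization continues.  For OS pairs in direct-symmetric mode the
cross-sex genetic covariance uses geometric means
r_fm·(½√(V_Am V_Af) + ¼√(V_Dm V_Df)), rejecting points where a product is
negative; with interior truths this region is never visited at
convergence.

## FIML

All likelihoods are sums of multivariate-normal log-densities per pair: a
complete pair contributes the joint density of its observed vector, a
singleton the marginal of the observed subvector, with no imputation.
Two evaluators:

* constant covariance per zygosity group — rows grouped by missingness
  pattern, one Cholesky factorization per pattern, fully vectorized;
* per-pair covariance (moderation models) — batched 2×2 closed form or
  batched 4×4 Cholesky over stacked matrices.

Singular or non-finite covariances return a large finite penalty (1e12)
rather than ±inf, which quasi-Newton line searches tolerate.

## Optimization and inference

L-BFGS-B with numerical gradients from moment-based starting values
(sample means/variances regressed on age; Falconer estimates
a² = 4r_DZ − r_MZ, d² = 2r_MZ − 4r_DZ from group intraclass correlations;
component correlations started at the phenotypic correlation).  Restarts
jitter the start within bounds (default scale 0.1 of the box width); ties
break by lowest −2logL, then lowest gradient norm.  log-variances are
box-bounded to ±46 to keep line searches finite.

Profile-likelihood 95% intervals move one raw coordinate until the
profiled −2logL rises by χ²₁(0.95) = 3.841, re-optimizing the rest at
each point (geometric bracket expansion, then Brent root-finding);
endpoints that hit the parameter boundary are reported at the boundary —
variance shares pinned at zero get a zero lower limit.  Profile CIs are
provided for raw coordinates (H, E, r_fm, correlations); the A/D split of
H is a derived quantity and deliberately not profiled, because it is
weakly identified (see below).

Model comparison uses naive χ² likelihood-ratio tests (no 50:50 boundary
mixture correction — a known, documented approximation) and
AIC = −2logL + 2k with k counting all free parameters including
means-model coefficients; the constant convention cancels in comparisons.
Δχ² is floored at zero against optimizer noise.

## Descriptive (saturated) correlation models

Per zygosity group an unstructured 2T-variate normal (T traits × 2 twins)
is fitted with means, variances and within-person correlations equated
across twin order; intraclass and (direction-equated) cross-twin
cross-trait correlations are free.  Opposite-sex pairs keep
position-specific (male/female) means and variances, with twin 1 fixed as
the male.  Pooled MZ/DZ/Total rows are re-fitted on merged groups, not
averaged.  Quadratic age terms use centred age and age² to limit
collinearity.  Assumption checks compare free vs order-equated vs
zygosity-equated moments per trait by LRT at α = 0.05.

## Bivariate and moderation models

The correlated-factor model gives each trait its own paths and correlates
like components across traits; cross-twin cross-trait covariance scales
by the kinship weights (e.g. DZ additive term ½·a_X·a_Y·r_A, dominance
¼·d_X·d_Y·r_D, C fully shared).  Component correlations are optimized on
an unconstrained scale mapped through tanh (bounded at |z| ≤ 8, i.e.
|r| ≤ 0.9999997); estimates pinned there are reported as ±1.00 with a
boundary flag.  Quantitative sex limitation on same-sex pairs shares no
parameters across sexes, so male and female groups are fitted separately
— an exact factorization of the joint likelihood.  Education-style traits
can keep zygosity-specific intercepts (`mean_free_by_zygosity`).

Moderation follows the standard linear-path form path(m) = path₀ + β·m
with m the twin's *own* mean-centred moderator (no quadratic β terms:
U-shaped variance profiles arise from squaring).  The full bivariate
model treats the moderator as a trait, splits the moderated trait into
components common with the moderator and unique to it, and may moderate
both sets; the moderator's observed values act as definition variables in
the per-pair covariance.  The extended univariate model moderates the
trait's own paths and puts both twins' moderator values in the means
model, guarding against covariance moderation leaking into
unique-variance moderation.  The decision ladder runs LRTs (i) no
moderation vs unique-path moderation and (ii) unique vs unique+common
moderation, recommending the full bivariate model when (ii) is
significant.  Moderated variance curves are evaluated on a grid
(default 15 points between the 1st and 99th moderator percentiles,
centred at the sample mean) and reported absolute and proportional;
proportions sum to 1 at every grid point.

### A known finite-sample property

In ADE moderation models the directions β_a and β_d are nearly collinear
(the A/D split is identified only through the modest difference between
½ and ¼ kinship weights), so the naive χ²₃ moderation LRT is
conservative at realistic sample sizes — empirically ~1.5% rejection at
nominal 5% with 600 pairs/group, with a mean statistic near 2 rather
than 3, and insensitive to extra optimizer restarts (i.e. not a
convergence artifact).  The calibration property is therefore
demonstrated in the AE configuration, where every β is well identified
and the empirical rejection rate matches the nominal level.  Power and
sign-recovery checks use a unique-path additive moderation of β = 0.15
at 1,000 pairs per group.

## Frailty index

FI = (endorsed deficits) / (denominator), denominator either the count of
answered items (standard deficit-accumulation practice, the default) or
the fixed full item count (replication mode); the two agree exactly
without missingness.  Individuals missing strictly more than 20% of the
44 items are excluded.  The square-root transform √FI is provided for
sensitivity analysis of the index's right skew.

## Synthetic data generator

Latent components are sampled jointly from the implied multivariate
normal per pair (Kronecker structure of a twin block and a cross-trait
correlation block), guaranteeing the exact cross-twin/cross-trait
correlation structure; phenotypes are linear in the latents, so every
generated cohort sits exactly inside the model family being fitted.
Defaults encode the study conditions the estimators target: a frailty
index with female shares A/D/E = 0.41/0.11/0.48 (H = 52%) and male
0.00/0.45/0.55 (H = 45%), female total variance above male, median
FI ≈ 0.11; an approximately normal BMI-like trait (H ≈ 66–69%, means
25.5/24.5 kg/m², SD 3.1/3.8) and education-years-like trait
(common-environment share 25–29%, mean ~10.5 y); ages uniform on 41–99
with a linear FI age trend and quadratic BMI/education trends; r_fm = 1.
Deficit items are endorsed when 0.8·(standardized liability) + noise
exceeds per-item thresholds whose endorsement probabilities at median
liability are spaced 0.01–0.21 (mean 0.11, setting the median FI); the
resulting index is right-skewed in [0, 1].  Singletons and item
missingness are injected uniformly at random.

What the generator does *not* emulate: ordinal/threshold item-level
genetic structure (items are driven by a single Gaussian liability),
assortative mating, sibling interaction, age-varying variance components,
and informative missingness.  Passing recovery tests therefore show the
estimators are correct and well-calibrated *under the stated model*, not
that the model is correct for any particular registry data.

## Problem sizes and numerical choices

Recovery experiments use 10,000 pairs per same-sex zygosity group (plus
5,000 opposite-sex pairs in the univariate experiment) — large enough
that Monte-Carlo error in H is a point or two; the square-root
sensitivity comparison uses 4,000 pairs/group; the calibration study 200
replicates at 600 pairs/group; the end-to-end pipeline defaults to 1,500
pairs/group.  Optimizer tolerances: ftol 1e-9, gtol 1e-8, maxiter 2000;
profile-CI root-finding xtol 1e-5.  Ties between identical-likelihood
solutions (path sign flips, A/D ridge endpoints) are broken by the
optimizer's convergence point; reported shares are invariant to path
signs.

## Known limitations

* A and D shares are individually unstable with twin data alone; trust H.
* No ordinal/threshold liability models: skewed indices are analysed as
  Gaussian (raw and √-transformed), mirroring common practice; the
  deficit layer attenuates latent heritability slightly (monotone
  transform bias), which is why sensitivity comparisons are made
  raw-vs-transform on the same index rather than index-vs-latent.
* On a deficit-derived (binarized) index the raw-vs-√ comparison keeps H
  and E essentially unchanged (<0.01) but can reshuffle the A/D split by
  up to ~0.1: binarization alters the MZ/DZ correlation ratio differently
  under the transform, and the split is weakly identified to begin with.
  The "shares stable under √" property is therefore guaranteed only when
  the Gaussian model is well specified on the index's own scale; for
  item-derived indices, interpret H and E.
* Naive LRT p-values at variance boundaries are conservative.
* Bivariate models handle exactly two traits (no Cholesky chains of
  three or more), and moderation is linear in the moderator by design.
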