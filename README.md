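# twinkin

Variance-components twin modelling in Python: saturated correlation models,
univariate ACE/ADE sex-limitation models, correlated-factor bivariate
models, gene–environment moderation models — all fitted by full-information
maximum likelihood (FIML) — plus a deficit-accumulation frailty index and a
synthetic twin-cohort generator that validates every estimator by parameter
recovery.

## Who this is for

Researchers in genetic epidemiology and behaviour genetics who analyse
classical twin data (monozygotic, same-sex dizygotic and opposite-sex
dizygotic pairs, with singletons) and want a scriptable, testable Python
stack for the standard model sequence: descriptive twin correlations →
univariate variance decomposition with sex limitation → bivariate
decomposition of trait covariance → moderation (G×E).  The motivating
application is the frailty index (FI) — the fraction of endorsed health
deficits out of 44 assessed — and its relation to BMI and education, but
every model is trait-agnostic.

## The models

A phenotype is decomposed into additive genetic (A), dominance genetic (D)
or common environmental (C), and unique environmental (E) sources.
Cross-twin correlations of the latent components follow the classical
rules: A correlates 1 in MZ and ½ in DZ pairs, D correlates 1 and ¼, C
correlates 1 in both, E is uncorrelated.  Broad-sense heritability is
H = a² + d² as a share of total variance.

* **Sex limitation** — paths are sex-specific (quantitative sex
  difference); for opposite-sex pairs the genetic cross-twin covariance is
  scaled by a correlation r_fm, with r_fm < 1 indicating qualitatively
  different genetic sources in men and women.  The "no sex difference"
  model equates standardized H across sexes while total variance stays
  free.
* **Correlated-factor bivariate model** — per-trait paths plus component
  correlations r_A, r_D (or r_C), r_E across traits.  Derived quantities:
  the broad-sense genetic correlation
  r_H = (a_X a_Y r_A + d_X d_Y r_D) / √((a_X²+d_X²)(a_Y²+d_Y²)),
  the implied phenotypic correlation r_P, and its source decomposition
  (the genetic share of r_P is the bivariate heritability).
* **Moderation** — path coefficients become linear functions of each
  twin's own moderator value, path(m) = path₀ + β·m (Purcell's full
  bivariate form when the trait–moderator covariance is itself moderated;
  the extended univariate form, with both twins' moderator values in the
  means model, otherwise).  Variance curves over the moderator grid come
  out absolute and proportional.
* **FIML** — every model sums multivariate-normal log-densities per pair;
  singletons contribute their marginal density, so incomplete pairs are
  used without imputation.  Likelihood-ratio tests and AIC
  (= −2logL + 2k) compare models; profile-likelihood confidence intervals
  are available for variance shares and correlations.

## Worked example

```python
import twinkin as tk

fi = tk.TraitTruth(
    name="FI", family="ADE",
    shares={"M": (0.00, 0.45, 0.55), "F": (0.41, 0.11, 0.48)},
    total_var={"M": 0.0056, "F": 0.0090},
    mean={"M": 0.105, "F": 0.125}, age_slope=0.0022)
cfg = tk.GeneratorConfig(
    n_pairs={"MZM": 3000, "MZF": 3000, "DZM": 3000, "DZF": 3000, "DZOS": 1500},
    traits=[fi], r_fm=1.0, seed=5)
cohort = tk.simulate_univariate(cfg)

spec = tk.ModelSpec(trait="FI", family="ADE", sex_limitation="quantitative")
fit = tk.fit(spec, cohort, n_restarts=2, seed=1)
for sex in ("m", "f"):
    e = fit.estimates
    print(f"{sex.upper()}: A {100*e[f'a2_{sex}']:.0f}%  D {100*e[f'd2_{sex}']:.0f}%  "
          f"E {100*e[f'e2_{sex}']:.0f}%  H {100*e[f'H_{sex}']:.0f}%")
print("female H 95% CI:", tk.profile_ci(fit, "H_f"))
```

prints (examples/03_univariate_sex_limitation.py):

```
M: A 0%  D 47%  E 53%  H 47%
F: A 39%  D 14%  E 48%  H 52%
female H 95% CI: (49%, 55%)
```

The fit recovers the generating truth: broad-sense heritability ~45% in
men (all of it non-additive here, with A pinned at its zero boundary) and
~52% in women, the remainder unique-environmental.  The A/D split is far
less stable than their sum H — the expected behaviour when MZ and DZ
pairs are the only relative classes.

More narrative scripts live in `examples/` (frailty-index construction,
descriptive correlations, bivariate FI–BMI decomposition, moderation
curves, and the full study pipeline).  A thin CLI mirrors the library:
`twinkin simulate | validate | fi | fit-univariate | correlations |
fit-bivariate | fit-moderation | run`.

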