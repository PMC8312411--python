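"""Simulate a five-group twin cohort and summarize its structure.

The generator draws latent additive-genetic (A), dominance (D) and unique-
environment (E) components per pair with the classical cross-twin
correlations (MZ 1/1, DZ 1/2 and 1/4), applies sex-specific paths and age
trends, and demotes a fraction of pairs to singletons.
"""

import twinkin as tk

cfg = tk.default_study_config(n_pairs=1000)
cfg.seed = 1
cohort = tk.simulate_univariate(cfg)
cohort = tk.inject_missing(cohort, singleton_fraction=0.2, seed=2)

print(tk.validate_summary(cohort))
# Each zygosity group should show ~1000 rows with ~200 singleton pairs;
# singletons stay in the cohort because FIML uses their means and variances.
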