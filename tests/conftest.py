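import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

import twinkin as tk


@pytest.fixture(scope="session")
def small_univariate_cohort():
    """ADE cohort, all five groups, known truth, modest n."""
    fi = tk.TraitTruth(
        name="FI", family="ADE",
        shares={"M": (0.30, 0.15, 0.55), "F": (0.41, 0.11, 0.48)},
        total_var={"M": 1.0, "F": 1.3},
        mean={"M": 0.0, "F": 0.2}, age_slope=0.01)
    cfg = tk.GeneratorConfig(n_pairs=500, traits=[fi], r_fm=1.0, seed=101)
    return tk.simulate_univariate(cfg)


@pytest.fixture(scope="session")
def female_bivariate_cohort():
    """Correlated-factor ADE cohort (female same-sex groups only)."""
    x = tk.TraitTruth(name="X", family="ADE", shares={"F": (0.45, 0.10, 0.45)},
                      total_var={"F": 1.0}, mean={"F": 0.0}, age_slope=0.01)
    y = tk.TraitTruth(name="Y", family="ADE", shares={"F": (0.55, 0.10, 0.35)},
                      total_var={"F": 2.0}, mean={"F": 5.0}, age_slope=-0.02)
    cfg = tk.GeneratorConfig(
        n_pairs={"MZF": 1500, "DZF": 1500}, traits=[x, y],
        cross=tk.CrossTraitTruth(r_A=0.5, r_DC=0.3, r_E=0.2), seed=202)
    return tk.simulate_bivariate(cfg)
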