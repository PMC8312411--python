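"""Correlated-factor bivariate models: recovery, decomposition, selection."""

import numpy as np
import pytest

import twinkin as tk


@pytest.fixture(scope="module")
def fitted(female_bivariate_cohort):
    return tk.fit_bivariate(female_bivariate_cohort, ("X", "Y"), family="ADE",
                            sexes=("F",), n_restarts=2, seed=1)


def test_component_recovery(fitted):
    e = fitted.per_sex["F"]
    # generating truth: X (0.45, 0.10, 0.45), Y (0.55, 0.10, 0.35),
    # r_A=0.5, r_D=0.3, r_E=0.2 at 1500 pairs/group
    assert e["H_X"] == pytest.approx(0.55, abs=0.06)
    assert e["H_Y"] == pytest.approx(0.65, abs=0.06)
    rH_true = (np.sqrt(0.45 * 0.55) * 0.5 + np.sqrt(0.10 * 0.10) * 0.3) \
        / np.sqrt(0.55 * 0.65)
    assert e["r_H"] == pytest.approx(rH_true, abs=0.08)
    assert e["r_E"] == pytest.approx(0.2, abs=0.08)


def test_rp_reconstruction_matches_saturated(female_bivariate_cohort, fitted):
    """Implied phenotypic correlation agrees with the saturated estimate."""
    table = tk.fit_saturated(female_bivariate_cohort, ["X", "Y"], pooled=False)
    r_sat = np.mean([table.row("MZF")["r_pheno_X_Y"],
                     table.row("DZF")["r_pheno_X_Y"]])
    assert fitted.per_sex["F"]["r_P"] == pytest.approx(r_sat, abs=0.02)


def test_decomposition_shares_sum_to_one(fitted):
    d = tk.decompose_rp(fitted)["F"]
    assert d["defined"]
    total = d["genetic"] + d["common_env"] + d["unique_env"]
    assert total == pytest.approx(1.0, abs=1e-6)


def test_near_identical_traits_recover_unit_correlations():
    x = tk.TraitTruth(name="X", family="ADE", shares={"F": (0.5, 0.1, 0.4)},
                      total_var={"F": 1.0}, mean={"F": 0.0})
    cfg = tk.GeneratorConfig(n_pairs={"MZF": 1200, "DZF": 1200}, traits=[x],
                             seed=33)
    coh = tk.simulate_univariate(cfg)
    f = coh.frame.copy()
    rng = np.random.default_rng(1)
    for suf in ("_1", "_2"):   # tiny independent jitter keeps Sigma nonsingular
        f["Y" + suf] = f["X" + suf] + rng.normal(0, 0.03, len(f))
    coh2 = tk.Cohort(f, ["X", "Y"])
    est = tk.fit_bivariate(coh2, ("X", "Y"), family="ADE", sexes=("F",),
                           n_restarts=1, seed=2)
    e = est.per_sex["F"]
    assert e["r_P"] > 0.99
    assert e["r_H"] > 0.97
    assert e["r_E"] > 0.95


def test_zero_cross_correlations_flagged_undefined():
    x = tk.TraitTruth(name="X", shares={"F": (0.5, 0.1, 0.4)},
                      total_var={"F": 1.0}, mean={"F": 0.0})
    y = tk.TraitTruth(name="Y", shares={"F": (0.4, 0.1, 0.5)},
                      total_var={"F": 1.0}, mean={"F": 0.0})
    cfg = tk.GeneratorConfig(n_pairs={"MZF": 2000, "DZF": 2000},
                             traits=[x, y],
                             cross=tk.CrossTraitTruth(0, 0, 0), seed=34)
    coh = tk.simulate_bivariate(cfg)
    est = tk.fit_bivariate(coh, ("X", "Y"), family="ADE", sexes=("F",),
                           n_restarts=1, seed=3)
    e = est.per_sex["F"]
    assert abs(e["r_P"]) < 0.04
    # shares remain defined only when r_P is not numerically zero
    if not e["shares_defined"]:
        assert np.isnan(e["share_genetic"])


def test_single_source_limit_gives_unit_bivariate_heritability():
    """r_A = 1, r_E = 0: the phenotypic correlation is all genetic."""
    x = tk.TraitTruth(name="X", shares={"F": (0.6, 0.0, 0.4)},
                      total_var={"F": 1.0}, mean={"F": 0.0})
    y = tk.TraitTruth(name="Y", shares={"F": (0.6, 0.0, 0.4)},
                      total_var={"F": 1.0}, mean={"F": 0.0})
    cfg = tk.GeneratorConfig(n_pairs={"MZF": 3000, "DZF": 3000},
                             traits=[x, y],
                             cross=tk.CrossTraitTruth(1.0, 0.0, 0.0), seed=35)
    coh = tk.simulate_bivariate(cfg)
    est = tk.fit_bivariate(coh, ("X", "Y"), family="AE", sexes=("F",),
                           n_restarts=1, seed=4)
    e = est.per_sex["F"]
    assert e["r_P"] == pytest.approx(0.6, abs=0.04)     # = genetic share of var
    assert e["share_genetic"] == pytest.approx(1.0, abs=0.05)


def test_family_selection_prefers_generating_family(female_bivariate_cohort):
    report = tk.compare_bivariate_families(female_bivariate_cohort, ("X", "Y"),
                                           sexes=("F",), n_restarts=1, seed=5)
    assert report["best_by_aic"] == "ADE"
    assert report["models"]["ADE"]["AIC"] < report["models"]["AE"]["AIC"]
    # structured models do not reject against saturated on well-specified data
    assert report["models"]["ADE"]["lrt_vs_saturated"]["p"] > 0.01


def test_ace_generated_data_selects_ace():
    x = tk.TraitTruth(name="X", family="ACE", shares={"F": (0.35, 0.30, 0.35)},
                      total_var={"F": 1.0}, mean={"F": 0.0})
    y = tk.TraitTruth(name="Y", family="ACE", shares={"F": (0.30, 0.35, 0.35)},
                      total_var={"F": 1.0}, mean={"F": 0.0})
    cfg = tk.GeneratorConfig(n_pairs={"MZF": 2500, "DZF": 2500},
                             traits=[x, y],
                             cross=tk.CrossTraitTruth(0.4, 0.5, 0.2), seed=36)
    coh = tk.simulate_bivariate(cfg)
    report = tk.compare_bivariate_families(coh, ("X", "Y"), sexes=("F",),
                                           n_restarts=1, seed=6)
    assert report["best_by_aic"] == "ACE"


def test_nesting_fixed_zero_correlations(female_bivariate_cohort, fitted):
    """Forcing all cross-trait correlations to 0 cannot improve the fit."""
    from twinkin.bivariate import _BivariateProblem

    prob = _BivariateProblem(female_bivariate_cohort, ("X", "Y"), "ADE", "F")
    x = fitted.fits["F"].params.copy()
    for n in prob.param_names:
        if n.startswith("z_r"):
            x[prob.param_names.index(n)] = 0.0
    from twinkin import likelihood as lk
    best, _ = lk.multistart_minimize(
        lambda v: prob.objective(_fix_zero(v, prob)), x, prob.bounds,
        n_restarts=1, seed=0)
    assert best.fun >= fitted.minus2ll - 1e-6


def _fix_zero(v, prob):
    v = v.copy()
    for n in prob.param_names:
        if n.startswith("z_r"):
            v[prob.param_names.index(n)] = 0.0
    return v
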