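"""Likelihood engine: expected covariances, FIML, fitting, CIs, LRTs."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import twinkin as tk
from twinkin.core import (ModelSpec, UnivariateProblem, expected_pair_cov,
                          fiml_loglik)
from twinkin.data_model import Cohort


def _paths_from_shares(a2, d2, e2, V=1.0, sex="f"):
    return {f"a_{sex}": np.sqrt(a2 * V), f"d_{sex}": np.sqrt(d2 * V),
            f"e_{sex}": np.sqrt(e2 * V)}


@given(st.tuples(st.floats(0.01, 0.6), st.floats(0.0, 0.35),
                 st.floats(0.05, 0.6)))
def test_expected_cov_matches_falconer_algebra(shares):
    """MZ off-diagonal = a2+d2, DZ = a2/2+d2/4, exactly."""
    a2, d2, e2 = shares
    V = a2 + d2 + e2
    spec = ModelSpec(family="ADE", sex_limitation="quantitative")
    params = _paths_from_shares(a2, d2, e2)
    mz = expected_pair_cov(spec, "MZF", params)
    dz = expected_pair_cov(spec, "DZF", params)
    assert mz[0, 0] == pytest.approx(V, abs=1e-12)
    assert mz[0, 1] / mz[0, 0] == pytest.approx((a2 + d2) / V, abs=1e-10)
    assert dz[0, 1] / dz[0, 0] == pytest.approx((a2 / 2 + d2 / 4) / V, abs=1e-10)


def test_e_only_off_diagonal_zero():
    spec = ModelSpec(family="ADE")
    cov = expected_pair_cov(spec, "MZM", {"a_m": 0, "d_m": 0, "e_m": 1.0})
    assert cov[0, 1] == 0


def test_dzos_rfm_one_reduces_to_same_sex_formula():
    spec = ModelSpec(family="ADE", sex_limitation="full")
    p = {"a_m": 0.5, "d_m": 0.4, "e_m": 0.7,
         "a_f": 0.6, "d_f": 0.3, "e_f": 0.6, "r_fm": 1.0}
    cov = expected_pair_cov(spec, "DZOS", p)
    want = 0.5 * p["a_m"] * p["a_f"] + 0.25 * p["d_m"] * p["d_f"]
    assert cov[0, 1] == pytest.approx(want, abs=1e-12)
    # additive-only scope differs once r_fm < 1
    p["r_fm"] = 0.5
    joint = expected_pair_cov(spec, "DZOS", p)[0, 1]
    add_only = expected_pair_cov(
        ModelSpec(family="ADE", sex_limitation="full", r_fm_scope="additive"),
        "DZOS", p)[0, 1]
    assert joint == pytest.approx(0.5 * (0.5 * 0.5 * 0.6 + 0.25 * 0.4 * 0.3))
    assert add_only == pytest.approx(0.5 * 0.5 * 0.5 * 0.6 + 0.25 * 0.4 * 0.3)


def test_fiml_equals_per_pair_mvn_oracle(small_univariate_cohort):
    """Pattern-grouped FIML equals scipy's per-pair MVN density (1e-8)."""
    from scipy.stats import multivariate_normal

    spec = ModelSpec(trait="FI", family="ADE", sex_limitation="quantitative")
    prob = UnivariateProblem(spec, small_univariate_cohort)
    x = prob.x0
    ours = prob.objective(x)
    oracle = 0.0
    for g, gd in prob.groups.items():
        sigma = prob._group_sigma(x, g)
        mu = prob._mu_for_group(x, g, gd)
        for i in range(gd.n):
            obs = ~np.isnan(gd.y[i])
            oracle += -2 * multivariate_normal.logpdf(
                gd.y[i][obs], mu[i][obs], sigma[np.ix_(obs, obs)])
    assert ours == pytest.approx(oracle, abs=1e-8)


def test_duplicating_pairs_doubles_minus2ll(small_univariate_cohort):
    import pandas as pd

    spec = ModelSpec(trait="FI", family="ADE")
    base = fiml_loglik(spec, small_univariate_cohort, {})
    f = small_univariate_cohort.frame
    f2 = pd.concat([f, f.assign(pair_id=f["pair_id"] + "_dup")],
                   ignore_index=True)
    doubled = fiml_loglik(spec, Cohort(f2, small_univariate_cohort.phenotype_names), {})
    assert doubled == pytest.approx(2 * base, rel=1e-12)


def test_saturated_never_fits_worse_and_nesting(small_univariate_cohort):
    coh = small_univariate_cohort
    sat = tk.fit(ModelSpec(trait="FI", family="saturated"), coh, n_restarts=1)
    ade = tk.fit(ModelSpec(trait="FI", family="ADE", sex_limitation="full"),
                 coh, n_restarts=1)
    ae = tk.fit(ModelSpec(trait="FI", family="AE", sex_limitation="full"),
                coh, n_restarts=1)
    assert sat.minus2ll <= ade.minus2ll + 1e-6
    assert ade.minus2ll <= ae.minus2ll + 1e-6  # AE nested in ADE


def test_aic_identity(small_univariate_cohort):
    fr = tk.fit(ModelSpec(trait="FI", family="AE"), small_univariate_cohort,
                n_restarts=1)
    assert fr.aic == pytest.approx(fr.minus2ll + 2 * fr.n_params, abs=1e-12)


def test_shares_sum_to_one_and_h_in_unit_interval(small_univariate_cohort):
    fr = tk.fit(ModelSpec(trait="FI", family="ADE", sex_limitation="quantitative"),
                small_univariate_cohort, n_restarts=1)
    for s in ("m", "f"):
        total = (fr.estimates[f"a2_{s}"] + fr.estimates[f"d2_{s}"]
                 + fr.estimates[f"e2_{s}"])
        assert total == pytest.approx(1.0, abs=1e-8)
        assert 0.0 <= fr.estimates[f"H_{s}"] <= 1.0


def test_e_only_truth_recovers_null_heritability():
    tr = tk.TraitTruth(name="FI", family="ADE", shares={"F": (0.0, 0.0, 1.0)},
                       total_var={"F": 1.0}, mean={"F": 0.0})
    cfg = tk.GeneratorConfig(n_pairs={"MZF": 1500, "DZF": 1500},
                             traits=[tr], seed=77)
    coh = tk.simulate_univariate(cfg)
    fr = tk.fit(ModelSpec(trait="FI", family="ADE"), coh, n_restarts=2, seed=1)
    assert fr.estimates["H_f"] <= 0.05


def test_lrt_model_vs_itself_and_nesting_check(small_univariate_cohort):
    fr = tk.fit(ModelSpec(trait="FI", family="AE"), small_univariate_cohort,
                n_restarts=1)
    dchi, ddf, p = tk.lrt(fr, fr)
    assert (dchi, ddf, p) == (0.0, 0, 1.0)
    other = tk.fit(ModelSpec(trait="BMI", family="AE"), _bmi_cohort(),
                   n_restarts=1)
    with pytest.raises(ValueError, match="nested"):
        tk.lrt(fr, other)


def _bmi_cohort():
    tr = tk.TraitTruth(name="BMI", family="ADE", shares={"F": (0.4, 0.2, 0.4)},
                       total_var={"F": 9.0}, mean={"F": 25.0})
    return tk.simulate_univariate(
        tk.GeneratorConfig(n_pairs={"MZF": 200, "DZF": 200}, traits=[tr], seed=5))


def test_no_sex_difference_model_equates_h_not_variance(small_univariate_cohort):
    fr = tk.fit(ModelSpec(trait="FI", family="ADE", sex_limitation="none"),
                small_univariate_cohort, n_restarts=1)
    assert fr.estimates["H_m"] == pytest.approx(fr.estimates["H_f"], abs=1e-10)
    # total variances remain sex-specific (generated 1.0 vs 1.3)
    assert fr.estimates["V_f"] > fr.estimates["V_m"] * 1.1


def test_direct_symmetric_agrees_with_path_mode_interior_truth():
    tr = tk.TraitTruth(name="FI", family="ADE", shares={"F": (0.40, 0.15, 0.45)},
                       total_var={"F": 1.0}, mean={"F": 0.0})
    cfg = tk.GeneratorConfig(n_pairs={"MZF": 3000, "DZF": 3000}, traits=[tr],
                             seed=31)
    coh = tk.simulate_univariate(cfg)
    spec = ModelSpec(trait="FI", family="ADE", sex_limitation="quantitative")
    p = tk.fit(spec, coh, n_restarts=2, seed=0)
    d = tk.direct_symmetric_fit(spec, coh, n_restarts=2, seed=0)
    for k in ("a2_f", "d2_f", "e2_f"):
        assert d.estimates[k] == pytest.approx(p.estimates[k], abs=1e-4)


def test_direct_symmetric_straddles_zero_at_null_truth():
    """With a2 = 0 truth, direct estimates may go negative; their mean ~ 0."""
    tr = tk.TraitTruth(name="FI", family="AE", shares={"F": (0.0, 0.0, 1.0)},
                       total_var={"F": 1.0}, mean={"F": 0.0})
    vals = []
    for rep in range(10):
        cfg = tk.GeneratorConfig(n_pairs={"MZF": 400, "DZF": 400},
                                 traits=[tr], seed=500 + rep)
        coh = tk.simulate_univariate(cfg)
        fr = tk.direct_symmetric_fit(
            ModelSpec(trait="FI", family="AE", sex_limitation="quantitative"),
            coh, n_restarts=1, seed=rep)
        vals.append(fr.estimates["a2_f"])
    vals = np.array(vals)
    assert vals.min() < 0 < vals.max()
    assert abs(vals.mean()) < 0.05


def test_profile_ci_boundary_and_complement():
    """Zero truths give a zero lower bound; 1-upper(H) tracks lower(E)."""
    tr = tk.TraitTruth(name="FI", family="AE", shares={"F": (0.3, 0.0, 0.7)},
                       total_var={"F": 1.0}, mean={"F": 0.0})
    cfg = tk.GeneratorConfig(n_pairs={"MZF": 800, "DZF": 800}, traits=[tr],
                             seed=41)
    coh = tk.simulate_univariate(cfg)
    fr = tk.fit(ModelSpec(trait="FI", family="AE", sex_limitation="quantitative"),
                coh, n_restarts=1, seed=0)
    lo, hi = tk.profile_ci(fr, "H_f")
    assert lo < fr.estimates["H_f"] < hi
    # in an AE model e2 = 1 - H exactly, so the intervals are complements
    assert lo == pytest.approx(1 - (1 - lo), abs=1e-12)
    # boundary case: E-only truth pins the lower bound of H at 0
    tr0 = tk.TraitTruth(name="FI", family="AE", shares={"F": (0.0, 0.0, 1.0)},
                        total_var={"F": 1.0}, mean={"F": 0.0})
    coh0 = tk.simulate_univariate(
        tk.GeneratorConfig(n_pairs={"MZF": 400, "DZF": 400}, traits=[tr0],
                           seed=42))
    fr0 = tk.fit(ModelSpec(trait="FI", family="AE",
                           sex_limitation="quantitative"),
                 coh0, n_restarts=1, seed=0)
    lo0, hi0 = tk.profile_ci(fr0, "H_f")
    assert lo0 == 0.0
    assert hi0 < 0.2


def test_singletons_contribute_information(small_univariate_cohort):
    """Dropping singleton twins changes the likelihood (they are used)."""
    coh = tk.inject_missing(small_univariate_cohort, 0.3, 0.0, seed=9)
    spec = ModelSpec(trait="FI", family="ADE")
    with_single = fiml_loglik(spec, coh, {})
    f = coh.frame
    complete = Cohort(f[f.present1 & f.present2].reset_index(drop=True),
                      coh.phenotype_names)
    without = fiml_loglik(spec, complete, {})
    assert with_single > without  # more observations, larger -2LL


def test_variance_components_container():
    vc = tk.VarianceComponents(a2=0.41, dc2=0.11, e2=0.48,
                               total_variance=0.009, family="ADE")
    assert vc.H == pytest.approx(0.52)
    ace = tk.VarianceComponents(a2=0.41, dc2=0.11, e2=0.48,
                                total_variance=1.0, family="ACE")
    assert ace.H == pytest.approx(0.41)  # C does not count toward H
    with pytest.raises(ValueError, match="sum to 1"):
        tk.VarianceComponents(a2=0.5, dc2=0.4, e2=0.4, total_variance=1.0)


@given(st.tuples(st.floats(0.0, 0.6), st.floats(0.0, 0.35)))
def test_mz_similarity_never_below_dz(shares):
    """Nonnegative components imply MZ covariance >= DZ covariance."""
    a2, d2 = shares
    e2 = 1.0 - a2 - d2
    if e2 < 0.05:
        return
    spec = ModelSpec(family="ADE")
    params = _paths_from_shares(a2, d2, e2)
    mz = expected_pair_cov(spec, "MZF", params)[0, 1]
    dz = expected_pair_cov(spec, "DZF", params)[0, 1]
    assert mz >= dz - 1e-12


def test_quantitative_sexlim_lrt_detects_true_sex_difference():
    """With truly sex-specific H (45% vs 52%) at 3,000 pairs/group, the
    quantitative-vs-no-sex-difference LRT rejects decisively."""
    tr = tk.TraitTruth(name="FI", family="ADE",
                       shares={"M": (0.00, 0.45, 0.55), "F": (0.41, 0.11, 0.48)},
                       total_var={"M": 1.0, "F": 1.3},
                       mean={"M": 0.0, "F": 0.3}, age_slope=0.01)
    cfg = tk.GeneratorConfig(
        n_pairs={"MZM": 3000, "MZF": 3000, "DZM": 3000, "DZF": 3000},
        traits=[tr], seed=91)
    coh = tk.simulate_univariate(cfg)
    quant = tk.fit(ModelSpec(trait="FI", family="ADE",
                             sex_limitation="quantitative"),
                   coh, n_restarts=1, seed=0)
    none = tk.fit(ModelSpec(trait="FI", family="ADE", sex_limitation="none"),
                  coh, n_restarts=1, seed=0)
    dchi, ddf, p = tk.lrt(quant, none)
    assert ddf == 1
    assert p < 0.01
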