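"""G-by-E moderation: reduction to base models, curves, recovery, selection."""

import numpy as np
import pytest

import twinkin as tk
from twinkin.moderation import _FullBivariateProblem, ModerationSpec


def _moderated_cohort(beta_unique=(0, 0, 0), beta_common=(0, 0, 0),
                      n=2000, seed=21, abs_moderator=False):
    mod = tk.TraitTruth(name="M", family="ADE", shares={"F": (0.5, 0.19, 0.31)},
                        total_var={"F": 4.0}, mean={"F": 25.0})
    tr = tk.TraitTruth(name="T", family="ADE", shares={"F": (0.4, 0.1, 0.5)},
                       total_var={"F": 1.0}, mean={"F": 0.0})
    mt = tk.ModerationTruth(common0=(0.25, 0.05, 0.10),
                            unique0=(0.55, 0.25, 0.60),
                            beta_common=beta_common, beta_unique=beta_unique,
                            abs_moderator=abs_moderator)
    cfg = tk.GeneratorConfig(n_pairs={"MZF": n, "DZF": n}, traits=[tr, mod],
                             moderation=mt, seed=seed)
    return tk.simulate_moderated(cfg)


def test_unmoderated_full_model_matches_correlated_factor_likelihood():
    """With beta = 0 the full bivariate moderation model is a smooth
    reparameterization of the correlated-factor model: evaluating it at the
    converted parameters reproduces the correlated-factor -2LL."""
    coh = _moderated_cohort()
    base = tk.fit_bivariate(coh, ("M", "T"), family="ADE", sexes=("F",),
                            n_restarts=2, seed=1)
    fr = base.fits["F"]
    prob = _FullBivariateProblem(
        coh, ModerationSpec(trait="T", moderator="M", family="ADE",
                            moderated_paths=()), "F")
    # convert correlated-factor estimates to common/unique (Cholesky) paths
    e = fr.estimates

    def raw(trait, comp_share, V):
        return np.sqrt(e[f"{comp_share}_{trait}"] * e[f"V_{trait}"])

    aM, dM, eM = raw("M", "a2", "V"), raw("M", "d2", "V"), raw("M", "e2", "V")
    aT, dT, eT = raw("T", "a2", "V"), raw("T", "d2", "V"), raw("T", "e2", "V")
    rA, rD, rE = e["r_A"], e["r_D"], e["r_E"]
    x = np.zeros(len(prob.param_names))

    def seti(name, v):
        x[prob.param_names.index(name)] = v

    # means: correlated-factor model centres age identically
    names = dict(zip(fr.param_names, fr.params))
    seti("b0_m", names["b0_M"])
    seti("bage_m", names["bage1_M"])
    seti("b0_t", names["b0_T"])
    seti("bage_t", names["bage1_T"])
    for c, pM, pT, r in (("a", aM, aT, rA), ("d", dM, dT, rD), ("e", eM, eT, rE)):
        seti(f"{c}M", pM)
        seti(f"{c}C0", pT * r)
        seti(f"{c}U0", pT * np.sqrt(max(0.0, 1 - r ** 2)))
    assert prob.objective(x) == pytest.approx(fr.minus2ll, abs=1e-6)


def test_moderated_variance_proportions_sum_to_one():
    coh = _moderated_cohort(beta_unique=(0.1, 0, 0.1), n=800)
    mf = tk.fit_extended_univariate_moderation(coh, "T", "M", sexes=("F",),
                                               n_restarts=1, seed=2)
    cv = mf.curves["F"]
    props = (cv.abs_A + cv.abs_DC + cv.abs_E) / cv.total
    np.testing.assert_allclose(props, 1.0, atol=1e-8)
    assert np.all(cv.total > 0)


def test_grid_outside_observed_range_rejected():
    coh = _moderated_cohort(n=300)
    with pytest.raises(ValueError, match="outside the observed range"):
        tk.fit_extended_univariate_moderation(coh, "T", "M", sexes=("F",),
                                              grid=np.array([0.0, 60.0]),
                                              n_restarts=1)


def test_unique_e_moderation_recovered_with_flat_genetic_curve():
    coh = _moderated_cohort(beta_unique=(0.0, 0.0, 0.18), n=3000, seed=23)
    mf = tk.fit_extended_univariate_moderation(coh, "T", "M", sexes=("F",),
                                               n_restarts=2, seed=3)
    est = mf.fits["F"].estimates
    assert est["beta_e"] > 0.08          # sign and rough magnitude
    cv = mf.curves["F"]
    assert cv.abs_E[-1] > cv.abs_E[0]    # E(m) rises across the grid
    rel_a_change = abs(cv.abs_A[-1] - cv.abs_A[0]) / cv.abs_A.mean()
    rel_e_change = (cv.abs_E[-1] - cv.abs_E[0]) / cv.abs_E.mean()
    assert rel_e_change > rel_a_change


def test_u_shaped_heritability_from_abs_moderation():
    """Moderation on |m| makes genetic variance rise at both moderator
    extremes relative to the centre."""
    coh = _moderated_cohort(beta_unique=(0.35, 0.0, 0.0), n=3000, seed=24,
                            abs_moderator=True)
    mf = tk.fit_full_bivariate_moderation(
        coh, "T", "M", sexes=("F",), n_restarts=2, seed=4, grid_points=11)
    cv = mf.curves["F"]
    mid = len(cv.grid) // 2
    assert cv.prop_H[0] > cv.prop_H[mid]
    assert cv.prop_H[-1] > cv.prop_H[mid]


def test_missing_cotwin_moderator_downgrades_pair():
    coh = _moderated_cohort(n=300)
    f = coh.frame.copy()
    f.loc[f.index[:40], "M_2"] = np.nan
    coh2 = tk.Cohort(f, coh.phenotype_names)
    with pytest.warns(UserWarning, match="downgraded"):
        tk.fit_extended_univariate_moderation(coh2, "T", "M", sexes=("F",),
                                              n_restarts=1, seed=5)


def test_sequence_selects_full_bivariate_under_covariance_moderation():
    coh = _moderated_cohort(beta_common=(0.12, 0.0, 0.0),
                            beta_unique=(0.0, 0.0, 0.12), n=2500, seed=25)
    seq = tk.moderation_test_sequence(coh, "T", "M", sexes=("F",), seed=6)
    assert seq["recommendation"] == "full_bivariate"


def test_sequence_selects_extended_univariate_under_unique_only_moderation():
    coh = _moderated_cohort(beta_unique=(0.15, 0.0, 0.15), n=2500, seed=26)
    seq = tk.moderation_test_sequence(coh, "T", "M", sexes=("F",), seed=7)
    assert seq["any_unique_moderation"]
    assert seq["recommendation"] == "extended_univariate"
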