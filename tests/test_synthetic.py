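"""Generator correctness: cross-twin structure, determinism, missingness."""

import numpy as np
import pytest

import twinkin as tk
from twinkin.synthetic import simulate_multitrait


def _trait(shares, var=1.0, family="ADE", name="X", sexes=("F",)):
    return tk.TraitTruth(name=name, family=family,
                         shares={s: shares for s in sexes},
                         total_var={s: var for s in sexes},
                         mean={s: 0.0 for s in sexes})


def _icc(cohort, group, trait="X"):
    sub = cohort.frame[cohort.frame.zygosity_group == group]
    return float(np.corrcoef(sub[trait + "_1"], sub[trait + "_2"])[0, 1])


def test_e_only_gives_uncorrelated_twins():
    cfg = tk.GeneratorConfig(n_pairs={"MZF": 4000}, traits=[_trait((0, 0, 1))],
                             seed=1)
    r = _icc(tk.simulate_univariate(cfg), "MZF")
    assert abs(r) < 3 / np.sqrt(4000)


def test_pure_additive_mz_correlation_is_one():
    cfg = tk.GeneratorConfig(n_pairs={"MZF": 500},
                             traits=[_trait((1 - 1e-9, 0, 1e-9))], seed=2)
    assert _icc(tk.simulate_univariate(cfg), "MZF") > 0.999


def test_falconer_intraclass_at_female_study_shares():
    """Shares A=0.41, D=0.11, E=0.48 imply rMZ=0.52 and rDZ=0.2325."""
    tr = tk.TraitTruth(name="X", family="ADE", shares={"F": (0.41, 0.11, 0.48)},
                       total_var={"F": 1.0}, mean={"F": 0.0})
    cfg = tk.GeneratorConfig(n_pairs={"MZF": 10000, "DZF": 10000},
                             traits=[tr], seed=3)
    coh = tk.simulate_univariate(cfg)
    tol = 4 / np.sqrt(10000)
    assert _icc(coh, "MZF") == pytest.approx(0.41 + 0.11, abs=tol)
    assert _icc(coh, "DZF") == pytest.approx(0.41 / 2 + 0.11 / 4, abs=tol)


def test_cross_twin_component_structure_all_groups():
    """Sample within-pair covariance matches the implied value per group."""
    tr = tk.TraitTruth(name="X", family="ADE",
                       shares={"M": (0.3, 0.2, 0.5), "F": (0.5, 0.1, 0.4)},
                       total_var={"M": 1.0, "F": 1.0},
                       mean={"M": 0.0, "F": 0.0})
    n = 8000
    cfg = tk.GeneratorConfig(n_pairs=n, traits=[tr], r_fm=0.6, seed=4)
    coh = tk.simulate_univariate(cfg)
    tol = 4 / np.sqrt(n)
    expected = {
        "MZM": 0.5, "MZF": 0.6,
        "DZM": 0.3 / 2 + 0.2 / 4, "DZF": 0.5 / 2 + 0.1 / 4,
        # OS: r_fm * (1/2 a_m a_f + 1/4 d_m d_f), joint convention
        "DZOS": 0.6 * (0.5 * np.sqrt(0.3 * 0.5) + 0.25 * np.sqrt(0.2 * 0.1)),
    }
    for g, want in expected.items():
        sub = coh.frame[coh.frame.zygosity_group == g]
        got = float(np.cov(sub["X_1"], sub["X_2"])[0, 1])
        assert got == pytest.approx(want, abs=tol), g


def test_identical_seed_identical_cohort(tmp_path):
    cfg = tk.GeneratorConfig(n_pairs=200, traits=[_trait((0.4, 0.1, 0.5),
                                                         sexes=("M", "F"))],
                             seed=7, singleton_fraction=0.2)
    a, b = tk.simulate_univariate(cfg), tk.simulate_univariate(cfg)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    tk.write_cohort(a, p1)
    tk.write_cohort(b, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_bivariate_zero_cross_correlations():
    cfg = tk.GeneratorConfig(
        n_pairs={"MZF": 4000}, traits=[_trait((0.4, 0.1, 0.5)),
                                       _trait((0.5, 0.1, 0.4), name="Y")],
        cross=tk.CrossTraitTruth(0.0, 0.0, 0.0), seed=8)
    coh = tk.simulate_bivariate(cfg)
    r = np.corrcoef(coh.frame["X_1"], coh.frame["Y_1"])[0, 1]
    assert abs(r) < 3 / np.sqrt(4000)


def test_bivariate_phenotypic_correlation_algebra():
    """r_P = sum over components of sqrt(share_X) sqrt(share_Y) r_comp."""
    sx, sy = (0.52, 0.0, 0.48), (0.69, 0.0, 0.31)
    rA, rE = 0.26, 0.0604
    cfg = tk.GeneratorConfig(
        n_pairs={"MZF": 8000, "DZF": 8000},
        traits=[_trait(sx), _trait(sy, var=3.0, name="Y")],
        cross=tk.CrossTraitTruth(rA, 0.0, rE), seed=9)
    coh = tk.simulate_bivariate(cfg)
    want = np.sqrt(sx[0] * sy[0]) * rA + np.sqrt(sx[2] * sy[2]) * rE
    got = np.corrcoef(coh.frame["X_1"], coh.frame["Y_1"])[0, 1]
    assert got == pytest.approx(want, abs=4 / np.sqrt(16000))


def test_invalid_correlations_rejected():
    with pytest.raises(ValueError):
        tk.CrossTraitTruth(r_A=1.2)
    with pytest.raises(ValueError):
        tk.GeneratorConfig(n_pairs=10, traits=[_trait((0.4, 0.1, 0.5))], r_fm=1.5)
    with pytest.raises(ValueError, match="sum to 1"):
        tk.TraitTruth(name="X", shares={"F": (0.5, 0.5, 0.5)},
                      total_var={"F": 1.0}, mean={"F": 0.0})


def test_moderated_reduces_to_bivariate_when_betas_zero():
    """With beta=0 the trait variance is flat across moderator tertiles."""
    mod = _trait((0.5, 0.2, 0.3), var=4.0, name="M")
    tr = _trait((0.4, 0.1, 0.5), name="T")
    mt = tk.ModerationTruth(common0=(0.3, 0.1, 0.1), unique0=(0.5, 0.2, 0.6),
                            beta_common=(0, 0, 0), beta_unique=(0, 0, 0))
    cfg = tk.GeneratorConfig(n_pairs={"MZF": 6000}, traits=[tr, mod],
                             moderation=mt, seed=10)
    coh = tk.simulate_moderated(cfg)
    m = coh.frame["M_1"].to_numpy()
    t = coh.frame["T_1"].to_numpy()
    qs = np.quantile(m, [1 / 3, 2 / 3])
    v = [t[m <= qs[0]].var(), t[(m > qs[0]) & (m <= qs[1])].var(),
         t[m > qs[1]].var()]
    assert max(v) / min(v) < 1.2


def test_moderated_unique_e_variance_increases_across_tertiles():
    mod = _trait((0.5, 0.2, 0.3), var=4.0, name="M")
    tr = _trait((0.4, 0.1, 0.5), name="T")
    mt = tk.ModerationTruth(common0=(0.3, 0.1, 0.1), unique0=(0.5, 0.2, 0.6),
                            beta_unique=(0.0, 0.0, 0.25))
    cfg = tk.GeneratorConfig(n_pairs={"MZF": 6000}, traits=[tr, mod],
                             moderation=mt, seed=11)
    coh = tk.simulate_moderated(cfg)
    m = coh.frame["M_1"].to_numpy()
    t = coh.frame["T_1"].to_numpy()
    qs = np.quantile(m, [1 / 3, 2 / 3])
    v = [t[m <= qs[0]].var(), t[(m > qs[0]) & (m <= qs[1])].var(),
         t[m > qs[1]].var()]
    assert v[0] < v[1] < v[2]


def test_moderated_unique_a_raises_mz_similarity_at_high_moderator():
    mod = _trait((0.5, 0.2, 0.3), var=4.0, name="M")
    tr = _trait((0.4, 0.1, 0.5), name="T")
    mt = tk.ModerationTruth(common0=(0.2, 0.0, 0.1), unique0=(0.4, 0.0, 0.7),
                            beta_unique=(0.3, 0.0, 0.0))
    cfg = tk.GeneratorConfig(n_pairs={"MZF": 8000}, traits=[tr, mod],
                             moderation=mt, seed=12)
    coh = tk.simulate_moderated(cfg)
    f = coh.frame
    pair_mean_m = (f["M_1"] + f["M_2"]) / 2
    top = pair_mean_m > pair_mean_m.quantile(2 / 3)
    bottom = pair_mean_m < pair_mean_m.quantile(1 / 3)
    r_top = np.corrcoef(f.loc[top, "T_1"], f.loc[top, "T_2"])[0, 1]
    r_bottom = np.corrcoef(f.loc[bottom, "T_1"], f.loc[bottom, "T_2"])[0, 1]
    assert r_top > r_bottom


def test_inject_missing_rates():
    cfg = tk.GeneratorConfig(n_pairs={"MZF": 1000},
                             traits=[_trait((0.4, 0.1, 0.5))], seed=13)
    coh = tk.simulate_univariate(cfg)
    assert tk.inject_missing(coh, 0.0, 0.0, seed=0) == coh
    out = tk.inject_missing(coh, 0.25, 0.0, seed=1)
    n_single = (~(out.frame["present1"] & out.frame["present2"])).sum()
    assert 200 <= n_single <= 300  # binomial(1000, 0.25) within ~3 sd
    assert np.isnan(
        out.frame.loc[~out.frame["present1"], "X_1"].to_numpy()).all()


def test_item_missingness_triggers_exclusion_rule():
    """30% item missingness makes P(excluded) = P(Binom(44,.3) > 8.8) > 0."""
    from scipy.stats import binom

    fi = tk.TraitTruth(name="FI", shares={"F": (0.4, 0.1, 0.5)},
                       total_var={"F": 1.0}, mean={"F": 0.0})
    cfg = tk.GeneratorConfig(n_pairs={"MZF": 800}, traits=[fi], seed=14)
    coh = tk.simulate_deficits(tk.simulate_univariate(cfg), tk.DeficitConfig(),
                               seed=14)
    coh = tk.inject_missing(coh, 0.0, 0.3, seed=15)
    coh = tk.add_fi_to_cohort(coh, fi_name="FIdx")
    frac_excluded = np.isnan(coh.frame["FIdx_1"].to_numpy()).mean()
    p_theory = binom.sf(8, 44, 0.3)  # more than 8.8 of 44 -> at least 9
    assert frac_excluded == pytest.approx(p_theory, abs=0.08)
    assert frac_excluded > 0


def test_multitrait_cross_family_dc_rejected():
    ade = _trait((0.4, 0.1, 0.5), name="X")
    ace = tk.TraitTruth(name="Z", family="ACE", shares={"F": (0.4, 0.2, 0.4)},
                        total_var={"F": 1.0}, mean={"F": 0.0})
    cfg = tk.GeneratorConfig(n_pairs={"MZF": 10}, traits=[ade, ace], seed=1)
    with pytest.raises(ValueError, match="cross-family"):
        simulate_multitrait(cfg, cross={"DC": np.array([[1, 0.3], [0.3, 1]])})
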