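"""Frailty-index construction, exclusion rule, and the sqrt transform."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import twinkin as tk
from twinkin.frailty import compute_fi, sqrt_transform


def _items(n_endorsed, n_missing=0, n_items=44):
    v = np.zeros(n_items)
    v[:n_endorsed] = 1.0
    if n_missing:
        v[-n_missing:] = np.nan
    return v


def test_five_deficits_fixed_denominator_worked_example():
    """Five endorsed deficits of 44 give FI = 5/44 = 0.11 at two decimals."""
    fi = compute_fi(_items(5), denominator="fixed")[0]
    assert round(fi, 2) == 0.11


@pytest.mark.parametrize("n_endorsed,expected", [(0, 0.0), (44, 1.0), (11, 0.25)])
def test_fixed_denominator_exact_values(n_endorsed, expected):
    assert compute_fi(_items(n_endorsed), denominator="fixed")[0] == expected


def test_exclusion_rule_is_strict_over_20_percent():
    # 10 of 44 missing: 22.7% > 20% -> excluded
    assert np.isnan(compute_fi(_items(3, n_missing=10))[0])
    # 8 of 44 missing: 18.2% <= 20% -> retained
    assert not np.isnan(compute_fi(_items(3, n_missing=8))[0])
    # exactly 20% missing of a 10-item index is retained (strict inequality)
    v = _items(2, n_missing=2, n_items=10)
    assert not np.isnan(compute_fi(v)[0])


def test_denominator_modes_agree_without_missingness():
    mat = np.vstack([_items(k) for k in range(0, 45, 4)])
    np.testing.assert_allclose(compute_fi(mat, denominator="fixed"),
                               compute_fi(mat, denominator="nonmissing"))


def test_nonmissing_denominator_rescales():
    v = _items(5, n_missing=4)  # 5 endorsed of 40 answered
    assert compute_fi(v)[0] == pytest.approx(5 / 40)
    assert compute_fi(v, denominator="fixed")[0] == pytest.approx(5 / 44)


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError, match="empty"):
        compute_fi(np.empty((1, 0)))
    with pytest.raises(ValueError, match="0, 1 or missing"):
        compute_fi(np.array([0.0, 2.0, 1.0]))
    with pytest.raises(ValueError, match="non-negative"):
        sqrt_transform(np.array([-0.1]))


@given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
def test_fi_monotone_and_order_invariant(bits):
    v = np.array(bits, dtype=float)
    fi = compute_fi(v, denominator="fixed")[0]
    rng = np.random.default_rng(0)
    fi_shuffled = compute_fi(rng.permutation(v), denominator="fixed")[0]
    assert fi == pytest.approx(fi_shuffled)
    w = v.copy()
    if (w == 0).any():
        w[np.argmin(w)] = 1.0
        assert compute_fi(w, denominator="fixed")[0] >= fi


@pytest.mark.parametrize("x,expected", [(0.0, 0.0), (1.0, 1.0), (0.25, 0.5)])
def test_sqrt_transform_values(x, expected):
    assert sqrt_transform(np.array([x]))[0] == pytest.approx(expected)


def test_sqrt_reduces_skew_on_synthetic_cohort():
    fi = tk.TraitTruth(name="FI", family="ADE",
                       shares={"F": (0.41, 0.11, 0.48)}, total_var={"F": 1.0},
                       mean={"F": 0.0})
    cfg = tk.GeneratorConfig(n_pairs={"MZF": 2000, "DZF": 2000},
                             traits=[fi], seed=9)
    cohort = tk.simulate_univariate(cfg)
    cohort = tk.simulate_deficits(cohort, tk.DeficitConfig(), seed=9)
    cohort = tk.add_fi_to_cohort(cohort, fi_name="FIdx")
    vals = np.concatenate([cohort.frame["FIdx_1"], cohort.frame["FIdx_2"]])
    raw = tk.fi_descriptives(vals)
    trans = tk.fi_descriptives(sqrt_transform(vals))
    assert raw["skewness"] > 0
    assert abs(trans["skewness"]) < abs(raw["skewness"])
    assert 0 <= np.nanmin(vals) and np.nanmax(vals) <= 1


def test_deficit_threshold_calibration_hits_target_median():
    """Default thresholds give a cohort median FI near the 5-of-44 benchmark."""
    fi = tk.TraitTruth(name="FI", family="ADE",
                       shares={"F": (0.41, 0.11, 0.48)}, total_var={"F": 1.0},
                       mean={"F": 0.0})
    cfg = tk.GeneratorConfig(n_pairs={"MZF": 3000, "DZF": 3000},
                             traits=[fi], seed=21)
    cohort = tk.simulate_deficits(tk.simulate_univariate(cfg),
                                  tk.DeficitConfig(), seed=22)
    cohort = tk.add_fi_to_cohort(cohort, fi_name="FIdx")
    vals = np.concatenate([cohort.frame["FIdx_1"], cohort.frame["FIdx_2"]])
    assert tk.fi_descriptives(vals)["median"] == pytest.approx(5 / 44, abs=0.02)


def test_all_or_none_thresholds():
    cfg = tk.DeficitConfig(n_items=10, endorse_probs=np.full(10, 1e-12))
    fi = tk.TraitTruth(name="FI", shares={"F": (0.4, 0.1, 0.5)},
                       total_var={"F": 1.0}, mean={"F": 0.0})
    gc = tk.GeneratorConfig(n_pairs={"MZF": 50}, traits=[fi], seed=1)
    coh = tk.simulate_deficits(tk.simulate_univariate(gc), cfg, seed=2)
    coh = tk.add_fi_to_cohort(coh, fi_name="FIdx")
    assert (coh.frame[["FIdx_1", "FIdx_2"]].to_numpy() == 0).all()
    cfg_hi = tk.DeficitConfig(n_items=10, endorse_probs=np.full(10, 1 - 1e-12))
    coh = tk.simulate_deficits(tk.simulate_univariate(gc), cfg_hi, seed=2)
    coh = tk.add_fi_to_cohort(coh, fi_name="FIdx")
    assert (coh.frame[["FIdx_1", "FIdx_2"]].to_numpy() == 1).all()
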