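import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from fluxstress.stats import (
    aggregate,
    anova_suite,
    cohens_d,
    levene_test,
    one_way_dunnett,
    slope_test,
    t_test,
    tukey_fences,
    two_way_tukey,
)


def quartiles_oracle(values):
    """Independent linearly-interpolated quartiles (explicit index arithmetic)."""
    v = sorted(values)
    n = len(v)

    def q(p):
        pos = p * (n - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        return v[lo] + frac * (v[hi] - v[lo])

    return q(0.25), q(0.75)


def test_fences_flag_the_textbook_outlier():
    """[1,2,3,100]: Q1=1.75, Q3=27.25 by interpolation, so only 100 falls
    outside [Q1-1.5 IQR, Q3+1.5 IQR]."""
    q1, q3 = quartiles_oracle([1, 2, 3, 100])
    assert (q1, q3) == (1.75, 27.25)
    np.testing.assert_array_equal(tukey_fences([1, 2, 3, 100]),
                                  [True, True, True, False])


def test_fences_constant_and_short_lists_are_all_inliers():
    assert tukey_fences([5, 5, 5, 5, 5]).all()
    assert tukey_fences([1, 100, 10000]).all()  # guard: < 4 values


@given(st.lists(st.sampled_from([0.0, 1.0, 3.0, 7.5, 20.0]), min_size=4, max_size=8),
       st.sampled_from([1.0, 1.5, 3.0]))
def test_fences_match_quantile_oracle(values, k):
    q1, q3 = quartiles_oracle(values)
    iqr = q3 - q1
    expected = [(q1 - k * iqr <= x <= q3 + k * iqr) for x in values]
    np.testing.assert_array_equal(tukey_fences(values, k), expected)


def _df(groups):
    rows = []
    for (exp, cond), vals in groups.items():
        for v in vals:
            rows.append({"experiment_id": exp, "condition": cond, "value": v})
    return pd.DataFrame(rows)


def test_aggregate_identical_wells_has_zero_sem():
    d = _df({(f"E{i}", "c"): [7.0, 7.0, 7.0] for i in range(1, 5)})
    out = aggregate(d, "value", ["condition"])
    assert out.loc[0, "mean"] == 7.0
    assert out.loc[0, "sem"] == 0.0
    assert out.loc[0, "n"] == 4


def test_aggregate_sem_matches_sd_over_sqrt_n():
    d = _df({("E1", "c"): [50.0], ("E2", "c"): [52.0],
             ("E3", "c"): [54.0], ("E4", "c"): [56.0]})
    out = aggregate(d, "value", ["condition"], k_technical=None, k_experimental=None)
    assert out.loc[0, "mean"] == 53.0
    assert out.loc[0, "sem"] == pytest.approx(np.std([50, 52, 54, 56], ddof=1) / 2)


def test_aggregate_experimental_fences_drop_an_experiment():
    d = _df({("E1", "c"): [50.0], ("E2", "c"): [51.0],
             ("E3", "c"): [52.0], ("E4", "c"): [500.0]})
    out = aggregate(d, "value", ["condition"], k_technical=None, k_experimental=1.5)
    assert out.loc[0, "n"] == 3
    assert out.loc[0, "mean"] == pytest.approx(51.0)


def test_cohens_d_pooled_formula():
    a = 10 + np.array([-1, 1, -1, 1]) * np.sqrt(3)  # mean 10, SD 2
    b = 5 + np.array([-1, 1, -1, 1]) * np.sqrt(3)   # mean 5, SD 2
    eff = cohens_d(a, b)
    assert eff.d == pytest.approx(2.5)
    assert eff.ci_low < eff.d < eff.ci_high


def test_cohens_d_identical_groups():
    eff = cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert eff.d == 0.0
    assert eff.ci_low < 0 < eff.ci_high


def test_slope_test_exact_line():
    x = np.array([0, 6, 12, 24, 48, 72], float)
    res = slope_test(x, 2 * x)
    assert res.slope["estimate"] == pytest.approx(2.0)
    assert res.slope["r2"] == pytest.approx(1.0)
    assert res.df == (1, 4)


def test_slope_test_needs_three_distinct_x():
    with pytest.raises(ValueError):
        slope_test([1, 1, 2, 2], [0, 1, 2, 3])


def test_t_test_identical_groups_p_near_one():
    res = t_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert res.p == pytest.approx(1.0)


def test_omnibus_detects_a_ten_sigma_shift():
    rng = np.random.default_rng(0)
    d = pd.DataFrame({
        "condition": ["a"] * 6 + ["b"] * 6 + ["c"] * 6,
        "value": np.r_[rng.normal(0, 1, 6), rng.normal(0, 1, 6), rng.normal(10, 1, 6)],
    })
    res = one_way_dunnett(d, "value", "condition", "a", rng=rng)
    omnibus = res[0]
    assert omnibus.test == "ONE_WAY_ANOVA"
    assert omnibus.p < 1e-4


def test_dunnett_all_equal_means_is_null():
    """k=5 doses vs control with identical group means: every Dunnett
    statistic is 0 and every adjusted p is ~1."""
    pattern = [-1.0, 0.0, 1.0]
    d = pd.DataFrame({
        "condition": np.repeat([f"g{i}" for i in range(6)], 3),
        "value": pattern * 6,
    })
    res = one_way_dunnett(d, "value", "condition", "g0", rng=np.random.default_rng(1))
    adj = [r.p for r in res if r.test == "DUNNETT"]
    assert len(adj) == 5
    assert min(adj) > 0.9


def test_dunnett_adjusted_p_dominates_unadjusted_t():
    rng = np.random.default_rng(7)
    d = pd.DataFrame({
        "condition": np.repeat(["ctrl", "a", "b", "c"], 4),
        "value": rng.normal(0, 1, 16),
    })
    res = one_way_dunnett(d, "value", "condition", "ctrl", rng=rng)
    ctrl = d[d["condition"] == "ctrl"]["value"]
    for r in res:
        if r.test != "DUNNETT":
            continue
        g = r.label.split()[-3]
        raw = sps.ttest_ind(d[d["condition"] == g]["value"], ctrl).pvalue
        assert r.p >= raw - 1e-3  # Monte-Carlo tolerance of the adjusted p


def test_levene_flags_heteroscedastic_groups():
    rng = np.random.default_rng(3)
    res = levene_test([rng.normal(0, 1, 30), rng.normal(0, 6, 30)])
    assert res.p < 0.05


def test_two_way_tukey_terms_and_pairs():
    rng = np.random.default_rng(5)
    d = pd.DataFrame({
        "arm": np.repeat(["x", "y"], 8),
        "group": list(np.tile(np.repeat(["c", "t"], 4), 2)),
        "value": rng.normal(0, 1, 16),
    })
    d.loc[(d["arm"] == "y") & (d["group"] == "t"), "value"] += 25
    res = two_way_tukey(d, "value", "arm", "group")
    kinds = {r.test for r in res}
    assert kinds == {"TWO_WAY_ANOVA", "TUKEY_HSD"}
    pairs = [r for r in res if r.test == "TUKEY_HSD"]
    assert len(pairs) == 6  # 4 cells -> 6 pairwise contrasts
    shifted = [r for r in pairs if "y|t" in r.label]
    assert all(r.p < 0.05 for r in shifted)


def test_anova_suite_appends_levene_and_validates_design():
    d = pd.DataFrame({"condition": np.repeat(["a", "b"], 4),
                      "value": [1.0, 2, 3, 4, 2, 3, 4, 5], "arm": "x"})
    res = anova_suite(d, "ONE_WAY_DUNNETT", group="condition", control="a",
                      rng=np.random.default_rng(0))
    assert res[-1].test == "LEVENE"
    with pytest.raises(ValueError, match="design"):
        anova_suite(d, "THREE_WAY")
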