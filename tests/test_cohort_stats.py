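"""Representativeness tests, location tables, stability calls, outcome fits."""

import math

import numpy as np
import pandas as pd
import pytest

import deltamethyl as dm


# ---------------------------------------------------------------------------
# One-sample tests
# ---------------------------------------------------------------------------

def test_prop_test_null_value_gives_unit_p():
    z, p = dm.one_sample_prop_test(100, 200, 0.5)
    assert z == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("x, n, p0", [(0, 10, 0.0), (0, 10, 1.0)])
def test_prop_test_degenerate_p0_rejected(x, n, p0):
    with pytest.raises(ValueError):
        dm.one_sample_prop_test(x, n, p0)


def test_prop_test_p_matches_erfc_reference(rng):
    """Two-sided normal p agrees with the closed-form erfc expression to 1e-10."""
    for _ in range(100):
        n = int(rng.integers(20, 2000))
        x = int(rng.integers(0, n + 1))
        p0 = float(rng.uniform(0.05, 0.95))
        z, p = dm.one_sample_prop_test(x, n, p0)
        assert p == pytest.approx(math.erfc(abs(z) / math.sqrt(2.0)), abs=1e-10)


def test_gof_chisq_exact_proportions_give_zero():
    chi2, df, p = dm.gof_chisq([50, 30, 20], [0.5, 0.3, 0.2])
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert (df, p) == (2, pytest.approx(1.0))


def test_gof_chisq_two_categories_equals_squared_z(rng):
    """Internal consistency: chi-square on a 2-vector equals the z statistic squared."""
    for _ in range(100):
        n = int(rng.integers(20, 500))
        x = int(rng.integers(1, n))
        p0 = float(rng.uniform(0.1, 0.9))
        z, _ = dm.one_sample_prop_test(x, n, p0)
        chi2, df, _ = dm.gof_chisq([x, n - x], [p0, 1 - p0])
        assert chi2 == pytest.approx(z**2, abs=1e-10)
        assert df == 1


def test_gof_chisq_p_matches_gamma_reference(rng):
    """Chi-square survival probabilities agree with an independent series evaluation."""
    from sympy import Float, Rational, lowergamma, gamma as sym_gamma

    for _ in range(20):
        k = int(rng.integers(2, 6))
        props = rng.dirichlet(np.ones(k))
        obs = rng.integers(5, 100, size=k).astype(float)
        chi2, df, p = dm.gof_chisq(obs, props)
        ref = 1 - lowergamma(Rational(df, 2), Float(chi2) / 2) / sym_gamma(Rational(df, 2))
        assert p == pytest.approx(float(ref), abs=1e-10)


def test_one_sample_t_reference_values():
    t, p = dm.one_sample_t(10.0, 2.0, 16, 9.0)
    assert t == pytest.approx(2.0, abs=1e-12)
    from scipy import stats

    assert p == pytest.approx(2 * stats.t.sf(2.0, 15), abs=1e-12)
    t2, _ = dm.one_sample_t(15.3, 14.1, 201, 14.4)
    assert t2 == pytest.approx(0.905, abs=0.005)
    t3, p3 = dm.one_sample_t(5.0, 1.0, 30, 5.0)
    assert (t3, p3) == (0.0, pytest.approx(1.0))


def test_one_sample_t_zero_sd_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        dm.one_sample_t(1.0, 0.0, 10, 0.0)


def test_representativeness_report_mixed_tests():
    margins = pd.DataFrame(
        [
            {"variable": "gender", "test": "prop_z", "x": 116, "n": 201, "X": 748, "N": 1456},
            {"variable": "birth_order", "test": "chisq_gof", "x": 80, "n": 188, "X": 491, "N": 1152},
            {"variable": "birth_order", "test": "chisq_gof", "x": 60, "n": 188, "X": 394, "N": 1152},
            {"variable": "birth_order", "test": "chisq_gof", "x": 48, "n": 188, "X": 267, "N": 1152},
            {"variable": "bf_weeks", "test": "t_one_sample", "mean": 15.3, "sd": 14.1, "n": 201, "mu0": 14.4},
        ]
    )
    out = dm.representativeness_report(margins).set_index("variable")
    assert round(out.loc["gender", "p"], 2) == 0.07
    assert round(out.loc["birth_order", "p"], 2) == 0.69
    assert 0 < out.loc["bf_weeks", "p"] <= 1


# ---------------------------------------------------------------------------
# Location enrichment
# ---------------------------------------------------------------------------

def _annotation(mapping):
    return pd.DataFrame(
        {"cpg_id": list(mapping), "location": [mapping[k] for k in mapping]}
    )


def test_location_enrichment_single_category_degenerates_to_null():
    ann = _annotation({f"c{i}": "Body" for i in range(6)})
    lists = {"EBF": ["c0", "c1"], "EFF": ["c2", "c3"], "Mixed": ["c4", "c5"]}
    tables = dm.location_enrichment(lists, ann)
    assert tables["tss"]["chi2"] == 0.0 and tables["tss"]["p"] == 1.0


def test_location_enrichment_hand_pearson_value():
    """Counts (13,14 | 17,31 | 0,12) give chi-square ~8.57 on 2 df."""
    mapping = {}
    lists = {"EBF": [], "EFF": [], "Mixed": []}
    for mode, n_in, n_out in (("EBF", 13, 14), ("EFF", 17, 31), ("Mixed", 0, 12)):
        for i in range(n_in):
            cid = f"{mode}_in{i}"
            mapping[cid] = "TSS200"
            lists[mode].append(cid)
        for i in range(n_out):
            cid = f"{mode}_out{i}"
            mapping[cid] = "Body"
            lists[mode].append(cid)
    tables = dm.location_enrichment(lists, _annotation(mapping))
    assert tables["tss"]["chi2"] == pytest.approx(8.567, abs=0.01)
    assert tables["tss"]["df"] == 2


def test_location_enrichment_multi_label_counts_both():
    ann = _annotation({"a": "Body;TSS1500", "b": "3'UTR", "c": "TSS200", "d": "Body"})
    tables = dm.location_enrichment({"EBF": ["a", "b"], "EFF": ["c", "d"]}, ann)
    # 'a' counts as both TSS and Body
    assert tables["tss"]["counts"].loc["in", "EBF"] == 1
    assert tables["body"]["counts"].loc["in", "EBF"] == 1


def test_location_enrichment_needs_two_modes_and_known_labels():
    ann = _annotation({"a": "Body"})
    with pytest.raises(ValueError):
        dm.location_enrichment({"EBF": ["a"]}, ann)
    with pytest.raises(ValueError, match="unknown"):
        dm.location_enrichment({"EBF": ["a"], "EFF": ["b"]}, _annotation({"a": "Promoter", "b": "Body"}))


# ---------------------------------------------------------------------------
# Stability classifier
# ---------------------------------------------------------------------------

def _m_matrix(arr, prefix="cg"):
    p, n = arr.shape
    return dm.MethylationMatrix(
        pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(p)], columns=[f"S{j}" for j in range(n)]),
        "M",
    )


def test_identical_timepoints_are_all_stable(rng):
    m10 = _m_matrix(rng.normal(size=(20, 30)))
    calls = dm.stability_classify(m10, m10)
    assert (calls["call"] == "stable").all()


def test_stability_agrees_with_mixed_model_oracle(rng):
    """Closed-form REML equals statsmodels MixedLM on effect size; p agrees closely."""
    import warnings

    from statsmodels.regression.mixed_linear_model import MixedLM

    n = 60
    base = rng.normal(size=(4, n))
    m10 = _m_matrix(base + rng.normal(0, 0.3, size=(4, n)))
    m18 = _m_matrix(base + rng.normal(0, 0.3, size=(4, n)) + 0.1)
    calls = dm.stability_classify(m10, m18).set_index("cpg_id")
    age = np.concatenate([np.zeros(n), np.ones(n)])
    groups = np.concatenate([np.arange(n)] * 2)
    exog = np.column_stack([np.ones(2 * n), age])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cpg in calls.index:
            y = np.concatenate([m10.values.loc[cpg].to_numpy(), m18.values.loc[cpg].to_numpy()])
            fit = MixedLM(y, exog, groups=groups).fit(reml=True)
            assert calls.loc[cpg, "effect"] == pytest.approx(fit.params[1], abs=1e-8)
            # same Wald statistic; p-values differ only by t(n-1) vs normal reference
            ours_t = calls.loc[cpg, "effect"] / (fit.bse[1])
            assert ours_t == pytest.approx(fit.tvalues[1], abs=1e-6)
            from scipy import stats

            p_t_reference = 2 * stats.t.sf(abs(fit.tvalues[1]), n - 1)
            assert calls.loc[cpg, "p"] == pytest.approx(p_t_reference, abs=1e-5)


def test_stability_type_one_and_power(rng):
    base = rng.normal(size=(300, 100))
    m10 = _m_matrix(base + rng.normal(0, 0.2, size=(300, 100)))
    m18_null = _m_matrix(base + rng.normal(0, 0.2, size=(300, 100)))
    rate = (dm.stability_classify(m10, m18_null)["call"] == "dynamic").mean()
    assert 0.04 < rate < 0.17  # ~alpha=0.1 with binomial noise at 300 CpGs
    m18_shift = _m_matrix(m18_null.values.to_numpy() + 1.0)
    power = (dm.stability_classify(m10, m18_shift)["call"] == "dynamic").mean()
    assert power == 1.0


def test_stability_requires_three_paired_subjects(rng):
    m10 = _m_matrix(rng.normal(size=(3, 2)))
    with pytest.raises(ValueError):
        dm.stability_classify(m10, m10)


# ---------------------------------------------------------------------------
# Outcome regressions per feeding group
# ---------------------------------------------------------------------------

def test_outcome_regression_constant_and_perfect_fits(rng):
    idx = pd.Index([f"S{i}" for i in range(30)])
    delta = pd.Series(rng.normal(size=30), index=idx)
    modes = pd.Series(["EBF"] * 10 + ["EFF"] * 10 + ["Mixed"] * 10, index=idx)

    flat = dm.outcome_by_feeding_regression(delta, pd.Series(3.0, index=idx), modes)
    np.testing.assert_allclose(flat["slope"], 0.0, atol=1e-10)

    linear = dm.outcome_by_feeding_regression(delta, 2.0 * delta + 1.0, modes)
    np.testing.assert_allclose(linear["slope"], 2.0, atol=1e-10)
    np.testing.assert_allclose(linear["intercept"], 1.0, atol=1e-10)


def test_outcome_regression_hand_four_points():
    idx = pd.Index(["a", "b", "c", "d"])
    x = pd.Series([0.0, 1.0, 2.0, 3.0], index=idx)
    y = pd.Series([1.0, 3.0, 4.0, 8.0], index=idx)
    modes = pd.Series(["EBF"] * 4, index=idx)
    out = dm.outcome_by_feeding_regression(x, y, modes)
    slope_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    assert out.loc[0, "slope"] == pytest.approx(slope_hand, abs=1e-10)
    assert out.loc[0, "intercept"] == pytest.approx(y.mean() - slope_hand * x.mean(), abs=1e-10)


def test_outcome_regression_small_group_skipped_with_warning(rng):
    idx = pd.Index([f"S{i}" for i in range(5)])
    delta = pd.Series(rng.normal(size=5), index=idx)
    modes = pd.Series(["EBF", "EBF", "EBF", "EBF", "EFF"], index=idx)
    with pytest.warns(UserWarning, match="fewer"):
        out = dm.outcome_by_feeding_regression(delta, delta * 1.0, modes)
    assert list(out["mode"]) == ["EBF"]
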