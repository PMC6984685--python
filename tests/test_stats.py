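"""First-principles inference vs independent reference implementations."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from genediv import (
    benjamini_hochberg,
    env_regression_grid,
    levene_test,
    linear_regression,
    mann_whitney,
    pearson_correlation_matrix,
    welch_t_test,
)
from genediv.errors import DegenerateInputError, InputError, ParameterError
from genediv.stats import pearson_correlation, profile_variability_levene


def test_welch_hand_computed_example():
    res = welch_t_test([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
    assert res.statistic == pytest.approx(-1.8974, abs=1e-4)
    assert res.df == pytest.approx(5.882, abs=1e-3)


def test_welch_identical_groups():
    res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == 0.0
    assert res.pvalue == pytest.approx(1.0)


def test_welch_df_reduces_to_pooled_for_equal_variances_and_sizes():
    x = np.array([1.0, 2.0, 4.0, 7.0])
    res = welch_t_test(x, x + 3.0)  # identical variances, identical n
    assert res.df == pytest.approx(len(x) * 2 - 2)
    assert min(len(x), len(x)) - 1 <= res.df <= 2 * len(x) - 2


def test_welch_degenerate_input():
    with pytest.raises(DegenerateInputError):
        welch_t_test([2.0, 2.0], [2.0, 2.0])


def test_welch_matches_scipy_on_random_inputs():
    rng = np.random.default_rng(7)
    for _ in range(200):
        x = rng.normal(0, rng.uniform(0.5, 3), rng.integers(3, 20))
        y = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 3), rng.integers(3, 20))
        mine = welch_t_test(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-6)
        assert mine.pvalue == pytest.approx(ref.pvalue, abs=1e-6)


def test_levene_matches_scipy_oracle():
    a, b = [1.0, 2.0, 3.0, 4.0], [10.0, 20.0, 30.0, 40.0]
    mine = levene_test([a, b], center="mean")
    ref = sps.levene(a, b, center="mean")
    assert mine.statistic == pytest.approx(ref.statistic, abs=1e-6)
    assert mine.pvalue == pytest.approx(ref.pvalue, abs=1e-6)
    rng = np.random.default_rng(8)
    for _ in range(200):
        groups = [
            rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 4), rng.integers(3, 15))
            for _ in range(rng.integers(2, 5))
        ]
        for center in ("mean", "median"):
            mine = levene_test(groups, center=center)
            ref = sps.levene(*groups, center=center)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-6)
            assert mine.pvalue == pytest.approx(ref.pvalue, abs=1e-6)


def test_levene_symmetric_groups_give_unit_pvalue():
    res = levene_test([[1.0, 2.0, 3.0], [11.0, 12.0, 13.0]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.pvalue == pytest.approx(1.0)


def test_levene_validation():
    with pytest.raises(InputError):
        levene_test([[1.0, 2.0]])
    with pytest.raises(DegenerateInputError):
        levene_test([[1.0, 1.0], [5.0, 5.0]])
    with pytest.raises(ParameterError):
        levene_test([[1.0, 2.0], [3.0, 4.0]], center="mode")


def _brute_exact_mwu_p(x, y):
    """Two-sided exact p by enumerating all rank assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u_min = min(u_obs, n1 * len(y) - u_obs)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        r = ranks[list(combo)].sum()
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us)
    return min(1.0, 2.0 * np.mean(us <= u_min))


def test_mann_whitney_exact_example_and_path_selection():
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.pvalue == pytest.approx(0.1)  # 2/20 arrangements
    assert res.name == "mann_whitney_exact"
    # a 6-early vs 5-late seasonal design takes the exact path (30 <= 400, no ties)
    rng = np.random.default_rng(9)
    res65 = mann_whitney(rng.normal(size=6), rng.normal(size=5))
    assert res65.name == "mann_whitney_exact"


def test_mann_whitney_exact_matches_enumeration():
    rng = np.random.default_rng(10)
    for n1, n2 in [(2, 3), (4, 4), (5, 3), (6, 5)]:
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        assert mann_whitney(x, y).pvalue == pytest.approx(
            _brute_exact_mwu_p(x, y), abs=1e-12
        )


def test_mann_whitney_identical_multisets():
    x = [1.0, 2.0, 3.0, 4.0]
    res = mann_whitney(x, list(x))
    assert res.pvalue >= 0.99
    with pytest.raises(ParameterError, match="ties"):
        mann_whitney(x, list(x), exact=True)


def test_mann_whitney_normal_path_matches_scipy():
    rng = np.random.default_rng(11)
    for _ in range(100):
        x = rng.normal(size=rng.integers(21, 40))
        y = rng.normal(0.3, 1.0, size=rng.integers(21, 40))
        mine = mann_whitney(x, y, exact=False)
        ref = sps.mannwhitneyu(x, y, method="asymptotic")
        assert mine.pvalue == pytest.approx(ref.pvalue, abs=1e-6)


def test_regression_perfect_fit_and_errors():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = linear_regression(x, 2 * x)
    assert res.slope == pytest.approx(2.0)
    assert res.r2 == pytest.approx(1.0)
    with pytest.raises(DegenerateInputError):
        linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(InputError):
        linear_regression([1.0, 2.0], [1.0, 2.0])


def test_regression_matches_scipy_on_random_inputs():
    rng = np.random.default_rng(12)
    for _ in range(200):
        x = rng.normal(size=rng.integers(5, 30))
        y = 0.5 * x + rng.normal(size=x.size)
        mine = linear_regression(x, y)
        ref = sps.linregress(x, y)
        assert mine.slope == pytest.approx(ref.slope, abs=1e-9)
        assert mine.intercept == pytest.approx(ref.intercept, abs=1e-9)
        assert mine.r2 == pytest.approx(ref.rvalue**2, abs=1e-9)
        assert mine.pvalue == pytest.approx(ref.pvalue, abs=1e-6)


def test_regression_r2_invariant_to_affine_rescaling_of_x():
    rng = np.random.default_rng(13)
    x = rng.normal(size=15)
    y = 1.2 * x + rng.normal(size=15)
    base = linear_regression(x, y).r2
    assert linear_regression(3.5 * x - 7.0, y).r2 == pytest.approx(base, abs=1e-12)


def test_pearson_matrix_properties():
    rng = np.random.default_rng(14)
    x = rng.normal(size=20)
    table = pd.DataFrame({"x": x, "neg": -x, "z": rng.normal(size=20), "c": 1.0})
    corr = pearson_correlation_matrix(table)
    assert np.allclose(np.diag(corr), 1.0)
    assert corr.loc["x", "neg"] == pytest.approx(-1.0)
    assert np.isnan(corr.loc["x", "c"])  # constant column flagged undefined
    ref = np.corrcoef(x, table["z"])[0, 1]
    assert corr.loc["x", "z"] == pytest.approx(ref, abs=1e-9)
    assert pearson_correlation(x, x) == pytest.approx(1.0)


def test_benjamini_hochberg_against_reference():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(15)
    p = rng.uniform(size=40)
    mine = benjamini_hochberg(p)
    ref = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(mine, ref, atol=1e-12)


def test_regression_grid_planted_effect_and_shapes():
    rng = np.random.default_rng(16)
    env = pd.DataFrame(
        {
            "cl_mgL": np.r_[np.full(6, 4.0), np.full(5, 12.0)] + rng.normal(0, 0.5, 11),
            "temp_c": rng.normal(15, 3, 11),
        },
        index=[f"S{i:02d}" for i in range(11)],
    )
    metrics = pd.DataFrame(
        {
            "planted": 0.1 * env["cl_mgL"] + rng.normal(0, 0.05, 11),
            "noise": rng.normal(size=11),
        }
    )
    grid = env_regression_grid(metrics, env)
    assert len(grid) == 4
    cell = grid[(grid.metric == "planted") & (grid.covariate == "cl_mgL")].iloc[0]
    assert cell["p"] < 0.05 and cell["significant"]
    empty = env_regression_grid(metrics[[]], env)
    assert empty.empty
    with pytest.raises(InputError, match="sample index"):
        env_regression_grid(metrics.iloc[:-1], env)


def test_profile_variability_levene_orders_turnover_regimes():
    rng = np.random.default_rng(17)
    quiet = pd.DataFrame(0.25 + 0.001 * rng.normal(size=(4, 10)))
    noisy = pd.DataFrame(0.25 + 0.08 * rng.normal(size=(4, 10)))
    table = profile_variability_levene({"stable": quiet, "turnover": noisy})
    assert len(table) == 1
    assert table["p"].iloc[0] < 0.001
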