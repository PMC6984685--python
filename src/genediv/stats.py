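"""Classical inference implemented from first principles.

Test statistics, degrees of freedom and effect summaries are computed
directly from their defining formulas; only the tail probabilities come
from scipy's t, F and normal distributions.  Provided: Welch's unequal-
variance t-test, Levene's test for homogeneity of variance (mean- or
median-centered), the Mann–Whitney–Wilcoxon rank-sum test with an exact
small-sample path, ordinary least-squares regression with R² and an
F-based p-value, pairwise Pearson correlation, and the metric x covariate
regression grid used to screen environmental drivers.

Two-sided p-values throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, InputError, ParameterError


@dataclass
class TestResult:
    name: str
    statistic: float
    pvalue: float
    df: float | tuple[float, float] | None
    group_sizes: tuple[int, ...]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    fstat: float
    pvalue: float
    n: int


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise InputError(f"{name} is empty")
    if not np.isfinite(arr).all():
        raise InputError(f"{name} contains non-finite values")
    return arr


def welch_t_test(x, y) -> TestResult:
    """Welch's unequal-variance two-sample t-test.

    t = (x̄−ȳ)/√(s²ₓ/n₁+s²ᵧ/n₂) with Welch–Satterthwaite degrees of
    freedom; reduces to the pooled-variance df n₁+n₂−2 when variances and
    group sizes are equal.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise InputError("each group needs >= 2 values")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise DegenerateInputError("zero variance in both groups")
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult("welch_t", float(t), float(min(p, 1.0)), float(df), (n1, n2))


def levene_test(groups: Sequence, center: str = "mean") -> TestResult:
    """Levene's test for equality of variances across >= 2 groups.

    One-way ANOVA F-statistic on absolute deviations from the group center
    (mean for the classic test, median for the Brown–Forsythe variant).
    """
    if center not in ("mean", "median"):
        raise ParameterError(f"center must be 'mean' or 'median', got {center!r}")
    gs = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(gs) < 2:
        raise InputError("need >= 2 groups")
    if any(g.size < 2 for g in gs):
        raise InputError("each group needs >= 2 values")
    cfun = np.mean if center == "mean" else np.median
    z = [np.abs(g - cfun(g)) for g in gs]
    k = len(z)
    ns = np.array([g.size for g in z])
    N = int(ns.sum())
    zbar_g = np.array([g.mean() for g in z])
    zbar = np.concatenate(z).mean()
    num = (ns * (zbar_g - zbar) ** 2).sum() / (k - 1)
    den = sum(((g - m) ** 2).sum() for g, m in zip(z, zbar_g)) / (N - k)
    if den == 0:
        raise DegenerateInputError("all deviations are zero in every group")
    w = num / den
    p = sps.f.sf(w, k - 1, N - k)
    return TestResult(
        f"levene_{center}", float(w), float(p), (float(k - 1), float(N - k)),
        tuple(int(n) for n in ns),
    )


def _mwu_exact_cdf_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank arrangements giving each U value, by the standard
    recurrence f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u)."""
    max_u = n1 * n2
    # table[i][j] = array over u of counts for group sizes i, j
    prev = [np.ones(1) for _ in range(n2 + 1)]
    for i in range(1, n1 + 1):
        cur = [np.zeros(i * j + 1) for j in range(n2 + 1)]
        cur[0][0] = 1.0
        for j in range(1, n2 + 1):
            arr = np.zeros(i * j + 1)
            # f(i-1, j, u-j)
            arr[j:] += prev[j]
            # f(i, j-1, u)
            arr[: i * (j - 1) + 1] += cur[j - 1]
            cur[j] = arr
        prev = cur
    counts = prev[n2]
    assert counts.size == max_u + 1
    return counts


def mann_whitney(x, y, exact: bool | None = None) -> TestResult:
    """Mann–Whitney–Wilcoxon rank-sum test.

    The exact two-sided p-value (enumeration of the U distribution) is used
    when there are no ties and n₁·n₂ <= 400, otherwise the normal
    approximation with tie correction and continuity correction.  Set
    ``exact`` to force a path (forcing exact with ties is an error).
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    if exact is None:
        exact = (not has_ties) and n1 * n2 <= 400
    if exact:
        if has_ties:
            raise ParameterError("exact Mann–Whitney p-value is undefined with ties")
        counts = _mwu_exact_cdf_counts(n1, n2)
        total = counts.sum()
        u_min = min(u1, u2)
        p = 2.0 * counts[: int(u_min) + 1].sum() / total
        p = min(p, 1.0)
        name = "mann_whitney_exact"
    else:
        N = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
        sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term)
        if sigma2 <= 0:
            raise DegenerateInputError("all values tied; Mann–Whitney undefined")
        z = (max(u1, u2) - mu - 0.5) / np.sqrt(sigma2)
        p = min(1.0, 2.0 * sps.norm.sf(z))
        name = "mann_whitney_normal"
    return TestResult(name, float(u1), float(p), None, (n1, n2))


def linear_regression(x, y) -> RegressionResult:
    """Simple ordinary least-squares regression of y on x.

    R² = 1 − SSE/SST; the p-value comes from F(1, n−2).  A constant
    response yields slope 0, R² 0 and p 1 (nothing to explain); a constant
    covariate is an error.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size != y.size:
        raise InputError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise InputError("need n >= 3")
    sxx = ((x - x.mean()) ** 2).sum()
    if sxx == 0:
        raise DegenerateInputError("constant covariate x")
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        return RegressionResult(0.0, float(y.mean()), 0.0, float("nan"), 1.0, n)
    sse = ((y - (intercept + slope * x)) ** 2).sum()
    r2 = 1.0 - sse / sst
    r2 = min(max(r2, 0.0), 1.0)
    if sse == 0:
        return RegressionResult(float(slope), float(intercept), 1.0, float("inf"), 0.0, n)
    f = (n - 2) * r2 / (1.0 - r2)
    p = sps.f.sf(f, 1, n - 2)
    return RegressionResult(float(slope), float(intercept), float(r2), float(f), float(p), n)


def pearson_correlation(x, y) -> float:
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size != y.size or x.size < 3:
        raise InputError("need equal-length vectors with n >= 3")
    dx, dy = x - x.mean(), y - y.mean()
    denom = np.sqrt((dx**2).sum() * (dy**2).sum())
    if denom == 0:
        return float("nan")
    return float((dx * dy).sum() / denom)


def pearson_correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r between numeric columns; diagonal 1.

    Entries involving a constant column are NaN (undefined) — screen these
    before treating covariates as independent.
    """
    cols = list(table.columns)
    if table.shape[0] < 3:
        raise InputError("need >= 3 rows")
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            r = pearson_correlation(table[a], table[b])
            out.loc[a, b] = out.loc[b, a] = r
    return out


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (FDR)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def env_regression_grid(
    metrics: pd.DataFrame,
    env: pd.DataFrame,
    alpha: float = 0.05,
    marginal_alpha: float = 0.10,
) -> pd.DataFrame:
    """OLS of every metric column on every environmental covariate column.

    Rows of the two tables must share the same sample index.  Returns a
    long-format table (metric, covariate, slope, intercept, r2, f, p, n,
    p_adj, significant, marginal); ``p_adj`` is Benjamini–Hochberg across
    the whole grid, reported alongside the raw p-values.
    """
    if len(metrics.columns) == 0:
        return pd.DataFrame(
            columns=[
                "metric", "covariate", "slope", "intercept", "r2", "f", "p",
                "n", "p_adj", "significant", "marginal",
            ]
        )
    if not metrics.index.equals(env.index):
        raise InputError("metrics and env tables must share the same sample index")
    rows = []
    for m in metrics.columns:
        for c in env.columns:
            res = linear_regression(env[c], metrics[m])
            rows.append(
                {
                    "metric": m,
                    "covariate": c,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "r2": res.r2,
                    "f": res.fstat,
                    "p": res.pvalue,
                    "n": res.n,
                }
            )
    grid = pd.DataFrame(rows)
    grid["p_adj"] = benjamini_hochberg(grid["p"].to_numpy())
    grid["significant"] = grid["p"] < alpha
    grid["marginal"] = (grid["p"] >= alpha) & (grid["p"] < marginal_alpha)
    return grid


def profile_variability_levene(
    rel_matrices: Mapping[str, pd.DataFrame], center: str = "mean"
) -> pd.DataFrame:
    """Between-family comparison of phylotype profile variability.

    For each gene family the observations entering Levene's test are the
    phylotype-centered relative abundances (each phylotype's temporal
    series minus its own temporal mean), so the test compares the average
    magnitude of temporal abundance deviation between families.  Returns
    the pairwise test table.
    """
    def centered(df: pd.DataFrame) -> np.ndarray:
        v = df.to_numpy(dtype=float)
        return (v - v.mean(axis=1, keepdims=True)).ravel()

    names = sorted(rel_matrices)
    obs = {name: centered(rel_matrices[name]) for name in names}
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = levene_test([obs[a], obs[b]], center=center)
            rows.append(
                {"family_a": a, "family_b": b, "W": res.statistic, "p": res.pvalue}
            )
    return pd.DataFrame(rows)
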