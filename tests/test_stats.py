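"""Agreement statistics vs independent brute-force formula oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from thrombodens.errors import DegenerateInputError
from thrombodens.stats import (
    bland_altman,
    fit_ols,
    icc,
    kruskal_wallis,
    paired_t,
    pearson,
)


# ---------------------------------------------------------------------------
# Brute-force oracles (kept deliberately independent of the implementations)
# ---------------------------------------------------------------------------


def ols_oracle(x, y):
    """Normal equations + textbook standard errors and t-quantile CIs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (n - 2)
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tq = sps.t.ppf(0.975, n - 2)
    return {
        "intercept": beta[0],
        "slope": beta[1],
        "intercept_ci": (beta[0] - tq * se[0], beta[0] + tq * se[0]),
        "slope_ci": (beta[1] - tq * se[1], beta[1] + tq * se[1]),
    }


def pearson_oracle(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def paired_t_oracle(a, b):
    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return t, p


def icc_a1_oracle(a, b):
    """ICC(A,1) from an explicitly constructed two-way ANOVA table."""
    data = np.column_stack([a, b]).astype(float)
    n, k = data.shape
    grand = data.mean()
    ms_rows = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((data - data.mean(axis=1, keepdims=True) - data.mean(axis=0) + grand) ** 2).sum()
    ms_err = sse / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    )


def kruskal_oracle(groups):
    """Hand-ranked H with tie correction."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    r = np.arange(1, len(pooled) + 1, dtype=float)
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = r[i : j + 1].mean()
        i = j + 1
    N = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        rg = ranks[start : start + len(g)]
        h += rg.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    return h / tie


FIXTURES_XY = [
    ([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0],
     [2.1, 3.9, 6.2, 8.1, 9.8, 12.3, 13.9, 16.2, 18.1, 19.7]),
    ([3.2, 1.4, 4.1, 5.9, 2.6, 5.3, 5.8, 9.7, 9.3, 2.3],
     [31.0, 41.0, 59.0, 26.0, 53.0, 58.0, 97.0, 93.0, 23.0, 84.0]),
    ([10.0, 20.0, 30.0, 40.0, 50.0, 60.0],
     [55.0, 48.0, 47.0, 41.0, 37.0, 29.0]),
]


class TestOLS:
    def test_exact_line(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2 * v + 1 for v in x]
        fit = fit_ols(x, y)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("x,y", FIXTURES_XY)
    def test_matches_normal_equations_oracle(self, x, y):
        fit = fit_ols(x, y)
        ref = ols_oracle(x, y)
        assert fit.slope == pytest.approx(ref["slope"], abs=1e-9)
        assert fit.intercept == pytest.approx(ref["intercept"], abs=1e-9)
        assert fit.slope_ci == pytest.approx(ref["slope_ci"], abs=1e-9)
        assert fit.intercept_ci == pytest.approx(ref["intercept_ci"], abs=1e-9)

    def test_null_simulation_slope_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        assert abs(fit_ols(x, y).slope) < 0.05

    def test_r2_equals_pcc_squared(self):
        x, y = FIXTURES_XY[1]
        fit = fit_ols(x, y)
        assert fit.r2 == pytest.approx(fit.pcc**2, abs=1e-9)

    def test_pcc_equals_pearson(self):
        x, y = FIXTURES_XY[1]
        assert fit_ols(x, y).pcc == pytest.approx(pearson(x, y)[0], abs=1e-12)

    def test_constant_regressor_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_ols([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestPearson:
    def test_perfect_correlation(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert pearson(x, x)[0] == pytest.approx(1.0, abs=1e-12)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pearson(x, -x)[0] == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("x,y", FIXTURES_XY)
    def test_matches_covariance_oracle(self, x, y):
        assert pearson(x, y)[0] == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPairedT:
    def test_identical_pairs(self):
        a = [1.0, 2.0, 3.0]
        md, t, p = paired_t(a, a)
        assert (md, t, p) == (0.0, 0.0, 1.0)

    def test_matches_hand_computation(self):
        a = [51.0, 48.2, 55.1, 44.0, 49.9, 61.3, 39.7, 52.6]
        b = [43.4, 47.1, 50.0, 40.2, 45.5, 58.8, 35.1, 49.0]
        md, t, p = paired_t(a, b)
        t_ref, p_ref = paired_t_oracle(a, b)
        assert t == pytest.approx(t_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, abs=1e-9)
        assert md == pytest.approx(np.mean(np.asarray(a) - np.asarray(b)), abs=1e-12)

    def test_power_for_true_shift(self):
        rng = np.random.default_rng(1)
        a = rng.normal(50, 5, 50)
        b = a + 5 + rng.normal(0, 1, 50)
        assert paired_t(a, b)[2] < 0.05


class TestBlandAltman:
    def test_identical(self):
        rep = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.mean_difference == 0.0
        assert rep.loa_lower == 0.0 and rep.loa_upper == 0.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        a = rng.normal(50, 8, 10)
        b = a + rng.normal(2, 3, 10)
        rep = bland_altman(a, b)
        d = a - b
        assert rep.mean_difference == pytest.approx(d.mean(), abs=1e-12)
        assert rep.loa_lower == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-12)
        assert rep.loa_upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(50, 8, 12)
        b = a + rng.normal(0, 3, 12)
        base = bland_altman(a, b)
        shifted = bland_altman(a, b + 5.0)
        assert shifted.mean_difference == pytest.approx(base.mean_difference - 5.0, abs=1e-9)
        assert shifted.sd_difference == pytest.approx(base.sd_difference, abs=1e-9)

    def test_limits_cover_most_differences(self):
        rng = np.random.default_rng(4)
        a = rng.normal(50, 8, 1000)
        b = a + rng.normal(1, 4, 1000)
        rep = bland_altman(a, b)
        d = a - b
        frac = np.mean((d >= rep.loa_lower) & (d <= rep.loa_upper))
        assert frac >= 0.90


class TestICC:
    def test_perfect_agreement(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert icc(a, a).icc_value == pytest.approx(1.0, abs=1e-12)

    def test_matches_anova_oracle(self):
        a = [51.0, 48.2, 55.1, 44.0, 49.9, 61.3]
        b = [49.5, 50.1, 52.8, 46.2, 47.0, 59.9]
        rep = icc(a, b, model="A-1")
        assert rep.icc_value == pytest.approx(icc_a1_oracle(a, b), abs=1e-9)
        assert rep.icc_model == "A-1"

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        a = [51.0, 48.2, 55.1, 44.0, 49.9, 61.3, 41.2, 47.8]
        b = [49.5, 50.1, 52.8, 46.2, 47.0, 59.9, 44.4, 45.1]
        df = pd.DataFrame(
            {
                "targets": list(range(8)) * 2,
                "raters": ["r1"] * 8 + ["r2"] * 8,
                "ratings": a + b,
            }
        )
        ref = pingouin.intraclass_corr(df, "targets", "raters", "ratings")
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc(a, b, model="A-1").icc_value == pytest.approx(icc2, abs=1e-6)

    def test_shuffled_near_zero(self):
        rng = np.random.default_rng(5)
        a = rng.normal(50, 10, 100)
        b = rng.permutation(a)
        assert abs(icc(a, b).icc_value) < 0.2

    def test_common_shift_invariance(self):
        a = np.array([51.0, 48.2, 55.1, 44.0, 49.9])
        b = np.array([49.5, 50.1, 52.8, 46.2, 47.0])
        base = icc(a, b).icc_value
        shifted = icc(a + 7.0, b + 7.0).icc_value
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_zero_between_subject_variance(self):
        with pytest.raises(DegenerateInputError):
            icc([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])


class TestKruskalWallis:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        h, p = kruskal_wallis([g, list(g)])
        assert h == pytest.approx(0.0, abs=1e-9)
        assert p > 0.9

    def test_matches_hand_ranked_oracle_with_ties(self):
        groups = [
            [40.0, 42.0, 42.0, 45.0],
            [44.0, 42.0, 47.0, 49.0, 50.0],
            [52.0, 50.0, 55.0],
        ]
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(kruskal_oracle(groups), abs=1e-9)

    def test_power_for_shifted_groups(self):
        rng = np.random.default_rng(6)
        g1 = rng.normal(40, 5, 30)
        g2 = rng.normal(50, 5, 30)
        assert kruskal_wallis([g1, g2])[1] < 0.05

    def test_all_identical_rejected(self):
        with pytest.raises(DegenerateInputError):
            kruskal_wallis([[3.0, 3.0], [3.0, 3.0]])
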