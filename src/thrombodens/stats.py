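"""Agreement and association statistics.

Implements the comparison machinery between manual ROI measurements and
entire-thrombus density descriptors: simple OLS with t-based confidence
intervals, Pearson correlation, paired t-test, Bland-Altman limits of
agreement, two-way intraclass correlation, and the Kruskal-Wallis
rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError

__all__ = [
    "RegressionFit",
    "AgreementReport",
    "fit_ols",
    "pearson",
    "paired_t",
    "bland_altman",
    "icc",
    "kruskal_wallis",
]


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    slope_ci: tuple
    intercept_ci: tuple
    pcc: float
    r2: float
    p_value: float
    n: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci": list(self.slope_ci),
            "intercept_ci": list(self.intercept_ci),
            "pcc": self.pcc,
            "r2": self.r2,
            "p": self.p_value,
            "n": self.n,
        }


@dataclass
class AgreementReport:
    n: int
    mean_difference: Optional[float] = None
    sd_difference: Optional[float] = None
    loa_lower: Optional[float] = None
    loa_upper: Optional[float] = None
    icc_value: Optional[float] = None
    icc_model: Optional[str] = None

    def as_dict(self) -> dict:
        out = {"n": self.n}
        if self.mean_difference is not None:
            out.update(
                mean_difference=self.mean_difference,
                sd_difference=self.sd_difference,
                loa_lower=self.loa_lower,
                loa_upper=self.loa_upper,
            )
        if self.icc_value is not None:
            out.update(icc=self.icc_value, icc_model=self.icc_model)
        return out


def _clean_xy(x, y, min_n):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    return x, y


def fit_ols(x: Sequence[float], y: Sequence[float], ci_level: float = 0.95) -> RegressionFit:
    """Simple least-squares fit ``y = intercept + slope * x`` with t-based CIs."""
    x, y = _clean_xy(x, y, 3)
    if np.ptp(x) == 0:
        raise DegenerateInputError("regressor is constant")
    n = x.size
    res = sps.linregress(x, y)
    dof = n - 2
    tcrit = sps.t.ppf(0.5 + ci_level / 2.0, dof)
    slope_ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    intercept_ci = (
        res.intercept - tcrit * res.intercept_stderr,
        res.intercept + tcrit * res.intercept_stderr,
    )
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci=tuple(float(v) for v in slope_ci),
        intercept_ci=tuple(float(v) for v in intercept_ci),
        pcc=float(res.rvalue),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=n,
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple:
    """Pearson correlation with two-sided t-based p-value: ``(r, p)``."""
    x, y = _clean_xy(x, y, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("Pearson correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def paired_t(a: Sequence[float], b: Sequence[float]) -> tuple:
    """Classical paired t-test on ``a - b``: ``(mean difference, t, p)``."""
    a, b = _clean_xy(a, b, 2)
    d = a - b
    md = float(d.mean())
    if np.ptp(d) == 0:
        if md == 0:
            return 0.0, 0.0, 1.0
        raise DegenerateInputError("paired differences have zero variance")
    t, p = sps.ttest_rel(a, b)
    return md, float(t), float(p)


def bland_altman(a: Sequence[float], b: Sequence[float]) -> AgreementReport:
    """Bland-Altman agreement of paired measurements.

    Differences are ``a - b`` (reference minus comparison); limits of
    agreement are ``mean ± 1.96 SD`` with the n-1 SD.
    """
    a, b = _clean_xy(a, b, 2)
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(
        n=a.size,
        mean_difference=md,
        sd_difference=sd,
        loa_lower=md - 1.96 * sd,
        loa_upper=md + 1.96 * sd,
    )


def icc(a: Sequence[float], b: Sequence[float], model: str = "A-1") -> AgreementReport:
    """Two-rater intraclass correlation from the two-way ANOVA mean squares.

    ``model="A-1"`` is the two-way, absolute-agreement, single-measurement
    coefficient ICC(A,1); ``model="C-1"`` is the consistency form ICC(C,1).
    The model label is always carried in the report.
    """
    a, b = _clean_xy(a, b, 3)
    if model not in ("A-1", "C-1"):
        raise ValueError(f"unknown ICC model {model!r}")
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_rows == 0:
        raise DegenerateInputError("zero between-subject variance: ICC undefined")
    if model == "A-1":
        value = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    else:
        value = (msr - mse) / (msr + (k - 1) * mse)
    return AgreementReport(n=n, icc_value=float(value), icc_model=model)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple:
    """Kruskal-Wallis rank test across groups: ``(H, p)``.

    Uses the tie-corrected H statistic with a chi-square reference.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise DegenerateInputError("all values identical: rank test undefined")
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)
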