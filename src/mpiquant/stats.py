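"""Agreement and regression statistics for pipeline validation.

The central statistic is the intraclass correlation coefficient for a
two-way model with *absolute agreement* — the variant SPSS labels
"two-way mixed / absolute agreement", i.e. McGraw & Wong's ICC(A,1)
(single measures) and ICC(A,k) (average measures).  It is the right
agreement measure when the question is whether an algorithm's TIV values
can replace a human rater's, because it penalises systematic bias, not
just poor correlation.

Given an n-subject x k-rater matrix without replication, the two-way
ANOVA decomposition yields MSR (between subjects), MSC (between raters)
and MSE (residual), and

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
    ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE)/n)

with the F test of "true value 0" F = MSR/MSE on (n-1, (n-1)(k-1))
degrees of freedom.  Confidence intervals use the McGraw-Wong formulas
with a Satterthwaite-approximated denominator df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RatingsMatrix",
    "ICCResult",
    "RegressionResult",
    "icc_absolute_agreement",
    "linear_regression",
]


@dataclass
class RatingsMatrix:
    """An n-subjects x k-raters grid of measurements (complete, no gaps)."""

    values: np.ndarray
    subjects: list | None = None
    raters: list | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"ratings must be 2-D (subjects x raters), got shape {v.shape}")
        n, k = v.shape
        if n < 2 or k < 2:
            raise ValueError(f"need >= 2 subjects and >= 2 raters, got {n} x {k}")
        if not np.all(np.isfinite(v)):
            raise ValueError("ratings matrix must be complete (no missing cells)")
        self.values = v
        if self.subjects is None:
            self.subjects = [f"s{i}" for i in range(n)]
        if self.raters is None:
            self.raters = [f"r{j}" for j in range(k)]


@dataclass
class ICCResult:
    icc_single: float
    icc_average: float
    ci95_single: tuple
    ci95_average: tuple
    f_value: float
    df1: int
    df2: int
    p_value: float
    ms_rows: float
    ms_cols: float
    ms_error: float


def _coerce_ratings(ratings) -> np.ndarray:
    if isinstance(ratings, RatingsMatrix):
        return ratings.values
    try:  # pandas DataFrame
        arr = ratings.to_numpy(dtype=float)
    except AttributeError:
        arr = np.asarray(ratings, dtype=float)
    return RatingsMatrix(arr).values  # reuse validation


def icc_absolute_agreement(ratings, confidence: float = 0.95) -> ICCResult:
    """Two-way absolute-agreement ICC, single and average measures.

    ``ratings`` is an n x k array-like, DataFrame or
    :class:`RatingsMatrix`.  Raises on a constant matrix, where the ICC
    is undefined (no subject variance to agree about).
    """
    x = _coerce_ratings(ratings)
    n, k = x.shape
    alpha = 1.0 - confidence
    grand = x.mean()
    rows = x.mean(axis=1)
    cols = x.mean(axis=0)
    msr = k * float(np.sum((rows - grand) ** 2)) / (n - 1)
    msc = n * float(np.sum((cols - grand) ** 2)) / (k - 1)
    mse = float(np.sum((x - rows[:, None] - cols[None, :] + grand) ** 2)) / ((n - 1) * (k - 1))
    if msr == 0.0 and mse == 0.0:
        raise ValueError("constant ratings matrix: ICC is undefined")

    icc1 = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    icck = (msr - mse) / (msr + (msc - mse) / n)

    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    if mse == 0.0:
        f = np.inf
        p = 0.0
        ci1 = (icc1, icc1)
        cik = (icck, icck)
    else:
        f = msr / mse
        p = float(sps.f.sf(f, df1, df2))
        # McGraw-Wong CI for ICC(A,1) with Satterthwaite df
        denom = n * (1.0 - icc1)
        if denom <= 0:  # icc1 == 1 within rounding
            ci1 = (icc1, icc1)
        else:
            a = k * icc1 / denom
            b = 1.0 + k * icc1 * (n - 1) / denom
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lower = n * (msr - f_u * mse) / (
                f_u * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            upper = n * (f_l * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_l * msr
            )
            ci1 = (float(lower), float(upper))
        # average-measures bounds via the Spearman-Brown step-up
        def _step_up(r):
            return k * r / (1.0 + (k - 1) * r)

        cik = (float(_step_up(ci1[0])), float(_step_up(ci1[1])))

    return ICCResult(
        icc_single=float(icc1),
        icc_average=float(icck),
        ci95_single=ci1,
        ci95_average=cik,
        f_value=float(f),
        df1=df1,
        df2=df2,
        p_value=float(p),
        ms_rows=msr,
        ms_cols=msc,
        ms_error=mse,
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def linear_regression(x, y) -> RegressionResult:
    """OLS of y on x with R^2 and the two-sided p-value for slope != 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.unique(x).size < 2:
        raise ValueError("predictor x is constant")
    if np.ptp(y) == 0.0:
        # flat response: slope 0 explains nothing and there is nothing to explain
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, int(x.size))
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n=int(x.size),
    )
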