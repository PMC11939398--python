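"""Statistical analyses applied to simulator outputs.

Ordinary least squares (simple and multiple) and one-way ANOVA, each
reporting an F statistic with its degrees of freedom and a tail p-value.
These mirror the analyses run on the bench recordings; on the near-noiseless
simulator, only the signs and magnitudes of the fitted effects are
physiologically meaningful, so downstream checks assert those rather than
the p-values themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import CollinearityError, ConfigurationError, InsufficientDataError

ALPHA = 0.05  # significance threshold used when reporting


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    n: int
    f_statistic: float
    df: Tuple[int, int]
    p_value: float
    r_squared: float
    units: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def as_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept, "n": self.n,
                "f_statistic": self.f_statistic, "df": list(self.df),
                "p_value": self.p_value, "r_squared": self.r_squared,
                "units": self.units, "significant": self.significant}


@dataclass
class AnovaResult:
    group_labels: List[str]
    group_means: List[float]
    f_statistic: float
    df: Tuple[int, int]
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def as_dict(self) -> dict:
        return {"group_labels": self.group_labels, "group_means": self.group_means,
                "f_statistic": self.f_statistic, "df": list(self.df),
                "p_value": self.p_value, "significant": self.significant}


def f_tail_p(f: float, df1: int, df2: int) -> float:
    """Upper tail probability of the F(df1, df2) distribution."""
    if not np.isfinite(f):
        return 0.0
    return float(sps.f.sf(f, df1, df2))


def linear_regression_f(x: Sequence[float], y: Sequence[float],
                        units: str = "") -> RegressionResult:
    """Closed-form simple OLS with the ANOVA F test of the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise InsufficientDataError("simple regression needs n >= 3 paired points")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ConfigurationError("degenerate predictor: x is constant")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    yhat = intercept + slope * x
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_reg = ss_tot - ss_res
    df = (1, n - 2)
    if ss_res <= max(1e-12 * ss_tot, 0.0):
        f = float("inf")
        p = 0.0
        r2 = 1.0 if ss_tot > 0.0 else 0.0
    else:
        f = (ss_reg / df[0]) / (ss_res / df[1])
        f = max(f, 0.0)
        p = f_tail_p(f, *df)
        r2 = ss_reg / ss_tot if ss_tot > 0.0 else 0.0
    if ss_tot == 0.0:  # constant response
        slope, f, p, r2 = 0.0, 0.0, 1.0, 0.0
    return RegressionResult(slope=float(slope), intercept=intercept, n=n,
                            f_statistic=float(f), df=df, p_value=float(p),
                            r_squared=float(r2), units=units)


def one_way_anova(groups: Sequence[Sequence[float]],
                  labels: Sequence[str] | None = None) -> AnovaResult:
    """Standard between/within variance decomposition."""
    if len(groups) < 2:
        raise InsufficientDataError("ANOVA needs >= 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrs):
        if len(g) < 2:
            raise InsufficientDataError(f"group {i} has fewer than 2 observations")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(arrs))]
    n = sum(len(g) for g in arrs)
    k = len(arrs)
    grand = float(np.concatenate(arrs).mean())
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in arrs))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in arrs))
    df = (k - 1, n - k)
    if ss_within == 0.0:
        f = 0.0 if ss_between == 0.0 else float("inf")
    else:
        f = (ss_between / df[0]) / (ss_within / df[1])
    p = 1.0 if f == 0.0 else f_tail_p(f, *df)
    return AnovaResult(group_labels=labels,
                       group_means=[float(g.mean()) for g in arrs],
                       f_statistic=float(f), df=df, p_value=float(p))


def multiple_regression(design: np.ndarray, y: Sequence[float]
                        ) -> Tuple[np.ndarray, float, float]:
    """OLS with intercept on a predictor matrix; returns
    (coefficients [intercept first], overall F, p).

    The overall F compares the full model with the intercept-only model.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise InsufficientDataError("need n > number of predictors + 1")
    Xd = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(Xd)
    if rank < p + 1:
        # name the offending predictor columns via the null space
        _, s, vt = np.linalg.svd(Xd)
        null = vt[rank:]
        cols = sorted({int(j) - 1 for row in null
                       for j in np.nonzero(np.abs(row) > 1e-8)[0] if j > 0})
        raise CollinearityError(
            f"rank-deficient design: dependent column(s) {cols}", columns=cols)
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    df = (p, n - p - 1)
    if ss_res <= 1e-12 * max(ss_tot, 1.0):
        f, pv = float("inf"), 0.0
    else:
        f = ((ss_tot - ss_res) / df[0]) / (ss_res / df[1])
        pv = f_tail_p(f, *df)
    return beta, float(f), float(pv)
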