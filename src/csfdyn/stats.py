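"""Two-group statistics used throughout: unpaired Student t-test,
simple linear regression, mean ± SEM, and Grubbs single-outlier flagging.

The t-test is the classical equal-variance two-sided Student test (a
Welch option is exposed); regression p-values come from the slope's
t-statistic. The outlier check is Grubbs' two-sided test and only flags —
it never removes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "RegressionResult", "unpaired_t",
           "simple_linreg", "flag_outlier", "sem"]


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    df: float
    p_value: float
    significant: bool
    alpha: float
    n_a: int
    n_b: int


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean (ddof=1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return 0.0
    return float(v.std(ddof=1) / np.sqrt(v.size))


def unpaired_t(group_a: Sequence[float], group_b: Sequence[float],
               alpha: float = 0.05, equal_var: bool = True) -> GroupComparison:
    """Two-sided unpaired t-test with means and SEMs.

    ``equal_var=True`` (default) is the classical Student test with
    pooled variance and df = n_a + n_b − 2; ``False`` gives Welch.
    Byte-identical groups return t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    if not np.isfinite(t):  # zero pooled variance with equal means
        t, p = 0.0, 1.0
    return GroupComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=sem(a), sem_b=sem(b),
        t_statistic=t, df=df, p_value=p,
        significant=bool(p < alpha), alpha=alpha,
        n_a=int(a.size), n_b=int(b.size),
    )


def simple_linreg(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x; two-sided p from the slope's
    t-statistic. Constant y returns slope 0 with R² reported as 0."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.size < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(xv, xv[0]):
        raise ValueError("x is constant: slope undefined")
    if np.allclose(yv, yv[0]):
        return RegressionResult(slope=0.0, intercept=float(yv[0]),
                                r_squared=0.0, p_value=1.0, n=int(xv.size))
    res = sps.linregress(xv, yv)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue**2),
                            p_value=float(res.pvalue), n=int(xv.size))


def _grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value G_crit at level alpha for n points."""
    tcrit = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(tcrit**2 / (n - 2 + tcrit**2))


def flag_outlier(values: Sequence[float], alpha: float = 0.05) -> Optional[int]:
    """Grubbs' two-sided test for a single outlier.

    Returns the index of the most extreme value if its Grubbs statistic
    ``|x − mean|/sd`` exceeds the critical value at ``alpha``, else None.
    Flags only — the caller decides whether to exclude. Exact ties in
    extremity (e.g. symmetric data) are never flagged.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    sd = v.std(ddof=1)
    if sd == 0:
        return None
    dev = np.abs(v - v.mean())
    order = np.argsort(dev)
    if np.isclose(dev[order[-1]], dev[order[-2]]):
        return None  # tie in extremity: no single outlier
    idx = int(order[-1])
    g = dev[idx] / sd
    if g > _grubbs_critical(v.size, alpha):
        return idx
    return None
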