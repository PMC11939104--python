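"""Group-comparison and association statistics for cohort outcomes.

The statistical layer mirrors a construct-validity study design: per
outcome, elite and amateur groups are compared with a pooled-variance
independent t test at a Bonferroni-corrected alpha (0.05 divided by the
number of tests); identical lab/field outcomes are compared with a
paired t test; and lab-field associations are summarized by the better
of a linear or quadratic least-squares fit (the quadratic is reported
only when it improves R-squared by more than 0.01, to avoid the
nested-model always-wins artifact).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError, InvalidParameterError, UnidentifiableFitError
from .kinematics import FieldOutcomes

#: margin by which the quadratic R-squared must beat the linear one
CURVILINEAR_MARGIN = 0.01


@dataclass
class GroupComparison:
    """Pooled two-sample t test result for one outcome."""

    outcome: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    t: float
    df: int
    p: float
    significant: Optional[bool] = None
    infinite_t: bool = False


@dataclass
class AssociationFit:
    """Best of linear/quadratic OLS fit of y on x."""

    x_name: str
    y_name: str
    model: str                  # "linear" | "quadratic"
    coefficients: np.ndarray    # highest order first (numpy.polyfit order)
    r2: float
    r2_linear: float
    r2_quadratic: float


def best_attempt(attempts: Sequence[FieldOutcomes]) -> FieldOutcomes:
    """The attempt with the fastest end time (ties: first attempt)."""
    if not attempts:
        raise InvalidInputError("empty attempt list")
    return min(attempts, key=lambda a: a.duration)  # min() keeps the first on ties


def bonferroni_alpha(alpha: float, k: int) -> float:
    """Per-test alpha after Bonferroni correction: alpha / k."""
    if k < 1:
        raise InvalidParameterError("number of tests must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise InvalidParameterError("alpha must lie in (0, 1]")
    return alpha / k


def independent_t(a: np.ndarray, b: np.ndarray, outcome: str = "") -> GroupComparison:
    """Student (pooled-variance) two-sample t test, df = n1 + n2 - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("need at least 2 observations per group")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / df
    infinite = False
    if pooled_var == 0.0:
        if np.mean(a) == np.mean(b):
            t, p = 0.0, 1.0
        else:
            t = float("inf") if np.mean(a) > np.mean(b) else float("-inf")
            p, infinite = 0.0, True
    else:
        t, p = sps.ttest_ind(a, b, equal_var=True)
        t, p = float(t), float(p)
    return GroupComparison(
        outcome=outcome,
        n1=n1, n2=n2,
        mean1=float(np.mean(a)), mean2=float(np.mean(b)),
        sd1=float(np.std(a, ddof=1)), sd2=float(np.std(b, ddof=1)),
        t=t, df=df, p=p, infinite_t=infinite,
    )


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Paired t test on complete pairs; df = n - 1.

    Returns ``(t, df, p)``; zero-variance differences with a nonzero mean
    yield an infinite t (p = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidInputError("paired samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    d = x[keep] - y[keep]
    n = d.size
    if n < 2:
        raise InvalidInputError("need at least 2 complete pairs")
    df = n - 1
    if np.std(d, ddof=1) == 0.0:
        if np.mean(d) == 0.0:
            return 0.0, df, 1.0
        return float("inf") if np.mean(d) > 0 else float("-inf"), df, 0.0
    t, p = sps.ttest_1samp(d, 0.0)
    return float(t), df, float(p)


def _polyfit_r2(x: np.ndarray, y: np.ndarray, deg: int) -> tuple[np.ndarray, float]:
    coef = np.polyfit(x, y, deg)
    resid = y - np.polyval(coef, x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return coef, 1.0
    return coef, 1.0 - float(np.sum(resid**2)) / ss_tot


def fit_association(
    x: np.ndarray, y: np.ndarray, x_name: str = "x", y_name: str = "y"
) -> AssociationFit:
    """Fit linear and quadratic OLS of y on x; report the better one.

    The quadratic is only reported when its R-squared beats the linear
    fit by more than ``CURVILINEAR_MARGIN``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise InvalidInputError("need at least 4 points")
    if float(np.ptp(x)) == 0.0:
        raise UnidentifiableFitError("constant predictor")
    lin_coef, r2_lin = _polyfit_r2(x, y, 1)
    quad_coef, r2_quad = _polyfit_r2(x, y, 2)
    if r2_quad > r2_lin + CURVILINEAR_MARGIN:
        model, coef, r2 = "quadratic", quad_coef, r2_quad
    else:
        model, coef, r2 = "linear", lin_coef, r2_lin
    return AssociationFit(
        x_name=x_name, y_name=y_name, model=model,
        coefficients=coef, r2=r2, r2_linear=r2_lin, r2_quadratic=r2_quad,
    )


def summarize(
    cohort: pd.DataFrame,
    outcomes: Optional[Sequence[str]] = None,
    group_col: str = "group",
    groups: tuple[str, str] = ("amateur", "elite"),
    alpha: float = 0.05,
    n_tests: Optional[int] = None,
) -> pd.DataFrame:
    """Per-outcome group summary with Bonferroni-starred pooled t tests.

    ``groups`` orders the comparison: t is computed as group2 minus
    group1 (so a positive t means the second -- elite -- group scores
    higher).  Missing values are dropped pairwise per outcome; an
    outcome with fewer than 2 observations in either group is omitted
    with a warning.
    """
    if outcomes is None:
        outcomes = [
            c for c in cohort.columns
            if c not in (group_col, "player") and pd.api.types.is_numeric_dtype(cohort[c])
        ]
    if n_tests is None:
        n_tests = len(outcomes)
    alpha_corr = bonferroni_alpha(alpha, n_tests)

    g1 = cohort[cohort[group_col] == groups[0]]
    g2 = cohort[cohort[group_col] == groups[1]]
    rows = []
    for name in outcomes:
        a = g1[name].dropna().to_numpy()
        b = g2[name].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            warnings.warn(f"outcome {name!r} has a group with < 2 observations; omitted")
            continue
        cmp = independent_t(b, a, outcome=name)  # group2 - group1 sign
        rows.append({
            "outcome": name,
            f"n_{groups[0]}": a.size,
            f"mean_{groups[0]}": float(np.mean(a)),
            f"sd_{groups[0]}": float(np.std(a, ddof=1)),
            f"n_{groups[1]}": b.size,
            f"mean_{groups[1]}": float(np.mean(b)),
            f"sd_{groups[1]}": float(np.std(b, ddof=1)),
            "t": cmp.t,
            "df": cmp.df,
            "p": cmp.p,
            "significant": bool(cmp.p < alpha_corr),
        })
    return pd.DataFrame(rows)
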