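"""Model-quality criteria for correlation-weight QSAR models.

Beyond the standard regression statistics (R², Lin's concordance, RMSE,
MAE, Fisher F, leave-one-out Q²) this module implements three correlation
criteria used as optimization rewards:

IIC — index of ideality of correlation
    the Pearson r penalized by asymmetry between the mean absolute errors
    of the negative-residual and non-negative-residual points:
    ``IIC = r * min(MAE-, MAE+) / max(MAE-, MAE+)``.

CII — correlation intensity index
    Every observation is classified by the effect of deleting it on the
    Pearson correlation of the remaining points: if r increases the point
    is an *opponent* of the correlation, if r decreases it is a
    *supporter*.  CII = 1 minus the summed opponent influence, so a model
    with no opponents scores 1.

CCCP — coefficient of conformism of a correlative prediction
    1 minus the ratio of total opponent influence to total supporter
    influence.  Unlike CII it weighs the opponents against the supporters,
    so a correlation carried by a broad consensus scores near 1 while one
    held together by a few influential points can go negative.

The opponent/supporter partition comes from a shared leave-one-out
influence kernel, computed in O(n) from the five sufficient sums and
verified in the test suite against O(n²) brute-force recomputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, UndefinedStatisticError

__all__ = [
    "RegressionStats",
    "ClassificationStats",
    "pearson_r",
    "loo_influence",
    "cii",
    "cccp",
    "iic",
    "q2_loo",
    "lin_ccc",
    "regression_stats",
    "classification_stats",
]

_VAR_TOL = 1e-300  # guards exact-zero variance only; tiny real variance is legitimate


@dataclass
class RegressionStats:
    """One row of a regression report (one data subset).

    ``cccp`` and ``iic`` are NaN when undefined for the subset (no
    supporters / one-sided residuals); report writers print those as "-".
    """

    n: int
    r2: float
    ccc: float
    iic: float
    cii: float
    q2: float
    cccp: float
    rmse: float
    mae: float
    f: float


@dataclass
class ClassificationStats:
    n: int
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    mcc_defined: bool = True


def _as_xy(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateDataError("observed/predicted must be equal-length 1-D")
    return x, y


def pearson_r(observed, predicted) -> float:
    x, y = _as_xy(observed, predicted)
    n = x.size
    if n < 3:
        raise DegenerateDataError("need n >= 3 for a correlation")
    sx, sy = x.sum(), y.sum()
    vx = n * (x * x).sum() - sx * sx
    vy = n * (y * y).sum() - sy * sy
    if vx <= _VAR_TOL or vy <= _VAR_TOL:
        raise DegenerateDataError("zero variance in a correlation input")
    return float((n * (x * y).sum() - sx * sy) / math.sqrt(vx * vy))


def loo_influence(observed, predicted, *, on_r2: bool = False) -> np.ndarray:
    """Leave-one-out influence of each observation on the correlation.

    Returns ``delta`` with ``delta[k] = r(without k) - r(all)``; positive
    entries are opponents of the correlation, negative entries supporters.
    Computed in O(n) by downdating the five sufficient sums.

    With ``on_r2=True`` the influence is measured on r² instead of r (the
    sign convention for opponents/supporters is preserved because r² is
    monotone in |r|).
    """
    x, y = _as_xy(observed, predicted)
    n = x.size
    if n < 4:
        raise DegenerateDataError("need n >= 4 so every deletion leaves >= 3 points")
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()

    vx_all = n * sxx - sx * sx
    vy_all = n * syy - sy * sy
    if vx_all <= _VAR_TOL or vy_all <= _VAR_TOL:
        raise DegenerateDataError("zero variance in the full series")
    r_all = (n * sxy - sx * sy) / math.sqrt(vx_all * vy_all)

    m = n - 1
    vx = m * (sxx - x * x) - (sx - x) ** 2
    vy = m * (syy - y * y) - (sy - y) ** 2
    bad = np.nonzero((vx <= _VAR_TOL) | (vy <= _VAR_TOL))[0]
    if bad.size:
        raise DegenerateDataError(
            f"zero variance after deleting observation {int(bad[0])}"
        )
    r_loo = (m * (sxy - x * y) - (sx - x) * (sy - y)) / np.sqrt(vx * vy)
    if on_r2:
        return r_loo**2 - r_all**2
    return r_loo - r_all


def cii(delta: np.ndarray) -> float:
    """Correlation intensity index: 1 minus the summed opponent influence."""
    d = np.asarray(delta, dtype=float)
    return float(1.0 - d[d > 0].sum())


def cccp(delta: np.ndarray, *, literal_ratio: bool = False) -> float:
    """Coefficient of conformism of a correlative prediction.

    ``1 - (opponent mass / supporter mass)`` by default; equals 1 when
    there are no opponents and goes negative when the opponents outweigh
    the supporters.  ``literal_ratio=True`` returns the bare ratio instead.

    Raises
    ------
    UndefinedStatisticError
        when there are no supporters (zero denominator).
    """
    d = np.asarray(delta, dtype=float)
    supporters = -d[d < 0].sum()
    if supporters <= 0:
        raise UndefinedStatisticError("CCCP undefined: no supporters of correlation")
    ratio = float(d[d > 0].sum() / supporters)
    return ratio if literal_ratio else 1.0 - ratio


def iic(observed, predicted) -> float:
    """Index of ideality of correlation.

    Splits the points by residual sign (residual = observed - predicted;
    zeros count with the non-negative side) and penalizes r by the
    imbalance of the two mean absolute errors.  A perfect fit has IIC = r
    by the equal-MAE convention.

    Raises
    ------
    UndefinedStatisticError
        when all residuals fall on one side (and are not all zero).
    """
    x, y = _as_xy(observed, predicted)
    r = pearson_r(x, y)
    resid = x - y
    if np.all(resid == 0):
        return r
    neg = resid < 0
    pos = ~neg
    if not neg.any() or not pos.any():
        raise UndefinedStatisticError("IIC undefined: one-sided residuals")
    mae_neg = float(np.abs(resid[neg]).mean())
    mae_pos = float(resid[pos].mean())
    hi = max(mae_neg, mae_pos)
    if hi == 0:
        return r
    return r * min(mae_neg, mae_pos) / hi


def lin_ccc(observed, predicted) -> float:
    """Lin's concordance correlation coefficient."""
    x, y = _as_xy(observed, predicted)
    n = x.size
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population (1/n) moments, per Lin
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom <= _VAR_TOL:
        raise DegenerateDataError("CCC undefined: both series constant and equal")
    return float(2 * cov / denom)


def q2_loo(observed, predicted) -> float:
    """Leave-one-out cross-validated determination coefficient.

    Refits the univariate line observed ~ predicted with each point held
    out (via the hat-matrix identity PRESS_i = e_i / (1 - h_ii)) and
    returns 1 - PRESS / SS_tot.
    """
    y, x = _as_xy(observed, predicted)  # regress observed on predicted
    n = x.size
    if n < 4:
        raise DegenerateDataError("need n >= 4 for LOO Q2")
    sxx = ((x - x.mean()) ** 2).sum()
    if sxx <= _VAR_TOL:
        raise DegenerateDataError("zero variance in predictor")
    b1 = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    b0 = y.mean() - b1 * x.mean()
    e = y - (b0 + b1 * x)
    h = 1.0 / n + (x - x.mean()) ** 2 / sxx
    press = float(((e / (1.0 - h)) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= _VAR_TOL:
        raise DegenerateDataError("zero variance in observed values")
    return 1.0 - press / ss_tot


def regression_stats(observed, predicted) -> RegressionStats:
    """All regression criteria for one (observed, predicted) series.

    ``f`` is the Fisher statistic of the univariate regression,
    ``r2 (n-2) / (1-r2)``, reported as +inf for an exact fit.  IIC and
    CCCP that are undefined for the series are reported as NaN rather
    than raising, since a report row remains useful without them.
    """
    x, y = _as_xy(observed, predicted)
    n = x.size
    if n < 4:
        raise DegenerateDataError("need n >= 4 for the full criteria set")
    r = pearson_r(x, y)
    r2 = r * r
    resid = x - y
    rmse = float(np.sqrt((resid**2).mean()))
    mae = float(np.abs(resid).mean())
    f = math.inf if (1.0 - r2) <= 1e-15 else r2 * (n - 2) / (1.0 - r2)
    try:
        iic_val = iic(x, y)
    except UndefinedStatisticError:
        iic_val = math.nan
    delta = loo_influence(x, y)
    cii_val = cii(delta)
    try:
        cccp_val = cccp(delta)
    except UndefinedStatisticError:
        cccp_val = math.nan
    return RegressionStats(
        n=n,
        r2=r2,
        ccc=lin_ccc(x, y),
        iic=iic_val,
        cii=cii_val,
        q2=q2_loo(x, y),
        cccp=cccp_val,
        rmse=rmse,
        mae=mae,
        f=f,
    )


def classification_stats(actual, predicted) -> ClassificationStats:
    """Confusion-matrix statistics for 0/1 labels.

    MCC uses the 2x2 determinant form; a zero denominator is reported as
    mcc = 0 with ``mcc_defined = False``.
    """
    a = np.asarray(actual)
    p = np.asarray(predicted)
    if a.shape != p.shape or a.ndim != 1:
        raise DegenerateDataError("actual/predicted must be equal-length 1-D")
    if not (set(np.unique(a)) <= {0, 1} and set(np.unique(p)) <= {0, 1}):
        raise DegenerateDataError("labels must be 0/1")
    if len(set(np.unique(a))) < 2:
        raise DegenerateDataError("both classes must be present in actual labels")
    tp = int(np.sum((a == 1) & (p == 1)))
    tn = int(np.sum((a == 0) & (p == 0)))
    fp = int(np.sum((a == 0) & (p == 1)))
    fn = int(np.sum((a == 1) & (p == 0)))
    n = tp + tn + fp + fn
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / n
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom == 0:
        return ClassificationStats(n, sens, spec, acc, 0.0, mcc_defined=False)
    mcc = (tp * tn - fp * fn) / denom
    return ClassificationStats(n, sens, spec, acc, float(mcc))
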