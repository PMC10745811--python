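"""Statistical core: correlation, regression, slope comparison, and robust
regression with FDR-based outlier removal (ROUT).

Every regression in the association pipeline runs through these functions so
that outlier handling and p-value conventions are uniform.  p-values are never
truncated here; formatting (e.g. "< 0.0001") is a reporting concern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps


class DegenerateDataError(ValueError):
    """Raised when data cannot support the requested statistic."""


def _as_xy(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    return x, y


def pearson_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation coefficient with the exact two-sided t-based p.

    p is computed from t = r * sqrt((n - 2) / (1 - r^2)) with n - 2 degrees of
    freedom, which is exact under bivariate normality.
    """
    x, y = _as_xy(x, y)
    n = x.size
    if n < 3:
        raise DegenerateDataError(f"pearson_test needs n >= 3, got n = {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("pearson_test needs nonzero variance in both variables")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class RegressionFit:
    """Ordinary least-squares fit of y on x with a mean-response CI band."""

    n: int
    slope: float
    intercept: float
    residual_ss: float
    slope_se: float
    r: float
    p_r: float
    ci_band: Callable[[float], tuple[float, float]]

    def predict(self, x0: float) -> float:
        return self.intercept + self.slope * x0


def linfit_ci(x: Sequence[float], y: Sequence[float], level: float = 0.95) -> RegressionFit:
    """Least-squares line with the pointwise CI of the mean response.

    The half-width at x0 is t_{1-(1-level)/2, n-2} * sqrt(MSE * (1/n +
    (x0 - xbar)^2 / Sxx)); with a perfect fit (MSE = 0) the band has zero
    width everywhere.
    """
    x, y = _as_xy(x, y)
    n = x.size
    if n < 3:
        raise DegenerateDataError(f"linfit_ci needs n >= 3, got n = {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise DegenerateDataError("linfit_ci needs nonzero variance in x")
    xbar = float(x.mean())
    slope = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xbar)
    resid = y - (intercept + slope * x)
    rss = float(resid @ resid)
    mse = rss / (n - 2)
    slope_se = float(np.sqrt(mse / sxx))
    if np.ptp(y) == 0:
        r, p_r = 0.0, 1.0
    else:
        r, p_r = pearson_test(x, y)
    tq = float(sps.t.ppf(1 - (1 - level) / 2, n - 2))

    def ci_band(x0: float) -> tuple[float, float]:
        mean = intercept + slope * x0
        half = tq * np.sqrt(mse * (1.0 / n + (x0 - xbar) ** 2 / sxx))
        return (mean - half, mean + half)

    return RegressionFit(
        n=n, slope=slope, intercept=intercept, residual_ss=rss,
        slope_se=slope_se, r=r, p_r=p_r, ci_band=ci_band,
    )


def compare_slopes(
    x_a: Sequence[float], y_a: Sequence[float],
    x_b: Sequence[float], y_b: Sequence[float],
) -> tuple[float, float]:
    """F-test for equality of two regression slopes (ANCOVA interaction test).

    Compares the pooled-slope model (one common slope, separate intercepts)
    against separate slopes per group:

        F = (SS_pooled - SS_separate) / MSE_separate,  df = (1, n_a + n_b - 4)

    Returns ``(F, p)``.  Identical to testing the group-by-x interaction term.
    """
    x_a, y_a = _as_xy(x_a, y_a)
    x_b, y_b = _as_xy(x_b, y_b)
    n_a, n_b = x_a.size, x_b.size
    if n_a < 3 or n_b < 3:
        raise DegenerateDataError("compare_slopes needs n >= 3 in each group")
    if np.ptp(x_a) == 0 or np.ptp(x_b) == 0:
        raise DegenerateDataError("compare_slopes needs nonzero x variance in each group")

    def _rss_sep(x, y):
        sxx = np.sum((x - x.mean()) ** 2)
        b = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        a = y.mean() - b * x.mean()
        r = y - (a + b * x)
        return float(r @ r), float(b), float(sxx)

    rss_a, slope_a, sxx_a = _rss_sep(x_a, y_a)
    rss_b, slope_b, sxx_b = _rss_sep(x_b, y_b)
    rss_sep = rss_a + rss_b
    # pooled common slope: weighted average of the per-group slopes by Sxx
    sxy = slope_a * sxx_a + slope_b * sxx_b
    slope_c = sxy / (sxx_a + sxx_b)

    def _rss_common(x, y, b):
        a = y.mean() - b * x.mean()
        r = y - (a + b * x)
        return float(r @ r)

    rss_pooled = _rss_common(x_a, y_a, slope_c) + _rss_common(x_b, y_b, slope_c)
    df_sep = n_a + n_b - 4
    if df_sep <= 0:
        raise DegenerateDataError("compare_slopes needs n_a + n_b > 4")
    mse_sep = rss_sep / df_sep
    if mse_sep == 0:
        # both groups fit exactly: slopes differ iff the fitted slopes differ
        if np.isclose(slope_a, slope_b):
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (rss_pooled - rss_sep) / mse_sep
    f = max(f, 0.0)
    p = float(sps.f.sf(f, 1, df_sep))
    return float(f), p


def ttest_unpaired(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Unpaired two-sided t-test; Student's pooled-variance form by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError("ttest_unpaired needs n >= 2 in each group")
    if not welch and np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        raise DegenerateDataError("ttest_unpaired: zero pooled variance with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# ROUT: robust regression and outlier removal

@dataclass
class OutlierReport:
    """Result of ROUT outlier detection on one (x, y) regression."""

    flagged_indices: np.ndarray
    Q: float
    robust_slope: float
    robust_intercept: float
    rsdr: float
    converged: bool


_ZERO_TOL = 1e-10


def _robust_linefit(x: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                    max_iter: int = 200) -> tuple[float, float, float, bool]:
    """IRLS line fit with Lorentzian-loss weights w = 1 / (1 + (res/RSDR)^2).

    Returns (slope, intercept, rsdr, converged).  RSDR is the robust residual
    scale: the 68.27th percentile (linear-interpolation definition) of the
    absolute residuals times sqrt(n / (n - 2)).
    """
    n = x.size
    slope, intercept = np.polyfit(x, y, 1)
    prev_ss = None
    converged = False
    rsdr = 0.0
    for _ in range(max_iter):
        resid = y - (intercept + slope * x)
        rsdr = float(np.percentile(np.abs(resid), 68.27)) * np.sqrt(n / (n - 2))
        if rsdr <= _ZERO_TOL * max(1.0, float(np.abs(y).max())):
            converged = True  # (near-)exact robust fit
            break
        w = 1.0 / (1.0 + (resid / rsdr) ** 2)
        sw = w.sum()
        xw = (w * x).sum() / sw
        yw = (w * y).sum() / sw
        sxx = (w * (x - xw) ** 2).sum()
        if sxx == 0:
            break
        slope = float((w * (x - xw) * (y - yw)).sum() / sxx)
        intercept = float(yw - slope * xw)
        ss = float((w * (y - (intercept + slope * x)) ** 2).sum())
        if prev_ss is not None and abs(prev_ss - ss) <= tol * max(prev_ss, 1e-300):
            converged = True
            break
        prev_ss = ss
    resid = y - (intercept + slope * x)
    rsdr = float(np.percentile(np.abs(resid), 68.27)) * np.sqrt(n / (n - 2))
    return float(slope), float(intercept), rsdr, converged


def rout_outliers(
    x: Sequence[float], y: Sequence[float], Q: float = 1.0
) -> tuple[OutlierReport, np.ndarray, np.ndarray]:
    """Detect regression outliers with the ROUT procedure at FDR Q (percent).

    The line is first fitted robustly (IRLS, Lorentzian loss), the robust
    residual scale RSDR is taken as the 68.27th-percentile absolute residual
    with a sqrt(n/(n-2)) degrees-of-freedom correction, and residuals are then
    tested largest-first: the point of rank i is flagged when its two-sided
    t-tail probability at |residual|/RSDR (n-2 df) falls below
    Q*(n - i + 1)/(100*n); testing stops at the first retained point.  Points
    with exactly tied residuals are tested jointly at the worse rank.

    Returns ``(report, x_clean, y_clean)``; with fewer than 5 points no
    removal is attempted (a warning is issued) because the robust scale has no
    residual degrees of freedom to stand on.
    """
    x, y = _as_xy(x, y)
    n = x.size
    if not 0 < Q < 100:
        raise ValueError(f"Q must be in (0, 100) percent, got {Q}")
    if n < 5:
        warnings.warn(
            f"rout_outliers: n = {n} < 5, no outlier removal attempted", stacklevel=2
        )
        slope, intercept = (np.polyfit(x, y, 1) if n >= 2 and np.ptp(x) > 0 else (0.0, float(np.mean(y))))
        report = OutlierReport(
            flagged_indices=np.array([], dtype=int), Q=Q,
            robust_slope=float(slope), robust_intercept=float(intercept),
            rsdr=0.0, converged=True,
        )
        return report, x, y
    if np.ptp(x) == 0:
        raise DegenerateDataError("rout_outliers needs nonzero variance in x")

    slope, intercept, rsdr, converged = _robust_linefit(x, y)
    resid = y - (intercept + slope * x)
    abs_resid = np.abs(resid)
    scale_ref = max(1.0, float(abs_resid.max()))

    if rsdr <= _ZERO_TOL * scale_ref:
        # Robust fit is exact for the bulk: any point measurably off the line
        # is an outlier; with all points collinear nothing is flagged.
        flagged = np.flatnonzero(abs_resid > _ZERO_TOL * scale_ref)
    else:
        order = np.argsort(-abs_resid, kind="stable")
        tvals = abs_resid[order] / rsdr
        pvals = 2.0 * sps.t.sf(tvals, n - 2)
        flagged_mask = np.zeros(n, dtype=bool)
        i = 0
        while i < n:
            # joint treatment of exact residual ties: worst (largest) rank
            j = i
            while j + 1 < n and abs_resid[order[j + 1]] == abs_resid[order[i]]:
                j += 1
            rank = j + 1  # 1-based, worse rank of the tied block
            alpha_i = Q * (n - rank + 1) / (100.0 * n)
            if pvals[i] < alpha_i:
                flagged_mask[order[i : j + 1]] = True
                i = j + 1
            else:
                break
        flagged = np.flatnonzero(flagged_mask)

    keep = np.setdiff1d(np.arange(n), flagged, assume_unique=True)
    report = OutlierReport(
        flagged_indices=flagged, Q=Q, robust_slope=slope,
        robust_intercept=intercept, rsdr=rsdr, converged=converged,
    )
    return report, x[keep], y[keep]
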