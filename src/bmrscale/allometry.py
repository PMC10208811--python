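"""Log-log allometric regression: OLS and WLS fits of BMR on body mass.

The allometric model is BMR = a * m**b, fitted in base-10 log space as
log10(BMR) = log10(a) + b * log10(m).  The coefficient ``a`` (ml O2/h at
m = 1 g) is the antilog of the intercept; its standard error is obtained
by the delta method.  Fitted exponents can be tested against the
theoretical 3/4 slope with Welch's t-test.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, SingularDesignError
from .io_tables import SpeciesRecord

LN10 = math.log(10.0)


@dataclasses.dataclass
class AllometricFit:
    """Estimated allometric coefficient and exponent with uncertainties.

    ``a`` is in ml O2/h at body mass 1 g; ``b`` is dimensionless.
    ``lambda_hat`` is Pagel's λ and is only set for PGLS fits.
    """

    group_label: str
    a: float
    b: float
    se_a: float
    se_b: float
    intercept_log10: float
    se_intercept_log10: float
    r2: float
    n: int
    method: str
    lambda_hat: float | None = None

    def predict_bmr(self, mass_g):
        """Predicted BMR (ml O2/h) at the given body mass (g)."""
        return self.a * np.asarray(mass_g, dtype=float) ** self.b


def log10_transform(records: Iterable[SpeciesRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Return (log10 mass, log10 BMR) vectors, preserving record order."""
    records = list(records)
    mass = np.array([r.mass_g for r in records], dtype=float)
    bmr = np.array([r.bmr for r in records], dtype=float)
    if np.any(mass <= 0) or np.any(bmr <= 0):
        raise ValueError("mass and BMR must be strictly positive for log transform")
    return np.log10(mass), np.log10(bmr)


def delta_method_se_a(intercept_log10: float, se_intercept_log10: float) -> float:
    """Delta-method standard error of a = 10**intercept.

    d(10^c)/dc = 10^c * ln(10), so se(a) = a * ln(10) * se(c).
    """
    if se_intercept_log10 < 0:
        raise ValueError("standard error must be non-negative")
    return 10.0 ** intercept_log10 * LN10 * se_intercept_log10


def _check_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise InsufficientDataError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise SingularDesignError("predictor is constant; slope is not identifiable")
    return x, y


def fit_ols(x, y, group_label: str = "", method: str = "OLS") -> AllometricFit:
    """Ordinary least squares of y on x with classical n-2 df errors."""
    x, y = _check_xy(x, y)
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    slope = float(np.sum((x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - intercept - slope * x
    rss = float(resid @ resid)
    tss = float(np.sum((y - ybar) ** 2))
    sigma2 = rss / (n - 2)
    se_slope = math.sqrt(sigma2 / sxx)
    se_intercept = math.sqrt(sigma2 * (1.0 / n + xbar**2 / sxx))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    a = 10.0 ** intercept
    return AllometricFit(
        group_label=group_label,
        a=a,
        b=slope,
        se_a=delta_method_se_a(intercept, se_intercept),
        se_b=se_slope,
        intercept_log10=intercept,
        se_intercept_log10=se_intercept,
        r2=r2,
        n=n,
        method=method,
    )


def fit_wls(x, y, weights, group_label: str = "") -> AllometricFit:
    """Weighted least squares; weights are normalized so a common
    rescaling of all weights leaves every output unchanged.

    With integer weights k_i the point estimates coincide with OLS on
    the dataset where observation i is repeated k_i times.
    """
    x, y = _check_xy(x, y)
    w = np.asarray(weights, dtype=float)
    if w.shape != x.shape:
        raise ValueError("weights must match x in length")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    n = x.size
    w = w * (n / w.sum())  # mean weight 1
    sw = float(w.sum())
    xbar = float(np.sum(w * x) / sw)
    ybar = float(np.sum(w * y) / sw)
    sxx = float(np.sum(w * (x - xbar) ** 2))
    if sxx == 0:
        raise SingularDesignError("weighted predictor variance is zero")
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - intercept - slope * x
    rss = float(np.sum(w * resid**2))
    tss = float(np.sum(w * (y - ybar) ** 2))
    sigma2 = rss / (n - 2)
    se_slope = math.sqrt(sigma2 / sxx)
    se_intercept = math.sqrt(sigma2 * (1.0 / sw + xbar**2 / sxx))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return AllometricFit(
        group_label=group_label,
        a=10.0 ** intercept,
        b=slope,
        se_a=delta_method_se_a(intercept, se_intercept),
        se_b=se_slope,
        intercept_log10=intercept,
        se_intercept_log10=se_intercept,
        r2=r2,
        n=n,
        method="WLS",
    )


def fit_group(records: Sequence[SpeciesRecord], group_label: str = "",
              weights=None) -> AllometricFit:
    """Convenience: log-transform a record collection and fit OLS/WLS."""
    x, y = log10_transform(records)
    if weights is None:
        return fit_ols(x, y, group_label=group_label)
    return fit_wls(x, y, weights, group_label=group_label)


def welch_test_slope(b: float, se_b: float, df: float, b0: float = 0.75
                     ) -> tuple[float, float, float]:
    """One-sample t-test of a fitted slope against the constant ``b0``.

    The theoretical exponent (default 3/4) is treated as exact, so
    t = (b - b0)/se_b on the fit's residual degrees of freedom.
    Returns (t, df, two-sided p).
    """
    if se_b <= 0:
        raise ValueError("slope standard error must be positive")
    t = (b - b0) / se_b
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def welch_compare_slopes(b1: float, se1: float, df1: float,
                         b2: float, se2: float, df2: float
                         ) -> tuple[float, float, float]:
    """Welch's t-test for two independently fitted slopes.

    Uses the Welch–Satterthwaite approximation for the degrees of
    freedom.  Returns (t, df, two-sided p).
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("slope standard errors must be positive")
    v1, v2 = se1**2, se2**2
    t = (b1 - b2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / df1 + v2**2 / df2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p
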