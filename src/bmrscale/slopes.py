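"""Slope-homogeneity analysis: three nested pooled OLS models and ANCOVA.

The three candidate descriptions of the pooled log10 BMR ~ log10 mass
data are:

* M0 — one regression line for all species (no group factor);
* M1 — a common slope with a separate intercept per group;
* M2 — separate slopes and intercepts per group.

Models are scored by AIC and BIC with the Gaussian likelihood profiled
over the residual variance, lnL = −(n/2)(ln(2π·RSS/n) + 1), and the
variance counted as a parameter (matching R's lm/BIC convention).  The
shared exponent reported for M1 is the "common slope" used downstream
to normalize clade intercepts.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .allometry import log10_transform
from .errors import InsufficientDataError
from .io_tables import SpeciesRecord

MODEL_IDS = ("M0", "M1", "M2")


@dataclasses.dataclass
class PooledModelFit:
    model_id: str
    k_params: int
    rss: float
    df_resid: int
    log_likelihood: float
    aic: float
    bic: float


@dataclasses.dataclass
class ModelComparison:
    models: dict[str, PooledModelFit]
    best_by_bic: str
    best_by_aic: str
    common_slope: float
    common_slope_se: float
    group_intercepts: dict[str, float]
    n: int
    groups: list[str]


def _prepare(records: Iterable[SpeciesRecord]
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    records = list(records)
    counts = Counter(r.group for r in records)
    small = sorted(g for g, c in counts.items() if c < 2)
    if small:
        warnings.warn(f"excluding groups with < 2 species: {small}")
        records = [r for r in records if r.group not in small]
    groups = sorted({r.group for r in records})
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups with >= 2 species each")
    x, y = log10_transform(records)
    gidx = np.array([groups.index(r.group) for r in records])
    return x, y, gidx, groups


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _score(model_id: str, rss: float, n: int, p: int) -> PooledModelFit:
    loglik = -0.5 * n * (math.log(2 * math.pi * rss / n) + 1.0)
    k = p + 1  # + residual variance
    return PooledModelFit(
        model_id=model_id,
        k_params=k,
        rss=rss,
        df_resid=n - p,
        log_likelihood=loglik,
        aic=2 * k - 2 * loglik,
        bic=k * math.log(n) - 2 * loglik,
    )


def _designs(x: np.ndarray, gidx: np.ndarray, n_groups: int
             ) -> dict[str, np.ndarray]:
    n = x.size
    dummies = np.zeros((n, n_groups))
    dummies[np.arange(n), gidx] = 1.0
    return {
        "M0": np.column_stack([np.ones(n), x]),
        "M1": np.column_stack([dummies, x]),
        "M2": np.column_stack([dummies, dummies * x[:, None]]),
    }


def fit_pooled_models(records: Iterable[SpeciesRecord]) -> ModelComparison:
    """Fit M0/M1/M2 on pooled log10 data and rank them by AIC and BIC.

    Groups with fewer than 2 species are excluded with a warning.  BIC
    ties closer than 1e-9 are broken toward the simpler model (models
    are scanned in M0, M1, M2 order with strict improvement required).
    """
    x, y, gidx, groups = _prepare(records)
    n = x.size
    G = len(groups)
    designs = _designs(x, gidx, G)
    fits: dict[str, PooledModelFit] = {}
    betas: dict[str, np.ndarray] = {}
    for mid in MODEL_IDS:
        X = designs[mid]
        beta, rss = _ols_rss(X, y)
        betas[mid] = beta
        fits[mid] = _score(mid, rss, n, X.shape[1])

    def argbest(key) -> str:
        best = MODEL_IDS[0]
        for mid in MODEL_IDS[1:]:
            if key(fits[mid]) < key(fits[best]) - 1e-9:
                best = mid
        return best

    X1 = designs["M1"]
    beta1 = betas["M1"]
    sigma2 = fits["M1"].rss / fits["M1"].df_resid
    cov = np.linalg.inv(X1.T @ X1) * sigma2
    return ModelComparison(
        models=fits,
        best_by_bic=argbest(lambda f: f.bic),
        best_by_aic=argbest(lambda f: f.aic),
        common_slope=float(beta1[-1]),
        common_slope_se=float(math.sqrt(cov[-1, -1])),
        group_intercepts={g: float(beta1[i]) for i, g in enumerate(groups)},
        n=n,
        groups=groups,
    )


def ancova_slope_test(records: Iterable[SpeciesRecord]
                      ) -> tuple[float, tuple[int, int], float]:
    """Nested-model F test of slope heterogeneity (M2 vs M1).

    F = [(RSS1 − RSS2)/(df1 − df2)] / [RSS2/df2]; the p-value is the
    upper tail of F(df1 − df2, df2).  Rejecting means the groups do not
    share a common scaling exponent.
    """
    comp = fit_pooled_models(records)
    m1, m2 = comp.models["M1"], comp.models["M2"]
    ddf = m1.df_resid - m2.df_resid
    f = max(0.0, (m1.rss - m2.rss) / ddf) / (m2.rss / m2.df_resid)
    p = float(stats.f.sf(f, ddf, m2.df_resid))
    return f, (ddf, m2.df_resid), p


def common_slope(records: Iterable[SpeciesRecord]) -> tuple[float, float]:
    """The shared exponent of model M1 (common slope, group intercepts)
    with its OLS standard error."""
    comp = fit_pooled_models(records)
    return comp.common_slope, comp.common_slope_se
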