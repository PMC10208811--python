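"""Clade-level second-stage regressions.

These relate the scaling parameters and the dimensionless BMR ratio to
clade divergence time (mya), and the BMR ratio to the reconstructed
group means of activity duration and body temperature.  All fits are
plain OLS at the group level (optionally WLS with species-count
weights); no phylogenetic correction is applied at this 6-to-9-group
scale.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

from .allometry import fit_ols, fit_wls, welch_test_slope
from .errors import InsufficientDataError
from .io_tables import GroupMeta, meta_by_group
from .normalize import RatioTable


@dataclasses.dataclass
class CorrelateFit:
    """A group-level bivariate regression with its significance test."""

    predictor_name: str
    response_name: str
    slope: float
    intercept: float
    r2: float
    p: float
    n: int
    weighting: str = "none"
    groups: tuple[str, ...] = ()


def _group_regression(pairs: Sequence[tuple[str, float, float]],
                      predictor_name: str, response_name: str,
                      weights: Sequence[float] | None = None) -> CorrelateFit:
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"need at least 3 groups with both {predictor_name} and "
            f"{response_name}, got {len(pairs)}"
        )
    labels = tuple(p[0] for p in pairs)
    x = np.array([p[1] for p in pairs])
    y = np.array([p[2] for p in pairs])
    if weights is None:
        fit = fit_ols(x, y)
        weighting = "none"
    else:
        fit = fit_wls(x, y, np.asarray(weights, dtype=float))
        weighting = "n_species"
    if fit.se_b > 0:
        _, _, p = welch_test_slope(fit.b, fit.se_b, fit.n - 2, b0=0.0)
    else:
        p = 0.0 if fit.b != 0 else 1.0
    return CorrelateFit(
        predictor_name=predictor_name,
        response_name=response_name,
        slope=fit.b,
        intercept=fit.intercept_log10,  # identity-scale intercept here
        r2=fit.r2,
        p=p,
        n=fit.n,
        weighting=weighting,
        groups=labels,
    )


def regress_on_divergence(values: Mapping[str, float],
                          meta: Iterable[GroupMeta],
                          response_name: str = "value",
                          weighted: bool = False) -> CorrelateFit:
    """OLS (or species-count WLS) of a per-group quantity on divergence time.

    ``values`` maps group label to the response (e.g. a at the common
    slope, the clade exponent, or the BMR ratio); groups missing from
    either side are dropped.
    """
    lookup = meta_by_group(meta)
    pairs = [(g, lookup[g].mya, float(v)) for g, v in values.items()
             if g in lookup and v is not None and np.isfinite(v)]
    pairs.sort(key=lambda p: -p[1])
    weights = [lookup[g].n_species for g, _, _ in pairs] if weighted else None
    return _group_regression(pairs, "divergence_time_mya", response_name, weights)


def activity_from_sleep(sleep_h):
    """Activity duration in h/day: 24 minus sleep duration."""
    s = np.asarray(sleep_h, dtype=float)
    if np.any((s < 0) | (s > 24)):
        raise ValueError("sleep duration must lie in [0, 24] hours")
    out = 24.0 - s
    return float(out) if out.ndim == 0 else out


def _ratio_response_pairs(ratio_table: RatioTable, meta: Iterable[GroupMeta],
                          attr: str, transform=None
                          ) -> tuple[list[tuple[str, float, float]], list[float], list[str]]:
    lookup = meta_by_group(meta)
    pairs, weights, missing = [], [], []
    for row in ratio_table.rows:
        m = lookup.get(row.group_label)
        value = getattr(m, attr, None) if m is not None else None
        if value is None:
            missing.append(row.group_label)
            continue
        if transform is not None:
            value = transform(value)
        pairs.append((row.group_label, row.ratio, float(value)))
        weights.append(m.n_species)
    return pairs, weights, missing


def correlate_activity_bmr(ratio_table: RatioTable, meta: Iterable[GroupMeta],
                           weighted: bool = False) -> CorrelateFit:
    """Regression of activity duration (24 − sleep) on the BMR ratio."""
    pairs, weights, _ = _ratio_response_pairs(
        ratio_table, meta, "sleep_h", transform=activity_from_sleep
    )
    return _group_regression(pairs, "bmr_ratio", "activity_h",
                             weights if weighted else None)


def correlate_tb_bmr(ratio_table: RatioTable, meta: Iterable[GroupMeta],
                     weighted: bool = False) -> CorrelateFit:
    """Regression of mean body temperature (°C) on the BMR ratio.

    Groups without a body-temperature mean are dropped (and simply
    reduce n); they are never imputed.
    """
    pairs, weights, _ = _ratio_response_pairs(ratio_table, meta, "tb_c")
    return _group_regression(pairs, "bmr_ratio", "body_temperature_c",
                             weights if weighted else None)


def regress_paired_difference(values_a: Mapping[str, float],
                              values_b: Mapping[str, float],
                              lambdas: Mapping[str, float],
                              response_name: str = "difference") -> CorrelateFit:
    """Regress a per-group difference (a-method minus b-method estimate)
    on the group's fitted Pagel's λ.

    Generic utility for asking whether stronger phylogenetic signal
    produces larger OLS-vs-PGLS discrepancies in a or b.
    """
    common = sorted(set(values_a) & set(values_b) & set(lambdas))
    pairs = [(g, float(lambdas[g]), float(values_a[g]) - float(values_b[g]))
             for g in common]
    return _group_regression(pairs, "lambda_hat", response_name)
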