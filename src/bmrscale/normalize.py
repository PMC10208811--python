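"""Common-slope normalization and the dimensionless BMR-ratio table.

Once a common scaling exponent b is established, each clade's intercept
is refitted with the slope held fixed; the antilogged intercepts
a_common (ml O2/h at 1 g) become size-free measures of metabolic level.
Dividing by a reference clade (Passeriformes, the highest-BMR clade)
yields the dimensionless BMR ratio, which is invariant to the unit in
which BMR is measured.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .allometry import delta_method_se_a
from .errors import InsufficientDataError
from .io_tables import SpeciesRecord
from .allometry import log10_transform


@dataclasses.dataclass
class FixedSlopeFit:
    """Per-group intercept refitted at a fixed common exponent."""

    group_label: str
    b_common: float
    intercept_log10: float
    se_intercept_log10: float
    a_common: float
    se_a_common: float
    r2: float
    n: int


@dataclasses.dataclass
class RatioRow:
    group_label: str
    a_common: float
    se_a_common: float
    r2: float
    ratio: float


@dataclasses.dataclass
class RatioTable:
    common_b: float
    reference_group: str
    rows: list[RatioRow]

    def ratios(self) -> dict[str, float]:
        return {r.group_label: r.ratio for r in self.rows}

    def a_values(self) -> dict[str, float]:
        return {r.group_label: r.a_common for r in self.rows}

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        """Presentation-layer rounding of the ratios."""
        return {r.group_label: round(r.ratio, ndigits) for r in self.rows}


def refit_fixed_slope(x, y, b_common: float, group_label: str = "") -> FixedSlopeFit:
    """Refit the intercept with the slope constrained to ``b_common``.

    The least-squares intercept of y = b_common·x + c is the mean of the
    offset residuals y − b_common·x; its standard error is the sample sd
    of those residuals over √n.  R² is 1 − RSS/TSS with RSS taken about
    the constrained line, so it can be lower than the free-slope R².
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("need at least 2 points for a fixed-slope refit")
    offset = y - b_common * x
    c = float(offset.mean())
    se_c = float(offset.std(ddof=1) / math.sqrt(x.size))
    resid = offset - c
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return FixedSlopeFit(
        group_label=group_label,
        b_common=b_common,
        intercept_log10=c,
        se_intercept_log10=se_c,
        a_common=10.0 ** c,
        se_a_common=delta_method_se_a(c, se_c),
        r2=r2,
        n=x.size,
    )


def refit_groups(records: Iterable[SpeciesRecord], b_common: float
                 ) -> dict[str, FixedSlopeFit]:
    """Fixed-slope refit per group of a species table."""
    by_group: dict[str, list[SpeciesRecord]] = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r)
    fits = {}
    for g in sorted(by_group):
        x, y = log10_transform(by_group[g])
        fits[g] = refit_fixed_slope(x, y, b_common, group_label=g)
    return fits


def bmr_ratio_table(fits: Mapping[str, FixedSlopeFit] | Mapping[str, float],
                    reference_group: str,
                    common_b: float | None = None) -> RatioTable:
    """Build the dimensionless BMR-ratio table relative to a reference.

    ``fits`` maps group label to either a :class:`FixedSlopeFit` or a
    bare coefficient a_common (useful when working from published
    coefficients).  The reference group's ratio is exactly 1.
    """
    if reference_group not in fits:
        raise KeyError(
            f"reference group {reference_group!r} not present; "
            f"available: {sorted(fits)}"
        )

    def unpack(v) -> tuple[float, float, float]:
        if isinstance(v, FixedSlopeFit):
            return v.a_common, v.se_a_common, v.r2
        return float(v), float("nan"), float("nan")

    a_ref = unpack(fits[reference_group])[0]
    if a_ref <= 0:
        raise ValueError("reference coefficient must be positive")
    rows = []
    for g in fits:
        a, se, r2 = unpack(fits[g])
        ratio = 1.0 if g == reference_group else a / a_ref
        rows.append(RatioRow(g, a, se, r2, ratio))
    b = common_b
    if b is None:
        vals = [v.b_common for v in fits.values() if isinstance(v, FixedSlopeFit)]
        b = vals[0] if vals else float("nan")
    return RatioTable(common_b=b, reference_group=reference_group, rows=rows)
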