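"""Reading and writing species tables, group metadata, and fit reports.

The species table is a CSV/TSV with required headers
``species,group,mass_g,bmr_mlO2_h``; masses are in grams and BMR in
ml O2/hour.  Group metadata (divergence time, reconstructed sleep and
body-temperature means, species counts) and the published per-clade
scaling summaries ship as packaged fixtures so the whole pipeline runs
without any download.
"""

from __future__ import annotations

import dataclasses
import io
import json
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataValidationError, FormatError

SPECIES_COLUMNS = ("species", "group", "mass_g", "bmr_mlO2_h")
META_COLUMNS = ("group", "mya", "sleep_h", "tb_c", "n_species")

#: Six endotherm clades, ordered from oldest to most recent divergence.
ENDOTHERM_GROUPS = (
    "Monotremata",
    "Marsupialia",
    "Eutheria",
    "Palaeognathae",
    "Non-Passeriformes",
    "Passeriformes",
)

#: Alternative molecular-clock estimate for the monotreme split; the
#: packaged metadata table carries the value used in the cross-clade
#: regressions (217 mya).
MONOTREMATA_DIVERGENCE_ALTERNATIVE_MYA = 271.0


@dataclasses.dataclass(frozen=True)
class SpeciesRecord:
    """One species' clade label, body mass (g), and BMR (ml O2/h)."""

    species: str
    group: str
    mass_g: float
    bmr: float

    def __post_init__(self) -> None:
        if not (self.mass_g > 0 and math.isfinite(self.mass_g)):
            raise DataValidationError(
                f"body mass must be positive and finite, got {self.mass_g!r} "
                f"for species {self.species!r}"
            )
        if not (self.bmr > 0 and math.isfinite(self.bmr)):
            raise DataValidationError(
                f"BMR must be positive and finite, got {self.bmr!r} "
                f"for species {self.species!r}"
            )


@dataclasses.dataclass(frozen=True)
class GroupMeta:
    """Clade-level metadata: divergence time, sleep/body-temperature means, size.

    ``sleep_h`` and ``tb_c`` are ``None`` when no group mean is
    available (the ectotherm rows); they are never coded as zero.
    """

    group: str
    mya: float
    sleep_h: float | None
    tb_c: float | None
    n_species: int

    def __post_init__(self) -> None:
        if not self.mya > 0:
            raise DataValidationError(f"divergence time must be positive: {self.group}")
        if self.sleep_h is not None and not 0.0 <= self.sleep_h <= 24.0:
            raise DataValidationError(
                f"sleep duration must lie in [0, 24] h/day: {self.group}"
            )


class SpeciesTable(list):
    """A list of :class:`SpeciesRecord` with a per-row rejection report.

    ``rejected`` holds ``(row_number, reason)`` pairs for rows that
    failed validation (1-based, counting the header as row 1).
    """

    def __init__(self, records: Iterable[SpeciesRecord] = (),
                 rejected: Sequence[tuple[int, str]] = ()):
        super().__init__(records)
        self.rejected: list[tuple[int, str]] = list(rejected)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.species, r.group, r.mass_g, r.bmr) for r in self],
            columns=list(SPECIES_COLUMNS),
        )


def _sniff_sep(source) -> str:
    """Detect comma vs tab from the first non-comment line."""
    if hasattr(source, "read"):
        head = source.readline()
        source.seek(0)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            head = fh.readline()
    if isinstance(head, bytes):
        head = head.decode("utf-8")
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


def read_species_table(source, sep: str | None = None) -> SpeciesTable:
    """Read a species table from a CSV/TSV path or stream.

    Rows whose mass or BMR is non-positive or unparseable are rejected
    and reported in ``result.rejected`` rather than aborting the read.
    Only comma and tab delimiters are auto-detected; anything else must
    be passed explicitly via ``sep``.

    Raises
    ------
    FormatError
        if a required column is missing.
    DataValidationError
        if species names are duplicated.
    """
    if sep is None:
        sep = _sniff_sep(source)
    try:
        df = pd.read_csv(source, sep=sep, comment="#",
                         dtype={"species": str, "group": str},
                         float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"could not parse species table: {exc}") from exc

    missing = [c for c in SPECIES_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"species table is missing required column(s): {', '.join(missing)}"
        )

    dupes = df["species"][df["species"].duplicated()].unique().tolist()
    if dupes:
        raise DataValidationError(f"duplicate species names: {dupes}")

    records: list[SpeciesRecord] = []
    rejected: list[tuple[int, str]] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            mass = float(row.mass_g)
            bmr = float(row.bmr_mlO2_h)
        except (TypeError, ValueError):
            rejected.append((pos, "mass or BMR not numeric"))
            continue
        try:
            records.append(SpeciesRecord(str(row.species), str(row.group), mass, bmr))
        except DataValidationError as exc:
            rejected.append((pos, str(exc)))
    return SpeciesTable(records, rejected)


def write_species_table(records: Iterable[SpeciesRecord], destination) -> None:
    """Write records as CSV with full float precision (round-trip safe)."""
    frame = SpeciesTable(records).to_frame()
    frame.to_csv(destination, index=False, float_format="%.17g")


def _meta_from_frame(df: pd.DataFrame) -> list[GroupMeta]:
    metas = []
    for row in df.itertuples(index=False):
        metas.append(
            GroupMeta(
                group=str(row.group),
                mya=float(row.mya),
                sleep_h=None if pd.isna(row.sleep_h) else float(row.sleep_h),
                tb_c=None if pd.isna(row.tb_c) else float(row.tb_c),
                n_species=int(row.n_species),
            )
        )
    labels = [m.group for m in metas]
    if len(set(labels)) != len(labels):
        raise DataValidationError("group labels must be unique in metadata table")
    return metas


def read_group_meta(source) -> list[GroupMeta]:
    """Read a group-metadata CSV (headers ``group,mya,sleep_h,tb_c,n_species``)."""
    df = pd.read_csv(source, comment="#")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata table missing column(s): {', '.join(missing)}")
    return _meta_from_frame(df)


def builtin_group_meta() -> list[GroupMeta]:
    """The packaged nine-group metadata table.

    Divergence times and extant species counts are published clade
    values; sleep and body-temperature columns are reconstructed group
    means (present only for the six endotherm clades).
    """
    with resources.files("bmrscale.data").joinpath("group_meta.csv").open("r") as fh:
        return read_group_meta(fh)


def builtin_scaling_summary() -> pd.DataFrame:
    """Published per-clade allometric summaries as a DataFrame.

    Columns: group, mya, a_common (coefficient at the common slope),
    b_ols (clade OLS exponent; NaN for Monotremata), a_ols, bmr_ratio
    (endotherms only), n_bmr (BMR sample size behind each endotherm fit).
    """
    with resources.files("bmrscale.data").joinpath("group_scaling.csv").open("r") as fh:
        return pd.read_csv(fh, comment="#")


def meta_by_group(metas: Iterable[GroupMeta]) -> Mapping[str, GroupMeta]:
    return {m.group: m for m in metas}


# ---------------------------------------------------------------------------
# fit reports

_REPORT_FIELDS = (
    "group_label", "method", "n", "a", "se_a", "b", "se_b",
    "intercept_log10", "se_intercept_log10", "r2", "lambda_hat",
)


def _fit_row(fit) -> dict:
    row = {}
    for field in _REPORT_FIELDS:
        value = getattr(fit, field, None)
        row[field] = value
    return row


def write_fit_report(fits: Sequence, destination) -> None:
    """Write fits as CSV (``<destination>.csv``) and JSON (``.json``).

    ``destination`` is a base path without extension.  Column order is
    fixed; floats are serialized at 17 significant digits so a
    write-read-write cycle is byte-identical.
    """
    base = Path(destination)
    base.parent.mkdir(parents=True, exist_ok=True)
    rows = [_fit_row(f) for f in fits]

    def fmt(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return ""
        if isinstance(v, float):
            return "%.17g" % v
        return str(v)

    lines = [",".join(_REPORT_FIELDS)]
    for row in rows:
        lines.append(",".join(fmt(row[f]) for f in _REPORT_FIELDS))
    base.with_suffix(".csv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    base.with_suffix(".json").write_text(
        json.dumps(rows, indent=2, allow_nan=False, default=lambda v: None) + "\n",
        encoding="utf-8",
    )


def read_fit_report(source) -> pd.DataFrame:
    """Re-read a CSV fit report written by :func:`write_fit_report`."""
    df = pd.read_csv(source, float_precision="round_trip")
    missing = [c for c in _REPORT_FIELDS if c not in df.columns]
    if missing:
        raise FormatError(f"fit report missing column(s): {', '.join(missing)}")
    return df
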