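"""Tabular data model: isotope records, CSV I/O and quality control.

The analysis operates on two tables: consumer records (one row per individual
with species group, site, invasion status, body length and δ15N/δ13C values)
and primary-producer (algae) baseline records used for δ15N baseline
correction.  Units: lengths in mm (total length for fish, carapace length for
crayfish), isotope deltas in ‰.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "IsotopeRecord",
    "BaselineRecord",
    "QCReport",
    "LengthSummary",
    "SchemaError",
    "EmptyStratumError",
    "read_isotope_table",
    "read_baseline_table",
    "write_isotope_table",
    "write_baseline_table",
    "records_to_frame",
    "frame_to_records",
    "qc_cn_ratio",
    "length_summary",
]

#: Consumer groups analysed by default.  Minnows (several ecologically similar
#: cyprinid species) are pooled into a single group; species identity, when
#: present in the input, is carried but ignored by the models.
DEFAULT_GROUPS = (
    "flathead_catfish",
    "channel_catfish",
    "smallmouth_bass",
    "minnow",
    "crayfish",
)

CONSUMER_COLUMNS = (
    "record_id",
    "group",
    "site_id",
    "invaded",
    "length_mm",
    "d15n_permil",
    "d13c_permil",
    "cn_ratio",
    "year",
)

BASELINE_COLUMNS = ("site_id", "d15n_permil", "d13c_permil")

#: δ13C for freshwater consumers typically falls in this band; values outside
#: it are legal but suspicious (sample mix-up, unit error) and draw a warning.
D13C_PLAUSIBLE = (-40.0, -10.0)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class EmptyStratumError(ValueError):
    """A summary was requested for a group/status stratum with no records."""


@dataclass
class IsotopeRecord:
    """One individual's isotope measurement with covariates."""

    record_id: str
    group: str
    site_id: str
    invaded: bool
    length_mm: float
    d15n_permil: float
    d13c_permil: float
    cn_ratio: float | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError("group must be non-empty")
        if not self.site_id:
            raise ValueError("site_id must be non-empty")
        if not self.length_mm > 0:
            raise ValueError(
                f"record {self.record_id!r}: length_mm must be positive, "
                f"got {self.length_mm}"
            )
        lo, hi = D13C_PLAUSIBLE
        if not lo <= self.d13c_permil <= hi:
            warnings.warn(
                f"record {self.record_id!r}: d13c_permil={self.d13c_permil} "
                f"outside the plausible band [{lo}, {hi}] ‰",
                stacklevel=2,
            )


@dataclass
class BaselineRecord:
    """One primary-producer (algae) isotope measurement at a site."""

    site_id: str
    d15n_permil: float
    d13c_permil: float

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValueError("site_id must be non-empty")


@dataclass
class QCReport:
    """Outcome of the C:N lipid-correction screen."""

    n_records: int
    n_flagged_cn: int
    flagged_ids: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_flagged_cn > self.n_records:
            raise ValueError("n_flagged_cn cannot exceed n_records")


@dataclass
class LengthSummary:
    """Sample statistics of body length for one group × status stratum."""

    group: str
    invaded: bool
    n: int
    min: float
    max: float
    median: float
    mean: float
    sd: float | None  # None when n < 2 (sd undefined)


def _apply_schema(
    frame: pd.DataFrame,
    schema: Mapping[str, str] | None,
    required: Sequence[str],
    optional: Sequence[str] = (),
) -> pd.DataFrame:
    if schema:
        frame = frame.rename(columns={v: k for k, v in schema.items()})
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"required column {col!r} missing from input table")
    for col in optional:
        if col not in frame.columns:
            frame[col] = None
    return frame


def _parse_float(value, column: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"row {row}: non-numeric value {value!r} in column {column!r}"
        ) from None


def _is_missing(value) -> bool:
    if value is None:
        return True
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


def read_isotope_table(
    path, schema: Mapping[str, str] | None = None
) -> list[IsotopeRecord]:
    """Read and validate a consumer CSV, returning records in row order.

    ``schema`` maps canonical column names (``group``, ``site_id``, ...) to
    the file's column names when they differ.  ``record_id``, ``cn_ratio``
    and ``year`` are optional; a missing ``record_id`` is filled with the row
    index.
    """
    frame = pd.read_csv(path)
    frame = _apply_schema(
        frame,
        schema,
        required=("group", "site_id", "invaded", "length_mm", "d15n_permil", "d13c_permil"),
        optional=("record_id", "cn_ratio", "year"),
    )
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        rid = getattr(row, "record_id")
        records.append(
            IsotopeRecord(
                record_id=str(i) if _is_missing(rid) else str(rid),
                group=str(row.group),
                site_id=str(row.site_id),
                invaded=bool(row.invaded),
                length_mm=_parse_float(row.length_mm, "length_mm", i),
                d15n_permil=_parse_float(row.d15n_permil, "d15n_permil", i),
                d13c_permil=_parse_float(row.d13c_permil, "d13c_permil", i),
                cn_ratio=None
                if _is_missing(row.cn_ratio)
                else _parse_float(row.cn_ratio, "cn_ratio", i),
                year=None if _is_missing(row.year) else int(row.year),
            )
        )
    return records


def read_baseline_table(
    path, schema: Mapping[str, str] | None = None
) -> list[BaselineRecord]:
    """Read an algae baseline CSV (site_id, d15n_permil, d13c_permil)."""
    frame = pd.read_csv(path)
    frame = _apply_schema(frame, schema, required=BASELINE_COLUMNS)
    return [
        BaselineRecord(
            site_id=str(row.site_id),
            d15n_permil=_parse_float(row.d15n_permil, "d15n_permil", i),
            d13c_permil=_parse_float(row.d13c_permil, "d13c_permil", i),
        )
        for i, row in enumerate(frame.itertuples(index=False))
    ]


def records_to_frame(records: Iterable[IsotopeRecord | BaselineRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame preserving row order."""
    records = list(records)
    if records and isinstance(records[0], BaselineRecord):
        cols = BASELINE_COLUMNS
    else:
        cols = CONSUMER_COLUMNS
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


def frame_to_records(frame: pd.DataFrame) -> list[IsotopeRecord]:
    """Validate a consumer DataFrame row-by-row into records."""
    frame = _apply_schema(
        frame.copy(),
        None,
        required=("group", "site_id", "invaded", "length_mm", "d15n_permil", "d13c_permil"),
        optional=("record_id", "cn_ratio", "year"),
    )
    out = []
    for i, row in enumerate(frame.itertuples(index=False)):
        rid = getattr(row, "record_id")
        out.append(
            IsotopeRecord(
                record_id=str(i) if _is_missing(rid) else str(rid),
                group=str(row.group),
                site_id=str(row.site_id),
                invaded=bool(row.invaded),
                length_mm=float(row.length_mm),
                d15n_permil=float(row.d15n_permil),
                d13c_permil=float(row.d13c_permil),
                cn_ratio=None if _is_missing(row.cn_ratio) else float(row.cn_ratio),
                year=None if _is_missing(row.year) else int(row.year),
            )
        )
    return out


def write_isotope_table(records: Iterable[IsotopeRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_baseline_table(records: Iterable[BaselineRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def qc_cn_ratio(
    records: Iterable[IsotopeRecord], threshold: float = 3.5
) -> QCReport:
    """Screen consumer C:N ratios for the lipid-correction requirement.

    Lipids are depleted in 13C; when tissue C:N reaches ~3.5 a lipid
    correction of δ13C is normally required.  Records at or above the
    threshold are flagged (the boundary value is flagged: only strictly lower
    ratios are known to be safe).  Missing C:N yields a warning, not a flag —
    it is an accounting gap, not evidence of lipid richness.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    records = list(records)
    flagged, warns = [], []
    for rec in records:
        if rec.cn_ratio is None:
            warns.append(f"record {rec.record_id!r}: cn_ratio missing")
        elif rec.cn_ratio >= threshold:
            flagged.append(rec.record_id)
    return QCReport(
        n_records=len(records),
        n_flagged_cn=len(flagged),
        flagged_ids=flagged,
        warnings=warns,
    )


def length_summary(
    records: Iterable[IsotopeRecord], group: str, invaded: bool
) -> LengthSummary:
    """Min/max/median/mean/SD of length in one group × status stratum.

    SD uses the n−1 denominator and is reported missing (None) for a single
    record.
    """
    lengths = [
        r.length_mm for r in records if r.group == group and r.invaded == invaded
    ]
    if not lengths:
        raise EmptyStratumError(
            f"no records for group={group!r}, invaded={invaded}"
        )
    n = len(lengths)
    lengths.sort()
    mean = sum(lengths) / n
    if n >= 2:
        sd = math.sqrt(sum((x - mean) ** 2 for x in lengths) / (n - 1))
    else:
        sd = None
    mid = n // 2
    median = lengths[mid] if n % 2 else 0.5 * (lengths[mid - 1] + lengths[mid])
    return LengthSummary(
        group=group,
        invaded=invaded,
        n=n,
        min=lengths[0],
        max=lengths[-1],
        median=median,
        mean=mean,
        sd=sd,
    )
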