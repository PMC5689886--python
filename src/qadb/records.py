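"""Verification-record data model and cohort table I/O.

A verification record is one plan check from an independent 3D dose
recalculation: the mean target-dose difference between the independent
system and the local treatment planning system (as a percentage of the
plan maximum dose), and the global (3%, 3 mm) gamma passing rate, together
with the stratification labels (TPS, technique, site, linac, energy, date)
used to subset the database.

The canonical on-disk format is a single-header UTF-8 CSV with ISO 8601
dates and a fixed column order (:data:`CSV_COLUMNS`).
"""

from __future__ import annotations

import csv
import datetime
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TECHNIQUES",
    "LINACS",
    "ENERGIES",
    "TPS_SYSTEMS",
    "CSV_COLUMNS",
    "METRICS",
    "SchemaError",
    "RecordValidationError",
    "VerificationRecord",
    "CohortTable",
    "SubgroupStats",
    "read_cohort",
    "write_cohort",
    "filter_cohort",
    "summarize_cohort",
]

#: Delivery techniques. "SRMT" is accepted at read time as an alias of IMRS
#: (the same radiosurgery technique appears under both labels in practice).
TECHNIQUES = ("3DCRT", "IMRT", "DCA", "IMRS")
_TECHNIQUE_ALIASES = {"SRMT": "IMRS"}

LINACS = ("LA1", "LA2", "LA3", "LA4")

#: Photon energies; mixed-energy plans are encoded as the single value 6/10X.
ENERGIES = ("6X", "6FFF", "10X", "6/10X")

TPS_SYSTEMS = ("Eclipse", "iPlan")

#: Exact CSV column order of the canonical cohort file.
CSV_COLUMNS = (
    "record_id",
    "check_date",
    "treatment_site",
    "technique",
    "linac",
    "energy",
    "software_version",
    "tps",
    "mean_dose_diff_pct",
    "gamma_pass_pct",
)

#: Numeric metrics a cohort stores per record.
METRICS = ("mean_dose_diff_pct", "gamma_pass_pct")

SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    """The CSV header does not match the declared schema."""


class RecordValidationError(ValueError):
    """A row violates a record invariant; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class VerificationRecord:
    """One plan's verification result with its stratification labels."""

    record_id: str
    check_date: datetime.date
    treatment_site: str
    technique: str
    linac: str
    energy: str
    software_version: str
    tps: str
    mean_dose_diff_pct: float
    gamma_pass_pct: float

    def __post_init__(self) -> None:
        if self.technique in _TECHNIQUE_ALIASES:
            object.__setattr__(
                self, "technique", _TECHNIQUE_ALIASES[self.technique]
            )
        if self.technique not in TECHNIQUES:
            raise RecordValidationError(
                f"technique {self.technique!r} not in {TECHNIQUES}"
            )
        if self.linac not in LINACS:
            raise RecordValidationError(f"linac {self.linac!r} not in {LINACS}")
        if self.energy not in ENERGIES:
            raise RecordValidationError(
                f"energy {self.energy!r} not in {ENERGIES}"
            )
        if self.tps not in TPS_SYSTEMS:
            raise RecordValidationError(f"tps {self.tps!r} not in {TPS_SYSTEMS}")
        if not isinstance(self.check_date, datetime.date):
            raise RecordValidationError("check_date must be a calendar date")
        if not math.isfinite(self.mean_dose_diff_pct):
            raise RecordValidationError("mean_dose_diff_pct must be finite")
        if not (0.0 <= self.gamma_pass_pct <= 100.0):
            raise RecordValidationError(
                f"gamma_pass_pct must lie in [0, 100], got {self.gamma_pass_pct}"
            )


@dataclass(frozen=True)
class CohortTable:
    """Ordered collection of verification records with provenance.

    Record ids need not be unique (a patient may have several plans) but
    the (record_id, check_date, technique) triple must be.
    """

    records: tuple[VerificationRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        keys = [(r.record_id, r.check_date, r.technique) for r in self.records]
        if len(set(keys)) != len(keys):
            seen: set = set()
            for i, k in enumerate(keys):
                if k in seen:
                    raise RecordValidationError(
                        f"duplicate (record_id, check_date, technique) {k}", row=i
                    )
                seen.add(k)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VerificationRecord]:
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        """Return the cohort as a DataFrame in canonical column order."""
        return pd.DataFrame(
            [[getattr(r, c) for c in CSV_COLUMNS] for r in self.records],
            columns=list(CSV_COLUMNS),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "CohortTable":
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        records = []
        for i, row in enumerate(df.itertuples(index=False)):
            d = row.check_date
            if isinstance(d, str):
                d = datetime.date.fromisoformat(d)
            elif isinstance(d, pd.Timestamp):
                d = d.date()
            records.append(
                VerificationRecord(
                    record_id=str(row.record_id),
                    check_date=d,
                    treatment_site=str(row.treatment_site),
                    technique=str(row.technique),
                    linac=str(row.linac),
                    energy=str(row.energy),
                    software_version=str(row.software_version),
                    tps=str(row.tps),
                    mean_dose_diff_pct=float(row.mean_dose_diff_pct),
                    gamma_pass_pct=float(row.gamma_pass_pct),
                )
            )
        return cls(records=tuple(records), provenance=provenance)


@dataclass(frozen=True)
class SubgroupStats:
    """n, mean, sample SD and extrema of one metric within one stratum.

    ``sigma`` is the n−1-denominator sample standard deviation and is
    ``None`` (explicitly absent, never zero) for single-record groups.
    """

    label: str
    metric: str
    n: int
    mu: float
    sigma: float | None
    max_v: float
    min_v: float

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric {self.metric!r} not in {METRICS}")
        if self.sigma is not None:
            if self.n < 2:
                raise ValueError("sigma requires n >= 2")
            if self.sigma < 0:
                raise ValueError("sigma must be non-negative")
        if not (self.min_v <= self.mu <= self.max_v):
            raise ValueError("mean must lie between the extrema")


def _format_float(x: float) -> str:
    # repr of a Python float is the shortest string that round-trips,
    # which makes write∘read the identity on files this module wrote.
    return repr(float(x))


def read_cohort(path: str | Path, schema_version: str = SCHEMA_VERSION) -> CohortTable:
    """Read and validate a cohort CSV, preserving row order.

    Raises :class:`SchemaError` for header mismatches and
    :class:`RecordValidationError` (with the row index) for bad cells.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty file: missing header row") from None
        if tuple(header) != CSV_COLUMNS:
            missing = set(CSV_COLUMNS) - set(header)
            extra = set(header) - set(CSV_COLUMNS)
            raise SchemaError(
                f"header mismatch: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}, order must be {list(CSV_COLUMNS)}"
            )
        records = []
        for i, row in enumerate(reader):
            if len(row) != len(CSV_COLUMNS):
                raise RecordValidationError(
                    f"expected {len(CSV_COLUMNS)} cells, got {len(row)}", row=i
                )
            cells = dict(zip(CSV_COLUMNS, row))
            try:
                date = datetime.date.fromisoformat(cells["check_date"])
            except ValueError:
                raise RecordValidationError(
                    f"unparseable date {cells['check_date']!r}", row=i
                ) from None
            try:
                dose = float(cells["mean_dose_diff_pct"])
                gamma = float(cells["gamma_pass_pct"])
            except ValueError as exc:
                raise RecordValidationError(str(exc), row=i) from None
            try:
                rec = VerificationRecord(
                    record_id=cells["record_id"],
                    check_date=date,
                    treatment_site=cells["treatment_site"],
                    technique=cells["technique"],
                    linac=cells["linac"],
                    energy=cells["energy"],
                    software_version=cells["software_version"],
                    tps=cells["tps"],
                    mean_dose_diff_pct=dose,
                    gamma_pass_pct=gamma,
                )
            except RecordValidationError as exc:
                raise RecordValidationError(str(exc), row=i) from None
            records.append(rec)
    return CohortTable(records=tuple(records), provenance=str(path))


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort to the canonical CSV format (UTF-8, ISO dates)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for r in table.records:
            writer.writerow(
                [
                    r.record_id,
                    r.check_date.isoformat(),
                    r.treatment_site,
                    r.technique,
                    r.linac,
                    r.energy,
                    r.software_version,
                    r.tps,
                    _format_float(r.mean_dose_diff_pct),
                    _format_float(r.gamma_pass_pct),
                ]
            )


def filter_cohort(
    table: CohortTable, criteria: Mapping[str, object]
) -> CohortTable:
    """Return records matching every criterion (conjunction), order preserved.

    Each criterion maps a record field to an allowed value or set of
    values. Unknown field names raise ``KeyError``.
    """
    fields = set(CSV_COLUMNS)
    normalized: dict[str, set] = {}
    for key, allowed in criteria.items():
        if key not in fields:
            raise KeyError(f"unknown record field {key!r}")
        if isinstance(allowed, (str, bytes)) or not isinstance(allowed, Iterable):
            allowed = {allowed}
        normalized[key] = set(allowed)
    kept = tuple(
        r
        for r in table.records
        if all(getattr(r, k) in v for k, v in normalized.items())
    )
    return CohortTable(records=kept, provenance=table.provenance)


def _group_label(group_keys: Sequence[str], values: Sequence[object]) -> str:
    if not group_keys:
        return "all"
    return ", ".join(f"{k}={v}" for k, v in zip(group_keys, values))


def summarize_cohort(
    table: CohortTable, group_keys: Sequence[str], metric: str
) -> list[SubgroupStats]:
    """Per-stratum n, μ, σ (sample SD), max and min of one metric.

    Groups appear in order of first occurrence; a single-record group
    reports ``sigma=None``. An empty table yields an empty list.
    """
    if metric not in METRICS:
        raise ValueError(f"metric {metric!r} not in {METRICS}")
    fields = set(CSV_COLUMNS)
    for k in group_keys:
        if k not in fields:
            raise KeyError(f"unknown record field {k!r}")
    groups: dict[tuple, list[float]] = {}
    for r in table.records:
        key = tuple(getattr(r, k) for k in group_keys)
        groups.setdefault(key, []).append(getattr(r, metric))
    out = []
    for key, values in groups.items():
        arr = np.asarray(values, dtype=float)
        sigma = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
        out.append(
            SubgroupStats(
                label=_group_label(group_keys, key),
                metric=metric,
                n=int(arr.size),
                mu=float(arr.mean()),
                sigma=sigma,
                max_v=float(arr.max()),
                min_v=float(arr.min()),
            )
        )
    return out
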