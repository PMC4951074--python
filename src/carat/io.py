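"""Reading and writing patient-registry tables.

Cohorts are stored as UTF-8 comma-separated text with a header row and a
leading ``#``-comment line carrying the schema version. Booleans are
serialized as ``1``/``0``; an empty field means the value is absent
(allowed only for the optional columns). Nested factor sets are flattened
with ``stroke_``, ``bleed_`` and ``safety_`` prefixes, so the columns map
one-to-one onto :class:`~carat.records.PatientRecord` fields.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
from pydantic import ValidationError

from .records import (
    BleedRiskFactors,
    PatientRecord,
    SafetyChecklist,
    StrokeRiskFactors,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
SCHEMA_COMMENT = f"# carat-cohort-schema={SCHEMA_VERSION}"


class SchemaError(ValueError):
    """The file's columns do not match the documented cohort schema."""


class CohortValidationError(ValueError):
    """A row violates a record invariant (strict mode only)."""


_SCALAR_COLUMNS = [
    "patient_id",
    "gp_id",
    "arm",
    "age",
    "sex",
    "chronic_condition_count",
    "rx_med_count",
    "otc_med_count",
    "afib_duration",
    "afib_type",
    "prior_hospitalization",
    "hospitalization_reason",
    "rhythm",
    "baseline_therapy",
    "inr_subtherapeutic",
]
_STROKE_FIELDS = list(StrokeRiskFactors.model_fields)
_BLEED_FIELDS = list(BleedRiskFactors.model_fields)
_SAFETY_FIELDS = list(SafetyChecklist.model_fields)

COLUMNS: list[str] = (
    _SCALAR_COLUMNS[:-2]
    + [f"stroke_{f}" for f in _STROKE_FIELDS]
    + [f"bleed_{f}" for f in _BLEED_FIELDS]
    + [f"safety_{f}" for f in _SAFETY_FIELDS]
    + _SCALAR_COLUMNS[-2:]
)

_OPTIONAL = {"hospitalization_reason", "inr_subtherapeutic"}
_BOOL_SCALARS = {"prior_hospitalization", "inr_subtherapeutic"}
_INT_SCALARS = {"age", "chronic_condition_count", "rx_med_count", "otc_med_count"}


def _serialize_value(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if hasattr(value, "value"):  # Enum
        return str(value.value)
    return str(value)


def record_to_row(record: PatientRecord) -> dict[str, str]:
    row: dict[str, str] = {}
    for col in _SCALAR_COLUMNS:
        row[col] = _serialize_value(getattr(record, col))
    for prefix, sub in (
        ("stroke", record.stroke),
        ("bleed", record.bleed),
        ("safety", record.safety),
    ):
        for name in type(sub).model_fields:
            row[f"{prefix}_{name}"] = _serialize_value(getattr(sub, name))
    return row


def _parse_bool(raw: str, column: str) -> bool:
    if raw == "1":
        return True
    if raw == "0":
        return False
    raise ValueError(f"column {column!r}: expected 0/1, got {raw!r}")


def row_to_record(row: dict[str, str]) -> PatientRecord:
    data: dict[str, object] = {}
    for col in _SCALAR_COLUMNS:
        raw = str(row[col]).strip()
        if raw == "":
            if col in _OPTIONAL:
                data[col] = None
                continue
            raise ValueError(f"column {col!r}: required value missing")
        if col in _BOOL_SCALARS:
            data[col] = _parse_bool(raw, col)
        elif col in _INT_SCALARS:
            data[col] = int(raw)
        else:
            data[col] = raw
    for prefix, fields, cls in (
        ("stroke", _STROKE_FIELDS, StrokeRiskFactors),
        ("bleed", _BLEED_FIELDS, BleedRiskFactors),
        ("safety", _SAFETY_FIELDS, SafetyChecklist),
    ):
        sub = {
            f: _parse_bool(str(row[f"{prefix}_{f}"]).strip(), f"{prefix}_{f}")
            for f in fields
        }
        data[prefix] = cls(**sub)
    return PatientRecord(**data)


def read_cohort(
    path: str | Path, strict: bool = True
) -> tuple[list[PatientRecord], int]:
    """Read a cohort table.

    Returns ``(records, n_skipped)``. In strict mode any invariant
    violation raises :class:`CohortValidationError` (so ``n_skipped`` is
    always 0); in lenient mode offending rows are logged and skipped.
    Extra columns (e.g. appended score columns) are ignored.
    """
    path = Path(path)
    frame = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    records: list[PatientRecord] = []
    skipped = 0
    for idx, row in enumerate(frame.to_dict(orient="records")):
        try:
            records.append(row_to_record(row))
        except (ValueError, ValidationError) as exc:
            if strict:
                pid = row.get("patient_id", f"<row {idx}>")
                raise CohortValidationError(
                    f"{path}: invalid row for patient {pid!r}: {exc}"
                ) from exc
            skipped += 1
            logger.warning("skipping invalid row %d (%s): %s", idx, row.get("patient_id"), exc)
    return records, skipped


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> int:
    """Write validated records as delimited text; returns the row count."""
    path = Path(path)
    rows = [record_to_row(r) for r in records]
    frame = pd.DataFrame(rows, columns=COLUMNS)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(SCHEMA_COMMENT + "\n")
        frame.to_csv(fh, index=False)
    return len(rows)
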