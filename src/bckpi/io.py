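"""Reading and writing the bottle-level export dialect.

CSV: comma-separated, quoted strings, UTF-8, header row, one bottle per row,
columns exactly::

    patient_id,age_years,center,area,hospital_service,sample_id,bottle_id,
    specimen_origin,bottle_type,collected_at,status,organisms,volume_ml

``collected_at`` is ISO-8601, ``organisms`` is semicolon-separated, the empty
string means missing.  JSONL mirrors the same keys with native JSON types
(``organisms`` as an array, ``volume_ml`` as a number or null).

Validation is total: every input row either lands in the returned cohort or
appears exactly once in the rejects report with its row number, offending
field and reason code.  A missing mandatory column or a duplicated
``bottle_id`` is a fatal schema error.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from collections import Counter
from datetime import datetime
from pathlib import Path
from typing import Optional, Union

from .model import (
    DEFAULT_VOLUME_CAP,
    BottleRecord,
    BottleStatus,
    BottleType,
    Cohort,
    SpecimenOrigin,
)

logger = logging.getLogger(__name__)

COLUMNS = [
    "patient_id", "age_years", "center", "area", "hospital_service",
    "sample_id", "bottle_id", "specimen_origin", "bottle_type",
    "collected_at", "status", "organisms", "volume_ml",
]


class SchemaError(ValueError):
    """Fatal input-shape error: bad header or duplicated bottle key."""


class DuplicateBottleIdError(SchemaError):
    pass


@dataclasses.dataclass
class RejectedRow:
    row_number: int          # 1-based data-row number (header excluded)
    field: str
    reason: str


@dataclasses.dataclass
class LoadResult:
    cohort: Cohort
    rejects: list[RejectedRow]


class _RowError(ValueError):
    def __init__(self, field: str, reason: str):
        super().__init__(f"{field}: {reason}")
        self.field = field
        self.reason = reason


def _parse_row(raw: dict, volume_cap: float) -> BottleRecord:
    def req(key: str) -> str:
        val = raw.get(key)
        if val is None:
            raise _RowError(key, "missing_value")
        return str(val).strip()

    age_raw = raw.get("age_years")
    try:
        age = int(age_raw)
    except (TypeError, ValueError):
        raise _RowError("age_years", "unparsable_age")

    def enum_field(key: str, enum_cls):
        val = req(key).upper()
        try:
            return enum_cls(val)
        except ValueError:
            raise _RowError(key, f"unknown_{key}")

    ts_raw = raw.get("collected_at")
    try:
        collected = datetime.fromisoformat(str(ts_raw).strip())
    except (TypeError, ValueError):
        raise _RowError("collected_at", "unparsable_timestamp")

    organisms_raw = raw.get("organisms")
    if organisms_raw is None:
        organisms: tuple[str, ...] = ()
    elif isinstance(organisms_raw, (list, tuple)):
        organisms = tuple(str(o).strip() for o in organisms_raw if str(o).strip())
    else:
        organisms = tuple(p.strip() for p in str(organisms_raw).split(";") if p.strip())

    vol_raw = raw.get("volume_ml")
    if vol_raw is None or (isinstance(vol_raw, str) and not vol_raw.strip()):
        volume: Optional[float] = None
    else:
        try:
            volume = float(vol_raw)
        except (TypeError, ValueError):
            raise _RowError("volume_ml", "unparsable_volume")

    rec = BottleRecord(
        patient_id=req("patient_id"),
        age_years=age,
        center=req("center"),
        area=req("area").upper(),
        hospital_service=req("hospital_service"),
        sample_id=req("sample_id"),
        bottle_id=req("bottle_id"),
        specimen_origin=enum_field("specimen_origin", SpecimenOrigin),
        bottle_type=enum_field("bottle_type", BottleType),
        collected_at=collected,
        status=enum_field("status", BottleStatus),
        organisms=organisms,
        volume_ml=volume,
    )
    errs = rec.validation_errors(volume_cap)
    if errs:
        raise _RowError(errs[0][0], errs[0][1])
    return rec


def _infer_format(path: Union[str, Path], fmt: Optional[str]) -> str:
    if fmt:
        return fmt.lower()
    suffix = Path(path).suffix.lower()
    return "jsonl" if suffix in (".jsonl", ".ndjson", ".json") else "csv"


def _iter_raw_rows(path: Path, fmt: str):
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in COLUMNS if c not in header]
            if missing:
                raise SchemaError(f"missing mandatory column(s): {missing}")
            yield from reader
    elif fmt == "jsonl":
        with open(path, encoding="utf-8") as fh:
            first = True
            for line in fh:
                if not line.strip():
                    continue
                obj = json.loads(line)
                if first:
                    missing = [c for c in COLUMNS if c not in obj]
                    if missing:
                        raise SchemaError(f"missing mandatory key(s): {missing}")
                    first = False
                yield obj
    else:
        raise ValueError(f"unknown format {fmt!r}")


def scan(
    path: Union[str, Path],
    format: Optional[str] = None,
    volume_cap: float = DEFAULT_VOLUME_CAP,
    period_start: Optional[datetime] = None,
    period_end: Optional[datetime] = None,
) -> LoadResult:
    """Parse and validate a bottle export, keeping row-level diagnostics."""
    path = Path(path)
    fmt = _infer_format(path, format)
    rows = list(_iter_raw_rows(path, fmt))

    # Duplicate bottle keys are a fatal error, detected before row parsing.
    ids = Counter(str(r.get("bottle_id", "")).strip() for r in rows)
    dupes = sorted(b for b, n in ids.items() if b and n > 1)
    if dupes:
        raise DuplicateBottleIdError(f"duplicate bottle_id value(s): {dupes[:10]}")

    records: list[BottleRecord] = []
    rejects: list[RejectedRow] = []
    for i, raw in enumerate(rows, start=1):
        try:
            records.append(_parse_row(raw, volume_cap))
        except _RowError as err:
            rejects.append(RejectedRow(row_number=i, field=err.field, reason=err.reason))
    cohort = Cohort(records=records, period_start=period_start,
                    period_end=period_end, provenance=f"read from {path}")
    return LoadResult(cohort=cohort, rejects=rejects)


def read_bottles(
    path: Union[str, Path],
    format: Optional[str] = None,
    rejects_path: Optional[Union[str, Path]] = None,
    volume_cap: float = DEFAULT_VOLUME_CAP,
) -> Cohort:
    """Read a validated :class:`~bckpi.model.Cohort` from a bottle export.

    Invalid rows are dropped with a logged count; pass ``rejects_path`` to
    write the row-level rejects report, or use :func:`scan` for programmatic
    access to it.
    """
    result = scan(path, format=format, volume_cap=volume_cap)
    if result.rejects:
        logger.warning("read_bottles: rejected %d row(s) from %s",
                       len(result.rejects), path)
    if rejects_path is not None:
        write_rejects(result.rejects, rejects_path)
    return result.cohort


def write_rejects(rejects: list[RejectedRow], path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row_number", "field", "reason"])
        for rej in rejects:
            writer.writerow([rej.row_number, rej.field, rej.reason])


def _record_to_row(rec: BottleRecord) -> list[str]:
    return [
        rec.patient_id, str(rec.age_years), rec.center, rec.area,
        rec.hospital_service, rec.sample_id, rec.bottle_id,
        rec.specimen_origin.value, rec.bottle_type.value,
        rec.collected_at.isoformat(), rec.status.value,
        ";".join(rec.organisms),
        "" if rec.volume_ml is None else repr(float(rec.volume_ml)),
    ]


def _record_to_obj(rec: BottleRecord) -> dict:
    return {
        "patient_id": rec.patient_id,
        "age_years": rec.age_years,
        "center": rec.center,
        "area": rec.area,
        "hospital_service": rec.hospital_service,
        "sample_id": rec.sample_id,
        "bottle_id": rec.bottle_id,
        "specimen_origin": rec.specimen_origin.value,
        "bottle_type": rec.bottle_type.value,
        "collected_at": rec.collected_at.isoformat(),
        "status": rec.status.value,
        "organisms": list(rec.organisms),
        "volume_ml": rec.volume_ml,
    }


def write_cohort(cohort: Cohort, path: Union[str, Path], format: Optional[str] = None) -> None:
    """Write a cohort in the input dialect; ``read_bottles`` round-trips it."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
            writer.writerow(COLUMNS)
            for rec in cohort.records:
                writer.writerow(_record_to_row(rec))
    elif fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in cohort.records:
                fh.write(json.dumps(_record_to_obj(rec)) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
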