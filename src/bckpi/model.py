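"""Domain records for bottle-level blood-culture data.

The atomic input is one blood-culture bottle as exported by the laboratory
middleware: patient demographics, admission ward, the progressive sample
identification code tying bottles of one venipuncture together, the bottle
identifier, specimen origin (peripheral vein vs. intravascular device),
collection date/time, the instrument's positive/negative flag, bottle type
(aerobic/anaerobic), species identified from positive bottles, and the
measured blood fill volume.  A :class:`Cohort` is a validated collection of
such records over a surveillance period.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from datetime import datetime
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

#: Hospitalization areas used by the default stratification.  The area field
#: is an open label set; these are the canonical values.
KNOWN_AREAS = ("SURGICAL", "EMERGENCY", "MEDICAL", "TRAUMATOLOGY", "ICU")

#: Sanity cap for per-bottle blood volume, mL.  Standard adult bottles hold
#: 8-10 mL; anything above this is treated as a data error.
DEFAULT_VOLUME_CAP = 15.0


class SpecimenOrigin(str, enum.Enum):
    PV = "PV"
    CVC = "CVC"
    OTHER_DEVICE = "OTHER_DEVICE"


class BottleType(str, enum.Enum):
    AEROBIC = "AEROBIC"
    ANAEROBIC = "ANAEROBIC"
    OTHER = "OTHER"


class BottleStatus(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


@dataclasses.dataclass
class BottleRecord:
    """One blood-culture bottle (one input row)."""

    patient_id: str
    age_years: int
    center: str
    area: str
    hospital_service: str
    sample_id: str
    bottle_id: str
    specimen_origin: SpecimenOrigin
    bottle_type: BottleType
    collected_at: datetime
    status: BottleStatus
    organisms: tuple[str, ...] = ()
    volume_ml: Optional[float] = None

    def validation_errors(self, volume_cap: float = DEFAULT_VOLUME_CAP) -> list[tuple[str, str]]:
        """Return ``(field, reason_code)`` pairs; empty when the record is valid.

        Rules: identifiers non-empty, age a non-negative integer, organisms
        present only on POSITIVE bottles, volume within ``[0, volume_cap]``
        when present.
        """
        errors: list[tuple[str, str]] = []
        for field in ("patient_id", "bottle_id", "sample_id", "center", "area",
                      "hospital_service"):
            if not getattr(self, field):
                errors.append((field, "missing_value"))
        if not isinstance(self.age_years, int) or self.age_years < 0:
            errors.append(("age_years", "bad_age"))
        if self.status is BottleStatus.NEGATIVE and self.organisms:
            errors.append(("organisms", "organisms_on_negative_bottle"))
        if self.status is BottleStatus.POSITIVE and not self.organisms:
            errors.append(("organisms", "positive_without_organism"))
        if self.volume_ml is not None:
            if self.volume_ml < 0:
                errors.append(("volume_ml", "negative_volume"))
            elif self.volume_ml > volume_cap:
                errors.append(("volume_ml", "volume_above_cap"))
        return errors


@dataclasses.dataclass
class Cohort:
    """Validated bottle records over a surveillance period.

    When period bounds are omitted they default to the observed min/max
    collection time, so the within-period invariant holds by construction.
    """

    records: list[BottleRecord]
    period_start: Optional[datetime] = None
    period_end: Optional[datetime] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.records:
            times = [r.collected_at for r in self.records]
            if self.period_start is None:
                self.period_start = min(times)
            if self.period_end is None:
                self.period_end = max(times)

    def __len__(self) -> int:
        return len(self.records)

    def validate(self, volume_cap: float = DEFAULT_VOLUME_CAP) -> None:
        """Raise :class:`ValueError` on any invariant violation."""
        seen: set[str] = set()
        for rec in self.records:
            if rec.bottle_id in seen:
                raise ValueError(f"duplicate bottle_id {rec.bottle_id!r}")
            seen.add(rec.bottle_id)
            errs = rec.validation_errors(volume_cap)
            if errs:
                raise ValueError(f"invalid record {rec.bottle_id!r}: {errs}")
            if self.period_start and rec.collected_at < self.period_start:
                raise ValueError(f"{rec.bottle_id!r} collected before period start")
            if self.period_end and rec.collected_at > self.period_end:
                raise ValueError(f"{rec.bottle_id!r} collected after period end")


def filter_adults(cohort: Cohort, min_age: int = 18) -> Cohort:
    """Restrict a cohort to adult patients (``age_years >= min_age``).

    The boundary is inclusive: an 18-year-old is an adult.  Idempotent and
    monotone; the number of removed bottles is logged.
    """
    kept = [r for r in cohort.records if r.age_years >= min_age]
    removed = len(cohort.records) - len(kept)
    if removed:
        logger.info("filter_adults: removed %d bottle(s) below age %d", removed, min_age)
    return Cohort(
        records=kept,
        period_start=cohort.period_start,
        period_end=cohort.period_end,
        provenance=cohort.provenance,
    )


def distinct_patients(records: Iterable[BottleRecord]) -> int:
    return len({r.patient_id for r in records})
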