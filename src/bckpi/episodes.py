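"""Grouping bottles into sampling sets and 24-hour episodes.

A *BC set* is the group of bottles drawn in one sampling procedure (same
progressive sample identification code) — typically an aerobic/anaerobic
pair, sometimes a single bottle.  A *BC episode* collects all bottles from
one patient in one hospital area within 24 hours of the first (index)
sample, which anchors hour 0.  Windows are fixed and anchored: a bottle
falling outside the window starts a new episode, it never extends the old
one.  The "within 24 h" bound is read as a closed interval, so a bottle at
exactly anchor + 24 h belongs to the anchored episode.

Episode classification:

* CVC episode — at least one bottle drawn from an intravascular device;
  any peripheral-vein samples in the same episode belong to the CVC episode.
* PV episode — all bottles from peripheral vein.
* solitary — exactly one set (covering both the single-set and the
  single-bottle case), a sensitivity-reducing practice tracked by KPI 2.
* unpaired CVC — a CVC episode with no peripheral-vein bottle at all, which
  precludes differential-time-to-positivity interpretation (KPI 3).
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import logging
from collections import defaultdict
from datetime import datetime, timedelta
from typing import Iterable, Optional, Union

from .model import BottleRecord, BottleStatus, BottleType, Cohort, SpecimenOrigin

logger = logging.getLogger(__name__)


class SetMode(str, enum.Enum):
    STRICT = "STRICT"      # split implausible sets (duplicate bottle type / mixed origin)
    LENIENT = "LENIENT"    # keep sample_id groups as exported


class Grouping(str, enum.Enum):
    PATIENT_AREA = "PATIENT_AREA"
    PATIENT_SERVICE = "PATIENT_SERVICE"
    PATIENT_ONLY = "PATIENT_ONLY"


class DevicePolicy(str, enum.Enum):
    """How OTHER_DEVICE origins (arterial line, port...) enter classification."""

    AS_CVC = "AS_CVC"
    AS_PV = "AS_PV"
    IGNORE = "IGNORE"


class SetConsistencyError(ValueError):
    """One sample_id spans multiple patients."""


@dataclasses.dataclass
class BCSet:
    """Bottles obtained from the same sampling procedure."""

    sample_id: str
    bottles: tuple[BottleRecord, ...]

    @property
    def patient_id(self) -> str:
        return self.bottles[0].patient_id

    @property
    def collection_time(self) -> datetime:
        return min(b.collected_at for b in self.bottles)

    @property
    def bottle_ids(self) -> tuple[str, ...]:
        return tuple(b.bottle_id for b in self.bottles)


@dataclasses.dataclass
class Episode:
    """All bottles from one patient (in one area) within the anchored window."""

    episode_id: str
    patient_id: str
    center: str
    area: str
    hospital_service: str
    anchor_time: datetime
    bottles: tuple[BottleRecord, ...]
    sets: Optional[tuple[BCSet, ...]] = None
    episode_type: Optional[str] = None       # "PV" | "CVC"
    is_solitary: Optional[bool] = None
    is_positive: Optional[bool] = None
    total_volume_ml: Optional[float] = None  # sum of known fill volumes
    n_missing_volume: int = 0

    @property
    def n_bottles(self) -> int:
        return len(self.bottles)

    @property
    def n_sets(self) -> int:
        return len(self.sets) if self.sets is not None else 0


def _is_device(bottle: BottleRecord, policy: DevicePolicy) -> bool:
    if bottle.specimen_origin is SpecimenOrigin.CVC:
        return True
    return bottle.specimen_origin is SpecimenOrigin.OTHER_DEVICE and policy is DevicePolicy.AS_CVC


def _is_pv(bottle: BottleRecord, policy: DevicePolicy) -> bool:
    if bottle.specimen_origin is SpecimenOrigin.PV:
        return True
    return bottle.specimen_origin is SpecimenOrigin.OTHER_DEVICE and policy is DevicePolicy.AS_PV


def _records(source: Union[Cohort, Iterable[BottleRecord]]) -> list[BottleRecord]:
    return list(source.records) if isinstance(source, Cohort) else list(source)


def build_sets(
    source: Union[Cohort, Iterable[BottleRecord]],
    mode: SetMode = SetMode.STRICT,
) -> list[BCSet]:
    """Partition bottles into sampling sets keyed by sample identification code.

    STRICT mode splits a sample_id group that is not a plausible single
    procedure — more than one bottle of the same type, or mixed specimen
    origins — into singleton sets, with a logged warning.  LENIENT keeps the
    exported grouping intact.  A sample_id shared across patients is a fatal
    consistency error.
    """
    records = _records(source)
    groups: dict[str, list[BottleRecord]] = defaultdict(list)
    for rec in records:
        groups[rec.sample_id].append(rec)

    sets: list[BCSet] = []
    for sample_id in groups:
        bottles = sorted(groups[sample_id], key=lambda b: (b.collected_at, b.bottle_id))
        patients = {b.patient_id for b in bottles}
        if len(patients) > 1:
            raise SetConsistencyError(
                f"sample_id {sample_id!r} spans patients {sorted(patients)}")
        implausible = False
        if mode is SetMode.STRICT and len(bottles) > 1:
            type_counts = defaultdict(int)
            for b in bottles:
                type_counts[b.bottle_type] += 1
            origins = {b.specimen_origin for b in bottles}
            implausible = any(n > 1 for n in type_counts.values()) or len(origins) > 1
        if implausible:
            logger.warning(
                "build_sets: sample_id %r not a plausible single procedure "
                "(%d bottles); split into singletons", sample_id, len(bottles))
            sets.extend(BCSet(sample_id=sample_id, bottles=(b,)) for b in bottles)
        else:
            sets.append(BCSet(sample_id=sample_id, bottles=tuple(bottles)))
    sets.sort(key=lambda s: (s.patient_id, s.collection_time, s.bottle_ids))
    return sets


def _group_label(rec: BottleRecord, grouping: Grouping) -> str:
    if grouping is Grouping.PATIENT_AREA:
        return rec.area
    if grouping is Grouping.PATIENT_SERVICE:
        return rec.hospital_service
    return ""


def _episode_id(patient_id: str, group_label: str, anchor: datetime) -> str:
    key = f"{patient_id}|{group_label}|{anchor.isoformat()}"
    return hashlib.sha1(key.encode("utf-8")).hexdigest()[:16]


def classify_episode(episode: Episode, device_policy: DevicePolicy = DevicePolicy.AS_CVC) -> Episode:
    """Fill the derived episode flags (in place; the episode is returned).

    Requires ``episode.sets`` to be attached.  ``episode_type`` is CVC iff at
    least one bottle is device-drawn; ``is_solitary`` iff the episode holds
    exactly one set; ``is_positive`` iff any bottle flagged positive.
    """
    if episode.sets is None:
        raise ValueError("classify_episode: episode has no set structure attached")
    episode.episode_type = (
        "CVC" if any(_is_device(b, device_policy) for b in episode.bottles) else "PV"
    )
    episode.is_solitary = len(episode.sets) == 1
    episode.is_positive = any(b.status is BottleStatus.POSITIVE for b in episode.bottles)
    known = [b.volume_ml for b in episode.bottles if b.volume_ml is not None]
    episode.total_volume_ml = sum(known) if known else None
    episode.n_missing_volume = len(episode.bottles) - len(known)
    return episode


def is_unpaired_cvc(episode: Episode, device_policy: DevicePolicy = DevicePolicy.AS_CVC) -> bool:
    """True iff a CVC episode includes no peripheral-vein sample."""
    if episode.episode_type != "CVC":
        return False
    return not any(_is_pv(b, device_policy) for b in episode.bottles)


def build_episodes(
    cohort: Union[Cohort, Iterable[BottleRecord]],
    window_hours: float = 24.0,
    grouping: Grouping = Grouping.PATIENT_AREA,
    set_mode: SetMode = SetMode.STRICT,
    device_policy: DevicePolicy = DevicePolicy.AS_CVC,
) -> list[Episode]:
    """Partition a cohort into anchored-window episodes and classify them.

    Within each grouping key, bottles are sorted by collection time (ties by
    bottle_id); the earliest unassigned bottle anchors an episode at hour 0
    and every bottle with ``collected_at <= anchor + window`` joins it; the
    next unassigned bottle anchors the next episode.  Every bottle lands in
    exactly one episode, independent of input row order.
    """
    if window_hours <= 0:
        raise ValueError("window_hours must be positive")
    records = _records(cohort)
    window = timedelta(hours=window_hours)

    by_key: dict[tuple[str, str], list[BottleRecord]] = defaultdict(list)
    for rec in records:
        by_key[(rec.patient_id, _group_label(rec, grouping))].append(rec)

    episodes: list[Episode] = []
    sample_to_episode: dict[str, set[str]] = defaultdict(set)
    for (patient_id, label) in sorted(by_key):
        bottles = sorted(by_key[(patient_id, label)],
                         key=lambda b: (b.collected_at, b.bottle_id))
        i = 0
        while i < len(bottles):
            anchor = bottles[i].collected_at
            j = i
            while j < len(bottles) and bottles[j].collected_at <= anchor + window:
                j += 1
            chunk = tuple(bottles[i:j])
            index = chunk[0]
            episode = Episode(
                episode_id=_episode_id(patient_id, label, anchor),
                patient_id=patient_id,
                center=index.center,
                area=index.area,
                hospital_service=index.hospital_service,
                anchor_time=anchor,
                bottles=chunk,
                sets=tuple(build_sets(chunk, mode=set_mode)),
            )
            classify_episode(episode, device_policy)
            episodes.append(episode)
            for b in chunk:
                sample_to_episode[b.sample_id].add(episode.episode_id)
            i = j

    straddling = [s for s, eps in sample_to_episode.items() if len(eps) > 1]
    if straddling:
        logger.warning("build_episodes: %d sampling procedure(s) straddle "
                       "episode boundaries, e.g. %r", len(straddling), straddling[0])
    return episodes


def episodes_to_rows(episodes: list[Episode],
                     device_policy: DevicePolicy = DevicePolicy.AS_CVC) -> list[dict]:
    """One export row per episode (the episode-level CSV/JSONL surface)."""
    rows = []
    for ep in episodes:
        rows.append({
            "episode_id": ep.episode_id,
            "patient_id": ep.patient_id,
            "center": ep.center,
            "area": ep.area,
            "hospital_service": ep.hospital_service,
            "anchor_time": ep.anchor_time.isoformat(),
            "n_bottles": ep.n_bottles,
            "n_sets": ep.n_sets,
            "episode_type": ep.episode_type,
            "is_solitary": ep.is_solitary,
            "is_positive": ep.is_positive,
            "total_volume_ml": ep.total_volume_ml,
            "is_unpaired_cvc": is_unpaired_cvc(ep, device_policy),
        })
    return rows
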