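"""Shared builders and independent oracles for the test suite.

The oracles here deliberately re-derive the grouping and review rules from
their plain-language definitions, independently of the library internals,
so equivalence tests are meaningful.
"""

from __future__ import annotations

from datetime import datetime, timedelta

from bckpi.model import BottleRecord, BottleStatus, BottleType, SpecimenOrigin

T0 = datetime(2023, 1, 1, 8, 0)


def make_bottle(bottle_id="B1", patient_id="P1", sample_id=None, hours=0.0,
                origin=SpecimenOrigin.PV, btype=BottleType.AEROBIC,
                status=BottleStatus.NEGATIVE, organisms=(), volume=6.0,
                center="C1", area="MEDICAL", service="MED-1", age=50):
    return BottleRecord(
        patient_id=patient_id, age_years=age, center=center, area=area,
        hospital_service=service,
        sample_id=sample_id if sample_id is not None else f"S-{bottle_id}",
        bottle_id=bottle_id, specimen_origin=origin, bottle_type=btype,
        collected_at=T0 + timedelta(hours=hours), status=status,
        organisms=tuple(organisms), volume_ml=volume)


def bruteforce_episode_partition(records, window_hours=24.0):
    """Anchored-window grouping per (patient, area), derived from scratch.

    Returns a set of frozensets of bottle_ids.  Quadratic scan: repeatedly
    take the globally earliest unassigned bottle of each (patient, area)
    group as anchor and claim every bottle within the closed window.
    """
    window = timedelta(hours=window_hours)
    episodes = []
    remaining = list(records)
    while remaining:
        # earliest unassigned bottle overall, ties by bottle_id
        anchor = min(remaining, key=lambda b: (b.collected_at, b.bottle_id))
        members = [b for b in remaining
                   if b.patient_id == anchor.patient_id
                   and b.area == anchor.area
                   and anchor.collected_at <= b.collected_at
                   <= anchor.collected_at + window]
        episodes.append(frozenset(b.bottle_id for b in members))
        ids = {b.bottle_id for b in members}
        remaining = [b for b in remaining if b.bottle_id not in ids]
    return set(episodes)


def literal_same_set_pair_rule(org_to_bottles: dict, set_of_bottle: dict) -> bool:
    """The after-review criterion applied literally to occurrence patterns:

    some organism is positive in exactly two bottles over the whole episode
    and those two bottles belong to the same sampling set.
    """
    for bottles in org_to_bottles.values():
        if len(bottles) == 2:
            a, b = sorted(bottles)
            if set_of_bottle[a] == set_of_bottle[b]:
                return True
    return False
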