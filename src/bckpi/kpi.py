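"""Stratified KPI computation for the blood-culture process.

KPI 1  mean blood volume — per bottle (bottle-count-weighted mean of known
       fill volumes) and per episode (mean of each episode's summed known
       volumes).  Bottles without a volume measurement are excluded from
       numerator and denominator and surfaced as ``n_missing``, never
       imputed as zero.
KPI 2  rate of solitary episodes over all episodes (PV and CVC alike).
KPI 3  rate of CVC episodes lacking any peripheral-vein set, over CVC
       episodes.
KPI 4a rate of restrictive-criteria contaminations over non-solitary PV
       episodes; KPI 4b adds contaminations confirmed after (automatic or
       manual) review, same denominator.

Auxiliary indicators: bottles/episode, episodes/patient, episode positivity
(optionally excluding contaminated episodes), and ordering intensity as
sets per 1,000 patient-days when patient-day denominators are supplied.

Strata are disjoint and cover all episodes at each level; numerators and
denominators are therefore additive from any level up to OVERALL.  Service-
level cells carry representativeness flags: volume and solitary-rate cells
need more than 500 episodes, the unpaired-CVC rate more than 75 CVC
episodes (strict thresholds, configurable) to be displayable.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import json
from collections import defaultdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

from .contamination import CONTAMINATED_CATEGORIES, Category, ContaminationAssessment
from .episodes import DevicePolicy, Episode, is_unpaired_cvc


class KpiId(str, enum.Enum):
    KPI1_BOTTLE = "KPI1_BOTTLE"
    KPI1_EPISODE = "KPI1_EPISODE"
    KPI2 = "KPI2"
    KPI3 = "KPI3"
    KPI4A = "KPI4A"
    KPI4B = "KPI4B"
    POSITIVITY = "POSITIVITY"
    BOTTLES_PER_EPISODE = "BOTTLES_PER_EPISODE"
    EPISODES_PER_PATIENT = "EPISODES_PER_PATIENT"
    SETS_PER_1000PD = "SETS_PER_1000PD"


#: Rates expressed as percentages.
RATE_KPIS = frozenset({KpiId.KPI2, KpiId.KPI3, KpiId.KPI4A, KpiId.KPI4B,
                       KpiId.POSITIVITY})

#: Display rounding: rates to 1 decimal; volumes and bottles/episode to 2.
DISPLAY_DECIMALS = {
    KpiId.KPI1_BOTTLE: 2, KpiId.KPI1_EPISODE: 2,
    KpiId.KPI2: 1, KpiId.KPI3: 1, KpiId.KPI4A: 1, KpiId.KPI4B: 1,
    KpiId.POSITIVITY: 1, KpiId.BOTTLES_PER_EPISODE: 2,
    KpiId.EPISODES_PER_PATIENT: 1, KpiId.SETS_PER_1000PD: 1,
}


class StratumLevel(str, enum.Enum):
    OVERALL = "OVERALL"
    CENTER = "CENTER"
    AREA = "AREA"
    SERVICE = "SERVICE"
    CENTER_X_AREA = "CENTER_X_AREA"


OVERALL_LABEL = "ALL"


def stratum_label(episode: Episode, level: StratumLevel) -> str:
    if level is StratumLevel.OVERALL:
        return OVERALL_LABEL
    if level is StratumLevel.CENTER:
        return episode.center
    if level is StratumLevel.AREA:
        return episode.area
    if level is StratumLevel.SERVICE:
        return episode.hospital_service
    return f"{episode.center}|{episode.area}"


def _strata(episodes: Sequence[Episode], level: StratumLevel) -> dict[str, list[Episode]]:
    out: dict[str, list[Episode]] = defaultdict(list)
    for ep in episodes:
        out[stratum_label(ep, level)].append(ep)
    return dict(sorted(out.items()))


@dataclasses.dataclass
class KpiCell:
    stratum_level: StratumLevel
    stratum_label: str
    kpi_id: KpiId
    numerator: float
    denominator: float
    value: Optional[float]
    displayable: bool = True
    n_missing: int = 0

    @property
    def display_value(self) -> Optional[float]:
        if self.value is None:
            return None
        return round(self.value, DISPLAY_DECIMALS[self.kpi_id])


def make_cell(level: StratumLevel, label: str, kpi_id: KpiId,
              numerator: float, denominator: float,
              n_missing: int = 0) -> KpiCell:
    """Cell with value = numerator/denominator (x100 for percentage rates);
    a zero denominator leaves the value undefined and not displayable."""
    if denominator > 0:
        value = numerator / denominator
        if kpi_id in RATE_KPIS:
            value *= 100.0
        displayable = True
    else:
        value = None
        displayable = False
    return KpiCell(level, label, kpi_id, numerator, denominator, value,
                   displayable, n_missing)


def kpi1_volume(episodes: Sequence[Episode], level: StratumLevel) -> list[KpiCell]:
    """Mean blood volume per bottle and per episode, by stratum."""
    cells = []
    for label, eps in _strata(episodes, level).items():
        vol_sum = 0.0
        n_known = 0
        n_missing_bottles = 0
        ep_sum = 0.0
        n_ep_known = 0
        for ep in eps:
            n_missing_bottles += ep.n_missing_volume
            n_known += ep.n_bottles - ep.n_missing_volume
            if ep.total_volume_ml is not None:
                vol_sum += ep.total_volume_ml
                ep_sum += ep.total_volume_ml
                n_ep_known += 1
        cells.append(make_cell(level, label, KpiId.KPI1_BOTTLE,
                               vol_sum, n_known, n_missing=n_missing_bottles))
        cells.append(make_cell(level, label, KpiId.KPI1_EPISODE,
                               ep_sum, n_ep_known,
                               n_missing=len(eps) - n_ep_known))
    return cells


def kpi2_solitary(episodes: Sequence[Episode], level: StratumLevel) -> list[KpiCell]:
    """Solitary episodes over all episodes, as a percentage."""
    return [
        make_cell(level, label, KpiId.KPI2,
                  sum(1 for ep in eps if ep.is_solitary), len(eps))
        for label, eps in _strata(episodes, level).items()
    ]


def kpi3_unpaired_cvc(episodes: Sequence[Episode], level: StratumLevel,
                      device_policy: DevicePolicy = DevicePolicy.AS_CVC) -> list[KpiCell]:
    """CVC episodes without any peripheral-vein sample, over CVC episodes."""
    cells = []
    for label, eps in _strata(episodes, level).items():
        cvc = [ep for ep in eps if ep.episode_type == "CVC"]
        unpaired = sum(1 for ep in cvc if is_unpaired_cvc(ep, device_policy))
        cells.append(make_cell(level, label, KpiId.KPI3, unpaired, len(cvc)))
    return cells


class Kpi4Mode(str, enum.Enum):
    RESTRICTIVE = "RESTRICTIVE"
    AFTER_REVIEW = "AFTER_REVIEW"


def kpi4_contamination(
    episodes: Sequence[Episode],
    assessments: Sequence[ContaminationAssessment],
    mode: Kpi4Mode,
    level: StratumLevel,
) -> list[KpiCell]:
    """Contamination rate over non-solitary PV episodes.

    RESTRICTIVE counts restrictive-criteria contaminations only (KPI 4a);
    AFTER_REVIEW adds contaminations confirmed after review (KPI 4b).
    """
    category_of = {a.episode_id: a.category for a in assessments}
    numer_cats = ((Category.RESTRICTIVE_CONTAMINATION,)
                  if mode is Kpi4Mode.RESTRICTIVE else CONTAMINATED_CATEGORIES)
    kpi_id = KpiId.KPI4A if mode is Kpi4Mode.RESTRICTIVE else KpiId.KPI4B
    cells = []
    for label, eps in _strata(episodes, level).items():
        eligible = [ep for ep in eps if ep.episode_type == "PV" and not ep.is_solitary]
        numer = sum(1 for ep in eligible
                    if category_of.get(ep.episode_id) in numer_cats)
        cells.append(make_cell(level, label, kpi_id, numer, len(eligible)))
    return cells


def auxiliary_indicators(
    episodes: Sequence[Episode],
    level: StratumLevel,
    patient_days: Optional[dict[str, float]] = None,
    assessments: Optional[Sequence[ContaminationAssessment]] = None,
    positivity_excludes_contaminated: bool = False,
) -> list[KpiCell]:
    """Bottles/episode, episodes/patient, positivity, sets per 1,000 patient-days.

    ``patient_days`` maps stratum label (``"ALL"`` for OVERALL) to census
    patient-days; without it the ordering-intensity cell is marked
    unavailable.  With ``positivity_excludes_contaminated`` episodes counted
    as contaminated (restrictive or after review) leave the positivity
    numerator.
    """
    contaminated: set[str] = set()
    if positivity_excludes_contaminated and assessments:
        contaminated = {a.episode_id for a in assessments
                        if a.category in CONTAMINATED_CATEGORIES}
    cells = []
    for label, eps in _strata(episodes, level).items():
        n_ep = len(eps)
        n_bottles = sum(ep.n_bottles for ep in eps)
        n_sets = sum(ep.n_sets for ep in eps)
        n_patients = len({ep.patient_id for ep in eps})
        n_pos = sum(1 for ep in eps
                    if ep.is_positive and ep.episode_id not in contaminated)
        cells.append(make_cell(level, label, KpiId.BOTTLES_PER_EPISODE, n_bottles, n_ep))
        cells.append(make_cell(level, label, KpiId.EPISODES_PER_PATIENT, n_ep, n_patients))
        cells.append(make_cell(level, label, KpiId.POSITIVITY, n_pos, n_ep))
        if patient_days is not None and label in patient_days and patient_days[label] > 0:
            cells.append(KpiCell(level, label, KpiId.SETS_PER_1000PD,
                                 n_sets, patient_days[label],
                                 n_sets / patient_days[label] * 1000.0))
        else:
            cells.append(KpiCell(level, label, KpiId.SETS_PER_1000PD,
                                 n_sets, 0.0, None, displayable=False))
    return cells


@dataclasses.dataclass
class KpiReport:
    cells: list[KpiCell]
    config: dict = dataclasses.field(default_factory=dict)
    generated_at: str = ""

    def __post_init__(self) -> None:
        if not self.generated_at:
            self.generated_at = datetime.now(timezone.utc).isoformat(timespec="seconds")

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode("utf-8")).hexdigest()[:12]

    def cell(self, level: StratumLevel, label: str, kpi_id: KpiId) -> KpiCell:
        for c in self.cells:
            if (c.stratum_level is level and c.stratum_label == label
                    and c.kpi_id is kpi_id):
                return c
        raise KeyError((level, label, kpi_id))

    def to_rows(self) -> list[dict]:
        return [{
            "stratum_level": c.stratum_level.value,
            "stratum_label": c.stratum_label,
            "kpi_id": c.kpi_id.value,
            "numerator": c.numerator,
            "denominator": c.denominator,
            "value": c.display_value,
            "displayable": c.displayable,
            "n_missing": c.n_missing,
        } for c in self.cells]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.to_rows())

    def write_csv(self, path: Union[str, Path]) -> None:
        import csv

        rows = self.to_rows()
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()) if rows else
                                    ["stratum_level", "stratum_label", "kpi_id",
                                     "numerator", "denominator", "value",
                                     "displayable", "n_missing"])
            writer.writeheader()
            writer.writerows(rows)
        with open(Path(path).with_suffix(".meta.json"), "w", encoding="utf-8") as fh:
            json.dump({"config_hash": self.config_hash, "config": self.config,
                       "generated_at": self.generated_at}, fh, indent=2, default=str)

    def write_json(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"config_hash": self.config_hash, "config": self.config,
                       "generated_at": self.generated_at,
                       "cells": self.to_rows()}, fh, indent=2, default=str)


DEFAULT_LEVELS = (StratumLevel.OVERALL, StratumLevel.CENTER, StratumLevel.AREA,
                  StratumLevel.SERVICE)


def compute_report(
    episodes: Sequence[Episode],
    assessments: Sequence[ContaminationAssessment],
    levels: Sequence[StratumLevel] = DEFAULT_LEVELS,
    patient_days: Optional[dict[str, float]] = None,
    device_policy: DevicePolicy = DevicePolicy.AS_CVC,
    config: Optional[dict] = None,
    kpi12_min_episodes: int = 500,
    kpi3_min_cvc: int = 75,
) -> KpiReport:
    """Compute every KPI at every requested level and apply display thresholds."""
    cells: list[KpiCell] = []
    for level in levels:
        cells += kpi1_volume(episodes, level)
        cells += kpi2_solitary(episodes, level)
        cells += kpi3_unpaired_cvc(episodes, level, device_policy)
        cells += kpi4_contamination(episodes, assessments, Kpi4Mode.RESTRICTIVE, level)
        cells += kpi4_contamination(episodes, assessments, Kpi4Mode.AFTER_REVIEW, level)
        cells += auxiliary_indicators(episodes, level, patient_days, assessments)
    report = KpiReport(cells=cells, config=dict(config or {}))
    return apply_display_thresholds(report, kpi12_min_episodes, kpi3_min_cvc)


def apply_display_thresholds(report: KpiReport,
                             kpi12_min_episodes: int = 500,
                             kpi3_min_cvc: int = 75) -> KpiReport:
    """Gray out service-level cells below the representativeness thresholds.

    Volume and solitary-rate cells require strictly more than
    ``kpi12_min_episodes`` episodes; the unpaired-CVC cell strictly more
    than ``kpi3_min_cvc`` CVC episodes.
    """
    episodes_in: dict[str, float] = {}
    cvc_in: dict[str, float] = {}
    for c in report.cells:
        if c.stratum_level is not StratumLevel.SERVICE:
            continue
        if c.kpi_id is KpiId.KPI2:
            episodes_in[c.stratum_label] = c.denominator
        elif c.kpi_id is KpiId.KPI3:
            cvc_in[c.stratum_label] = c.denominator
    for c in report.cells:
        if c.stratum_level is not StratumLevel.SERVICE:
            continue
        if c.kpi_id in (KpiId.KPI1_BOTTLE, KpiId.KPI1_EPISODE, KpiId.KPI2):
            if episodes_in.get(c.stratum_label, 0) <= kpi12_min_episodes:
                c.displayable = False
        elif c.kpi_id is KpiId.KPI3:
            if cvc_in.get(c.stratum_label, 0) <= kpi3_min_cvc:
                c.displayable = False
    return report
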