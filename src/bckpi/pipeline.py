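"""End-to-end analysis pipeline: read -> filter -> group -> assess -> report.

This is the library surface behind the ``bckpi compute`` command; the CLI
adds nothing but argument parsing and file placement.
"""

from __future__ import annotations

import dataclasses
from datetime import datetime
from typing import Optional, Sequence, Union

from . import io as bcio
from .contamination import (
    AdjudicationRecord,
    ContaminantPanel,
    ContaminationAssessment,
    apply_adjudications,
    assess_episode,
    run_auto_review,
)
from .episodes import DevicePolicy, Episode, Grouping, SetMode, build_episodes
from .kpi import DEFAULT_LEVELS, KpiReport, StratumLevel, compute_report
from .model import Cohort, filter_adults


@dataclasses.dataclass
class RunConfig:
    """Serializable configuration of one analysis run."""

    input_path: str = ""
    input_format: Optional[str] = None
    period_start: Optional[str] = None
    period_end: Optional[str] = None
    min_age: int = 18
    window_hours: float = 24.0
    grouping: Grouping = Grouping.PATIENT_AREA
    set_mode: SetMode = SetMode.STRICT
    device_policy: DevicePolicy = DevicePolicy.AS_CVC
    auto_review: bool = True
    kpi12_min_episodes: int = 500
    kpi3_min_cvc: int = 75
    panel_path: Optional[str] = None

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        for key in ("grouping", "set_mode", "device_policy"):
            data[key] = getattr(self, key).value
        return data


@dataclasses.dataclass
class PipelineResult:
    cohort: Cohort
    episodes: list[Episode]
    assessments: list[ContaminationAssessment]
    report: KpiReport
    rejects: list
    n_underage: int


def run_pipeline(
    source: Union[str, Cohort],
    config: Optional[RunConfig] = None,
    panel: Optional[ContaminantPanel] = None,
    adjudications: Optional[Sequence[AdjudicationRecord]] = None,
    patient_days: Optional[dict[str, float]] = None,
    levels: Sequence[StratumLevel] = DEFAULT_LEVELS,
) -> PipelineResult:
    """Run the full analysis on a file path or an in-memory cohort."""
    config = config or RunConfig()
    if panel is None:
        panel = (ContaminantPanel.from_yaml(config.panel_path)
                 if config.panel_path else ContaminantPanel())

    rejects: list = []
    if isinstance(source, Cohort):
        cohort = source
    else:
        result = bcio.scan(source, format=config.input_format)
        cohort, rejects = result.cohort, result.rejects
        config.input_path = str(source)

    if config.period_start or config.period_end:
        start = (datetime.fromisoformat(config.period_start)
                 if config.period_start else None)
        end = (datetime.fromisoformat(config.period_end)
               if config.period_end else None)
        kept = [r for r in cohort.records
                if (start is None or r.collected_at >= start)
                and (end is None or r.collected_at <= end)]
        cohort = Cohort(records=kept, period_start=start, period_end=end,
                        provenance=cohort.provenance)

    n_before = len(cohort)
    cohort = filter_adults(cohort, min_age=config.min_age)
    n_underage = n_before - len(cohort)

    episodes = build_episodes(cohort, window_hours=config.window_hours,
                              grouping=config.grouping, set_mode=config.set_mode,
                              device_policy=config.device_policy)
    assessments = [assess_episode(ep, panel) for ep in episodes]
    if config.auto_review:
        run_auto_review(episodes, assessments)
    if adjudications:
        apply_adjudications(assessments, adjudications)

    report = compute_report(
        episodes, assessments, levels=levels, patient_days=patient_days,
        device_policy=config.device_policy, config=config.to_dict(),
        kpi12_min_episodes=config.kpi12_min_episodes,
        kpi3_min_cvc=config.kpi3_min_cvc)
    return PipelineResult(cohort=cohort, episodes=episodes,
                          assessments=assessments, report=report,
                          rejects=rejects, n_underage=n_underage)
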