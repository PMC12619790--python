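"""KPI arithmetic, stratification, additivity and display thresholds."""

import pytest

from bckpi.contamination import ContaminantPanel, assess_episode, run_auto_review
from bckpi.episodes import build_episodes
from bckpi.kpi import (
    KpiCell,
    KpiId,
    Kpi4Mode,
    StratumLevel,
    apply_display_thresholds,
    auxiliary_indicators,
    compute_report,
    kpi1_volume,
    kpi2_solitary,
    kpi4_contamination,
    make_cell,
    KpiReport,
)
from bckpi.model import BottleStatus, BottleType
from bckpi.pipeline import run_pipeline
from helpers import make_bottle


def _cells_by(cells, kpi_id):
    return {c.stratum_label: c for c in cells if c.kpi_id is kpi_id}


class TestKpi1:
    def test_bottle_level_is_arithmetic_mean(self):
        bottles = [make_bottle("B1", sample_id="S1", volume=5.0),
                   make_bottle("B2", sample_id="S2", hours=1, volume=7.0)]
        eps = build_episodes(bottles)
        cell = _cells_by(kpi1_volume(eps, StratumLevel.OVERALL), KpiId.KPI1_BOTTLE)["ALL"]
        assert cell.value == 6.0

    def test_overall_is_weighted_mean_not_mean_of_means(self):
        bottles = [
            make_bottle("B1", patient_id="PA", area="MEDICAL", sample_id="S1", volume=8.0),
            make_bottle("B2", patient_id="PA", area="MEDICAL", sample_id="S1",
                        btype=BottleType.ANAEROBIC, hours=0.1, volume=8.0),
            make_bottle("B3", patient_id="PB", area="ICU", sample_id="S2", volume=5.0),
        ]
        eps = build_episodes(bottles)
        overall = _cells_by(kpi1_volume(eps, StratumLevel.OVERALL),
                            KpiId.KPI1_BOTTLE)["ALL"]
        assert overall.value == pytest.approx(7.0)   # (8+8+5)/3, not 6.75

    def test_missing_volume_excluded_and_counted(self):
        bottles = [make_bottle("B1", sample_id="S1", volume=6.0),
                   make_bottle("B2", sample_id="S2", hours=1, volume=None)]
        eps = build_episodes(bottles)
        cell = _cells_by(kpi1_volume(eps, StratumLevel.OVERALL), KpiId.KPI1_BOTTLE)["ALL"]
        assert (cell.value, cell.denominator, cell.n_missing) == (6.0, 1, 1)

    def test_stratum_without_volumes_is_undefined(self):
        eps = build_episodes([make_bottle("B1", volume=None)])
        cell = _cells_by(kpi1_volume(eps, StratumLevel.OVERALL), KpiId.KPI1_BOTTLE)["ALL"]
        assert cell.value is None and cell.displayable is False


class TestRates:
    def test_published_total_solitary_rate(self):
        assert make_cell(StratumLevel.OVERALL, "ALL", KpiId.KPI2,
                         12149, 55819).display_value == 21.8

    def test_zero_solitary_gives_zero(self):
        bottles = [make_bottle(f"B{i}", sample_id=f"S{i}", hours=0.1 * i)
                   for i in range(4)]
        eps = build_episodes(bottles)
        assert _cells_by(kpi2_solitary(eps, StratumLevel.OVERALL),
                         KpiId.KPI2)["ALL"].value == 0.0

    def test_empty_denominator_is_undefined(self):
        cell = make_cell(StratumLevel.AREA, "ICU", KpiId.KPI4A, 0, 0)
        assert cell.value is None and not cell.displayable

    def test_rate_values_bounded(self, small_generated):
        result = run_pipeline(small_generated.cohort)
        for c in result.report.cells:
            if c.kpi_id in (KpiId.KPI2, KpiId.KPI3, KpiId.KPI4A, KpiId.KPI4B,
                            KpiId.POSITIVITY) and c.value is not None:
                assert 0.0 <= c.value <= 100.0


class TestKpi4:
    def test_after_review_numerator_includes_confirmed(self):
        panel = ContaminantPanel()
        bottles = [
            # episode 1: restrictive (one S. epidermidis bottle among 4)
            make_bottle("A1", patient_id="P1", sample_id="S1", organisms=("Staphylococcus epidermidis",),
                        status=BottleStatus.POSITIVE),
            make_bottle("A2", patient_id="P1", sample_id="S1", btype=BottleType.ANAEROBIC, hours=0.1),
            make_bottle("A3", patient_id="P1", sample_id="S2", hours=0.5),
            make_bottle("A4", patient_id="P1", sample_id="S2", btype=BottleType.ANAEROBIC, hours=0.6),
            # episode 2: same-set pair -> confirmed after auto review
            make_bottle("C1", patient_id="P2", sample_id="S3", organisms=("Staphylococcus hominis",),
                        status=BottleStatus.POSITIVE),
            make_bottle("C2", patient_id="P2", sample_id="S3", btype=BottleType.ANAEROBIC,
                        hours=0.1, organisms=("Staphylococcus hominis",), status=BottleStatus.POSITIVE),
            make_bottle("C3", patient_id="P2", sample_id="S4", hours=0.5),
            make_bottle("C4", patient_id="P2", sample_id="S4", btype=BottleType.ANAEROBIC, hours=0.6),
        ]
        eps = build_episodes(bottles)
        assessments = [assess_episode(ep, panel) for ep in eps]
        run_auto_review(eps, assessments)
        a_cell = _cells_by(kpi4_contamination(eps, assessments, Kpi4Mode.RESTRICTIVE,
                                              StratumLevel.OVERALL), KpiId.KPI4A)["ALL"]
        b_cell = _cells_by(kpi4_contamination(eps, assessments, Kpi4Mode.AFTER_REVIEW,
                                              StratumLevel.OVERALL), KpiId.KPI4B)["ALL"]
        assert (a_cell.numerator, a_cell.denominator) == (1, 2)
        assert (b_cell.numerator, b_cell.denominator) == (2, 2)


class TestAuxiliary:
    def test_sets_per_1000_patient_days(self):
        bottles = [make_bottle(f"B{i}", sample_id=f"S{i}", hours=0.1 * i)
                   for i in range(4)]
        eps = build_episodes(bottles)
        cells = auxiliary_indicators(eps, StratumLevel.OVERALL,
                                     patient_days={"ALL": 40.0})
        cell = _cells_by(cells, KpiId.SETS_PER_1000PD)["ALL"]
        assert cell.value == pytest.approx(100.0)

    def test_sets_per_1000pd_unavailable_without_patient_days(self):
        eps = build_episodes([make_bottle("B1")])
        cell = _cells_by(auxiliary_indicators(eps, StratumLevel.OVERALL),
                         KpiId.SETS_PER_1000PD)["ALL"]
        assert cell.value is None and not cell.displayable


class TestAdditivity:
    @pytest.mark.parametrize("level", [StratumLevel.CENTER, StratumLevel.AREA])
    def test_stratum_sums_match_overall(self, small_generated, level):
        result = run_pipeline(small_generated.cohort)
        report = result.report
        for kpi_id in (KpiId.KPI1_BOTTLE, KpiId.KPI2, KpiId.KPI3, KpiId.KPI4A,
                       KpiId.KPI4B, KpiId.POSITIVITY, KpiId.BOTTLES_PER_EPISODE):
            strata = [c for c in report.cells
                      if c.stratum_level is level and c.kpi_id is kpi_id]
            overall = report.cell(StratumLevel.OVERALL, "ALL", kpi_id)
            assert sum(c.numerator for c in strata) == pytest.approx(overall.numerator)
            assert sum(c.denominator for c in strata) == pytest.approx(overall.denominator)

    def test_kpi4b_at_least_kpi4a_everywhere(self, small_generated):
        report = run_pipeline(small_generated.cohort).report
        a = {(c.stratum_level, c.stratum_label): c for c in report.cells
             if c.kpi_id is KpiId.KPI4A}
        for c in report.cells:
            if c.kpi_id is KpiId.KPI4B and c.value is not None:
                assert c.value >= a[(c.stratum_level, c.stratum_label)].value


class TestDisplayThresholds:
    def _report(self, n_episodes, n_cvc):
        cells = [
            make_cell(StratumLevel.SERVICE, "W", KpiId.KPI1_BOTTLE, 6.0 * n_episodes, n_episodes),
            make_cell(StratumLevel.SERVICE, "W", KpiId.KPI2, 1, n_episodes),
            make_cell(StratumLevel.SERVICE, "W", KpiId.KPI3, 1, n_cvc),
        ]
        return KpiReport(cells=cells)

    @pytest.mark.parametrize("n_ep,expected", [(501, True), (500, False)])
    def test_episode_threshold_is_strict(self, n_ep, expected):
        report = apply_display_thresholds(self._report(n_ep, 100))
        assert report.cell(StratumLevel.SERVICE, "W", KpiId.KPI2).displayable is expected
        assert report.cell(StratumLevel.SERVICE, "W", KpiId.KPI1_BOTTLE).displayable is expected

    @pytest.mark.parametrize("n_cvc,expected", [(76, True), (75, False)])
    def test_cvc_threshold_is_strict(self, n_cvc, expected):
        report = apply_display_thresholds(self._report(1000, n_cvc))
        assert report.cell(StratumLevel.SERVICE, "W", KpiId.KPI3).displayable is expected
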