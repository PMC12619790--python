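"""Ward-level heatmap rendering of a KPI report.

One row per hospital service, one column per KPI.  Cells under the
representativeness thresholds are rendered gray/NA.  Criticality is scaled
linearly between the per-KPI min and max across displayed services — low
volume is worse for the fill-volume KPI, high rates are worse for the
others — and drives the red intensity in the HTML variant; the CSV variant
carries the criticality score and the displayable flag as columns.
Reference benchmark lines (≥ 8.0 mL per bottle; ≤ 10% solitary) are noted
in the HTML legend and are configurable.
"""

from __future__ import annotations

import csv
import html
from pathlib import Path
from typing import Optional, Union

from .kpi import KpiCell, KpiId, KpiReport, StratumLevel

#: KPI columns shown on the heatmap, in order.  True marks KPIs where a
#: *low* value is critical.
HEATMAP_KPIS: tuple[tuple[KpiId, bool], ...] = (
    (KpiId.KPI1_BOTTLE, True),
    (KpiId.KPI2, False),
    (KpiId.KPI3, False),
    (KpiId.KPI4A, False),
    (KpiId.KPI4B, False),
)

DEFAULT_BENCHMARKS = {KpiId.KPI1_BOTTLE: 8.0, KpiId.KPI2: 10.0}


def _service_cells(report: KpiReport) -> dict[str, dict[KpiId, KpiCell]]:
    grid: dict[str, dict[KpiId, KpiCell]] = {}
    for cell in report.cells:
        if cell.stratum_level is StratumLevel.SERVICE:
            grid.setdefault(cell.stratum_label, {})[cell.kpi_id] = cell
    return dict(sorted(grid.items()))


def criticality_scores(report: KpiReport) -> dict[str, dict[KpiId, Optional[float]]]:
    """Per-service criticality in [0, 1] per heatmap KPI; None when grayed."""
    grid = _service_cells(report)
    scores: dict[str, dict[KpiId, Optional[float]]] = {s: {} for s in grid}
    for kpi_id, low_is_bad in HEATMAP_KPIS:
        shown = {s: cells[kpi_id].value for s, cells in grid.items()
                 if kpi_id in cells and cells[kpi_id].displayable
                 and cells[kpi_id].value is not None}
        lo = hi = 0.0
        if shown:
            lo, hi = min(shown.values()), max(shown.values())
        for s, cells in grid.items():
            cell = cells.get(kpi_id)
            if cell is None or not cell.displayable or cell.value is None:
                scores[s][kpi_id] = None
            elif hi == lo:
                scores[s][kpi_id] = 0.0
            else:
                frac = (cell.value - lo) / (hi - lo)
                scores[s][kpi_id] = (1.0 - frac) if low_is_bad else frac
    return scores


def render_heatmap(report: KpiReport, path: Union[str, Path],
                   out_format: str = "csv",
                   benchmarks: Optional[dict] = None) -> None:
    """Write the service x KPI heatmap as CSV or standalone HTML."""
    out_format = out_format.lower()
    if out_format == "csv":
        _render_csv(report, path)
    elif out_format == "html":
        _render_html(report, path, benchmarks or DEFAULT_BENCHMARKS)
    else:
        raise ValueError(f"unknown heatmap format {out_format!r}")


def _render_csv(report: KpiReport, path: Union[str, Path]) -> None:
    grid = _service_cells(report)
    scores = criticality_scores(report)
    header = ["hospital_service", "n_episodes", "n_cvc_episodes"]
    for kpi_id, _ in HEATMAP_KPIS:
        header += [f"{kpi_id.value}", f"{kpi_id.value}_displayable",
                   f"{kpi_id.value}_criticality"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for service, cells in grid.items():
            n_ep = cells[KpiId.KPI2].denominator if KpiId.KPI2 in cells else ""
            n_cvc = cells[KpiId.KPI3].denominator if KpiId.KPI3 in cells else ""
            row: list = [service, n_ep, n_cvc]
            for kpi_id, _ in HEATMAP_KPIS:
                cell = cells.get(kpi_id)
                score = scores[service].get(kpi_id)
                row += [
                    "" if cell is None or cell.display_value is None else cell.display_value,
                    bool(cell.displayable) if cell is not None else False,
                    "" if score is None else round(score, 3),
                ]
            writer.writerow(row)


def _render_html(report: KpiReport, path: Union[str, Path],
                 benchmarks: dict) -> None:
    grid = _service_cells(report)
    scores = criticality_scores(report)
    rows = []
    for service, cells in grid.items():
        tds = [f"<th>{html.escape(service)}</th>"]
        for kpi_id, _ in HEATMAP_KPIS:
            cell = cells.get(kpi_id)
            score = scores[service].get(kpi_id)
            if cell is None or score is None or cell.display_value is None:
                tds.append('<td class="gray">NA</td>')
            else:
                # white -> red with criticality
                g_b = int(round(255 * (1.0 - 0.85 * score)))
                tds.append(
                    f'<td style="background-color: rgb(255,{g_b},{g_b})">'
                    f"{cell.display_value}</td>")
        rows.append("<tr>" + "".join(tds) + "</tr>")
    bench = "; ".join(f"{k.value}: {v}" for k, v in benchmarks.items())
    head = "".join(f"<th>{k.value}</th>" for k, _ in HEATMAP_KPIS)
    doc = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>BC KPI heatmap</title>
<style>
table {{ border-collapse: collapse; font-family: sans-serif; }}
td, th {{ border: 1px solid #999; padding: 4px 8px; text-align: right; }}
td.gray {{ background-color: #ccc; color: #666; }}
</style></head><body>
<h1>Blood-culture KPIs by hospital service</h1>
<p>Gray cells fall below the representativeness thresholds.
Reference benchmarks: {html.escape(bench)}.
Report config hash: {report.config_hash}.</p>
<table><tr><th>service</th>{head}</tr>
{"".join(rows)}
</table></body></html>
"""
    Path(path).write_text(doc, encoding="utf-8")
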