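"""Deterministic text/CSV rendering of assessment and comparison outputs.

Percentages are rounded to 2 decimals at this layer only; upstream tables
stay at full precision.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .assessment import ZONES, DifferenceTable, ExposureSummary, WorkerSummary
from .stats import SignificanceTable

__all__ = [
    "exposure_long_table",
    "worker_summary_table",
    "significance_text",
    "render_report",
]


def exposure_long_table(
    summaries: dict[str, dict[str, ExposureSummary]]
) -> pd.DataFrame:
    """Tidy exposure table: worker, method, label, zone, percent."""
    rows = []
    for worker, by_method in summaries.items():
        for method, summary in by_method.items():
            for label, row in summary.table.iterrows():
                for zone in ZONES:
                    rows.append(
                        {
                            "worker": worker,
                            "method": method,
                            "label": label,
                            "zone": zone,
                            "percent": row[zone],
                        }
                    )
    return pd.DataFrame(rows)


def worker_summary_table(worker_summaries: list[WorkerSummary]) -> pd.DataFrame:
    """Worker rows of zone shares per method, plus an Average row."""
    rows = []
    for ws in worker_summaries:
        row: dict[str, object] = {"worker": ws.worker}
        for method in ws.table.index:
            for zone in ZONES:
                row[f"{method}_{zone}"] = ws.table.loc[method, zone]
        rows.append(row)
    out = pd.DataFrame(rows).set_index("worker")
    out.loc["Average"] = out.mean(axis=0)
    return out


def significance_text(sig: SignificanceTable) -> str:
    """Plain-text verdict table (t, p, SD/N) mirroring the study layout."""
    lines = [f"Paired t-tests over stressed body parts (alpha = {sig.alpha:g})", ""]
    header = f"{'worker':<10}{'zone':<8}{'pair':<9}{'n':>3}{'t':>9}{'p':>10}  verdict"
    lines.append(header)
    lines.append("-" * len(header))
    for _, row in sig.table.iterrows():
        t = "   nan" if pd.isna(row["t"]) else f"{row['t']:6.3f}"
        p = "   nan" if pd.isna(row["p_value"]) else f"{row['p_value']:8.4f}"
        verdict = row["conclusion"] + (" (degenerate)" if row["degenerate"] else "")
        lines.append(
            f"{row['worker']:<10}{row['zone']:<8}{row['pair']:<9}{row['n']:>3}"
            f"{t:>9}{p:>10}  {verdict}"
        )
    if sig.warnings:
        lines += ["", "Normality warnings:"] + [f"  - {w}" for w in sorted(set(sig.warnings))]
    return "\n".join(lines) + "\n"


def _md_table(df: pd.DataFrame, index_name: str) -> list[str]:
    df = df.round(2)
    cols = [index_name] + [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
    for idx, row in df.iterrows():
        cells = [str(idx)] + [f"{v:.2f}" if isinstance(v, float) else str(v) for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    return lines


def render_report(
    worker_summaries: list[WorkerSummary] | None = None,
    mean_diffs: pd.DataFrame | None = None,
    significance: SignificanceTable | None = None,
    title: str = "Ergonomic risk assessment report",
) -> str:
    """Markdown report bundling whatever outputs are present. Idempotent:
    rendering the same inputs yields byte-identical text."""
    lines = [f"# {title}", ""]
    if worker_summaries:
        lines += ["## Share of total work activity per risk zone (percent)", ""]
        lines += _md_table(worker_summary_table(worker_summaries), "worker")
        lines.append("")
    if mean_diffs is not None:
        lines += [
            "## Mean between-standard differences (percentage points)",
            "",
            "d1 = Captiv - Legislation, d2 = Captiv - STN EN, d3 = STN EN - Legislation",
            "",
        ]
        flat = mean_diffs.reset_index()
        flat["cell"] = flat["part"] + " / " + flat["zone"]
        flat = flat.set_index("cell")[["d1", "d2", "d3"]]
        lines += _md_table(flat, "part / zone")
        lines.append("")
    if significance is not None:
        lines += ["## Paired-test verdicts", "", "```", significance_text(significance), "```", ""]
    return "\n".join(lines)


def write_report(path: str | Path, **kwargs) -> None:
    Path(path).write_text(render_report(**kwargs))
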