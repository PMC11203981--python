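"""Published reference results from the motivating case study.

A published case study of five assembly-line workers reports, for each
worker, the percentage of total work activity spent in each risk zone under
the three standards.  The raw recordings behind those numbers are not
public, but the printed worker-level rows are usable inputs: averaging them
with the cohort-summary machinery reproduces the study's printed cohort
averages, and a consistency check flags the one printed average cell that
cannot be the arithmetic mean of its column (the legislation red column,
whose printed average row also fails to sum to 100).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "published_worker_table",
    "published_average_row",
    "consistency_report",
]

_WORKER_ROWS = {
    # worker: (L green, L orange, L red, C green, C orange, C red,
    #          S green, S orange, S red)
    "Worker 1": (67.46, 20.86, 11.68, 43.91, 10.65, 45.44, 25.04, 23.08, 51.88),
    "Worker 2": (62.76, 25.07, 12.17, 43.04, 8.06, 48.90, 23.18, 22.67, 54.15),
    "Worker 3": (57.20, 24.30, 18.50, 37.78, 11.68, 50.54, 28.27, 17.78, 53.94),
    "Worker 4": (59.36, 23.30, 17.34, 46.09, 6.97, 46.94, 28.01, 18.82, 53.17),
    "Worker 5": (68.49, 18.98, 12.53, 47.59, 9.42, 42.99, 33.54, 20.44, 46.02),
}

_AVERAGE_ROW = (63.05, 22.50, 17.92, 43.68, 9.36, 46.96, 27.61, 20.56, 51.83)

_COLUMNS = pd.MultiIndex.from_product(
    [["L", "C", "S"], ["green", "orange", "red"]], names=["method", "zone"]
)


def published_worker_table() -> pd.DataFrame:
    """Per-worker zone shares (percent) as printed, columns (method, zone)."""
    return pd.DataFrame.from_dict(_WORKER_ROWS, orient="index", columns=_COLUMNS)


def published_average_row() -> pd.Series:
    """The printed cohort-average row (percent)."""
    return pd.Series(_AVERAGE_ROW, index=_COLUMNS, name="Average")


def consistency_report(emit_warnings: bool = True) -> list[str]:
    """Internal-consistency findings on the printed summary table.

    Checks that (a) every printed average equals the arithmetic mean of its
    worker column to print precision and (b) each method's average row sums
    to 100.  Findings are returned and, by default, also emitted as
    :class:`UserWarning`.
    """
    table = published_worker_table()
    printed = published_average_row()
    findings: list[str] = []
    means = table.mean(axis=0).round(2)
    for col in table.columns:
        if abs(means[col] - printed[col]) > 0.005:
            findings.append(
                f"printed average for {col[0]}/{col[1]} is {printed[col]:.2f} but the "
                f"column mean is {means[col]:.2f}"
            )
    for method in ("L", "C", "S"):
        s = printed[method].sum()
        if abs(s - 100.0) > 0.05:
            findings.append(
                f"printed average row for method {method} sums to {s:.2f}, not 100"
            )
    if emit_warnings:
        for msg in findings:
            warnings.warn(msg, UserWarning, stacklevel=2)
    return findings
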