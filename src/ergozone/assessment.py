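"""Exposure assessment: per-sample zone timelines, time-in-zone percentages,
worker-level summaries and between-standard differences.

The central quantity is ``Z[method, part, zone]``: the percentage of
recording time a stressed body part spends in each risk zone under one
standard.  Between-standard differences are taken per zone, per part and per
worker:

    d1 = Z_C - Z_L      (Captiv minus Slovak legislation)
    d2 = Z_C - Z_S      (Captiv minus STN EN)
    d3 = Z_S - Z_L      (STN EN minus Slovak legislation)

so ``d1 = d2 + d3`` cell by cell, and for any method pair the differences
over the three zones sum to zero because each method's zone percentages
partition 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import AXES, STRESSED_PARTS, Segment
from .kinematics import (
    DEFAULT_FREQ_WINDOW_S,
    DEFAULT_HYSTERESIS_DEG,
    MotionRecording,
    movement_frequency,
)
from .standards import StandardRuleSet, Zone

__all__ = [
    "ZoneTimeline",
    "ExposureSummary",
    "WorkerSummary",
    "DifferenceTable",
    "compute_zone_timeline",
    "exposure_summary",
    "assess_recording",
    "average_summaries",
    "average_recordings",
    "worker_overall_summary",
    "worst_zone_share",
    "difference_table",
    "mean_differences",
    "cohort_average",
    "ZONES",
    "METHOD_PAIRS",
]

ZONES = ("green", "orange", "red")
#: Method pairs in reporting order, as (name, minuend, subtrahend) of the
#: difference convention above.
METHOD_PAIRS = (
    ("L vs C", "C", "L"),
    ("C vs S", "C", "S"),
    ("L vs S", "S", "L"),
)


class AssessmentError(ValueError):
    """Raised when a recording cannot be assessed under a rule set."""


@dataclass
class ZoneTimeline:
    """Per-sample zone per stressed body part, for one standard."""

    standard_id: str
    sampling_rate: float
    zones: dict[str, np.ndarray]  # part label -> int8 array of Zone values
    not_assessed: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.zones.values()))) if self.zones else 0


@dataclass
class ExposureSummary:
    """Time-in-zone percentages per stressed part for one standard.

    ``table`` is indexed by part label with float columns ``green``,
    ``orange``, ``red`` summing to 100 per row.  Percentages are kept at full
    precision; rounding to 2 decimals happens only at reporting.
    """

    method: str
    table: pd.DataFrame
    not_assessed: list[str] = field(default_factory=list)

    def labels(self) -> list[str]:
        return list(self.table.index)


@dataclass
class WorkerSummary:
    """Percent of total work activity per zone, per method (one worker)."""

    worker: str
    table: pd.DataFrame  # index: method, columns: green/orange/red
    aggregation: str = "mean"


@dataclass
class DifferenceTable:
    """Between-standard differences for one worker.

    ``table`` is indexed by (part, zone) with columns ``d1`` (C - L), ``d2``
    (C - S) and ``d3`` (S - L), in percentage points.
    """

    worker: str
    table: pd.DataFrame


def compute_zone_timeline(
    recording: MotionRecording,
    ruleset: StandardRuleSet,
    freq_window: float = DEFAULT_FREQ_WINDOW_S,
    hysteresis: float = DEFAULT_HYSTERESIS_DEG,
) -> ZoneTimeline:
    """Classify every sample of every stressed body part under one standard.

    Per movement axis, a sample is RED if any RED rule fires (angle,
    frequency, work type and support conditions all met), else ORANGE if any
    ORANGE rule fires, else GREEN.  Mirrored axes are then pooled into
    stressed parts by worst zone.  Parts of segments the standard does not
    define are reported as NOT_ASSESSED.
    """
    times = recording.times
    work_type = recording.context.work_type_at(times)
    quantum = 60.0 / freq_window  # one countable event per window, in /min
    freq_cache: dict[tuple[Segment, str, int, float], np.ndarray] = {}

    def freq_series(seg: Segment, channel: str, sign: int, thr: float) -> np.ndarray:
        key = (seg, channel, sign, thr)
        if key not in freq_cache:
            freq_cache[key] = movement_frequency(
                recording.get(seg, channel),
                threshold=thr,
                direction_sign=sign,
                window=freq_window,
                hysteresis=hysteresis,
            )
        return freq_cache[key]

    zones: dict[str, np.ndarray] = {}
    not_assessed: list[str] = []
    for part, members in STRESSED_PARTS.items():
        segment = AXES[members[0]].segment
        if segment in ruleset.unassessed_segments:
            not_assessed.append(part)
            continue
        part_zone = np.zeros(len(times), dtype=np.int8)
        for label in members:
            axis = AXES[label]
            try:
                series = recording.get(axis.segment, axis.channel)
            except KeyError as exc:
                raise AssessmentError(
                    f"standard {ruleset.standard_id}: {exc.args[0]}"
                ) from exc
            supported = recording.context.supported(axis.segment)
            red = np.zeros(len(times), dtype=bool)
            orange = np.zeros(len(times), dtype=bool)
            for rule in ruleset.rules_for_axis(label):
                mask = rule.angle.matches(series.samples)
                if rule.frequency.form != "none":
                    sign, thr = rule.angle.crossing_spec()
                    f = freq_series(axis.segment, axis.channel, sign, thr)
                    mask = mask & rule.frequency.matches(f, quantum)
                mask = mask & rule.context_matches(work_type, supported)
                if rule.zone is Zone.RED:
                    red |= mask
                else:
                    orange |= mask
            label_zone = np.where(red, Zone.RED, np.where(orange, Zone.ORANGE, Zone.GREEN))
            part_zone = np.maximum(part_zone, label_zone.astype(np.int8))
        zones[part] = part_zone
    return ZoneTimeline(
        standard_id=ruleset.standard_id,
        sampling_rate=recording.sampling_rate,
        zones=zones,
        not_assessed=not_assessed,
    )


def exposure_summary(timeline: ZoneTimeline) -> ExposureSummary:
    """Time-in-zone percentages: ``Z = 100 * samples_in_zone / samples``."""
    if not timeline.zones and not timeline.not_assessed:
        raise ValueError("empty timeline")
    rows = {}
    for part, z in timeline.zones.items():
        n = z.size
        if n == 0:
            continue
        rows[part] = [100.0 * np.count_nonzero(z == zone) / n for zone in
                      (Zone.GREEN, Zone.ORANGE, Zone.RED)]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(ZONES))
    return ExposureSummary(
        method=timeline.standard_id,
        table=table,
        not_assessed=list(timeline.not_assessed),
    )


def assess_recording(
    recording: MotionRecording,
    rulesets: dict[str, StandardRuleSet],
    freq_window: float = DEFAULT_FREQ_WINDOW_S,
    hysteresis: float = DEFAULT_HYSTERESIS_DEG,
) -> dict[str, ExposureSummary]:
    """Exposure summaries of one recording under several standards."""
    return {
        method: exposure_summary(
            compute_zone_timeline(recording, rs, freq_window, hysteresis)
        )
        for method, rs in rulesets.items()
    }


def average_summaries(summaries: list[ExposureSummary]) -> ExposureSummary:
    """Cell-wise mean of exposure summaries (e.g. over a worker's trials)."""
    if not summaries:
        raise ValueError("no summaries to average")
    methods = {s.method for s in summaries}
    if len(methods) > 1:
        raise ValueError(f"cannot average across methods {sorted(methods)}")
    tables = [s.table for s in summaries]
    for t in tables[1:]:
        if not t.index.equals(tables[0].index):
            raise ValueError("summaries cover different label sets")
    return ExposureSummary(
        method=summaries[0].method,
        table=sum(tables) / len(tables),
        not_assessed=list(summaries[0].not_assessed),
    )


def average_recordings(recordings: list[MotionRecording]) -> MotionRecording:
    """Sample-wise mean-angle recording across trials of one worker.

    Supports the alternative trial-aggregation mode in which the mean angle
    trajectory is classified once, instead of averaging trial-level
    percentages.
    """
    if not recordings:
        raise ValueError("no recordings to average")
    first = recordings[0]
    for rec in recordings[1:]:
        if rec.n_samples != first.n_samples or rec.sampling_rate != first.sampling_rate:
            raise ValueError("recordings must share length and rate")
        if set(rec.series) != set(first.series):
            raise ValueError("recordings must share channel sets")
    series = {}
    for key, s in first.series.items():
        mean = np.mean([rec.series[key].samples for rec in recordings], axis=0)
        series[key] = type(s)(s.segment, s.channel, s.sampling_rate, mean)
    return MotionRecording(
        worker=first.worker, trial=1, series=series, context=first.context
    )


def worker_overall_summary(
    summaries: dict[str, ExposureSummary], worker: str = ""
) -> WorkerSummary:
    """Percent of total work activity per zone: unweighted mean of Z over
    the assessed stressed parts, per method."""
    rows = {}
    for method, summary in summaries.items():
        if summary.table.empty:
            raise ValueError(f"method {method}: no assessed parts")
        rows[method] = summary.table.mean(axis=0)
    table = pd.DataFrame(rows).T[list(ZONES)]
    return WorkerSummary(worker=worker, table=table, aggregation="mean")


def worst_zone_share(timeline: ZoneTimeline) -> pd.Series:
    """Alternative worker aggregation: per-sample worst zone across all
    assessed parts, as percent of time."""
    if not timeline.zones:
        raise ValueError("timeline has no assessed parts")
    stacked = np.vstack(list(timeline.zones.values()))
    worst = stacked.max(axis=0)
    n = worst.size
    return pd.Series(
        {z: 100.0 * np.count_nonzero(worst == code) / n
         for z, code in zip(ZONES, (Zone.GREEN, Zone.ORANGE, Zone.RED))}
    )


def difference_table(
    summaries: dict[str, ExposureSummary], worker: str = ""
) -> DifferenceTable:
    """Between-standard differences d1 = C - L, d2 = C - S, d3 = S - L.

    Parts not assessed by every method are dropped pairwise -- here: from the
    common label set, since all three methods enter every column.
    """
    for m in ("L", "S", "C"):
        if m not in summaries:
            raise ValueError(f"difference table needs method {m}")
    common = summaries["L"].table.index
    for m in ("S", "C"):
        common = common.intersection(summaries[m].table.index)
    if common.empty:
        raise ValueError("no common assessed parts across methods")
    frames = []
    for part in common:
        for zone in ZONES:
            zl = summaries["L"].table.loc[part, zone]
            zs = summaries["S"].table.loc[part, zone]
            zc = summaries["C"].table.loc[part, zone]
            frames.append(
                {"part": part, "zone": zone, "d1": zc - zl, "d2": zc - zs, "d3": zs - zl}
            )
    table = pd.DataFrame(frames).set_index(["part", "zone"])
    return DifferenceTable(worker=worker, table=table)


def mean_differences(tables: list[DifferenceTable]) -> pd.DataFrame:
    """Arithmetic mean of difference tables across workers, per cell."""
    if not tables:
        raise ValueError("no difference tables")
    out = tables[0].table.copy()
    for t in tables[1:]:
        if not t.table.index.equals(out.index):
            raise ValueError("difference tables cover different cells")
        out = out + t.table
    return out / len(tables)


def cohort_average(worker_summaries: list[WorkerSummary]) -> pd.DataFrame:
    """Arithmetic mean of worker-level zone shares across workers (the
    'Average' row of a cohort summary table)."""
    if not worker_summaries:
        raise ValueError("no worker summaries")
    tables = [w.table for w in worker_summaries]
    for t in tables[1:]:
        if not t.index.equals(tables[0].index):
            raise ValueError("worker summaries cover different methods")
    return sum(tables) / len(tables)
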