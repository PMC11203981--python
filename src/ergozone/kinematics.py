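"""Joint-angle recordings: data model, CSV I/O, resampling and movement
frequency.

A :class:`MotionRecording` holds uniformly sampled signed joint-angle series
(degrees) for the instrumented segments of one worker/trial, plus the work
context (static vs dynamic work, per-segment support).  Movement frequency --
the repetitions-per-minute quantity that the standards' ``f`` conditions test
-- is estimated by counting hysteresis-filtered upward crossings of a
threshold inside a centred sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import SEGMENT_CHANNELS, MovementAxis, Segment

__all__ = [
    "JointAngleSeries",
    "WorkContext",
    "MotionRecording",
    "read_angle_csv",
    "write_angle_csv",
    "resample_uniform",
    "movement_frequency",
    "crossing_events",
    "label_direction",
    "DEFAULT_RATE_HZ",
    "DEFAULT_FREQ_WINDOW_S",
    "DEFAULT_HYSTERESIS_DEG",
]

#: Defaults for acquisition and repetition counting.  60 s matches the
#: per-minute unit of the standards' frequency conditions; the 5-degree
#: hysteresis suppresses double counts from sensor noise.
DEFAULT_RATE_HZ = 20.0
DEFAULT_FREQ_WINDOW_S = 60.0
DEFAULT_HYSTERESIS_DEG = 5.0

ANGLE_CSV_COLUMNS = ["time_s", "worker", "trial", "segment", "channel", "angle_deg"]


@dataclass
class JointAngleSeries:
    """Uniformly sampled signed joint angles (degrees) of one channel."""

    segment: Segment
    channel: str
    sampling_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ValueError(f"non-finite angle at sample {bad}")
        if self.channel not in SEGMENT_CHANNELS[self.segment]:
            raise ValueError(
                f"channel {self.channel!r} not defined for segment {self.segment.value}"
            )

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, 0-based."""
        return np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        """Represented span: each sample stands for one sampling interval."""
        return self.samples.size / self.sampling_rate


@dataclass
class WorkContext:
    """Work type and support conditions of a recording.

    ``intervals`` optionally assigns work types to disjoint half-open
    ``[t0, t1)`` spans covering the recording; otherwise ``work_type`` holds
    for the whole recording.  ``support`` flags segments resting on a support
    (e.g. back support) -- relevant for the static-work rules.
    """

    work_type: str = "dynamic"
    support: dict[Segment, bool] = field(default_factory=dict)
    intervals: list[tuple[float, float, str]] | None = None
    duration: float | None = None

    def __post_init__(self) -> None:
        if self.work_type not in ("static", "dynamic"):
            raise ValueError("work_type must be 'static' or 'dynamic'")
        if self.intervals:
            spans = sorted(self.intervals)
            for (a0, a1, wt) in spans:
                if a1 <= a0:
                    raise ValueError(f"empty interval [{a0}, {a1})")
                if wt not in ("static", "dynamic"):
                    raise ValueError(f"bad work type {wt!r} in interval")
            for (_, a1, _), (b0, _, _) in zip(spans, spans[1:]):
                if b0 < a1:
                    raise ValueError("work-type intervals overlap")

    def work_type_at(self, times: np.ndarray) -> np.ndarray:
        """Per-sample work type ('static'/'dynamic')."""
        out = np.full(times.shape, self.work_type, dtype="<U7")
        if self.intervals:
            for t0, t1, wt in self.intervals:
                out[(times >= t0) & (times < t1)] = wt
        return out

    def supported(self, segment: Segment) -> bool:
        return bool(self.support.get(segment, False))


@dataclass
class MotionRecording:
    """All channel series of one worker/trial plus its work context."""

    worker: str
    trial: int
    series: dict[tuple[Segment, str], JointAngleSeries]
    context: WorkContext = field(default_factory=WorkContext)

    def __post_init__(self) -> None:
        if self.trial not in (1, 2, 3):
            raise ValueError("trial must be 1, 2 or 3")
        rates = {s.sampling_rate for s in self.series.values()}
        lengths = {len(s) for s in self.series.values()}
        if len(rates) > 1:
            raise ValueError(f"series sampling rates differ: {sorted(rates)}")
        if len(lengths) > 1:
            raise ValueError(f"series lengths differ: {sorted(lengths)}")

    @property
    def sampling_rate(self) -> float:
        return next(iter(self.series.values())).sampling_rate

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.series.values())))

    @property
    def times(self) -> np.ndarray:
        return next(iter(self.series.values())).times

    def get(self, segment: Segment, channel: str) -> JointAngleSeries:
        try:
            return self.series[(segment, channel)]
        except KeyError:
            raise KeyError(
                f"recording has no channel {channel!r} for segment {segment.value}"
            ) from None

    def segments(self) -> list[Segment]:
        return sorted({seg for seg, _ in self.series}, key=lambda s: s.value)


def read_angle_csv(path: str | Path) -> MotionRecording:
    """Read one recording from long-format CSV.

    Columns: ``time_s, worker, trial, segment, channel, angle_deg``.  All
    channels must share one uniform, strictly monotone time grid; non-uniform
    input is rejected (resample first).
    """
    df = pd.read_csv(path)
    missing = [c for c in ANGLE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no samples")
    if df["angle_deg"].isna().any():
        row = int(df.index[df["angle_deg"].isna()][0])
        raise ValueError(f"{path}: NaN angle at row {row}")
    workers = df["worker"].unique()
    trials = df["trial"].unique()
    if len(workers) != 1 or len(trials) != 1:
        raise ValueError(f"{path}: expected a single worker/trial per file")

    series: dict[tuple[Segment, str], JointAngleSeries] = {}
    ref_times: np.ndarray | None = None
    for (seg_code, channel), grp in df.groupby(["segment", "channel"], sort=True):
        seg = Segment(seg_code)
        grp = grp.sort_values("time_s", kind="stable")
        times = grp["time_s"].to_numpy(dtype=float)
        if times.size >= 2:
            dup = np.flatnonzero(np.diff(times) == 0)
            if dup.size:
                raise ValueError(
                    f"{path}: duplicated timestamp {times[dup[0]]} on "
                    f"{seg.value}/{channel}"
                )
            dt = np.diff(times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError(
                    f"{path}: non-uniform sampling on {seg.value}/{channel}; "
                    "resample to a uniform grid first"
                )
            rate = 1.0 / dt[0]
        else:
            rate = DEFAULT_RATE_HZ
        if ref_times is None:
            ref_times = times
        elif times.size != ref_times.size or not np.allclose(times, ref_times):
            raise ValueError(f"{path}: channels do not share one time grid")
        series[(seg, channel)] = JointAngleSeries(
            seg, channel, rate, grp["angle_deg"].to_numpy(dtype=float)
        )
    return MotionRecording(
        worker=str(workers[0]), trial=int(trials[0]), series=series
    )


def write_angle_csv(recording: MotionRecording, path: str | Path) -> None:
    """Inverse of :func:`read_angle_csv`; deterministic column and row order
    (segment, channel, then time)."""
    frames = []
    for (seg, channel) in sorted(recording.series, key=lambda k: (k[0].value, k[1])):
        s = recording.series[(seg, channel)]
        frames.append(
            pd.DataFrame(
                {
                    "time_s": s.times,
                    "worker": recording.worker,
                    "trial": recording.trial,
                    "segment": seg.value,
                    "channel": channel,
                    "angle_deg": s.samples,
                }
            )
        )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=ANGLE_CSV_COLUMNS)
    out.to_csv(path, index=False, float_format="%.6f")


def resample_uniform(series: JointAngleSeries, target_rate: float) -> JointAngleSeries:
    """Linear interpolation onto a uniform grid spanning the original range."""
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    if len(series) < 2:
        raise ValueError("resampling requires at least 2 samples")
    t_old = series.times
    n_new = int(np.floor(t_old[-1] * target_rate)) + 1
    t_new = np.arange(n_new) / target_rate
    return JointAngleSeries(
        series.segment,
        series.channel,
        target_rate,
        np.interp(t_new, t_old, series.samples),
    )


def crossing_events(
    y: np.ndarray, threshold: float, hysteresis: float = DEFAULT_HYSTERESIS_DEG
) -> np.ndarray:
    """Indices of hysteresis-filtered upward crossings of *threshold*.

    An event fires when the signal reaches the threshold while armed; the
    detector re-arms only after the signal falls to ``threshold -
    hysteresis``.  The detector starts armed, so a series that begins at or
    above the threshold scores an event at its first sample.
    """
    y = np.asarray(y, dtype=float)
    above = y >= threshold
    rearm = y <= threshold - hysteresis
    state = np.where(above, 1, np.where(rearm, -1, 0))
    idx = np.flatnonzero(state)
    if idx.size == 0:
        return np.empty(0, dtype=int)
    s = state[idx]
    first = [idx[0]] if s[0] == 1 else []
    ups = np.flatnonzero((s[1:] == 1) & (s[:-1] == -1)) + 1
    return np.asarray(first + list(idx[ups]), dtype=int)


def movement_frequency(
    series: JointAngleSeries,
    threshold: float,
    direction_sign: int = 1,
    window: float = DEFAULT_FREQ_WINDOW_S,
    hysteresis: float = DEFAULT_HYSTERESIS_DEG,
) -> np.ndarray:
    """Per-sample movement frequency in events per minute.

    Counts hysteresis-filtered upward crossings of ``direction_sign * angle``
    through *threshold* inside a centred window of *window* seconds.  Near
    the edges the window is shifted (not shrunk) so it stays inside the
    recording at full length: a periodic signal then reports its steady-state
    rate at every sample.  Only when the whole recording is shorter than the
    window is the count scaled to the recorded span.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if window <= 0:
        raise ValueError("window must be > 0")
    if window < 2.0 / series.sampling_rate:
        raise ValueError("window shorter than 2 sampling intervals")
    y = direction_sign * series.samples
    events = crossing_events(y, threshold, hysteresis)
    t = series.times
    t_end = t[-1] if t.size else 0.0
    w_eff = min(window, t_end) if t_end > 0 else window
    lo = np.clip(t - window / 2.0, 0.0, max(t_end - w_eff, 0.0))
    hi = lo + w_eff
    ev_t = t[events]
    # half-open window [lo, hi), backed off by half a sample so that events
    # landing exactly on a window edge are attributed without float jitter
    eps = 0.5 / series.sampling_rate
    counts = np.searchsorted(ev_t, hi - eps, side="left") - np.searchsorted(
        ev_t, lo - eps, side="left"
    )
    span = max(w_eff, 1.0 / series.sampling_rate)
    return counts * 60.0 / span


def label_direction(series: JointAngleSeries, axis: MovementAxis) -> np.ndarray:
    """Unsigned excursion magnitude in the axis label's direction:
    ``max(direction_sign * angle, 0)`` per sample."""
    if axis.channel != series.channel or axis.segment != series.segment:
        raise ValueError(
            f"axis {axis.label} addresses {axis.segment.value}/{axis.channel}, "
            f"series is {series.segment.value}/{series.channel}"
        )
    return np.maximum(axis.direction_sign * series.samples, 0.0)
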