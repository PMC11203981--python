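"""Synthetic worker-motion generator.

Emulates standing assembly work with a quasi-static baseline posture and
semi-dynamic pick/place excursions: each channel is

    angle(t) = baseline + amplitude * w(t) + noise(t)

with ``w`` a square, smoothed-square or raised-cosine waveform of given cycle
period and duty fraction, and i.i.d. Gaussian sensor noise.  Because the
waveform occupancy is known analytically, recordings generated here carry
exact ground-truth time-in-zone percentages for any threshold rule, which is
what makes the downstream pipeline testable without factory recordings.

The default task profile sketches a pick-inspect-place light-assembly cycle:
a mild forward neck/trunk lean most of the time, with arm raises to around
90 deg and trunk flexion to around 40 deg during picks, cycling twice a
minute.  The defaults are chosen so that the three bundled standards genuinely
disagree about the same motion; they do not claim to replicate any particular
factory's trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import SEGMENT_CHANNELS, Segment
from .kinematics import (
    DEFAULT_RATE_HZ,
    JointAngleSeries,
    MotionRecording,
    WorkContext,
)

__all__ = [
    "ChannelProfile",
    "TaskProfile",
    "CohortSpec",
    "default_task_profile",
    "generate_recording",
    "generate_cohort",
    "square_wave_fixture",
    "fixture_recording",
]

WAVEFORMS = ("square", "smoothed_square", "sinusoid")


@dataclass(frozen=True)
class ChannelProfile:
    """Trajectory parameters of one signed channel (degrees / seconds)."""

    baseline: float = 0.0
    amplitude: float = 0.0
    period: float = 30.0
    duty: float = 0.3
    waveform: str = "smoothed_square"
    noise_sd: float = 2.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.duty <= 1.0:
            raise ValueError("duty must be in [0, 1]")
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.waveform not in WAVEFORMS:
            raise ValueError(f"unknown waveform {self.waveform!r}")


@dataclass(frozen=True)
class TaskProfile:
    """Per-channel trajectory profiles plus the noise seed."""

    channels: dict[tuple[Segment, str], ChannelProfile]
    seed: int = 0


def default_task_profile(noise_sd: float = 2.0, period: float = 30.0) -> TaskProfile:
    """Standing light-assembly task with pick/place excursions.

    The 30 s cycle puts the excursion repetition rate at 2/min, the pivot
    frequency of the legislative rules.
    """
    def ch(baseline, amplitude, duty, phase=0.0):
        return ChannelProfile(
            baseline=baseline,
            amplitude=amplitude,
            period=period,
            duty=duty,
            noise_sd=noise_sd,
            phase=phase,
        )

    channels = {
        (Segment.NECK, "flexion_extension"): ch(10.0, 25.0, 0.30),
        (Segment.NECK, "lateral_flexion"): ch(0.0, 12.0, 0.20, phase=3.0),
        (Segment.NECK, "rotation"): ch(0.0, 20.0, 0.25, phase=6.0),
        (Segment.LOWER_BACK, "flexion_extension"): ch(5.0, 35.0, 0.30),
        (Segment.LOWER_BACK, "lateral_flexion"): ch(0.0, 15.0, 0.20, phase=4.0),
        (Segment.LOWER_BACK, "rotation"): ch(0.0, 18.0, 0.20, phase=8.0),
        (Segment.RIGHT_SHOULDER, "vertical_rotation"): ch(15.0, 80.0, 0.25),
        (Segment.RIGHT_SHOULDER, "rotation_int_ext"): ch(0.0, 30.0, 0.20, phase=2.0),
        (Segment.RIGHT_SHOULDER, "horizontal_rotation"): ch(0.0, 25.0, 0.20, phase=5.0),
        (Segment.LEFT_SHOULDER, "vertical_rotation"): ch(10.0, 60.0, 0.20, phase=1.0),
        (Segment.LEFT_SHOULDER, "rotation_int_ext"): ch(0.0, 25.0, 0.15, phase=7.0),
        (Segment.LEFT_SHOULDER, "horizontal_rotation"): ch(0.0, 20.0, 0.15, phase=9.0),
        (Segment.RIGHT_ELBOW, "flexion_extension"): ch(45.0, 40.0, 0.30),
        (Segment.RIGHT_ELBOW, "rotation_int_ext"): ch(0.0, 25.0, 0.20, phase=3.0),
        (Segment.LEFT_ELBOW, "flexion_extension"): ch(40.0, 35.0, 0.25, phase=1.0),
        (Segment.LEFT_ELBOW, "rotation_int_ext"): ch(0.0, 20.0, 0.15, phase=6.0),
        (Segment.UPPER_BACK, "flexion_extension"): ch(5.0, 20.0, 0.30),
    }
    return TaskProfile(channels=channels)


def _waveform(profile: ChannelProfile, t: np.ndarray) -> np.ndarray:
    """Dimensionless excursion waveform w(t) in [0, 1]."""
    tau = np.mod(t + profile.phase, profile.period)
    if profile.waveform == "sinusoid":
        return 0.5 - 0.5 * np.cos(2.0 * np.pi * t / profile.period)
    high = (tau < profile.duty * profile.period).astype(float)
    if profile.waveform == "square":
        return high
    # smoothed_square: raised-cosine ramps over 5% of the period per edge,
    # carved out of the high phase so the plateau occupancy stays close to
    # the duty fraction.
    ramp = 0.05 * profile.period
    up = np.clip(tau / ramp, 0.0, 1.0)
    t_down = profile.duty * profile.period
    down = np.clip((tau - (t_down - ramp)) / ramp, 0.0, 1.0)
    w = np.where(
        tau < t_down,
        0.5 - 0.5 * np.cos(np.pi * up),
        0.0,
    )
    w = np.where((tau >= t_down - ramp) & (tau < t_down), 0.5 + 0.5 * np.cos(np.pi * down), w)
    return w * high


def generate_recording(
    profile: TaskProfile,
    context: WorkContext | None = None,
    rate: float = DEFAULT_RATE_HZ,
    duration: float = 300.0,
    worker: str = "W1",
    trial: int = 1,
) -> MotionRecording:
    """Deterministic (given ``profile.seed``) synthetic recording.

    The deterministic component depends only on the channel profiles; the
    seed drives the additive Gaussian noise alone.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    context = context or WorkContext(duration=duration)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(profile.seed)
    series: dict[tuple[Segment, str], JointAngleSeries] = {}
    # Channels are generated in sorted order so the RNG stream, and hence the
    # recording, is independent of dict insertion order.
    for (seg, channel) in sorted(profile.channels, key=lambda k: (k[0].value, k[1])):
        ch = profile.channels[(seg, channel)]
        angles = ch.baseline + ch.amplitude * _waveform(ch, t)
        if ch.noise_sd > 0:
            angles = angles + rng.normal(0.0, ch.noise_sd, size=n)
        else:
            rng.normal(0.0, 1.0, size=n)  # keep stream alignment across channels
        series[(seg, channel)] = JointAngleSeries(seg, channel, rate, angles)
    return MotionRecording(worker=worker, trial=trial, series=series, context=context)


@dataclass(frozen=True)
class CohortSpec:
    """Study-cohort layout and per-worker variability.

    Defaults mirror the emulated study: 5 workers, 3 trials each, with
    anthropometrics drawn from the reported ranges (age 23-46 y, weight
    52-86 kg, height 1.68-1.85 m) and mild per-worker jitter of the task
    profile (amplitude scale, baseline shift, period scale, duty shift).
    """

    n_workers: int = 5
    trials: int = 3
    duration: float = 300.0
    rate: float = DEFAULT_RATE_HZ
    age_range: tuple[float, float] = (23.0, 46.0)
    weight_range: tuple[float, float] = (52.0, 86.0)
    height_range: tuple[float, float] = (1.68, 1.85)
    amp_scale_sd: float = 0.08
    baseline_shift_sd: float = 2.0
    period_scale_sd: float = 0.10
    duty_shift_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")


def _jitter_profile(
    base: TaskProfile, rng: np.random.Generator, spec: CohortSpec, seed: int
) -> TaskProfile:
    amp = 1.0 + rng.normal(0.0, spec.amp_scale_sd)
    period = 1.0 + rng.normal(0.0, spec.period_scale_sd)
    channels = {}
    for key in sorted(base.channels, key=lambda k: (k[0].value, k[1])):
        ch = base.channels[key]
        channels[key] = replace(
            ch,
            baseline=ch.baseline + rng.normal(0.0, spec.baseline_shift_sd),
            amplitude=ch.amplitude * max(amp, 0.1),
            period=ch.period * max(period, 0.2),
            duty=float(np.clip(ch.duty + rng.normal(0.0, spec.duty_shift_sd), 0.0, 1.0)),
        )
    return TaskProfile(channels=channels, seed=seed)


def generate_cohort(
    spec: CohortSpec,
    base_profile: TaskProfile | None = None,
    profiles: dict[str, TaskProfile] | None = None,
) -> tuple[list[MotionRecording], pd.DataFrame]:
    """Generate ``n_workers x trials`` recordings plus a worker table.

    Each worker gets a jittered copy of *base_profile* (or an explicit entry
    from *profiles*); trials differ only in their noise realisation.  The
    worker table lists age, weight, height and BMI consistent with
    weight/height**2.
    """
    base = base_profile or default_task_profile()
    if profiles is not None and not profiles:
        raise ValueError("profiles mapping must not be empty")
    root = np.random.SeedSequence(spec.seed)
    worker_seeds = root.spawn(spec.n_workers)
    recordings: list[MotionRecording] = []
    rows = []
    for w in range(spec.n_workers):
        worker_id = f"W{w + 1}"
        wseq = worker_seeds[w]
        rng = np.random.default_rng(wseq)
        age = rng.uniform(*spec.age_range)
        weight = rng.uniform(*spec.weight_range)
        height = rng.uniform(*spec.height_range)
        bmi = weight / height**2
        rows.append(
            {
                "worker": worker_id,
                "age": round(age, 1),
                "weight_kg": round(weight, 1),
                "height_m": round(height, 2),
                "bmi": round(round(weight, 1) / round(height, 2) ** 2, 2),
            }
        )
        trial_seeds = wseq.spawn(spec.trials)
        if profiles is not None:
            if worker_id not in profiles:
                raise ValueError(f"no profile for {worker_id}")
            worker_profile = profiles[worker_id]
        else:
            worker_profile = _jitter_profile(base, rng, spec, seed=0)
        for trial in range(1, spec.trials + 1):
            noise_seed = int(trial_seeds[trial - 1].generate_state(1)[0] % (2**31))
            profile = replace(worker_profile, seed=noise_seed)
            recordings.append(
                generate_recording(
                    profile,
                    WorkContext(duration=spec.duration),
                    rate=spec.rate,
                    duration=spec.duration,
                    worker=worker_id,
                    trial=trial,
                )
            )
    return recordings, pd.DataFrame(rows)


def square_wave_fixture(
    low: float,
    high: float,
    duty: float,
    period: float,
    duration: float,
    rate: float = DEFAULT_RATE_HZ,
    segment: Segment = Segment.NECK,
    channel: str = "flexion_extension",
) -> JointAngleSeries:
    """Noise-free two-level series with analytically known level occupancy.

    Each cycle spends ``duty * period`` at *high* (cycle start) and the rest
    at *low*; the fraction of samples at the high level equals the duty
    fraction to within one sample quantum whenever the duration is a multiple
    of the period.
    """
    if not 0.0 <= duty <= 1.0:
        raise ValueError("duty must be in [0, 1]")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    tau = np.mod(t, period)
    samples = np.where(tau < duty * period, high, low)
    return JointAngleSeries(segment, channel, rate, samples.astype(float))


def fixture_recording(
    series_list: list[JointAngleSeries],
    work_type: str = "dynamic",
    worker: str = "W1",
    trial: int = 1,
    fill_segments: bool = True,
) -> MotionRecording:
    """Wrap fixture series into a full recording; unmentioned catalogue
    channels are filled with zeros so every standard finds its inputs."""
    if not series_list:
        raise ValueError("need at least one series")
    rate = series_list[0].sampling_rate
    n = len(series_list[0])
    series = {(s.segment, s.channel): s for s in series_list}
    if fill_segments:
        for seg, channels in SEGMENT_CHANNELS.items():
            for channel in channels:
                series.setdefault(
                    (seg, channel),
                    JointAngleSeries(seg, channel, rate, np.zeros(n)),
                )
    return MotionRecording(
        worker=worker,
        trial=trial,
        series=series,
        context=WorkContext(work_type=work_type, duration=n / rate),
    )
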