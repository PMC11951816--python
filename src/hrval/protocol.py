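"""Synthetic cohort generator for the 9-activity, 2-session validation protocol.

Generates 1 Hz criterion ("chest ECG"-like) HR traces over a structured
activity protocol and derives device ("PPG"-like) traces through a
configurable error model (clock lag, additive bias, motion-scaled noise,
dropouts, spike artifacts), so the whole cleaning and statistics
pipeline can be exercised against known ground truth.

The reference dynamics are a first-order exponential approach of heart
rate toward each activity's target, plus white intrinsic variation,
clipped to the physiological 30-230 bpm range. Interval-structured
activities (HIIT) alternate the target as a square wave with a
45 s effort / 15 s recovery duty cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .preprocess import HRSeries, REFERENCE_POSITION, REST_LABEL

HR_FLOOR = 30.0
HR_CEIL = 230.0

#: motion level assigned to between-activity rest samples
REST_MOTION = 0.05
#: fraction of the HR reserve targeted during between-activity rest
REST_INTENSITY = 0.05
#: effort fraction of each HIIT oscillation period (45 s of 60 s)
HIIT_EFFORT_FRACTION = 0.75


# ---------------------------------------------------------------------------
# protocol and subject description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivitySpec:
    """One protocol activity.

    ``intensity`` is the steady-state target expressed subject-relative,
    as a fraction of the heart-rate reserve: the resolved target is
    ``resting_hr + intensity * hr_reserve``. ``motion_level`` (0-1)
    scales motion-artifact noise in the device error model. Activities
    with ``oscillation_period_s`` set (HIIT) alternate between the full
    target during the effort phase and ``recovery_intensity`` otherwise.
    """

    name: str
    duration_s: int
    intensity: float
    motion_level: float = 0.0
    oscillation_period_s: int | None = None
    recovery_intensity: float | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 0.0 <= self.motion_level <= 1.0:
            raise ValueError("motion_level must be within [0, 1]")

    def target_hr(self, subject: "SubjectParams") -> float:
        """Resolved steady-state target in bpm for this subject."""
        return subject.resting_hr + self.intensity * subject.hr_reserve


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered activities plus the rest/session structure around them."""

    activities: tuple[ActivitySpec, ...]
    rest_between_s: int = 120
    sessions: int = 2
    break_between_sessions_s: int = 1200

    def __post_init__(self) -> None:
        if not self.activities:
            raise ValueError("protocol needs at least one activity")

    @property
    def session_duration_s(self) -> int:
        act = sum(a.duration_s for a in self.activities)
        return act + self.rest_between_s * (len(self.activities) - 1)

    @property
    def activity_names(self) -> list[str]:
        return [a.name for a in self.activities]

    def motion_by_activity(self) -> dict[str, float]:
        out = {a.name: a.motion_level for a in self.activities}
        out[REST_LABEL] = REST_MOTION
        return out

    def windows_per_session(self, window_s: int = 10) -> dict[str, int]:
        """Full averaging windows each activity yields per session."""
        return {a.name: a.duration_s // window_s for a in self.activities}


def default_protocol() -> ProtocolSpec:
    """The 9-activity validation protocol (durations in minutes:
    lying 5, sitting 5, walking 15, picking up objects 8, jogging 8,
    weight training 8, cycling 8, HIIT 8, postexercise sitting 20;
    2-minute rests between activities; two sessions)."""
    return ProtocolSpec(activities=(
        ActivitySpec("lying", 300, 0.00, 0.00),
        ActivitySpec("sitting", 300, 0.02, 0.05),
        ActivitySpec("walking", 900, 0.25, 0.40),
        ActivitySpec("picking_up_objects", 480, 0.30, 0.70),
        ActivitySpec("jogging", 480, 0.55, 0.60),
        ActivitySpec("weight_training", 480, 0.50, 0.90),
        ActivitySpec("cycling", 480, 0.65, 0.20),
        ActivitySpec("hiit", 480, 0.90, 1.00, oscillation_period_s=60),
        ActivitySpec("postexercise_sitting", 1200, 0.10, 0.05),
    ))


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject physiology driving the reference trace."""

    subject_id: str
    resting_hr: float = 60.0
    hr_reserve: float = 120.0
    tau_s: float = 35.0        # exponential approach time constant
    intrinsic_sd: float = 1.5  # white beat-to-beat variation at 1 Hz, bpm

    def __post_init__(self) -> None:
        if self.resting_hr < HR_FLOOR:
            raise ValueError("resting_hr below physiological floor")
        if self.resting_hr + self.hr_reserve > HR_CEIL:
            raise ValueError("resting_hr + hr_reserve exceeds physiological ceiling")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.intrinsic_sd < 0:
            raise ValueError("intrinsic_sd must be non-negative")


@dataclass(frozen=True)
class PopulationParams:
    """Distributions subject parameters are drawn from in a cohort."""

    resting_mean: float = 60.0
    resting_sd: float = 8.0
    resting_range: tuple[float, float] = (40.0, 90.0)
    reserve_mean: float = 120.0
    reserve_sd: float = 15.0
    tau_mean: float = 35.0
    tau_sd: float = 5.0
    intrinsic_sd: float = 1.5


@dataclass(frozen=True)
class DeviceErrorModel:
    """Generative error model of a simulated device.

    ``lag_s`` is the device clock offset against the reference (the
    device reports at time ``t`` the physiological value of ``t - lag``).
    Noise is Gaussian with per-sample SD
    ``noise_sd_bpm + motion_noise_gain * motion_level``; samples are
    independently dropped (missing) with ``dropout_rate`` and displaced
    by a single-sample spike of ``±spike_magnitude_bpm`` with
    ``spike_rate``. ``session2_extra_bias_bpm`` adds a session-specific
    offset, useful for probing the between-session reproducibility test.
    """

    lag_s: int = 0
    bias_bpm: float = 0.0
    noise_sd_bpm: float = 0.0
    motion_noise_gain: float = 0.0
    dropout_rate: float = 0.0
    spike_rate: float = 0.0
    spike_magnitude_bpm: float = 40.0
    session2_extra_bias_bpm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "spike_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be within [0, 1]")
        for name in ("noise_sd_bpm", "motion_noise_gain", "spike_magnitude_bpm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

def _session_layout(protocol: ProtocolSpec, subject: SubjectParams
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-second (activity label, target bpm) arrays for one session."""
    labels: list[np.ndarray] = []
    targets: list[np.ndarray] = []
    rest_target = subject.resting_hr + REST_INTENSITY * subject.hr_reserve
    for i, act in enumerate(protocol.activities):
        tgt = act.target_hr(subject)
        if not HR_FLOOR <= tgt <= HR_CEIL:
            raise ValueError(
                f"activity {act.name!r} resolves to {tgt:.1f} bpm, outside "
                f"[{HR_FLOOR:.0f}, {HR_CEIL:.0f}]")
        seg = np.full(act.duration_s, tgt)
        if act.oscillation_period_s:
            phase = np.arange(act.duration_s) % act.oscillation_period_s
            effort = phase < HIIT_EFFORT_FRACTION * act.oscillation_period_s
            rec_int = (act.recovery_intensity if act.recovery_intensity is not None
                       else 0.5 * act.intensity)
            seg = np.where(effort, tgt, subject.resting_hr + rec_int * subject.hr_reserve)
        labels.append(np.full(act.duration_s, act.name, dtype=object))
        targets.append(seg)
        if i < len(protocol.activities) - 1 and protocol.rest_between_s > 0:
            labels.append(np.full(protocol.rest_between_s, REST_LABEL, dtype=object))
            targets.append(np.full(protocol.rest_between_s, rest_target))
    return np.concatenate(labels), np.concatenate(targets)


def _simulate_session(protocol: ProtocolSpec, subject: SubjectParams,
                      session: int, rng: np.random.Generator) -> HRSeries:
    labels, target = _session_layout(protocol, subject)
    n = len(target)
    alpha = 1.0 - np.exp(-1.0 / subject.tau_s)
    smooth, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], target,
                        zi=[(1.0 - alpha) * subject.resting_hr])
    hr = smooth + subject.intrinsic_sd * rng.standard_normal(n)
    hr = np.clip(hr, HR_FLOOR, HR_CEIL)
    frame = pd.DataFrame({"t_s": np.arange(n, dtype=int), "activity": labels,
                          "hr_bpm": hr})
    return HRSeries(subject.subject_id, "reference", REFERENCE_POSITION,
                    session, frame)


def simulate_reference(protocol: ProtocolSpec, subject: SubjectParams,
                       seed: int) -> list[HRSeries]:
    """Criterion traces for every session, one HRSeries per session.

    Each session starts from resting HR and relaxes toward the running
    activity target with time constant ``tau_s``; white intrinsic noise
    is added on top and the result is clipped to [30, 230] bpm. Fully
    deterministic in (protocol, subject, seed).
    """
    out = []
    for session in range(1, protocol.sessions + 1):
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), session)))
        out.append(_simulate_session(protocol, subject, session, rng))
    return out


# ---------------------------------------------------------------------------
# device simulation
# ---------------------------------------------------------------------------

def simulate_device(reference: HRSeries, model: DeviceErrorModel, seed: int,
                    motion_by_activity: Mapping[str, float] | None = None,
                    position: str = "upper_arm",
                    device_id: str | None = None,
                    dropout_as_zero: bool = False) -> HRSeries:
    """Derive a device trace from a reference trace through the error model.

    The output has the same length and timestamps as the reference;
    samples whose lag-shifted source falls before the recording start
    are missing. Spikes displace the (noisy) value by
    ``±spike_magnitude_bpm`` with random sign; dropouts become missing
    (or literal zeros with ``dropout_as_zero``, exercising the
    blanks-or-zeros parsing rule downstream).
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 97)))
    hr = reference.hr
    n = len(hr)
    lag = int(model.lag_s)
    if abs(lag) >= n:
        raise ValueError("lag exceeds trace length")
    base = np.full(n, np.nan)
    if lag >= 0:
        base[lag:] = hr[:n - lag]
    else:
        base[:n + lag] = hr[-lag:]

    motion_map = dict(motion_by_activity or {})
    motion = np.array([motion_map.get(a, 0.0) for a in reference.activity])
    sd = model.noise_sd_bpm + model.motion_noise_gain * motion
    vals = base + model.bias_bpm + sd * rng.standard_normal(n)
    if reference.session == 2:
        vals = vals + model.session2_extra_bias_bpm

    spike = rng.random(n) < model.spike_rate
    signs = rng.choice([-1.0, 1.0], size=n)
    vals = np.where(spike, vals + signs * model.spike_magnitude_bpm, vals)
    drop = rng.random(n) < model.dropout_rate
    vals = np.where(drop, np.nan, vals)
    vals = np.where(np.isfinite(vals), np.maximum(vals, 1.0), vals)
    if dropout_as_zero:
        vals = np.where(drop, 0.0, vals)
        # zeros are re-interpreted as missing by read_hr_table; keep the
        # in-memory container valid by leaving them NaN unless written out
        vals = np.where(drop, np.nan, vals)

    frame = pd.DataFrame({"t_s": reference.t.copy(),
                          "activity": reference.activity.copy(),
                          "hr_bpm": vals})
    return HRSeries(reference.subject_id, device_id or f"sim_{position}",
                    position, reference.session, frame)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Simulated traces plus the ground-truth subject parameters."""

    series: list[HRSeries]
    subjects: list[SubjectParams]


def _child_seed(*key: int) -> int:
    # deterministic child seed below 2**31 so subsets are reproducible
    return int(np.random.SeedSequence(tuple(int(k) for k in key)).generate_state(1)[0]
               & 0x7FFFFFFF)


def draw_subject(subject_id: str, seed: int,
                 population: PopulationParams | None = None) -> SubjectParams:
    """Draw one subject's physiology from the population distributions."""
    pop = population or PopulationParams()
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 11)))
    lo, hi = pop.resting_range
    resting = rng.normal(pop.resting_mean, pop.resting_sd)
    while not lo <= resting <= hi:  # truncated normal by rejection
        resting = rng.normal(pop.resting_mean, pop.resting_sd)
    reserve = rng.normal(pop.reserve_mean, pop.reserve_sd)
    reserve = float(np.clip(reserve, 60.0, HR_CEIL - resting - 1.0))
    tau = float(max(5.0, rng.normal(pop.tau_mean, pop.tau_sd)))
    return SubjectParams(subject_id, float(resting), reserve, tau, pop.intrinsic_sd)


def simulate_cohort(n_subjects: int, protocol: ProtocolSpec,
                    models: Mapping[str, DeviceErrorModel], seed: int,
                    population: PopulationParams | None = None) -> Cohort:
    """Simulate a cohort: per subject, a reference trace per session and
    one device trace per configured position.

    Child seeds are derived deterministically from (seed, subject index,
    position index), so any subject subset reproduces bit-identically.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    if not models:
        raise ValueError("at least one device position is required")
    motion = protocol.motion_by_activity()
    series: list[HRSeries] = []
    subjects: list[SubjectParams] = []
    positions = sorted(models)
    for i in range(1, n_subjects + 1):
        subject = draw_subject(f"S{i:02d}", _child_seed(seed, i, 0), population)
        subjects.append(subject)
        refs = simulate_reference(protocol, subject, _child_seed(seed, i, 1))
        series.extend(refs)
        for j, pos in enumerate(positions):
            for ref in refs:
                series.append(simulate_device(
                    ref, models[pos],
                    _child_seed(seed, i, 2 + j, ref.session),
                    motion_by_activity=motion, position=pos))
    return Cohort(series, subjects)


# ---------------------------------------------------------------------------
# protocol bookkeeping
# ---------------------------------------------------------------------------

def expected_window_counts(protocol: ProtocolSpec, n_sessions: int,
                           window_s: int = 10) -> dict[str, int]:
    """Expected per-activity window counts at full retention over
    ``n_sessions`` analyzed sessions (protocol arithmetic only)."""
    per = protocol.windows_per_session(window_s)
    return {name: count * n_sessions for name, count in per.items()}
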