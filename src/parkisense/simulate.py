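"""Synthetic two-class cohorts of six-channel mobility recordings.

The generator emulates a clinic mobility protocol recorded by a single
lower-back IMU at 100 Hz: a 32-foot walk, two 20 s quiet-stance tasks
(eyes open / eyes closed), and two trials each of the Timed Up and Go
(TUG) and cognitive TUG. Recordings are built from piecewise kinematic
templates — raised-cosine trunk-pitch pulses for sit-to-stand and
stand-to-sit, raised-cosine yaw pulses integrating to 180 degrees for
turns, harmonic gait oscillation during walking, band-limited sway noise
during stance — plus additive white Gaussian sensor noise. Ground-truth
segment boundaries are recorded exactly as the template lays them down,
so every downstream stage (filtering, segmentation, features, the
classifier) is testable against a known answer.

Class structure: the majority class uses the neutral template; the
minority class gets multiplicative kinematic shifts (slower postural
transitions, slower turns, larger sway power, optionally shifted gait
harmonics). A zero-effect configuration (all multipliers 1) makes the
class label exchangeable with the signal content, which is the null
condition used to calibrate the classifier tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_io import (
    ACC_CHANNELS,
    CHANNELS,
    GYR_CHANNELS,
    SensorRecording,
    TaskMarker,
    write_recording,
)

# protocol task roster: task id -> number of trials
TASKS: dict[str, int] = {
    "walk32ft": 1,
    "stand_eo_20s": 1,
    "stand_ec_20s": 1,
    "tug": 2,
    "cogtug": 2,
}
STANCE_TASKS = ("stand_eo_20s", "stand_ec_20s")

MAJORITY_LABEL = "pd"
MINORITY_LABEL = "nonpd"
MINORITY_SUBTYPES = ("msa_p", "psp", "dlb", "cbs", "et", "dip")

SEGMENT_LABELS = ("sit_to_stand", "walk", "turn", "stand_to_sit", "quiet_stance")


@dataclass(frozen=True)
class ClassEffect:
    """Multiplicative kinematic shifts applied to the minority class.

    All multipliers are dimensionless and must be positive; all-ones means
    no class difference. ``transition_duration`` stretches sit-to-stand and
    stand-to-sit (same net pitch angle, lower peak velocity);
    ``turn_velocity`` scales the peak turn angular velocity (duration is
    stretched to preserve the 180 degree net yaw); ``sway_power`` scales
    the stance mediolateral sway variance; ``gait_harmonic`` scales the
    second-harmonic gait acceleration amplitude.
    """

    transition_duration: float = 1.5
    turn_velocity: float = 0.7
    sway_power: float = 1.5
    gait_harmonic: float = 1.0

    def __post_init__(self) -> None:
        for name in ("transition_duration", "turn_velocity", "sway_power", "gait_harmonic"):
            if getattr(self, name) <= 0:
                raise ValueError(f"effect multiplier {name} must be > 0")

    @classmethod
    def none(cls) -> "ClassEffect":
        return cls(1.0, 1.0, 1.0, 1.0)

    def scaled(self, s: float) -> "ClassEffect":
        """Interpolate multipliers toward the neutral template (s=0 -> all ones)."""
        return ClassEffect(*(1.0 + (m - 1.0) * s for m in (
            self.transition_duration, self.turn_velocity, self.sway_power, self.gait_harmonic)))


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort design: sizes, sensor settings, class effects, noise, seed."""

    n_majority: int = 260
    n_minority: int = 18
    sample_rate: float = 100.0
    tasks: tuple[str, ...] = tuple(TASKS)
    effect: ClassEffect = field(default_factory=ClassEffect)
    effect_tasks: frozenset[str] | None = None  # None -> effects in every task
    noise_sd_acc: float = 0.02  # g, per accelerometer channel
    noise_sd_gyr: float = 2.0  # dps, per gyroscope channel
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_majority >= self.n_minority >= 2):
            raise ValueError("need n_majority >= n_minority >= 2")
        if self.sample_rate <= 2 * 20.0:
            raise ValueError("sample_rate must exceed twice the 20 Hz filter cutoff")
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown task descriptor(s): {sorted(unknown)}")


# ---------------------------------------------------------------------------
# kinematic template parameters (neutral class)

@dataclass(frozen=True)
class KinematicParams:
    """Effect-adjusted template parameters for one recording."""

    sample_rate: float = 100.0
    still_s: float = 1.0
    transition_s: float = 1.5
    transition_angle_deg: float = 60.0
    turn_angle_deg: float = 180.0
    turn_peak_dps: float = 180.0
    tug_walk_s: float = 2.5
    walk32_s: float = 8.0
    stance_s: float = 20.0
    gait_freq_hz: float = 2.0
    gait_amp_g: float = 0.30
    gait_harmonic_g: float = 0.10
    sway_sd_g: float = 0.05
    duration_jitter: float = 0.05  # lognormal sigma on segment durations
    noise_sd_acc: float = 0.02
    noise_sd_gyr: float = 2.0

    @classmethod
    def for_task(
        cls,
        task: str,
        effect: ClassEffect | None = None,
        *,
        sample_rate: float = 100.0,
        noise_sd_acc: float = 0.02,
        noise_sd_gyr: float = 2.0,
        duration_jitter: float | None = None,
    ) -> "KinematicParams":
        if task not in TASKS:
            raise ValueError(f"unknown task descriptor: {task!r}")
        e = effect or ClassEffect.none()
        if duration_jitter is None:
            # dual-task cost: higher within-segment variability on cogTUG
            duration_jitter = 0.15 if task == "cogtug" else 0.05
        base = cls(
            sample_rate=sample_rate,
            noise_sd_acc=noise_sd_acc,
            noise_sd_gyr=noise_sd_gyr,
            duration_jitter=duration_jitter,
        )
        return replace(
            base,
            transition_s=base.transition_s * e.transition_duration,
            turn_peak_dps=base.turn_peak_dps * e.turn_velocity,
            sway_sd_g=base.sway_sd_g * math.sqrt(e.sway_power),
            gait_harmonic_g=base.gait_harmonic_g * e.gait_harmonic,
        )

    @property
    def turn_s(self) -> float:
        # duration follows from preserving net yaw under the Hann velocity pulse:
        # integral of peak * sin^2(pi t / d) over [0, d] is peak * d / 2
        return 2.0 * self.turn_angle_deg / self.turn_peak_dps


@dataclass
class GroundTruth:
    """True segment boundaries laid down by the template (half-open samples)."""

    task: str
    segments: list[tuple[str, int, int]]

    def boundaries(self) -> np.ndarray:
        return np.array(sorted({b for _, s, e in self.segments for b in (s, e)}))


def _hann_pulse(n: int, peak: float) -> np.ndarray:
    """Raised-cosine velocity pulse; integrates to peak * duration / 2."""
    t = np.arange(n) / max(n, 1)
    return peak * np.sin(np.pi * t) ** 2


def _gait(n: int, fs: float, p: KinematicParams, amp_scale: float = 1.0) -> dict[str, np.ndarray]:
    t = np.arange(n) / fs
    w = 2 * np.pi * p.gait_freq_hz
    a = p.gait_amp_g * amp_scale
    return {
        "acc_v": a * np.sin(w * t),
        "acc_ap": 0.6 * a * np.sin(w * t + 0.8) + p.gait_harmonic_g * amp_scale * np.sin(2 * w * t),
        "acc_ml": 0.2 * a * np.sin(0.5 * w * t),
        "gyr_ml": 12.0 * amp_scale * np.sin(w * t + 0.3),
        "gyr_ap": 6.0 * amp_scale * np.sin(w * t + 1.1),
    }


def _band_limited(n: int, rng: np.random.Generator, fs: float, cutoff: float = 2.0) -> np.ndarray:
    """Unit-SD low-frequency noise (postural sway surrogate)."""
    from scipy.signal import butter, filtfilt

    x = rng.standard_normal(max(n, 32))
    b, a = butter(2, cutoff, btype="low", fs=fs)
    y = filtfilt(b, a, x)[:n]
    sd = y.std()
    return y / sd if sd > 0 else y


def _tug_plan(p: KinematicParams, rng: np.random.Generator) -> list[tuple[str, float]]:
    """Ordered (label, duration) plan; the standard TUG decomposition."""
    j = lambda d: d * math.exp(p.duration_jitter * rng.standard_normal())
    return [
        ("still", p.still_s),
        ("sit_to_stand", j(p.transition_s)),
        ("walk", j(p.tug_walk_s)),
        ("turn", j(p.turn_s)),
        ("walk", j(p.tug_walk_s)),
        ("turn", j(p.turn_s)),
        ("stand_to_sit", j(p.transition_s)),
        ("still", p.still_s),
    ]


def simulate_recording(
    task: str,
    params: KinematicParams | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[SensorRecording, GroundTruth]:
    """Build one recording for one protocol task from the kinematic template.

    Returns the recording (single marker spanning the whole task) and the
    template's true segment boundaries. Deterministic given seed and params.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task descriptor: {task!r}")
    p = params or KinematicParams.for_task(task)
    fs = p.sample_rate
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if task in STANCE_TASKS:
        plan = [("still", 0.5), ("quiet_stance", p.stance_s), ("still", 0.5)]
    elif task == "walk32ft":
        plan = [("still", p.still_s), ("walk", p.walk32_s), ("still", p.still_s)]
    else:  # tug / cogtug
        plan = _tug_plan(p, rng)

    lengths = [max(2, int(round(d * fs))) for _, d in plan]
    n = int(sum(lengths))
    channels = {c: np.zeros(n) for c in CHANNELS}
    segments: list[tuple[str, int, int]] = []
    sway_factor = 1.3 if task == "stand_ec_20s" else 1.0

    turn_sign = 1.0
    pos = 0
    for (label, _), m in zip(plan, lengths):
        sl = slice(pos, pos + m)
        if label == "walk":
            for ch, x in _gait(m, fs, p).items():
                channels[ch][sl] += x
        elif label == "turn":
            channels["gyr_v"][sl] += _hann_pulse(m, turn_sign * 2.0 * p.turn_angle_deg / (m / fs))
            turn_sign = -turn_sign
            for ch, x in _gait(m, fs, p, amp_scale=0.5).items():
                channels[ch][sl] += x
        elif label in ("sit_to_stand", "stand_to_sit"):
            sign = 1.0 if label == "sit_to_stand" else -1.0
            channels["gyr_ap"][sl] += _hann_pulse(m, sign * 2.0 * p.transition_angle_deg / (m / fs))
            # trunk translation shows up as low-frequency acceleration bumps
            bump = np.sin(np.pi * np.arange(m) / m)
            channels["acc_ap"][sl] += sign * 0.20 * bump
            channels["acc_v"][sl] += 0.15 * bump
            channels["gyr_ml"][sl] += 10.0 * bump
        elif label == "quiet_stance":
            sd = p.sway_sd_g * sway_factor
            channels["acc_ml"][sl] += sd * _band_limited(m, rng, fs)
            channels["acc_ap"][sl] += 0.8 * sd * _band_limited(m, rng, fs)
            channels["gyr_v"][sl] += 1.5 * _band_limited(m, rng, fs)
        if label != "still":
            segments.append((label, pos, pos + m))
        pos += m

    for c in ACC_CHANNELS:
        channels[c] += p.noise_sd_acc * rng.standard_normal(n)
    for c in GYR_CHANNELS:
        channels[c] += p.noise_sd_gyr * rng.standard_normal(n)

    rec = SensorRecording(fs, channels, [TaskMarker(task, 0, n, 1)])
    return rec, GroundTruth(task, segments)


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class Participant:
    pid: str
    label: str  # MAJORITY_LABEL or MINORITY_LABEL
    subtype: str | None  # parkinsonism subtype, minority only
    recordings: dict[tuple[str, int], SensorRecording]
    truths: dict[tuple[str, int], GroundTruth]


def simulate_cohort(config: SimulationConfig | None = None) -> list[Participant]:
    """Simulate a full two-class cohort under the given design.

    Exactly ``n_majority + n_minority`` participants, each with every task
    in the roster (two trials of TUG and cogTUG). Class effects are applied
    only to minority participants, and only within ``effect_tasks`` when
    that restriction is set.
    """
    config = config or SimulationConfig()
    n_total = config.n_majority + config.n_minority
    ss = np.random.SeedSequence(config.seed)
    participant_seeds = ss.spawn(n_total)
    cohort: list[Participant] = []
    width = len(str(n_total))
    for i in range(n_total):
        minority = i >= config.n_majority
        label = MINORITY_LABEL if minority else MAJORITY_LABEL
        subtype = MINORITY_SUBTYPES[(i - config.n_majority) % len(MINORITY_SUBTYPES)] if minority else None
        recordings: dict[tuple[str, int], SensorRecording] = {}
        truths: dict[tuple[str, int], GroundTruth] = {}
        rec_seeds = participant_seeds[i].spawn(sum(TASKS[t] for t in config.tasks))
        k = 0
        for task in config.tasks:
            apply_effect = minority and (
                config.effect_tasks is None or task in config.effect_tasks
            )
            params = KinematicParams.for_task(
                task,
                config.effect if apply_effect else ClassEffect.none(),
                sample_rate=config.sample_rate,
                noise_sd_acc=config.noise_sd_acc,
                noise_sd_gyr=config.noise_sd_gyr,
            )
            for trial in range(1, TASKS[task] + 1):
                rng = np.random.default_rng(rec_seeds[k])
                k += 1
                rec, truth = simulate_recording(task, params, rng)
                rec.markers = [TaskMarker(task, 0, rec.n_samples, trial)]
                recordings[(task, trial)] = rec
                truths[(task, trial)] = truth
        cohort.append(Participant(f"P{i + 1:0{width}d}", label, subtype, recordings, truths))
    return cohort


def cohort_labels(cohort: list[Participant]) -> np.ndarray:
    return np.array([p.label for p in cohort])


def write_cohort(cohort: list[Participant], out_dir: str | Path) -> Path:
    """Write per-recording CSV/JSON files and a cohort manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for part in cohort:
        for (task, trial), rec in part.recordings.items():
            fname = f"{part.pid}_{task}_t{trial}.csv"
            write_recording(rec, out_dir / fname)
            truth = part.truths[(task, trial)]
            rows.append(
                {
                    "pid": part.pid,
                    "label": part.label,
                    "subtype": part.subtype or "",
                    "task": task,
                    "trial": trial,
                    "path": fname,
                    "true_segments": ";".join(f"{l}:{s}:{e}" for l, s, e in truth.segments),
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir / "manifest.csv"
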