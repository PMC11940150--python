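"""Subtask segmentation of complex mobility tasks.

TUG and cognitive-TUG windows are decomposed into the canonical
sit_to_stand, walk, turn, walk, turn, stand_to_sit sequence; the 32-foot
walk into its walking span. Turns are found on the vertical gyroscope via
trapezoidal integration of yaw angular velocity; postural transitions on
the anteroposterior gyroscope (trunk pitch by the channel contract) the
same way. Candidate windows are seeded where the smoothed angular
velocity exceeds a high threshold, merged across short gaps, expanded
outward under a sign-consistent low threshold (hysteresis), and kept only
if the net integrated angle clears a minimum. The smoothing window spans
one gait cycle, which cancels the locomotor oscillation that would
otherwise leak into the pitch channel during walking.

All thresholds are exposed in :class:`SegmentationParams`; the defaults
are calibrated to be robust on the synthetic templates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .signal_io import SensorRecording


class SegmentationError(RuntimeError):
    """Raised when a window cannot be decomposed; the recording is flagged
    for exclusion rather than silently mis-segmented."""


@dataclass(frozen=True)
class SegmentationParams:
    turn_angle_min_deg: float = 90.0
    turn_velocity_high_dps: float = 30.0
    pitch_angle_min_deg: float = 20.0
    pitch_velocity_high_dps: float = 15.0
    velocity_low_dps: float = 1.5
    smooth_window_s: float = 0.5  # one gait cycle at ~2 Hz
    merge_gap_s: float = 0.5
    min_segment_s: float = 0.3
    still_acc_sd_g: float = 0.08
    still_gyr_sd_dps: float = 8.0
    still_window_s: float = 0.25


@dataclass
class SegmentedTask:
    """Ordered, non-overlapping labeled segments within one task window."""

    task: str
    trial: int
    segments: list[tuple[str, int, int]]

    def labels(self) -> list[str]:
        return [l for l, _, _ in self.segments]

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "trial": self.trial,
            "segments": [
                {"label": l, "start": int(s), "end": int(e)} for l, s, e in self.segments
            ],
        }


def cumulative_yaw(gyr: np.ndarray, sample_rate: float) -> np.ndarray:
    """Trapezoid-rule cumulative integral of angular velocity, in degrees.

    The first element is 0; an input of length < 2 is an error.
    """
    gyr = np.asarray(gyr, dtype=float)
    if gyr.size < 2:
        raise ValueError("need at least 2 samples to integrate")
    return cumulative_trapezoid(gyr, dx=1.0 / sample_rate, initial=0.0)


def _smooth(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    w = max(1, int(round(window_s * fs)))
    kernel = np.ones(w) / w
    return np.convolve(x, kernel, mode="same")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _detect_pulses(
    v: np.ndarray,
    fs: float,
    high: float,
    low: float,
    angle_min: float,
    merge_gap_s: float,
    smooth_window_s: float,
) -> list[tuple[int, int]]:
    """Generic single-signed angular-velocity pulse detector with hysteresis."""
    s = _smooth(np.asarray(v, dtype=float), fs, smooth_window_s)
    runs = _runs(np.abs(s) >= high)
    # merge nearby runs (a mid-pulse dip should not split a window)
    merged: list[list[int]] = []
    gap = int(round(merge_gap_s * fs))
    for a, b in runs:
        if merged and a - merged[-1][1] <= gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    out: list[tuple[int, int]] = []
    n = len(v)
    for a, b in merged:
        sign = np.sign(s[(a + b) // 2]) or 1.0
        while a > 0 and s[a - 1] * sign > low:
            a -= 1
        while b < n and s[b] * sign > low:
            b += 1
        yaw = cumulative_yaw(v[a:b], fs) if b - a >= 2 else np.zeros(1)
        if abs(yaw[-1]) >= angle_min:
            out.append((a, b))
    return out


def detect_turns(
    gyr_v: np.ndarray, sample_rate: float, params: SegmentationParams | None = None
) -> list[tuple[int, int]]:
    """Maximal windows of net yaw >= the turn-angle minimum.

    Returns half-open (start, end) windows; an empty list when no turn is
    present (e.g. quiet stance).
    """
    p = params or SegmentationParams()
    return _detect_pulses(
        gyr_v,
        sample_rate,
        p.turn_velocity_high_dps,
        p.velocity_low_dps,
        p.turn_angle_min_deg,
        p.merge_gap_s,
        p.smooth_window_s,
    )


def detect_postural_transitions(
    rec: SensorRecording, params: SegmentationParams | None = None
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Sit-to-stand and stand-to-sit windows of a TUG-like recording.

    Trunk-pitch pulses are detected on the anteroposterior gyroscope; the
    first candidate (in time) is labeled sit_to_stand and the last
    stand_to_sit, matching the TUG protocol order regardless of sensor
    mounting polarity. Fewer than two candidates raises
    :class:`SegmentationError`.
    """
    p = params or SegmentationParams()
    pulses = _detect_pulses(
        rec.channels["gyr_ap"],
        rec.sample_rate,
        p.pitch_velocity_high_dps,
        p.velocity_low_dps,
        p.pitch_angle_min_deg,
        p.merge_gap_s,
        p.smooth_window_s,
    )
    if len(pulses) < 2:
        raise SegmentationError(
            f"segmentation failed: {len(pulses)} postural-transition candidate(s), need 2"
        )
    return pulses[0], pulses[-1]


def remove_stationary(
    rec: SensorRecording, params: SegmentationParams | None = None
) -> np.ndarray:
    """Boolean mask of retained (moving) samples.

    A sample is stationary when the centered rolling SDs of the vertical
    acceleration and mediolateral gyroscope both fall below the stillness
    thresholds; the thresholds sit well above the stance noise floor and
    well below locomotor amplitudes.
    """
    p = params or SegmentationParams()
    fs = rec.sample_rate
    w = max(2, int(round(p.still_window_s * fs)))

    def rolling_sd(x: np.ndarray) -> np.ndarray:
        k = np.ones(w) / w
        m = np.convolve(x, k, mode="same")
        m2 = np.convolve(x * x, k, mode="same")
        return np.sqrt(np.maximum(m2 - m * m, 0.0))

    still = (rolling_sd(rec.channels["acc_v"]) < p.still_acc_sd_g) & (
        rolling_sd(rec.channels["gyr_ml"]) < p.still_gyr_sd_dps
    )
    return ~still


def _trim_stationary(moving: np.ndarray, start: int, end: int) -> tuple[int, int]:
    """Shrink [start, end) to its outermost moving samples."""
    idx = np.flatnonzero(moving[start:end])
    if idx.size == 0:
        return start, start
    return start + int(idx[0]), start + int(idx[-1]) + 1


def segment_task(
    rec: SensorRecording,
    task: str,
    trial: int = 1,
    params: SegmentationParams | None = None,
) -> SegmentedTask:
    """Decompose a task window into its labeled subtasks.

    TUG/cogTUG yield the canonical six segments in protocol order;
    walk32ft yields its single walking span with stationary lead-in/out
    removed. Raises :class:`SegmentationError` when the expected structure
    cannot be recovered.
    """
    p = params or SegmentationParams()
    if task not in ("tug", "cogtug", "walk32ft"):
        raise ValueError(f"segment_task expects a complex task, got {task!r}")
    fs = rec.sample_rate
    min_len = int(round(p.min_segment_s * fs))
    moving = remove_stationary(rec, p)

    if task == "walk32ft":
        turns = detect_turns(rec.channels["gyr_v"], fs, p)
        in_turn = np.zeros(rec.n_samples, dtype=bool)
        for a, b in turns:
            in_turn[a:b] = True
        runs = _runs(moving & ~in_turn)
        runs = [(a, b) for a, b in runs if b - a >= min_len]
        if not runs:
            raise SegmentationError("segmentation failed: no walking span in walk32ft")
        a, b = max(runs, key=lambda r: r[1] - r[0])
        return SegmentedTask(task, trial, [("walk", a, b)])

    sts, st_sit = detect_postural_transitions(rec, p)
    if st_sit[0] <= sts[1]:
        raise SegmentationError("segmentation failed: transitions overlap")
    mid_v = rec.channels["gyr_v"][sts[1] : st_sit[0]]
    turns = [(a + sts[1], b + sts[1]) for a, b in detect_turns(mid_v, fs, p)]
    if len(turns) < 2:
        raise SegmentationError(
            f"segmentation failed: {len(turns)} turn(s) between transitions, need 2"
        )
    if len(turns) > 2:  # keep the two largest net-yaw windows, in time order
        yaw = lambda w: abs(cumulative_yaw(rec.channels["gyr_v"][w[0] : w[1]], fs)[-1])
        turns = sorted(sorted(turns, key=yaw)[-2:])
    (t1a, t1b), (t2a, t2b) = turns
    w1 = _trim_stationary(moving, sts[1], t1a)
    w2 = _trim_stationary(moving, t1b, t2a)
    segments = [
        ("sit_to_stand", sts[0], sts[1]),
        ("walk", *w1),
        ("turn", t1a, t1b),
        ("walk", *w2),
        ("turn", t2a, t2b),
        ("stand_to_sit", st_sit[0], st_sit[1]),
    ]
    for label, a, b in segments:
        if b - a < min_len:
            raise SegmentationError(
                f"segmentation failed: {label} segment shorter than "
                f"{p.min_segment_s} s ({(b - a) / fs:.2f} s)"
            )
    return SegmentedTask(task, trial, segments)
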