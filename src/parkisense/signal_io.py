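"""Six-channel inertial recordings: data model, CSV/JSON round-trip, filtering.

A recording holds three accelerometer axes (vertical, mediolateral,
anteroposterior; units g) and three gyroscope axes (same axes; units
degrees/s) sampled at a fixed rate, plus task markers delimiting the
mobility tasks performed while the sensor was worn on the lower back.
All sample indexing is 0-based and half-open, so consecutive windows
compose without overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

CHANNELS = ("acc_v", "acc_ml", "acc_ap", "gyr_v", "gyr_ml", "gyr_ap")
ACC_CHANNELS = CHANNELS[:3]
GYR_CHANNELS = CHANNELS[3:]


class RecordingError(ValueError):
    """A recording violates the data-model contract (bad channel, marker, rate)."""


@dataclass(frozen=True)
class TaskMarker:
    """Half-open [start, end) sample window of one task trial."""

    task: str
    start: int
    end: int
    trial: int = 1


@dataclass
class SensorRecording:
    """One participant x one session of six synchronized channels."""

    sample_rate: float
    channels: dict[str, np.ndarray]
    markers: list[TaskMarker] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise RecordingError(f"sample_rate must be > 0, got {self.sample_rate}")
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise RecordingError(f"missing channel: {', '.join(missing)}")
        lengths = {c: len(self.channels[c]) for c in CHANNELS}
        if len(set(lengths.values())) != 1:
            raise RecordingError(f"channel length mismatch: {lengths}")
        n = self.n_samples
        if n < 2:
            raise RecordingError("channels must hold at least 2 samples")
        for m in self.markers:
            if not (0 <= m.start < m.end <= n):
                raise RecordingError(
                    f"marker {m.task} trial {m.trial} window [{m.start}, {m.end}) "
                    f"out of bounds for {n} samples"
                )
        self.channels = {c: np.asarray(self.channels[c], dtype=float) for c in CHANNELS}

    @property
    def n_samples(self) -> int:
        return len(self.channels[CHANNELS[0]])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def marker(self, task: str, trial: int = 1) -> TaskMarker:
        for m in self.markers:
            if m.task == task and m.trial == trial:
                return m
        raise RecordingError(f"no marker for task {task!r} trial {trial}")


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth specification; zero_lag applies it forward-backward."""

    order: int = 4
    cutoff: float = 20.0
    zero_lag: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")

    def validate(self, sample_rate: float) -> None:
        if self.cutoff >= sample_rate / 2:
            raise ValueError(
                f"cutoff {self.cutoff} Hz >= Nyquist {sample_rate / 2} Hz"
            )


def lowpass_filter(rec: SensorRecording, spec: FilterSpec | None = None) -> SensorRecording:
    """Filter each channel independently with a low-pass Butterworth filter.

    With ``zero_lag`` the filter is applied forward then backward
    (``scipy.signal.filtfilt``), giving zero phase shift and the squared
    one-pass magnitude response. Edges are handled by reflective padding of
    length ``3 * order`` to suppress startup transients.
    """
    spec = spec or FilterSpec()
    spec.validate(rec.sample_rate)
    b, a = butter(spec.order, spec.cutoff, btype="low", fs=rec.sample_rate)
    out = {}
    for name, x in rec.channels.items():
        if spec.zero_lag:
            out[name] = filtfilt(b, a, x, padtype="even", padlen=min(3 * spec.order, len(x) - 1))
        else:
            from scipy.signal import lfilter

            out[name] = lfilter(b, a, x)
    return SensorRecording(rec.sample_rate, out, list(rec.markers))


def extract_task_window(rec: SensorRecording, task: str, trial: int = 1) -> SensorRecording:
    """Return the sub-recording on a task's half-open marker window.

    The extracted window carries a single marker rebased to sample 0.
    """
    m = rec.marker(task, trial)
    channels = {c: rec.channels[c][m.start : m.end] for c in CHANNELS}
    marker = TaskMarker(task=m.task, start=0, end=m.end - m.start, trial=m.trial)
    return SensorRecording(rec.sample_rate, channels, [marker])


def write_recording(rec: SensorRecording, path: str | Path) -> None:
    """Write channels as CSV (time_s + six channels) and markers as a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": rec.time()})
    for c in CHANNELS:
        df[c] = rec.channels[c]
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "sample_rate": rec.sample_rate,
        "markers": [
            {"task": m.task, "start": m.start, "end": m.end, "trial": m.trial}
            for m in rec.markers
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path) -> SensorRecording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`RecordingError` naming the defect for a missing channel
    column, non-monotone time, or an out-of-bounds marker.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise RecordingError(f"missing channel column: {', '.join(missing)}")
    if "time_s" in df.columns and np.any(np.diff(df["time_s"].to_numpy()) <= 0):
        raise RecordingError("non-monotone time column")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    markers = [
        TaskMarker(m["task"], int(m["start"]), int(m["end"]), int(m.get("trial", 1)))
        for m in sidecar.get("markers", [])
    ]
    channels = {c: df[c].to_numpy(dtype=float) for c in CHANNELS}
    return SensorRecording(float(sidecar["sample_rate"]), channels, markers)


def _sub_recording(rec: SensorRecording, start: int, end: int) -> SensorRecording:
    """Internal: slice [start, end) keeping no markers."""
    channels = {c: rec.channels[c][start:end] for c in CHANNELS}
    return SensorRecording(rec.sample_rate, channels, [])
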