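"""Reading and writing motion-capture marker tables and note-event streams.

Two in-memory containers anchor the pipeline:

``MotionRecording``
    synchronized vertical marker height series (five fingertips plus one
    marker per piano key) at a fixed sampling rate, heights in mm.
``NoteEventStream``
    the sounded performance: ordered note onsets (ms) with MIDI key
    velocities (0-127) and finger assignments (1-5).

Only the vertical (height) axis is modeled; horizontal marker coordinates
in input files are ignored with a logged notice.  The note-event clock is
authoritative: a recording carries a ``t0_ms`` offset aligning its first
sample to that clock.

File formats: a tidy CSV dialect (header ``time_ms,f1..f5,key_<pitch>...``),
standard C3D marker files (labels ``FINGER1..FINGER5``, ``KEY<pitch>``), and
Standard MIDI Files for note events (finger carried on the MIDI channel).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _c3d, _smf

log = logging.getLogger(__name__)

__all__ = [
    "MotionRecording", "NoteEventStream",
    "read_motion", "write_motion", "read_notes", "write_notes",
]

FINGERS = (1, 2, 3, 4, 5)


@dataclass
class MotionRecording:
    """Synchronized vertical marker heights for fingers and keys.

    finger_height maps finger number (1=thumb .. 5=little) to a height
    series in mm; key_height maps MIDI pitch to the key-surface marker
    series.  All series share one uniform time base:
    ``t = t0_ms + i * 1000 / sample_rate``.
    """

    sample_rate: float
    finger_height: dict[int, np.ndarray]
    key_height: dict[int, np.ndarray]
    t0_ms: float = 0.0
    performer_id: str | None = None
    melody_id: str | None = None
    tempo_condition: float | None = None

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.finger_height.values()}
        lengths |= {len(v) for v in self.key_height.values()}
        if len(lengths) != 1:
            raise ValueError(f"marker series lengths differ: {sorted(lengths)}")
        for name, series in self.iter_markers():
            arr = np.asarray(series, float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite heights in marker {name}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def iter_markers(self):
        for f in sorted(self.finger_height):
            yield f"f{f}", self.finger_height[f]
        for p in sorted(self.key_height):
            yield f"key_{p}", self.key_height[p]

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.finger_height.values())))

    @property
    def dt_ms(self) -> float:
        """Sample period in ms (8.333 ms at the standard 120 Hz)."""
        return 1000.0 / self.sample_rate

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * self.dt_ms

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms


@dataclass
class NoteEventStream:
    """Ordered note events: onset (ms), pitch, key velocity, finger."""

    onset_ms: np.ndarray
    pitch: np.ndarray
    key_velocity: np.ndarray
    finger: np.ndarray
    performer_id: str | None = None
    melody_id: str | None = None
    tempo_condition: float | None = None

    def __post_init__(self) -> None:
        self.onset_ms = np.asarray(self.onset_ms, float)
        self.pitch = np.asarray(self.pitch, int)
        self.key_velocity = np.asarray(self.key_velocity, float)
        self.finger = np.asarray(self.finger, int)
        n = len(self.onset_ms)
        if n == 0:
            raise ValueError("empty note-event stream")
        if not (len(self.pitch) == len(self.key_velocity) == len(self.finger) == n):
            raise ValueError("event field lengths differ")
        if np.any(np.diff(self.onset_ms) < 0):
            raise ValueError("onsets must be sorted")
        for f in np.unique(self.finger):
            on = self.onset_ms[self.finger == f]
            if len(on) > 1 and np.min(np.diff(on)) <= 0:
                raise ValueError(f"simultaneous events for one finger (finger {f})")
        bad = (self.key_velocity < 0) | (self.key_velocity > 127)
        if bad.any():
            raise ValueError(f"key velocity outside 0-127 at events {np.nonzero(bad)[0].tolist()}")

    def __len__(self) -> int:
        return len(self.onset_ms)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "onset_ms": self.onset_ms, "pitch": self.pitch,
            "key_velocity": self.key_velocity, "finger": self.finger,
        })


_FINGER_COL = re.compile(r"^f([1-5])$")
_KEY_COL = re.compile(r"^key_(\d+)$")
_C3D_FINGER = re.compile(r"^FINGER([1-5])$", re.I)
_C3D_KEY = re.compile(r"^KEY(\d+)$", re.I)


def _infer_format(path, fmt, choices) -> str:
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
        fmt = {"mid": "midi", "midi": "midi"}.get(fmt, fmt)
    if fmt not in choices:
        raise ValueError(f"unsupported format {fmt!r}; expected one of {sorted(choices)}")
    return fmt


def read_motion(path, format: str | None = None, **labels) -> MotionRecording:
    """Read a motion recording from CSV or C3D.

    Extra keyword arguments (performer_id, melody_id, tempo_condition) are
    attached to the returned recording.
    """
    fmt = _infer_format(path, format, {"csv", "c3d"})
    if fmt == "csv":
        return _read_motion_csv(path, **labels)
    return _read_motion_c3d(path, **labels)


def _read_motion_csv(path, **labels) -> MotionRecording:
    df = pd.read_csv(path)
    if "time_ms" not in df.columns:
        raise ValueError(f"{path}: missing time_ms column")
    t = df["time_ms"].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    steps = np.diff(t)
    if np.any(steps <= 0) or np.ptp(steps) > 1e-6 * np.mean(np.abs(steps)) + 1e-9:
        raise ValueError(f"{path}: nonuniform sampling in time_ms")
    fingers: dict[int, np.ndarray] = {}
    keys: dict[int, np.ndarray] = {}
    unknown = []
    for col in df.columns:
        if col == "time_ms":
            continue
        if m := _FINGER_COL.match(col):
            fingers[int(m.group(1))] = df[col].to_numpy(float)
        elif m := _KEY_COL.match(col):
            keys[int(m.group(1))] = df[col].to_numpy(float)
        else:
            unknown.append(col)
    if unknown:
        log.info("%s: ignoring non-vertical/unknown columns: %s", path, unknown)
    missing = [f for f in FINGERS if f not in fingers]
    if missing:
        raise ValueError(f"{path}: missing fingertip marker column(s) "
                         + ", ".join(f"f{f}" for f in missing))
    rate = 1000.0 / float(np.mean(steps))
    return MotionRecording(sample_rate=rate, finger_height=fingers, key_height=keys,
                           t0_ms=float(t[0]), **labels)


def _read_motion_c3d(path, **labels) -> MotionRecording:
    marker_labels, pts, rate = _c3d.read_c3d(path)
    fingers: dict[int, np.ndarray] = {}
    keys: dict[int, np.ndarray] = {}
    unknown = []
    for j, name in enumerate(marker_labels):
        z = pts[:, j, 2].astype(float)  # vertical axis only
        if m := _C3D_FINGER.match(name):
            fingers[int(m.group(1))] = z
        elif m := _C3D_KEY.match(name):
            keys[int(m.group(1))] = z
        else:
            unknown.append(name)
    if unknown:
        log.info("%s: ignoring unknown markers: %s", path, unknown)
    missing = [f for f in FINGERS if f not in fingers]
    if missing:
        raise ValueError(f"{path}: missing fingertip marker(s) "
                         + ", ".join(f"FINGER{f}" for f in missing))
    return MotionRecording(sample_rate=float(rate), finger_height=fingers,
                           key_height=keys, t0_ms=0.0, **labels)


def write_motion(rec: MotionRecording, path, format: str | None = None) -> None:
    """Write a recording as tidy CSV or as a float C3D marker file."""
    fmt = _infer_format(path, format, {"csv", "c3d"})
    if fmt == "csv":
        cols = {"time_ms": rec.times_ms}
        cols.update({name: np.asarray(series, float) for name, series in rec.iter_markers()})
        pd.DataFrame(cols).to_csv(path, index=False)
    else:
        names, series = zip(*rec.iter_markers())
        labels = ["FINGER" + n[1:] if n.startswith("f") else "KEY" + n[4:] for n in names]
        pts = np.zeros((rec.n_samples, len(labels), 3))
        pts[:, :, 2] = np.column_stack(series)
        _c3d.write_c3d(path, labels, pts, rec.sample_rate)


def read_notes(path, format: str | None = None, **labels) -> NoteEventStream:
    """Read a note-event stream from CSV or a Standard MIDI File."""
    fmt = _infer_format(path, format, {"csv", "midi"})
    if fmt == "csv":
        df = pd.read_csv(path)
        required = {"onset_ms", "pitch", "key_velocity", "finger"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: note CSV needs columns {sorted(required)}")
        df = df.sort_values("onset_ms", kind="stable")
        return NoteEventStream(df["onset_ms"].to_numpy(), df["pitch"].to_numpy(),
                               df["key_velocity"].to_numpy(), df["finger"].to_numpy(),
                               **labels)
    events = _smf.read_note_ons(path)
    if not events:
        raise ValueError(f"{path}: no note-on events")
    onsets, pitches, vels, chans = zip(*events)
    fingers = [c + 1 if c < 5 else 0 for c in chans]
    return NoteEventStream(np.array(onsets), np.array(pitches), np.array(vels),
                           np.array(fingers), **labels)


def write_notes(notes: NoteEventStream, path, format: str | None = None) -> None:
    fmt = _infer_format(path, format, {"csv", "midi"})
    if fmt == "csv":
        notes.to_frame().to_csv(path, index=False)
    else:
        _smf.write_note_ons(path, [
            (float(o), int(p), int(round(v)), int(f) - 1 if 1 <= f <= 5 else 0)
            for o, p, v, f in zip(notes.onset_ms, notes.pitch, notes.key_velocity, notes.finger)
        ])
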