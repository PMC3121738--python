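"""Key-bottom detection and event-region segmentation.

A performance is partitioned into *event regions*: the intervals between
successive key bottoms (the minima of the struck keys' marker series, which
land within about one sample of the MIDI onsets).  For a given finger each
region is exactly one of

``attack``    the region immediately preceding that finger's keypress,
``keypress``  the region beginning at that finger's key bottom,
``at_rest``   any other region (another finger is striking).

When the same finger plays two consecutive notes, the shared region counts
as the *attack* of the second note.  Curves are resampled onto a normalized
time axis per region with tau = 0 at the region-terminating key bottom and
tau = 1 at the region start (time runs backward with increasing tau).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import MotionRecording, NoteEventStream
from .smoothing import SmoothedCurve, evaluate

log = logging.getLogger(__name__)

__all__ = [
    "EventRegion", "NormalizedCurves", "LABELS",
    "detect_key_bottoms", "build_regions", "time_normalize", "regions_table",
]

LABELS = ("attack", "keypress", "at_rest")


@dataclass(frozen=True)
class EventRegion:
    """Interval between two successive key bottoms, labeled for one finger.

    ``note_index`` is the index of the note whose key bottom *ends* the
    region (region i spans the key bottoms of notes i and i+1, so it has
    note_index = i + 1).
    """

    start_ms: float
    end_ms: float
    note_index: int
    finger: int
    label: str

    def __post_init__(self):
        if not self.start_ms < self.end_ms:
            raise ValueError("region start must precede end")
        if self.label not in LABELS:
            raise ValueError(f"unknown region label {self.label!r}")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


def detect_key_bottoms(
    recording: MotionRecording,
    notes: NoteEventStream,
    tolerance_samples: float = 2.0,
    min_dip_mm: float = 1.0,
) -> np.ndarray:
    """Locate the key-bottom time of every note event.

    For each note, the struck key's marker series is searched within half
    the local IOI on either side of the MIDI onset; the key bottom is the
    time of the minimum.  A minimum farther than ``tolerance_samples`` from
    the onset is flagged with a warning; a window with no real dip (depth
    below ``min_dip_mm``) or a missing key series raises ``ValueError``
    listing the offending notes.

    Returns key-bottom times (ms, note-event clock), one per note.
    """
    t = recording.times_ms
    dt = recording.dt_ms
    onsets = notes.onset_ms
    n = len(onsets)
    iois = np.diff(onsets)
    half = np.empty(n)
    if n > 1:
        half[0], half[-1] = iois[0] / 2, iois[-1] / 2
        if n > 2:
            half[1:-1] = np.minimum(iois[:-1], iois[1:]) / 2
    else:
        half[:] = 250.0
    kb = np.empty(n)
    problems = []
    for j in range(n):
        pitch = int(notes.pitch[j])
        series = recording.key_height.get(pitch)
        if series is None:
            problems.append(f"note {j} (pitch {pitch}): no key marker series")
            continue
        m = (t >= onsets[j] - half[j]) & (t <= onsets[j] + half[j])
        if not m.any():
            problems.append(f"note {j} (pitch {pitch}): no samples near onset")
            continue
        seg = np.asarray(series, float)[m]
        if np.max(seg) - np.min(seg) < min_dip_mm:
            problems.append(f"note {j} (pitch {pitch}): no key dip near onset "
                            f"(depth {np.max(seg) - np.min(seg):.2f} mm)")
            continue
        kb[j] = t[m][int(np.argmin(seg))]
        if abs(kb[j] - onsets[j]) > tolerance_samples * dt:
            log.warning("note %d: key bottom %.1f ms is %.1f ms from MIDI onset",
                        j, kb[j], kb[j] - onsets[j])
    if problems:
        raise ValueError("key-bottom detection failed: " + "; ".join(problems))
    return kb


def build_regions(key_bottom_times, notes: NoteEventStream) -> list[EventRegion]:
    """Partition [first, last] key bottom into labeled regions per finger.

    N notes yield N-1 regions, each labeled once per finger.  A region is
    ``attack`` for the finger striking the note that ends it, ``keypress``
    for the finger that struck the note starting it (unless that same
    finger also ends it — then attack wins), else ``at_rest``.
    """
    kb = np.asarray(key_bottom_times, float)
    if len(kb) < 2:
        raise ValueError("need at least 2 key-bottom times")
    if np.any(np.diff(kb) <= 0):
        raise ValueError("key-bottom times must be strictly increasing")
    if len(kb) != len(notes):
        raise ValueError("one key-bottom time per note required")
    regions = []
    for i in range(len(kb) - 1):
        start, end = float(kb[i]), float(kb[i + 1])
        starter = int(notes.finger[i])      # keypress that begins this region
        ender = int(notes.finger[i + 1])    # keypress that ends this region
        for f in range(1, 6):
            if f == ender:
                label = "attack"
            elif f == starter:
                label = "keypress"
            else:
                label = "at_rest"
            regions.append(EventRegion(start, end, i + 1, f, label))
    return regions


@dataclass
class NormalizedCurves:
    """Position/velocity/acceleration resampled on normalized region time.

    tau runs 0 -> 1 from the region-terminating key bottom *backward* to
    the region start (index 0 is the key bottom).  Velocity and
    acceleration keep their physical signs and units (mm/s, mm/s^2 with
    respect to real time).
    """

    tau: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    region: EventRegion


def time_normalize(curve: SmoothedCurve, region: EventRegion,
                   n_points: int = 101) -> NormalizedCurves:
    """Resample a smoothed curve over one event region onto tau in [0, 1]."""
    if n_points < 3:
        raise ValueError("n_points must be at least 3")
    lo, hi = curve.domain_ms
    if region.start_ms < lo - 1e-9 or region.end_ms > hi + 1e-9:
        raise ValueError(f"region [{region.start_ms}, {region.end_ms}] ms outside "
                         f"curve domain [{lo}, {hi}] ms")
    if region.duration_ms < 3 * _sample_spacing_ms(curve):
        raise ValueError(f"region of {region.duration_ms:.1f} ms is shorter than 3 samples")
    tau = np.linspace(0.0, 1.0, n_points)
    times = region.end_ms - tau * region.duration_ms
    return NormalizedCurves(
        tau=tau,
        position=evaluate(curve, times, 0),
        velocity=evaluate(curve, times, 1),
        acceleration=evaluate(curve, times, 2),
        region=region,
    )


def _sample_spacing_ms(curve: SmoothedCurve) -> float:
    knots = np.unique(curve.knots_s) * 1000.0
    d = np.diff(knots)
    return float(np.min(d[d > 0])) if d.size else 0.0


def regions_table(regions: list[EventRegion], performance_id: str = "") -> pd.DataFrame:
    """Flatten regions to a tidy (BED-like) table for export."""
    return pd.DataFrame([{
        "performance_id": performance_id, "finger": r.finger,
        "note_index": r.note_index, "label": r.label,
        "start_ms": r.start_ms, "end_ms": r.end_ms,
    } for r in regions])
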