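"""Synthetic piano performances with known kinematic ground truth.

The generator emulates the structure of a motion-captured performance study:
right-hand pianists playing short isochronous melodies at prescribed tempi
while fingertip and key markers are sampled at 120 Hz.  Each keystroke
produces a lift-strike height bump whose amplitude grows with tempo, peaking
about one inter-onset interval (IOI) before the key bottom; timing noise is
multiplicative per IOI with a tempo-dependent coefficient of variation (CV);
"enslaved" fingers (middle and ring) sometimes rest on the key until their
own keypress; neighboring fingers receive a small passive coupling bump.

Finger trajectories are built from keyframes (rest height, bump peak, key
bottom) joined by raised-cosine segments with performer-specific warp
exponents, giving C1 curves whose velocity-acceleration phase-plane shape
differs between performers.  Every sounded tone carries a ground-truth
record (amplitude, peak time, IOI, key velocity, on-key flag) computed from
the final noiseless trajectory on a fine grid, so downstream feature
extraction can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_io import MotionRecording, NoteEventStream

__all__ = [
    "PerformerSignature", "Melody", "MELODIES", "TEMPI_MS",
    "generate_performance", "generate_cohort", "draw_signatures",
    "Performance", "Cohort",
]

#: eighth-note IOIs (ms) of the five prescribed tempo conditions
#: (metronome 60 / 180 / 210 / 240 / 250 quarter-note beats per minute)
TEMPI_MS = (500.0, 167.0, 143.0, 125.0, 120.0)

KEY_REST_MM = 10.0       # key surface height above key bottom at rest
ENSLAVED_FINGERS = (3, 4)


@dataclass(frozen=True)
class Melody:
    """A fingered melody: parallel pitch and finger (1..5) sequences."""

    melody_id: str
    pitches: tuple[int, ...]
    fingers: tuple[int, ...]

    def __post_init__(self):
        if len(self.pitches) != len(self.fingers) or not self.pitches:
            raise ValueError("melody needs equal-length, nonempty pitch/finger lists")

    def __len__(self) -> int:
        return len(self.pitches)


def _melody_from_fingering(melody_id, fingers, hand_position):
    return Melody(melody_id, tuple(hand_position[f] for f in fingers), tuple(fingers))


#: two 13-note isochronous melodies for a stationary right hand
#: (fingers 1..5 over a five-key span; one in C, one in F)
MELODIES = (
    _melody_from_fingering("m1", (1, 3, 2, 3, 1, 5, 4, 5, 1, 5, 1, 4, 3),
                           {1: 60, 2: 62, 3: 64, 4: 65, 5: 67}),
    _melody_from_fingering("m2", (1, 5, 2, 5, 3, 5, 4, 5, 3, 1, 5, 1, 4),
                           {1: 65, 2: 67, 3: 69, 4: 70, 5: 72}),
)

#: relative amplitude by finger: thumb highest, ring lowest
FINGER_AMP_FACTOR = {1: 1.08, 2: 1.00, 3: 0.97, 4: 0.90, 5: 0.95}


@dataclass(frozen=True)
class PerformerSignature:
    """Parameters of one performer's movement and sound signature.

    Units: amplitudes mm; tempo rate in eighth notes per second (1000/IOI_ms);
    times as fractions of the IOI; key velocity in MIDI units (0-127).
    """

    amp_base: float = 18.0             # bump amplitude at rate 0, mm
    amp_tempo_slope: float = 1.2       # mm per (s^-1) of eighth-note rate
    peak_time_frac: float = 1.1        # peak height this fraction of an IOI before key bottom
    shape_skew: float = 0.0            # asymmetry of the lift-strike bump
    vel_scale: float = 1.0             # warp exponent of the strike (descent) segment
    acc_scale: float = 1.0             # warp exponent of the lift (rise) segment
    timing_cv_base: float = 0.015      # CV of IOIs at rate 0
    timing_cv_slope: float = 0.005     # CV increase per (s^-1) of rate
    kv_mean: float = 55.0              # mean key velocity
    kv_sd: float = 6.0                 # key-velocity spread
    rest_prob: float = 0.37            # P(on-key rest) for enslaved fingers 3 and 4
    kv_tempo_slope: float = 1.0        # key-velocity increase per (s^-1) of rate
    kv_amp_coupling: float = 0.6       # key-velocity units per mm of amplitude deviation
    amp_jitter_sd: float = 1.5         # per-stroke amplitude jitter, mm
    peak_jitter_sd: float = 0.06       # per-stroke jitter of peak_time_frac
    shape_jitter_sd: float = 0.10      # per-stroke jitter of the *active* lift-strike
                                       # warp exponents; the post-impact rebound is
                                       # passive and keeps its stereotyped shape

    def __post_init__(self):
        if self.amp_base <= 0:
            raise ValueError("amp_base must be positive")
        if not 0 <= self.rest_prob <= 1:
            raise ValueError("rest_prob must lie in [0, 1]")
        if self.timing_cv_base < 0 or self.timing_cv_slope < 0:
            raise ValueError("timing CVs must be non-negative")
        if not (0 <= self.kv_mean - 3 * self.kv_sd and self.kv_mean + 3 * self.kv_sd <= 127):
            raise ValueError("kv_mean +/- 3 sd must lie within MIDI range 0-127")


def _cos_step(u: np.ndarray, p: float) -> np.ndarray:
    """Monotone C1 step 0->1 on u in [0,1]: raised cosine warped by exponent p."""
    return (0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))) ** p


class _Keyframes:
    """Piecewise raised-cosine curve through (time, height) keyframes.

    Each segment carries its own warp exponent; derivatives vanish at every
    keyframe, so keyframe heights are exact local extrema of the curve.
    Keyframes that would step backward in time (overlapping strokes) evict
    the earlier conflicting ones.
    """

    def __init__(self):
        self.t: list[float] = []
        self.h: list[float] = []
        self.p: list[float] = []  # exponent of the segment *ending* at this keyframe

    def add(self, t, h, p=1.0):
        while self.t and self.t[-1] >= t - 1e-9:
            self.t.pop(); self.h.pop(); self.p.pop()
        self.t.append(float(t)); self.h.append(float(h)); self.p.append(float(p))

    def sample(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(self.t)
        h = np.asarray(self.h)
        out = np.empty_like(times)
        out[times <= t[0]] = h[0]
        out[times >= t[-1]] = h[-1]
        for i in range(len(t) - 1):
            m = (times > t[i]) & (times <= t[i + 1])
            if m.any():
                u = (times[m] - t[i]) / (t[i + 1] - t[i])
                out[m] = h[i] + (h[i + 1] - h[i]) * _cos_step(u, self.p[i + 1])
        return out


def _clip_exponent(x: float) -> float:
    return float(np.clip(x, 0.55, 2.4))


def generate_performance(
    signature: PerformerSignature,
    tempo_ioi_ms: float,
    melody: Melody,
    noise_sd: float = 0.1,
    seed=None,
    sample_rate: float = 120.0,
    coupling: float = 0.10,
    performer_id: str | None = None,
) -> tuple[MotionRecording, NoteEventStream, pd.DataFrame]:
    """Simulate one performance of ``melody`` at the prescribed tempo.

    Parameters
    ----------
    tempo_ioi_ms : prescribed eighth-note IOI in ms (> 3 sample periods).
    noise_sd : Gaussian measurement noise on all markers, mm.
    seed : int or numpy Generator; identical seeds give bit-identical output.
    coupling : passive motion fraction transmitted to adjacent fingers
        (half of it two fingers away).

    Returns
    -------
    (MotionRecording, NoteEventStream, ground_truth DataFrame) with one
    ground-truth row per sounded tone: note_index, finger, pitch, onset_ms,
    key_bottom_ms, ioi_ms, amplitude_mm, anticipation_ms, key_velocity,
    on_key.  Amplitude/anticipation are measured on the noiseless final
    trajectory over the two event regions preceding each keypress (NaN for
    the first two notes, which lack two preceding regions).
    """
    dt = 1000.0 / sample_rate
    if tempo_ioi_ms <= 0:
        raise ValueError("tempo must be positive")
    if tempo_ioi_ms < 3 * dt:
        raise ValueError(f"IOI {tempo_ioi_ms} ms shorter than 3 samples ({3 * dt:.1f} ms)")
    rng = np.random.default_rng(seed)
    sig = signature
    n_notes = len(melody)
    rate = 1000.0 / tempo_ioi_ms  # eighth notes per second

    # --- timing: multiplicative IOI noise at the signature's CV ---
    cv = sig.timing_cv_base + sig.timing_cv_slope * rate
    factors = 1.0 + cv * rng.standard_normal(n_notes - 1)
    iois = tempo_ioi_ms * np.clip(factors, 0.2, None)
    lead_in = 2.0 * tempo_ioi_ms + 400.0
    onsets = lead_in + np.concatenate([[0.0], np.cumsum(iois)])
    # key bottom coincides with the MIDI onset to within one sample:
    # the key marker minimum falls on the nearest sample of the 120 Hz grid
    kb_times = np.round(onsets / dt) * dt

    total_ms = onsets[-1] + 2.0 * tempo_ioi_ms + 400.0
    n_samp = int(np.ceil(total_ms / dt)) + 1
    times = np.arange(n_samp) * dt

    # --- per-stroke kinematic parameters ---
    local_ioi = np.concatenate([[tempo_ioi_ms], iois])  # IOI preceding each note
    amp_nominal = (sig.amp_base + sig.amp_tempo_slope * rate) * np.array(
        [FINGER_AMP_FACTOR[f] for f in melody.fingers])
    amp = np.clip(amp_nominal + sig.amp_jitter_sd * rng.standard_normal(n_notes),
                  KEY_REST_MM + 3.0, None)
    peak_frac = np.clip(sig.peak_time_frac + sig.peak_jitter_sd * rng.standard_normal(n_notes),
                        0.25, 1.7)
    rest_draw = rng.random(n_notes)
    on_key = np.array([
        rest_draw[j] < (sig.rest_prob if f in ENSLAVED_FINGERS else 0.3 * sig.rest_prob)
        for j, f in enumerate(melody.fingers)
    ])

    p_up = _clip_exponent(sig.acc_scale * (1.0 + 0.25 * sig.shape_skew))
    p_down = _clip_exponent(sig.vel_scale * (1.0 - 0.25 * sig.shape_skew))
    rise_frac = float(np.clip(0.75 * (1.0 + 0.4 * sig.shape_skew), 0.35, 1.1))
    # the release is mostly passive key mechanics: only half of the
    # performer's lift idiosyncrasy survives into it
    p_release = _clip_exponent(1.0 + 0.3 * (p_up - 1.0))
    shape_jit = np.exp(sig.shape_jitter_sd * rng.standard_normal((n_notes, 2)))

    # --- finger trajectories from keyframes ---
    finger_clean: dict[int, np.ndarray] = {}
    for f in range(1, 6):
        kf = _Keyframes()
        kf.add(-2e9, KEY_REST_MM)
        prev_kb = -1e9
        for j in np.nonzero(np.asarray(melody.fingers) == f)[0]:
            t_kb = kb_times[j]
            ioi_j = local_ioi[j]
            # time to the next keystroke (any finger): the keypress region
            advance = (kb_times[j + 1] - t_kb) if j + 1 < n_notes else ioi_j
            # a lift may not reach back past this finger's previous key bottom
            gap = t_kb - prev_kb
            if on_key[j]:
                # finger rests on the key, rides it down and back up
                dip = min(0.35 * ioi_j, 90.0, 0.45 * gap)
                kf.add(t_kb - dip, KEY_REST_MM, 1.0)
                kf.add(t_kb, 0.0, p_down)
                kf.add(t_kb + dip, KEY_REST_MM, p_release)
            else:
                # the lift cannot begin until the previous key is released
                # (hold + release occupy ~0.5 of the inter-keystroke gap)
                floor = prev_kb + 0.55 * gap
                t_peak = max(t_kb - peak_frac[j] * ioi_j,
                             floor + 0.25 * (t_kb - floor))
                rise = min(rise_frac * peak_frac[j] * ioi_j,
                           0.8 * (t_peak - floor))
                kf.add(t_peak - rise, KEY_REST_MM, 1.0)
                kf.add(t_peak, amp[j], _clip_exponent(p_up * shape_jit[j, 0]))
                kf.add(t_kb, 0.0, _clip_exponent(p_down * shape_jit[j, 1]))
                # hold the key about half the interval, then a passive,
                # stereotyped release scaled to the available time
                kf.add(t_kb + 0.5 * advance, 0.0, 1.0)
                kf.add(t_kb + 0.88 * advance, KEY_REST_MM, p_release)
            prev_kb = t_kb
        finger_clean[f] = kf.sample(times)

    # --- passive inter-finger coupling (biomechanical enslavement) ---
    # a finger pressed into its key is mechanically grounded and receives
    # almost no transmitted motion; attenuate incoming coupling with depth
    coupled: dict[int, np.ndarray] = {}
    for f in range(1, 6):
        h = finger_clean[f].copy()
        ground = np.clip(finger_clean[f] / KEY_REST_MM, 0.05, 1.0)
        for g in range(1, 6):
            if g == f:
                continue
            c = coupling if abs(g - f) == 1 else (0.5 * coupling if abs(g - f) == 2 else 0.0)
            if c:
                h = h + c * ground * (finger_clean[g] - KEY_REST_MM)
        coupled[f] = h

    # --- key marker trajectories ---
    key_clean: dict[int, np.ndarray] = {}
    for pitch in sorted(set(melody.pitches)):
        kf = _Keyframes()
        kf.add(-1e6, KEY_REST_MM)
        for j in np.nonzero(np.asarray(melody.pitches) == pitch)[0]:
            w = min(0.3 * local_ioi[j], 80.0)  # sharp dip: key bottom is a hard stop
            kf.add(kb_times[j] - w, KEY_REST_MM, 1.0)
            kf.add(kb_times[j], 0.0, 1.0)
            kf.add(kb_times[j] + w, KEY_REST_MM, 1.0)
        key_clean[pitch] = kf.sample(times)

    # --- key velocities ---
    kv = (sig.kv_mean + sig.kv_tempo_slope * rate
          + sig.kv_amp_coupling * (amp - np.mean(amp)) * ~on_key
          + sig.kv_sd * rng.standard_normal(n_notes))
    kv = np.clip(np.round(kv), 1, 127)

    # --- ground truth from the noiseless coupled trajectories ---
    fine = 4
    t_fine = np.arange((n_samp - 1) * fine + 1) * (dt / fine)
    rows = []
    for j, (pitch, f) in enumerate(zip(melody.pitches, melody.fingers)):
        if j >= 2:
            w0, w1 = kb_times[j - 2], kb_times[j]
            vals = np.interp(t_fine, times, coupled[f])
            m = (t_fine >= w0) & (t_fine <= w1)
            seg, tseg = vals[m], t_fine[m]
            i_max = int(np.argmax(seg))
            h_max = float(seg[i_max])
            # amplitude is relative to the finger's height at key bottom
            # (the measured minimum defines the 0-mm reference)
            amp_true = h_max - float(seg[-1])
            antic_true = float(w1 - tseg[i_max])
            truly_on_key = h_max < KEY_REST_MM + 2.0
        else:
            amp_true = antic_true = np.nan
            truly_on_key = bool(on_key[j])
        rows.append({
            "note_index": j, "finger": f, "pitch": pitch,
            "onset_ms": onsets[j], "key_bottom_ms": kb_times[j],
            "ioi_ms": local_ioi[j], "amplitude_mm": amp_true,
            "anticipation_ms": antic_true, "key_velocity": float(kv[j]),
            "on_key": truly_on_key,
        })
    truth = pd.DataFrame(rows)

    # --- measurement noise ---
    finger_noisy = {f: coupled[f] + noise_sd * rng.standard_normal(n_samp) for f in coupled}
    key_noisy = {p: key_clean[p] + noise_sd * rng.standard_normal(n_samp) for p in key_clean}

    rec = MotionRecording(sample_rate=sample_rate, finger_height=finger_noisy,
                          key_height=key_noisy, t0_ms=0.0, performer_id=performer_id,
                          melody_id=melody.melody_id, tempo_condition=tempo_ioi_ms)
    notes = NoteEventStream(onsets, np.array(melody.pitches), kv,
                            np.array(melody.fingers), performer_id=performer_id,
                            melody_id=melody.melody_id, tempo_condition=tempo_ioi_ms)
    return rec, notes, truth


@dataclass
class Performance:
    """One generated performance with its ground truth."""

    performer_id: str
    melody_id: str
    tempo_ms: float
    recording: MotionRecording
    notes: NoteEventStream
    truth: pd.DataFrame


@dataclass
class Cohort:
    """A generated study: performances plus the signatures that produced them."""

    performances: list[Performance]
    signatures: dict[str, PerformerSignature]
    seed: int | None = None

    def truth_table(self) -> pd.DataFrame:
        frames = []
        for p in self.performances:
            df = p.truth.copy()
            df.insert(0, "performer_id", p.performer_id)
            df.insert(1, "melody_id", p.melody_id)
            df.insert(2, "tempo_ms", p.tempo_ms)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def draw_signatures(n_performers: int, separation: float, rng) -> dict[str, PerformerSignature]:
    """Draw performer signatures with between-performer spread ``separation``.

    separation=0 collapses every performer onto the common base signature;
    1.0 is a realistic spread for skilled pianists.
    """
    base = PerformerSignature()
    sigs = {}
    for i in range(n_performers):
        z = rng.standard_normal(9)
        sigs[f"P{i + 1}"] = replace(
            base,
            amp_base=max(12.0, base.amp_base + separation * 3.5 * z[0]),
            amp_tempo_slope=max(0.2, base.amp_tempo_slope + separation * 0.25 * z[1]),
            peak_time_frac=float(np.clip(base.peak_time_frac + separation * 0.14 * z[2], 0.55, 1.6)),
            shape_skew=float(np.clip(separation * 0.7 * z[3], -0.9, 0.9)),
            vel_scale=float(np.clip(np.exp(separation * 0.5 * z[4]), 0.55, 2.4)),
            acc_scale=float(np.clip(np.exp(separation * 0.5 * z[5]), 0.55, 2.4)),
            timing_cv_base=float(np.clip(base.timing_cv_base * np.exp(separation * 0.4 * z[6]),
                                         0.004, 0.06)),
            kv_mean=float(np.clip(base.kv_mean + separation * 9.0 * z[7], 25.0, 100.0)),
            rest_prob=float(np.clip(base.rest_prob + separation * 0.10 * z[8], 0.0, 0.9)),
        )
    return sigs


def generate_cohort(
    n_performers: int = 4,
    separation: float = 1.0,
    tempi=TEMPI_MS,
    melodies=MELODIES,
    noise_sd: float = 0.1,
    seed=None,
    dropout: bool = False,
    coupling: float = 0.10,
) -> Cohort:
    """Generate a full study: n_performers x melodies x tempi performances.

    With ``dropout=True`` the fastest tempi lose performances the way a real
    cohort would (not every pianist manages the fastest prescriptions); off
    by default, so the default design is fully crossed.

    Signature sampling and performance synthesis use disjoint child streams
    of ``seed``, so the same signatures can be re-realized under different
    noise and vice versa.
    """
    if n_performers < 2:
        raise ValueError("need at least 2 performers")
    ss = np.random.SeedSequence(seed)
    sig_stream, perf_stream = ss.spawn(2)
    signatures = draw_signatures(n_performers, separation, np.random.default_rng(sig_stream))
    perf_children = iter(perf_stream.spawn(n_performers * len(melodies) * len(tempi)))
    performances = []
    for pid, sig in signatures.items():
        for melody in melodies:
            for ti, tempo in enumerate(tempi):
                child = next(perf_children)
                if dropout and ti >= 2:
                    # progressively fewer performances at the fast tempi
                    keep_frac = {2: 0.75, 3: 0.5}.get(ti, 0.25)
                    if np.random.default_rng(child.spawn(1)[0]).random() > keep_frac:
                        continue
                rec, notes, truth = generate_performance(
                    sig, tempo, melody, noise_sd=noise_sd,
                    seed=np.random.default_rng(child),
                    coupling=coupling, performer_id=pid)
                performances.append(Performance(pid, melody.melody_id, tempo, rec, notes, truth))
    return Cohort(performances, signatures, seed=seed)
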