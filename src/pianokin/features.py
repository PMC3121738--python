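"""Per-keystroke timing, intensity and kinematic features.

Timing metrics come from the note-event stream: eighth-note inter-onset
intervals (IOIs) with the first and last tones of a performance excluded,
their coefficient of variation CV = sd/mean, and the percentage deviation of
the mean IOI from the prescribed IOI.  Kinematic metrics come from the
smoothed fingertip curves: *movement amplitude* is the maximum finger height
within the two event regions preceding a keypress minus the height at key
bottom (the 0-mm reference), and *anticipation time* is how long before the
key bottom that maximum occurs (also expressed as % of the IOI).  Strokes
whose maximum stays within a threshold of the key-rest height are excluded
as "finger resting on key".

``summarize_effects`` is a thin reporting layer over standard statistical
routines (one-way ANOVAs, Kruskal-Wallis per performer, Tukey HSD,
correlations, and a performer-prediction regression from the sounded
features alone).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import NoteEventStream
from .segmentation import EventRegion
from .smoothing import SmoothedCurve, evaluate

__all__ = [
    "StrokeFeatures", "TimingSummary",
    "compute_iois", "timing_summary", "prescribed_ioi",
    "movement_amplitude_and_anticipation", "residualize", "summarize_effects",
    "KEY_REST_MM",
]

KEY_REST_MM = 10.0  # key-surface rest height above key bottom, mm


@dataclass
class StrokeFeatures:
    """Features of a single keystroke."""

    note_index: int
    finger: int
    ioi_ms: float
    key_velocity: float
    amplitude_mm: float | None
    anticipation_ms: float | None
    anticipation_pct_ioi: float | None
    excluded_on_key: bool
    tempo_condition: float | None = None
    performer_id: str | None = None


@dataclass
class TimingSummary:
    """Performance-level timing and intensity summary."""

    mean_ioi_ms: float
    cv: float
    tempo_deviation_pct: float
    mean_key_velocity: float


def compute_iois(notes: NoteEventStream) -> np.ndarray:
    """IOIs among the interior tones (first and last tones excluded).

    For N onsets this returns the N-3 intervals between consecutive tones
    2..N-1 (1-based), i.e. the pairwise differences of the interior onsets.
    """
    if len(notes) < 4:
        raise ValueError("need at least 4 events for interior IOIs")
    return np.diff(notes.onset_ms[1:-1])


def timing_summary(iois, expected_ioi_ms: float,
                   key_velocities=None) -> TimingSummary:
    """CV = sd/mean of the IOIs; deviation = |mean - expected|/expected * 100."""
    iois = np.asarray(iois, float)
    if iois.size == 0:
        raise ValueError("empty IOI series")
    if expected_ioi_ms <= 0:
        raise ValueError("expected IOI must be positive")
    mean = float(np.mean(iois))
    if mean == 0:
        raise ValueError("zero mean IOI")
    sd = float(np.std(iois, ddof=1)) if iois.size > 1 else 0.0
    kv = float(np.mean(key_velocities)) if key_velocities is not None else float("nan")
    return TimingSummary(
        mean_ioi_ms=mean,
        cv=sd / mean,
        tempo_deviation_pct=abs(mean - expected_ioi_ms) / expected_ioi_ms * 100.0,
        mean_key_velocity=kv,
    )


def prescribed_ioi(metronome_bpm: float) -> int:
    """Eighth-note IOI (ms, rounded) prescribed by a quarter-note metronome.

    60 bpm -> 500 ms, 180 -> 167, 210 -> 143, 240 -> 125, 250 -> 120.
    """
    if metronome_bpm <= 0:
        raise ValueError("metronome rate must be positive")
    return round(60000.0 / metronome_bpm / 2.0)


def movement_amplitude_and_anticipation(
    curve: SmoothedCurve,
    regions: tuple[EventRegion, EventRegion],
    key_bottom_ms: float,
    ioi_ms: float,
    rest_height_threshold: float = 2.0,
    key_rest_mm: float = KEY_REST_MM,
    eval_step_ms: float = 1.0,
):
    """Movement amplitude and anticipation over the two regions before a keypress.

    The window is the union of the two contiguous event regions ending at
    ``key_bottom_ms``.  Amplitude is the height maximum in the window minus
    the height at the key bottom; anticipation is the time from that maximum
    to the key bottom (ties in the maximum break toward the earlier time,
    i.e. the larger anticipation).  If the maximum stays below
    ``key_rest_mm + rest_height_threshold`` the finger never left the key
    and the stroke is excluded.

    Returns ``(amplitude_mm, anticipation_ms, anticipation_pct_ioi)`` or
    ``None`` when the stroke is excluded on-key.
    """
    r_early, r_late = sorted(regions, key=lambda r: r.start_ms)
    if abs(r_early.end_ms - r_late.start_ms) > 1e-6:
        raise ValueError("the two event regions must be contiguous")
    if abs(r_late.end_ms - key_bottom_ms) > 1e-6:
        raise ValueError("regions must end at the keypress key bottom")
    lo, hi = curve.domain_ms
    if r_early.start_ms < lo - 1e-9 or key_bottom_ms > hi + 1e-9:
        raise ValueError("analysis window outside smoothed-curve domain")
    n = max(3, int(np.ceil((key_bottom_ms - r_early.start_ms) / eval_step_ms)) + 1)
    times = np.linspace(r_early.start_ms, key_bottom_ms, n)
    heights = evaluate(curve, times, 0)
    i_max = int(np.argmax(heights))  # first max -> earliest time -> larger anticipation
    h_max = float(heights[i_max])
    if h_max < key_rest_mm + rest_height_threshold:
        return None
    h_kb = float(evaluate(curve, np.array([key_bottom_ms]), 0)[0])
    amplitude = h_max - h_kb
    anticipation = float(key_bottom_ms - times[i_max])
    return amplitude, anticipation, anticipation / ioi_ms * 100.0


def residualize(amplitudes, key_velocities) -> np.ndarray:
    """Partial key velocity out of movement amplitudes.

    Ordinary least-squares regression of amplitude on key velocity; returns
    the residuals (mean zero, uncorrelated with key velocity).  If key
    velocity is constant the amplitudes are merely centered, with a warning.
    """
    a = np.asarray(amplitudes, float)
    kv = np.asarray(key_velocities, float)
    if a.shape != kv.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need equal-length 1-d arrays of at least 3 strokes")
    if np.ptp(kv) == 0:
        warnings.warn("key velocity is constant; returning centered amplitudes")
        return a - a.mean()
    slope, intercept = np.polyfit(kv, a, 1)
    return a - (intercept + slope * kv)


def summarize_effects(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Standard statistical summary of a stroke-feature table.

    Expects columns performer_id, tempo_ms, finger, and any of
    amplitude_mm, anticipation_ms, cv, key_velocity, tempo_deviation_pct.
    Emits a tidy table (analysis, response, term, statistic, value, p).
    Delegates to scipy/statsmodels; this package adds no inference of its
    own here.
    """
    import statsmodels.api as sm_api
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    required = {"performer_id", "tempo_ms"}
    if not required <= set(table.columns):
        raise ValueError(f"feature table needs columns {sorted(required)}")
    if table["tempo_ms"].nunique() < 2 or table["performer_id"].nunique() < 2:
        raise ValueError("need at least 2 tempo conditions and 2 performers")
    rows = []

    def add(analysis, response, term, statistic, value, p=np.nan):
        rows.append({"analysis": analysis, "response": response, "term": term,
                     "statistic": statistic, "value": float(value), "p": float(p)})

    responses = [c for c in ("amplitude_mm", "anticipation_ms", "anticipation_pct_ioi",
                             "cv", "key_velocity", "tempo_deviation_pct")
                 if c in table.columns]
    for resp in responses:
        df = table.dropna(subset=[resp])
        # one-way ANOVA over tempo conditions (performance as random unit)
        groups = [g[resp].to_numpy() for _, g in df.groupby("tempo_ms") if len(g) > 1]
        if len(groups) >= 2:
            F, p = stats.f_oneway(*groups)
            add("anova", resp, "tempo", "F", F, p)
        if "finger" in df.columns and df["finger"].nunique() >= 2:
            groups = [g[resp].to_numpy() for _, g in df.groupby("finger") if len(g) > 1]
            if len(groups) >= 2:
                F, p = stats.f_oneway(*groups)
                add("anova", resp, "finger", "F", F, p)
        # per-performer nonparametric check of the tempo effect
        for pid, g in df.groupby("performer_id"):
            gg = [x[resp].to_numpy() for _, x in g.groupby("tempo_ms") if len(x) > 1]
            if len(gg) >= 2:
                H, p = stats.kruskal(*gg)
                add("kruskal", resp, f"tempo|performer={pid}", "H", H, p)
        # Tukey HSD over tempo conditions
        if df["tempo_ms"].nunique() >= 2 and len(df) > df["tempo_ms"].nunique():
            tk = pairwise_tukeyhsd(df[resp].to_numpy(), df["tempo_ms"].to_numpy(), alpha=alpha)
            from itertools import combinations
            for (g1, g2), diff, p_adj in zip(combinations(tk.groupsunique, 2),
                                             tk.meandiffs, tk.pvalues):
                add("tukey_hsd", resp, f"tempo {g1} vs {g2}", "meandiff", diff, p_adj)

    if {"amplitude_mm", "key_velocity"} <= set(table.columns):
        df = table.dropna(subset=["amplitude_mm", "key_velocity"])
        if len(df) >= 3:
            r, p = stats.pearsonr(df["amplitude_mm"], df["key_velocity"])
            add("correlation", "amplitude_mm", "key_velocity", "r", r, p)
    if {"anticipation_ms", "key_velocity"} <= set(table.columns):
        df = table.dropna(subset=["anticipation_ms", "key_velocity"])
        if len(df) >= 3:
            r, p = stats.pearsonr(df["anticipation_ms"], df["key_velocity"])
            add("correlation", "anticipation_ms", "key_velocity", "r", r, p)

    # can the sounded outcome alone predict the performer?
    if {"key_velocity", "tempo_deviation_pct"} <= set(table.columns):
        df = table.dropna(subset=["key_velocity", "tempo_deviation_pct"]).copy()
        if len(df) >= 8:
            df["pianist_number"] = pd.factorize(df["performer_id"])[0] + 1
            X = sm_api.add_constant(df[["key_velocity", "tempo_deviation_pct"]])
            fit = sm_api.OLS(df["pianist_number"], X).fit()
            add("regression", "pianist_number", "key_velocity+tempo_deviation",
                "r_squared", fit.rsquared, fit.f_pvalue)
            for term in ("key_velocity", "tempo_deviation_pct"):
                add("regression", "pianist_number", term, "beta",
                    fit.params[term], fit.pvalues[term])
    return pd.DataFrame(rows)
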