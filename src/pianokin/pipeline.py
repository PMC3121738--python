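"""End-to-end orchestration: generate -> smooth -> segment -> features ->
similarity -> functional ANOVA -> classify -> report.

Stages are plain functions over in-memory objects so that scripts, tests
and the CLI can drive any slice of the chain; ``run_pipeline`` wires them
together from a ``RunConfig``, writes every stage's tables into the output
directory, and stamps each artifact with the config hash and package
version.  Reruns with the same config and seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, classify, fanova, synth
from .data_io import MotionRecording, NoteEventStream
from .features import (KEY_REST_MM, compute_iois, movement_amplitude_and_anticipation,
                       summarize_effects, timing_summary)
from .segmentation import build_regions, detect_key_bottoms, regions_table, time_normalize
from .similarity import PhaseTrajectory, consistency_by_region
from .smoothing import fit_smooth_multi, select_lambda_gcv

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "analyze_performances", "AnalyzedPerformance"]


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run.

    Unknown keys in a config file are rejected; the resolved config is
    serialized into the output directory next to the artifacts it produced.
    """

    # generator (used unless input paths are given)
    n_performers: int = 4
    separation: float = 1.0
    tempi: tuple = tuple(synth.TEMPI_MS)
    noise_sd: float = 0.1
    dropout: bool = False
    # or: explicit input files [(motion_path, notes_path), ...]
    inputs: list = field(default_factory=list)
    # smoothing
    lambda_grid: tuple = tuple(np.logspace(-13.0, -5.0, 9))
    lambda_fixed: float | None = None
    # segmentation / features
    n_points: int = 101
    rest_height_threshold: float = 2.0
    # fanova
    alphas: tuple = (0.05, 0.001)
    mask_alpha: float = 0.05
    # classifier
    folds: int = 10
    repeats: int = 5
    bags: int = 15
    hidden: tuple = (10, 20)
    pca_threshold: float = 0.95
    max_epochs: int = 300
    region_labels: tuple = ("attack", "keypress", "at_rest")
    # bookkeeping
    seed: int = 0
    out_dir: str = "pianokin_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=lambda o: list(o) if hasattr(o, "__iter__") else o))

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where results land does not change what they are
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class AnalyzedPerformance:
    """One performance after smoothing, segmentation and feature extraction."""

    performance_id: str
    performer_id: str
    melody_id: str
    tempo_ms: float
    lam: float
    key_bottoms: np.ndarray
    regions: list
    stroke_features: pd.DataFrame
    timing: dict
    trajectories: list[PhaseTrajectory]


def _smooth_performance(rec: MotionRecording, cfg: RunConfig):
    Y = np.column_stack([rec.finger_height[f] for f in sorted(rec.finger_height)])
    if cfg.lambda_fixed is not None:
        lam = float(cfg.lambda_fixed)
    else:
        lam = select_lambda_gcv((rec.times_ms, Y), candidates=cfg.lambda_grid)
    curves = dict(zip(sorted(rec.finger_height),
                      fit_smooth_multi(rec.times_ms, Y, lam=lam)))
    return curves, lam


def _analyze_one(pid: str, rec: MotionRecording, notes: NoteEventStream,
                 cfg: RunConfig, rng: np.random.Generator) -> AnalyzedPerformance:
    curves, lam = _smooth_performance(rec, cfg)
    kb = detect_key_bottoms(rec, notes)
    regions = build_regions(kb, notes)
    by_finger_idx = {(r.finger, r.note_index): r for r in regions}
    expected = float(rec.tempo_condition or np.median(np.diff(notes.onset_ms)))

    # --- per-keystroke features (interior notes only) ---
    n = len(notes)
    rows = []
    for j in range(2, n - 1):
        f = int(notes.finger[j])
        ioi_j = float(notes.onset_ms[j] - notes.onset_ms[j - 1])
        pair = (by_finger_idx[(f, j - 1)], by_finger_idx[(f, j)])
        res = movement_amplitude_and_anticipation(
            curves[f], pair, kb[j], ioi_j,
            rest_height_threshold=cfg.rest_height_threshold)
        rows.append({
            "performance_id": pid, "performer_id": rec.performer_id,
            "melody_id": rec.melody_id, "tempo_ms": expected,
            "note_index": j, "finger": f, "ioi_ms": ioi_j,
            "key_velocity": float(notes.key_velocity[j]),
            "amplitude_mm": res[0] if res else np.nan,
            "anticipation_ms": res[1] if res else np.nan,
            "anticipation_pct_ioi": res[2] if res else np.nan,
            "excluded_on_key": res is None,
        })
    strokes = pd.DataFrame(rows)

    iois = compute_iois(notes)
    ts = timing_summary(iois, expected, key_velocities=notes.key_velocity[1:-1])
    timing = {
        "performance_id": pid, "performer_id": rec.performer_id,
        "melody_id": rec.melody_id, "tempo_ms": expected,
        "mean_ioi_ms": ts.mean_ioi_ms, "cv": ts.cv,
        "tempo_deviation_pct": ts.tempo_deviation_pct,
        "mean_key_velocity": ts.mean_key_velocity, "lambda": lam,
    }

    # --- phase trajectories: striking finger's attack + keypress, and one
    # resting finger per attack window (balanced region sets) ---
    trajectories = []
    for j in range(2, n - 1):
        f = int(notes.finger[j])
        attack = by_finger_idx[(f, j)]
        keypress = by_finger_idx.get((f, j + 1))
        picks = [attack] if keypress is None or keypress.label != "keypress" \
            else [attack, keypress]
        resting = [g for g in range(1, 6)
                   if by_finger_idx[(g, j)].label == "at_rest"]
        if resting:
            picks.append(by_finger_idx[(int(rng.choice(resting)), j)])
        for r in picks:
            nc = time_normalize(curves[r.finger], r, n_points=cfg.n_points)
            trajectories.append(PhaseTrajectory.from_normalized(
                nc, performer_id=rec.performer_id,
                trajectory_id=f"{pid}:n{r.note_index}:f{r.finger}:{r.label}"))

    return AnalyzedPerformance(pid, rec.performer_id, rec.melody_id,
                               expected, lam, kb, regions, strokes, timing, trajectories)


def analyze_performances(performances, cfg: RunConfig,
                         seed=None) -> list[AnalyzedPerformance]:
    """Smooth, segment and featurize a list of synth.Performance items."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    out = []
    for p in performances:
        pid = f"{p.performer_id}-{p.melody_id}-{int(p.tempo_ms)}"
        out.append(_analyze_one(pid, p.recording, p.notes, cfg, rng))
    return out


def _stamp(df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = cfg.config_hash()
    df["pianokin_version"] = __version__
    return df


def run_pipeline(cfg: RunConfig, performances=None) -> dict:
    """Run every stage and write tables/reports under ``cfg.out_dir``.

    Returns the report dictionary (also written as report.json).  If
    ``performances`` is None, a synthetic cohort is generated from the
    config; otherwise the given list of synth.Performance objects is used.
    """
    t_start = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_times = {}

    def tick(name):
        stage_times[name] = round(time.time() - t_start - sum(stage_times.values()), 2)
        log.info("stage %-12s done (%.1fs)", name, stage_times[name])

    ss = np.random.SeedSequence(cfg.seed)
    s_gen, s_analyze, s_classify = ss.spawn(3)

    if performances is None:
        cohort = synth.generate_cohort(
            n_performers=cfg.n_performers, separation=cfg.separation,
            tempi=cfg.tempi, noise_sd=cfg.noise_sd, dropout=cfg.dropout,
            seed=int(s_gen.generate_state(1)[0] % (2**31)))
        performances = cohort.performances
    tick("generate")

    analyzed = analyze_performances(performances, cfg, seed=s_analyze)
    strokes = pd.concat([a.stroke_features for a in analyzed], ignore_index=True)
    timing = pd.DataFrame([a.timing for a in analyzed])
    regions = pd.concat([regions_table(a.regions, a.performance_id) for a in analyzed],
                        ignore_index=True)
    _stamp(strokes, cfg).to_csv(out / "stroke_features.csv", index=False)
    _stamp(timing, cfg).to_csv(out / "timing_summary.csv", index=False)
    _stamp(regions, cfg).to_csv(out / "regions.csv", index=False)
    tick("analyze")

    merged = strokes.merge(timing[["performance_id", "cv", "tempo_deviation_pct"]],
                           on="performance_id")
    effects = summarize_effects(merged)
    _stamp(effects, cfg).to_csv(out / "effects.csv", index=False)
    tick("effects")

    trajectories = [t for a in analyzed for t in a.trajectories]
    consistency = consistency_by_region(trajectories)
    _stamp(consistency.reset_index(), cfg).to_csv(out / "consistency.csv", index=False)
    tick("similarity")

    fan_results, fan_rows = {}, []
    for label in cfg.region_labels:
        sub = [t for t in trajectories if t.label == label]
        labels = [t.performer_id for t in sub]
        res = fanova.pointwise_fanova(sub, labels, alphas=cfg.alphas)
        fan_results[label] = res
        for ch, chres in res.channels.items():
            for a in cfg.alphas:
                fan_rows.append({"region": label, "channel": ch, "alpha": a,
                                 "significant_fraction": chres.significant_fraction[a],
                                 "df_between": res.df_between, "df_within": res.df_within})
    fan_table = pd.DataFrame(fan_rows)
    _stamp(fan_table, cfg).to_csv(out / "fanova.csv", index=False)
    tick("fanova")

    class_seeds = s_classify.generate_state(len(cfg.region_labels))
    class_report = {}
    for i, label in enumerate(cfg.region_labels):
        sub = [t for t in trajectories if t.label == label]
        mask = fan_results[label].combined_mask(cfg.mask_alpha)
        X = classify.build_feature_vectors(sub, mask)
        rep = classify.bagged_crossvalidate(
            X, np.array([t.performer_id for t in sub]),
            folds=cfg.folds, repeats=cfg.repeats, bags=cfg.bags,
            hidden=cfg.hidden, seed=int(class_seeds[i] % (2**31)),
            pca_threshold=cfg.pca_threshold, max_epochs=cfg.max_epochs)
        rep.confusion_pct.to_csv(out / f"confusion_{label}.csv")
        class_report[label] = {
            "accuracy": rep.accuracy,
            "accuracy_per_repeat": rep.accuracy_per_repeat,
            "per_class_accuracy": rep.per_class_accuracy,
            "chance": rep.chance,
            "n_trajectories": len(sub),
        }
    tick("classify")

    report = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "pianokin_version": __version__,
        "n_performances": len(analyzed),
        "timing_by_tempo": timing.groupby("tempo_ms")[["cv", "tempo_deviation_pct",
                                                       "mean_key_velocity"]]
                                 .mean().round(6).to_dict("index"),
        "amplitude_by_tempo": strokes.groupby("tempo_ms")["amplitude_mm"]
                                     .mean().round(3).to_dict(),
        "anticipation_pct_by_tempo": strokes.groupby("tempo_ms")["anticipation_pct_ioi"]
                                            .mean().round(2).to_dict(),
        "on_key_fraction": float(strokes["excluded_on_key"].mean()),
        "consistency": consistency["mean_similarity"].round(4).to_dict(),
        "consistency_pairs": consistency["n_pairs"].to_dict(),
        "fanova_significant_fraction": {
            label: {ch: res.channels[ch].significant_fraction[cfg.mask_alpha]
                    for ch in res.channels}
            for label, res in fan_results.items()},
        "classification": class_report,
        "stage_seconds": stage_times,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    return report
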