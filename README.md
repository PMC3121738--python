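# pianokin

Finger kinematics of piano performance: from motion-capture marker streams
and MIDI note events to tempo effects on movement, phase-plane consistency,
and performer identification from single keystrokes.

## The problem

When pianists play the same melody faster, their sound changes — tones get
louder and timing gets relatively more variable — but the movements that
produce those changes are rarely measured. Given synchronized recordings of
fingertip heights (120 Hz motion capture) and sounded notes (MIDI onsets and
key velocities), this package answers two questions:

1. **How does tempo shape the strokes?** Per keystroke it measures the
   *movement amplitude* (peak fingertip height over the two event regions
   before the keypress, relative to the key-bottom height, in mm) and the
   *anticipation time* (how long before key bottom that peak occurs, in ms
   and as % of the inter-onset interval, IOI), alongside IOI variability
   (CV = sd/mean) and tempo deviation.
2. **Are strokes individual?** Each stroke's velocity–acceleration phase
   trajectory, time-normalized within its event region, is compared across
   strokes by full Procrustes superposition (similarity 1 − d ∈ [0, 1]) and
   fed — after pointwise functional ANOVA selects the performer-discriminating
   portions and PCA compresses them to ≥ 95 % variance — to a two-hidden-layer
   (10 + 20 tanh units) network trained with resilient backpropagation,
   evaluated by five repeats of stratified 10-fold cross-validation with
   bagging.

The smoothing that makes velocity and acceleration evaluable is an order-6
penalized B-spline fit with a roughness penalty on the second derivative,
with the penalty weight λ chosen by generalized cross-validation (GCV).

Because no suitable public data set pairs per-finger mocap with MIDI at
multiple tempi, the package includes a first-class synthetic performance
generator (4 performers × 2 thirteen-note melodies × 5 tempi, eighth-note
IOI 500/167/143/125/120 ms) with per-keystroke ground truth, used to verify
every stage end to end.

## Worked example

```python
from pianokin import synth, pipeline

cfg = pipeline.RunConfig(seed=1, out_dir="run1")
report = pipeline.run_pipeline(cfg)          # ~1 minute on one CPU
print(report["amplitude_by_tempo"])
print(report["consistency"])
print({k: v["accuracy"] for k, v in report["classification"].items()})
```

prints (seed 1):

```
{120.0: 28.215, 125.0: 27.232, 143.0: 27.175, 167.0: 25.427, 500.0: 20.326}
{'at_rest': 0.1089, 'attack': 0.422, 'keypress': 0.6113}
{'attack': 0.723, 'keypress': 0.669, 'at_rest': 0.365}
```

Reading the numbers: mean stroke amplitude grows from 20.3 mm at the slow
tempo (500 ms IOI) to 28.2 mm at the fastest (120 ms) — fingers lift
*higher*, not lower, when playing faster. Phase-trajectory shape is most
reproducible during keypresses (Procrustes 0.61), intermediate during
attacks (0.42) and weakest at rest (0.11), while performer identification
from single strokes is best for attacks (72 % vs. 25 % chance), close
behind for keypresses and weakest — but still above chance — for at-rest
motion: individuality lives in the goal-directed approach to the key.

The same chain is available as numbered scripts (`analysis/01…05`, writing
tables under `results/`) and as a CLI:

```bash
pianokin all --seed 1 --out run1
pianokin generate --seed 7 --out cohort/     # CSV + MIDI + ground truth
```

## Layout

| path | contents |
| --- | --- |
| `src/pianokin/data_io.py` | MotionRecording / NoteEventStream; CSV, C3D, Standard MIDI File readers and writers |
| `src/pianokin/synth.py` | synthetic performance generator with ground truth |
| `src/pianokin/smoothing.py` | penalized B-spline smoothing, GCV, derivatives |
| `src/pianokin/segmentation.py` | key-bottom detection, event regions, time normalization |
| `src/pianokin/features.py` | IOI/CV/amplitude/anticipation, residualization, effect summaries |
| `src/pianokin/similarity.py` | Procrustes phase-plane similarity |
| `src/pianokin/fanova.py` | pointwise functional ANOVA |
| `src/pianokin/classify.py` | PCA + Rprop network + bagged cross-validation |
| `src/pianokin/pipeline.py`, `cli.py` | orchestration and `pianokin` command |
| `analysis/` | numbered driver scripts writing `results/` tables |
| `docs/methods.md` | models, parameters, numerical choices, limitations |
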