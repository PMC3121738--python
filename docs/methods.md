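# Methods

This note documents the models, parameters and numerical choices behind
`pianokin`, and what the synthetic cohort does and does not establish.

## Data model

A performance pairs a `MotionRecording` — vertical fingertip heights for
fingers 1–5 plus one marker per piano key, uniformly sampled (default
120 Hz, 8.33 ms resolution), heights in mm — with a `NoteEventStream` of
MIDI onsets (ms), key velocities (0–127) and finger assignments. Only the
vertical axis is modeled; horizontal coordinates in input files are ignored
with a logged notice. The note-event clock is authoritative; the recording
carries a `t0` offset onto it. Key bottom (the key marker's minimum, within
about one sample of the MIDI onset) defines time 0 per keystroke; the
finger's height at key bottom defines the 0-mm reference for amplitude.

## Spline smoothing

Heights are smoothed per performance with order-6 B-splines, knots at every
sample, and a penalty on the integrated squared second derivative, so that
acceleration — the highest derivative used — is what the penalty smooths.
Fitting uses sparse banded normal equations; GCV(λ) = n·RSS/(n − tr H)²,
with the trace computed exactly from the factorized system. One λ is chosen
per performance, on the stacked five-finger position data, and shared across
fingers so derivative magnitudes stay comparable; ties break toward the
larger λ.

Units matter for λ: fitting is done with time in seconds (heights in mm), so
penalty Gram entries at 120 Hz are O(10⁶) and λ in the 10⁻¹³–10⁻¹² range —
the default grid of `select_lambda_gcv` — remains numerically meaningful.
That range, however, nearly interpolates data carrying 0.1 mm white
measurement noise, which is the noise model of the synthetic cohort; the
*pipeline* therefore searches a wider grid (10⁻¹³–10⁻⁵, 9 log-spaced
candidates) and lets GCV decide. On synthetic performances GCV typically
selects 10⁻⁷–10⁻⁶, which recovers stroke amplitude to ≲ 0.1 mm and peak
timing to ≲ 1 sample (see the recovery tests). With λ = 0 the knots-at-
every-sample design is rank-deficient; the minimum-norm least-squares
solution is used there, for oracle comparisons only.

## Event regions and normalization

Key bottoms are argmin of the struck key's marker within ± half the local
IOI of each onset; a window whose depth is < 1 mm has no dip and is an
error, and a minimum more than 2 samples from the onset is flagged. N notes
give N − 1 regions tiling [first, last] key bottom. Per finger a region is
`attack` (it ends at that finger's keypress), `keypress` (it starts there),
else `at_rest`; if one finger plays consecutive notes the shared region
counts as the attack of the second note — attack precedence. Curves are
resampled on τ ∈ [0, 1] with 101 points (odd, so the midpoint is on the
grid), τ = 0 at the region-ending key bottom and τ increasing backward in
time; velocity (mm/s) and acceleration (mm/s²) keep their physical signs.

## Stroke features

IOIs exclude the first and last tones (no comparable beginning/ending); CV
is sd/mean, tempo deviation |mean − prescribed|/prescribed·100. Amplitude is
the height maximum over the two regions preceding a keypress minus the
height at key bottom, evaluated on a 1-ms grid; anticipation is key bottom
minus the argmax time (ties break to the earlier time, i.e. the larger
anticipation), also expressed as % of the local IOI. A stroke whose maximum
stays below the key-rest height (10 mm) plus a 2-mm threshold never left
the key and is excluded as on-key; both numbers are configurable.
Residualization regresses amplitude on key velocity by OLS and keeps the
residuals (mean 0, orthogonal to key velocity); constant key velocity falls
back to centering with a warning. The effect summary delegates entirely to
scipy/statsmodels (one-way ANOVAs with performance as the random unit,
per-performer Kruskal–Wallis, Tukey HSD, Pearson correlations, and an OLS
regression predicting pianist number from key velocity + tempo deviation).

## Procrustes similarity

A phase trajectory is the ordered (velocity, acceleration) point set on the
τ grid. Before superposition each axis is standardized to unit variance —
the axes carry different units, and without this the acceleration axis
(numerically larger) would dominate. Similarity is 1 − d with d the
residual of full Procrustes superposition (translation + rotation + uniform
scale) between unit-norm centered configurations; rotations only by
default, since reversing the direction of travel around a phase loop is a
physically different movement (a flag allows reflections). For 2-column
configurations the rotation-constrained optimum has the closed form
s = √(‖M‖²_F + 2 det M) with M the cross-covariance, which the vectorized
all-pairs path uses; a dense grid search over rotations verifies it.
Consistency is the mean over all unordered pairs within a group — same
performer, same finger, same region label — pooled per label.

## Functional ANOVA

At each τ grid point a one-way F statistic compares performers, separately
for the velocity and acceleration channels; degrees of freedom come from
the realized design (e.g. F(3, 41) and its 5 % threshold 2.83 for 4
performers and 45 curves). The α = .05 mask uses unadjusted pointwise
p-values; a second, conservative mask at α = .001 is also reported, since
pointwise tests at 101 correlated grid points overstate joint significance.
The classifier's feature mask is the union of the two channels' α = .05
masks.

## Classifier

Masked velocity and acceleration samples are concatenated per trajectory
and column-standardized. PCA retains the smallest number of components
reaching 95 % cumulative variance and is fitted inside each training fold
(fitting on all data would leak test information into the representation; a
flag reproduces that variant). The network is input → 10 tanh → 20 tanh →
softmax, trained full-batch with classic Rprop (η⁺ = 1.2, η⁻ = 0.5,
Δ₀ = 0.1, Δ ∈ [10⁻⁶, 50], weight backtracking on sign flips), early-stopped
on a 15 % validation split (patience 30, max 300 epochs). Evaluation is
5 × stratified 10-fold cross-validation; within each fold 15 networks are
trained on bootstrap resamples of the training part (resamples are redrawn
until every class is present) and predictions are majority votes. Reported
accuracy is the mean over the five repeats; the confusion matrix
accumulates all repeats. Fold shuffling, bootstrap draws and weight
initialization derive from one seed through separate spawned streams, so
reports are bit-reproducible.

## Synthetic cohort

The generator emulates the study conditions: 4 performers × 2 thirteen-note
fingered melodies over a stationary five-key hand position × 5 prescribed
tempi (eighth-note IOI 500/167/143/125/120 ms, i.e. metronome 60–250
quarter-note bpm), 120 Hz sampling, 0.1 mm Gaussian marker noise.

Each keystroke is a keyframe curve — rest (10 mm, the key-surface height)
→ lift peak → key bottom (0 mm) → hold ≈ half the inter-keystroke gap →
release back to rest — with raised-cosine segments warped by per-performer
exponents, giving C¹ trajectories whose keyframe heights are exact extrema
(hence exact nominal amplitudes). A lift cannot begin before the same
finger's previous key is released, so a finger reused after one
intervening note produces a compressed, later-peaking lift — a second
natural attack-shape class. Defaults encode the qualitative regularities
the analysis is meant to detect, chosen once as plausible magnitudes for
skilled pianists: amplitude 18 mm + 1.2 mm per s⁻¹ of eighth-note rate
(≈ 20 mm slow → 28 mm fastest), thumb strokes 8 % above and ring 10 % below
the hand mean; peak 1.1 IOI before key bottom; IOI CV 0.015 + 0.005 per s⁻¹
(≈ 0.02 slow → 0.05 fastest); key velocity mean 55 ± 6 MIDI units, rising
1 unit per s⁻¹ and coupled 0.6 units/mm to amplitude deviations; enslaved
fingers (middle, ring) rest on the key with probability 0.37 per stroke
(0.3× that for the others), reproducing ≈ 20 % on-key strokes concentrated
in fingers 3–4. Neighboring fingers receive 10 % (adjacent) / 5 % (next
but one) of a moving finger's displacement, attenuated when the receiving
finger is pressed into its key (it is then mechanically grounded). The
active lift–strike carries per-stroke motor jitter (amplitude sd 1.5 mm,
peak-time sd 0.06 IOI, shape-exponent sd 0.10) while the post-impact
release keeps a stereotyped, mostly-shared shape (30 % of the performer's
lift idiosyncrasy); this active/passive asymmetry is what yields the
observed region structure — keypress shapes most consistent, attacks most
performer-discriminative.

Ground truth per tone (amplitude, anticipation, on-key flag) is measured
from the final noiseless trajectory on a 4× refined grid, not copied from
the nominal parameters, because inter-finger coupling and lift compression
shift the realized peak; downstream recovery error then isolates
measurement noise and smoothing. Cohort signatures are drawn around the
base signature with a `separation` multiplier; separation 0 collapses all
performers (classification must fall to 25 % chance) and large separation
makes single-stroke identification > 80 % accurate. Signature drawing and
performance noise use disjoint spawned seed streams. An optional dropout
flag thins the fast-tempo cells the way a real cohort would; it is off by
default so the default design is fully crossed.

What the synthetic data do *not* emulate: correlated (non-white) marker
noise, marker occlusion and gap-filling, pitch errors and corrections,
expressive phrasing profiles, horizontal motion, and biomechanical detail
beyond linear coupling. Passing tests therefore show that the pipeline
recovers structure of this idealized kind at realistic noise levels — not
that real pianists must show the same effect sizes.

## Problem sizes and tolerances

The default cohort is 40 performances (≈ 15 000 motion samples each at the
slow tempo), 400 trajectories per region type; a full pipeline run takes
about a minute on one CPU, most of it in the 750 network trainings of the
three cross-validation experiments. Oracle equivalences are asserted at
1e-10 (pointwise ANOVA), 1e-3 (Procrustes grid search, spline derivative
vs. central differences), 1e-10 (PCA spectrum); recovery at 0.5 mm /
1 sample mean absolute error; the null functional-ANOVA significant
fraction at α ± 0.02 over 200 replicates. Degenerate inputs — constant
trajectories, empty masks, constant feature matrices, too-short regions,
flat key series — raise errors rather than propagate silently.

## Known limitations

* C3D support covers the common Intel/float marker layout only (no analog
  channels, DEC/MIPS formats, or multi-byte parameter records).
* The MIDI reader assumes tempo changes precede the first note when merging
  type-1 tracks; written files are type 0 with a 0.5 ms tick.
* GCV optimizes mean squared error over the whole curve, not peak
  sharpness; extremely fast strokes (few samples per region) are smoothed
  toward the grid resolution and regions shorter than 3 samples are
  rejected.
* Procrustes similarity compares equal-length ordered point sets; no
  elastic/time-warping alignment is attempted.
* The per-point functional ANOVA ignores the correlation between grid
  points; its masks are feature selectors, not joint inference.
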