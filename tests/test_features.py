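"""Timing, intensity and kinematic stroke features."""

import numpy as np
import pandas as pd
import pytest

from pianokin import features as feat, smoothing, synth
from pianokin.data_io import NoteEventStream
from pianokin.segmentation import EventRegion, build_regions, detect_key_bottoms


def _stream(onsets):
    n = len(onsets)
    return NoteEventStream(np.asarray(onsets, float), np.full(n, 60),
                           np.full(n, 64.0), (np.arange(n) % 5) + 1)


class TestIOIs:
    def test_first_and_last_tones_excluded(self):
        iois = feat.compute_iois(_stream([0, 500, 1000, 1500, 2000]))
        np.testing.assert_allclose(iois, [500.0, 500.0])

    def test_thirteen_isochronous_onsets(self):
        iois = feat.compute_iois(_stream(np.arange(13) * 125.0))
        assert len(iois) == 10
        np.testing.assert_allclose(iois, 125.0)

    def test_jittered_onsets_equal_difference_oracle(self, rng):
        onsets = np.cumsum(rng.uniform(100, 200, 10))
        iois = feat.compute_iois(_stream(onsets))
        np.testing.assert_allclose(iois, np.diff(onsets[1:-1]))

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            feat.compute_iois(_stream([0, 500, 1000]))


class TestTimingSummary:
    def test_perfect_timing(self):
        ts = feat.timing_summary([500.0] * 10, 500.0)
        assert ts.cv == 0.0 and ts.tempo_deviation_pct == 0.0

    def test_four_percent_deviation(self):
        ts = feat.timing_summary([520.0] * 5, 500.0)
        assert ts.tempo_deviation_pct == pytest.approx(4.0)

    def test_cv_matches_hand_computation(self):
        iois = np.array([480.0, 500.0, 520.0])
        ts = feat.timing_summary(iois, 500.0)
        # hand oracle: sd = sqrt(((−20)^2 + 0 + 20^2)/2) = 20, mean = 500
        assert ts.cv == pytest.approx(20.0 / 500.0)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            feat.timing_summary([500.0], 0.0)


class TestPrescribedIOI:
    @pytest.mark.parametrize("bpm,ioi", [(60, 500), (180, 167), (210, 143),
                                         (240, 125), (250, 120)])
    def test_metronome_prescriptions(self, bpm, ioi):
        assert feat.prescribed_ioi(bpm) == ioi


class TestAmplitudeAnticipation:
    @pytest.fixture()
    def bump_curve(self):
        """30 mm bump peaking 200 ms before the key bottom at 1500 ms (h=0 there)."""
        t = np.arange(0, 2000.0, 1000.0 / 120.0)
        h = np.zeros_like(t)
        m = np.abs(t - 1300.0) <= 200
        h[m] = 30.0 * 0.5 * (1 + np.cos(np.pi * (t[m] - 1300.0) / 200))
        return smoothing.fit_smooth((t, h), lam=1e-10)

    def _regions(self, kb=1500.0, ioi=167.0):
        return (EventRegion(kb - 2 * ioi, kb - ioi, 1, 1, "at_rest"),
                EventRegion(kb - ioi, kb, 2, 1, "attack"))

    def test_bump_recovered(self, bump_curve):
        regions = self._regions(ioi=300.0)
        amp, antic, pct = feat.movement_amplitude_and_anticipation(
            bump_curve, regions, 1500.0, 167.0, key_rest_mm=0.0)
        assert amp == pytest.approx(30.0, abs=0.05)
        assert antic == pytest.approx(200.0, abs=2.0)
        assert pct == pytest.approx(antic / 167.0 * 100.0)

    def test_flat_on_key_trajectory_excluded(self):
        t = np.arange(0, 2000.0, 1000.0 / 120.0)
        curve = smoothing.fit_smooth((t, np.full_like(t, 10.2)), lam=1e-10)
        res = feat.movement_amplitude_and_anticipation(
            curve, self._regions(ioi=300.0), 1500.0, 167.0)
        assert res is None

    def test_peak_at_key_bottom_gives_zero_anticipation(self):
        t = np.arange(0, 2000.0, 1000.0 / 120.0)
        h = 12.0 + 20.0 * np.clip((t - 900.0) / 600.0, 0, 1) ** 2
        curve = smoothing.fit_smooth((t, h), lam=1e-10)
        amp, antic, _ = feat.movement_amplitude_and_anticipation(
            curve, self._regions(ioi=300.0), 1500.0, 167.0)
        assert antic == pytest.approx(0.0, abs=1.0)

    def test_noncontiguous_regions_rejected(self, bump_curve):
        bad = (EventRegion(100.0, 400.0, 1, 1, "at_rest"),
               EventRegion(900.0, 1500.0, 2, 1, "attack"))
        with pytest.raises(ValueError, match="contiguous"):
            feat.movement_amplitude_and_anticipation(bump_curve, bad, 1500.0, 167.0)

    def test_amplitude_invariant_to_common_height_offset(self):
        """Rebasing: shifting heights and the rest reference leaves amp fixed."""
        t = np.arange(0, 2000.0, 1000.0 / 120.0)
        h = np.zeros_like(t)
        m = np.abs(t - 1300.0) <= 200
        h[m] = 30.0 * 0.5 * (1 + np.cos(np.pi * (t[m] - 1300.0) / 200))
        a0 = feat.movement_amplitude_and_anticipation(
            smoothing.fit_smooth((t, h), lam=1e-10), self._regions(ioi=300.0),
            1500.0, 167.0, key_rest_mm=0.0)
        a7 = feat.movement_amplitude_and_anticipation(
            smoothing.fit_smooth((t, h + 7.0), lam=1e-10), self._regions(ioi=300.0),
            1500.0, 167.0, key_rest_mm=7.0)
        assert a7[0] == pytest.approx(a0[0], abs=1e-9)
        assert a7[1] == pytest.approx(a0[1], abs=1e-9)


class TestEndToEndRecovery:
    def test_amplitude_and_anticipation_match_ground_truth(self):
        """Full chain at 0.1 mm noise recovers the generator's ground truth."""
        amp_err, antic_err = [], []
        for seed in range(3):
            rec, notes, truth = synth.generate_performance(
                synth.PerformerSignature(), 500.0, synth.MELODIES[0],
                noise_sd=0.1, seed=seed)
            Y = np.column_stack([rec.finger_height[f] for f in range(1, 6)])
            lam = smoothing.select_lambda_gcv((rec.times_ms, Y),
                                              candidates=np.logspace(-13, -5, 9))
            curves = dict(zip(range(1, 6),
                              smoothing.fit_smooth_multi(rec.times_ms, Y, lam=lam)))
            kb = detect_key_bottoms(rec, notes)
            regions = {(r.finger, r.note_index): r for r in build_regions(kb, notes)}
            for j in range(2, len(notes) - 1):
                f = int(notes.finger[j])
                gt = truth.iloc[j]
                res = feat.movement_amplitude_and_anticipation(
                    curves[f], (regions[(f, j - 1)], regions[(f, j)]),
                    kb[j], gt.ioi_ms)
                if res is None or gt.on_key:
                    continue
                amp_err.append(res[0] - gt.amplitude_mm)
                antic_err.append(res[1] - gt.anticipation_ms)
        assert np.mean(np.abs(amp_err)) < 0.5
        assert np.mean(np.abs(antic_err)) < 1000.0 / 120.0  # one sample


class TestResidualize:
    def test_exact_linear_relation_gives_zero_residuals(self):
        kv = np.array([30.0, 40.0, 50.0, 60.0])
        np.testing.assert_allclose(feat.residualize(2 * kv, kv), 0.0, atol=1e-10)

    def test_orthogonal_fixture_gives_centered_amplitudes(self):
        kv = np.array([-1.0, 1.0, -1.0, 1.0])
        amp = np.array([1.0, 1.0, -1.0, -1.0]) + 5.0  # orthogonal to kv
        np.testing.assert_allclose(feat.residualize(amp, kv), amp - amp.mean(),
                                   atol=1e-12)

    def test_residuals_uncorrelated_with_key_velocity(self, rng):
        kv = rng.uniform(30, 90, 50)
        amp = 0.3 * kv + rng.normal(0, 2, 50)
        resid = feat.residualize(amp, kv)
        assert abs(np.corrcoef(resid, kv)[0, 1]) < 1e-10
        assert resid.mean() == pytest.approx(0.0, abs=1e-10)

    def test_constant_key_velocity_warns_and_centers(self):
        amp = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="constant"):
            resid = feat.residualize(amp, np.full(3, 64.0))
        np.testing.assert_allclose(resid, amp - 2.0)


def _truth_table(separation, seed, tempi=(500.0, 167.0, 125.0)):
    """Feature table straight from generator ground truth (no smoothing)."""
    coh = synth.generate_cohort(n_performers=4, separation=separation,
                                tempi=tempi, seed=seed)
    rows = []
    for p in coh.performances:
        df = p.truth.iloc[2:-1].copy()
        iois = feat.compute_iois(p.notes)
        ts = feat.timing_summary(iois, p.tempo_ms)
        df["performer_id"] = p.performer_id
        df["tempo_ms"] = p.tempo_ms
        df["cv"] = ts.cv
        df["tempo_deviation_pct"] = ts.tempo_deviation_pct
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


class TestSummarizeEffects:
    def test_tempo_effect_on_amplitude_detected(self):
        """Power check: the tempo main effect is significant in >= 90% of runs."""
        hits = 0
        n_runs = 40
        for seed in range(n_runs):
            table = _truth_table(1.0, seed)
            out = feat.summarize_effects(table)
            row = out[(out.analysis == "anova") & (out.response == "amplitude_mm")
                      & (out.term == "tempo")]
            hits += int(row.p.iloc[0] < 0.05)
        assert hits >= 0.9 * n_runs

    def test_zero_separation_regression_near_zero(self):
        r2 = []
        for seed in range(10):
            table = _truth_table(0.0, seed)
            out = feat.summarize_effects(table)
            row = out[(out.analysis == "regression") & (out.statistic == "r_squared")]
            r2.append(row.value.iloc[0])
        assert np.mean(r2) < 0.05

    def test_kruskal_null_p_uniform(self, rng):
        """Identical groups: Kruskal-Wallis p-values are uniform on (0, 1)."""
        from scipy import stats
        ps = []
        for _ in range(100):
            table = pd.DataFrame({
                "performer_id": np.repeat(["P1", "P2"], 60),
                "tempo_ms": np.tile(np.repeat([500.0, 167.0, 125.0], 20), 2),
                "amplitude_mm": rng.normal(25, 3, 120),
            })
            out = feat.summarize_effects(table)
            krus = out[(out.analysis == "kruskal") & (out.response == "amplitude_mm")]
            ps.extend(krus.p.tolist())
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_requires_two_groups(self):
        table = pd.DataFrame({"performer_id": ["P1"] * 4, "tempo_ms": [500.0] * 4,
                              "amplitude_mm": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError):
            feat.summarize_effects(table)
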