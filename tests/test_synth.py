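"""Synthetic performance generator: reproducibility, calibration, ground truth."""

import dataclasses

import numpy as np
import pytest

from pianokin import synth


class TestGeneratePerformance:
    def test_zero_noise_gives_exact_prescribed_iois(self, slow_performance):
        _, notes, _ = slow_performance
        np.testing.assert_allclose(np.diff(notes.onset_ms), 500.0)

    def test_ground_truth_amplitude_and_anticipation_exact(self, slow_performance):
        """Noiseless, uncoupled strokes peak exactly at the nominal bump."""
        _, notes, truth = slow_performance
        rate = 1000.0 / 500.0
        fingers = list(synth.MELODIES[0].fingers)
        for j, row in truth.iloc[2:].iterrows():
            nominal = (18.0 + 1.2 * rate) * synth.FINGER_AMP_FACTOR[row.finger]
            # ground truth is read off the sampled trajectory on a dt/4 grid,
            # so the peak is located to within ~half a fine-grid step
            assert row.amplitude_mm == pytest.approx(nominal, abs=0.05)
            prev = [i for i in range(j) if fingers[i] == row.finger]
            gap_notes = j - prev[-1] if prev else None
            if gap_notes is None or gap_notes >= 3:
                # free lift: peak at the signature's nominal 1.1 IOI
                assert row.anticipation_ms == pytest.approx(1.1 * 500.0, abs=4.2)
            else:
                # reused finger: the lift cannot start before the previous
                # key is released, so the peak is clamped closer to the press
                assert 0.0 < row.anticipation_ms < 1.1 * 500.0

    def test_timing_cv_calibrated(self):
        """Empirical IOI CV matches the generating CV (Monte Carlo)."""
        sig = synth.PerformerSignature(timing_cv_base=0.05, timing_cv_slope=0.0)
        iois = []
        for s in range(80):
            _, notes, _ = synth.generate_performance(sig, 500.0, synth.MELODIES[0], seed=s)
            iois.extend(np.diff(notes.onset_ms))
        iois = np.asarray(iois)
        assert iois.std() / iois.mean() == pytest.approx(0.05, abs=0.005)

    def test_key_bottoms_within_one_sample_of_onsets(self, noisy_performance):
        _, _, truth = noisy_performance
        assert np.max(np.abs(truth.onset_ms - truth.key_bottom_ms)) <= 1000.0 / 120.0

    def test_bit_identical_for_same_seed(self):
        sig = synth.PerformerSignature()
        a = synth.generate_performance(sig, 167.0, synth.MELODIES[1], seed=9)
        b = synth.generate_performance(sig, 167.0, synth.MELODIES[1], seed=9)
        for f in range(1, 6):
            np.testing.assert_array_equal(a[0].finger_height[f], b[0].finger_height[f])
        np.testing.assert_array_equal(a[1].onset_ms, b[1].onset_ms)

    def test_too_fast_tempo_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            synth.generate_performance(synth.PerformerSignature(), 20.0,
                                       synth.MELODIES[0], seed=0)

    def test_enslaved_fingers_rest_on_key(self):
        """On-key strokes exist and come mostly from the middle/ring fingers."""
        sig = synth.PerformerSignature()
        counts = {"enslaved": 0, "other": 0, "total": 0}
        for s in range(30):
            _, _, truth = synth.generate_performance(sig, 500.0, synth.MELODIES[0], seed=s)
            on = truth.iloc[2:][truth.iloc[2:].on_key]
            counts["enslaved"] += int(on.finger.isin(synth.ENSLAVED_FINGERS).sum())
            counts["other"] += int((~on.finger.isin(synth.ENSLAVED_FINGERS)).sum())
            counts["total"] += len(truth) - 2
        assert counts["enslaved"] > counts["other"]
        frac = (counts["enslaved"] + counts["other"]) / counts["total"]
        assert 0.05 < frac < 0.4


class TestGenerateCohort:
    def test_default_design_fully_crossed(self):
        coh = synth.generate_cohort(seed=5)
        assert len(coh.performances) == 4 * 2 * 5
        assert len(coh.signatures) == 4

    def test_zero_separation_collapses_signatures(self):
        coh = synth.generate_cohort(separation=0.0, seed=5)
        sigs = list(coh.signatures.values())
        assert all(dataclasses.asdict(s) == dataclasses.asdict(sigs[0]) for s in sigs)

    def test_cohort_reproducible(self):
        a = synth.generate_cohort(seed=21)
        b = synth.generate_cohort(seed=21)
        for pa, pb in zip(a.performances, b.performances):
            np.testing.assert_array_equal(pa.notes.onset_ms, pb.notes.onset_ms)
            np.testing.assert_array_equal(pa.recording.finger_height[1],
                                          pb.recording.finger_height[1])

    def test_signatures_and_noise_on_disjoint_streams(self):
        """Same seed, different separation: performance noise stays aligned."""
        a = synth.generate_cohort(seed=3, separation=0.0)
        b = synth.generate_cohort(seed=3, separation=1.0)
        assert {p.performer_id for p in a.performances} == \
               {p.performer_id for p in b.performances}
        # IOI noise comes from the performance stream: with identical CVs the
        # relative IOI perturbations match across the two cohorts
        pa, pb = a.performances[0], b.performances[0]
        cv_a = a.signatures["P1"].timing_cv_base + a.signatures["P1"].timing_cv_slope * 2
        cv_b = b.signatures["P1"].timing_cv_base + b.signatures["P1"].timing_cv_slope * 2
        za = (np.diff(pa.notes.onset_ms) / 500.0 - 1.0) / cv_a
        zb = (np.diff(pb.notes.onset_ms) / 500.0 - 1.0) / cv_b
        np.testing.assert_allclose(za, zb, atol=1e-9)

    def test_dropout_thins_fast_tempi_only(self):
        coh = synth.generate_cohort(seed=5, dropout=True)
        by_tempo = {}
        for p in coh.performances:
            by_tempo.setdefault(p.tempo_ms, 0)
            by_tempo[p.tempo_ms] += 1
        assert by_tempo[500.0] == 8 and by_tempo[167.0] == 8
        assert by_tempo.get(120.0, 0) < 8

    def test_requires_two_performers(self):
        with pytest.raises(ValueError, match="at least 2"):
            synth.generate_cohort(n_performers=1, seed=0)


def test_melodies_match_study_design():
    """Two 13-note melodies over a five-finger hand position."""
    for m in synth.MELODIES:
        assert len(m) == 13
        assert set(m.fingers) <= {1, 2, 3, 4, 5}
        assert len(set(m.pitches)) == 5  # stationary hand, five keys
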