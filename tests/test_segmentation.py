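"""Key-bottom detection, event-region labeling, time normalization."""

import numpy as np
import pytest

from pianokin import smoothing
from pianokin.data_io import MotionRecording, NoteEventStream
from pianokin.segmentation import (EventRegion, build_regions, detect_key_bottoms,
                                   regions_table, time_normalize)


def _notes(onsets, fingers=None, pitches=None):
    n = len(onsets)
    return NoteEventStream(
        np.asarray(onsets, float),
        np.asarray(pitches if pitches is not None else [60] * n),
        np.full(n, 64.0),
        np.asarray(fingers if fingers is not None else ([1, 2, 3, 4, 5] * n)[:n]))


def _recording_with_dip(dip_center_ms=1000.0, n=360, depth=10.0, width=80.0):
    t = np.arange(n) * (1000.0 / 120.0)
    key = np.full(n, 10.0)
    m = np.abs(t - dip_center_ms) <= width
    key[m] = 10.0 - depth * 0.5 * (1 + np.cos(np.pi * (t[m] - dip_center_ms) / width))
    fingers = {f: np.full(n, 10.0) for f in range(1, 6)}
    return MotionRecording(120.0, fingers, {60: key}, 0.0)


class TestDetectKeyBottoms:
    def test_dip_minimum_found_despite_onset_offset(self):
        """Key bottom at 1000 ms is detected for a MIDI onset at 1004 ms."""
        rec = _recording_with_dip(1000.0)
        notes = _notes([1004.0], fingers=[1])
        kb = detect_key_bottoms(rec, notes)
        assert kb[0] == pytest.approx(1000.0, abs=1e-9)
        assert abs(kb[0] - 1004.0) <= 8.0

    def test_flat_key_series_errors_for_every_note(self):
        rec = _recording_with_dip(1000.0, depth=0.0)
        notes = _notes([500.0, 1000.0], fingers=[1, 2])
        with pytest.raises(ValueError) as err:
            detect_key_bottoms(rec, notes)
        assert "note 0" in str(err.value) and "note 1" in str(err.value)

    def test_noisy_dips_equal_windowed_argmin_oracle(self, rng):
        """Detection equals brute-force argmin over a +/- half-IOI window."""
        n = 1200
        t = np.arange(n) * (1000.0 / 120.0)
        onsets = 1000.0 + np.arange(8) * 500.0
        key = np.full(n, 10.0)
        for o in onsets:
            m = np.abs(t - o) <= 80
            key[m] -= 10.0 * 0.5 * (1 + np.cos(np.pi * (t[m] - o) / 80))
        key += rng.normal(0, 0.1, n)
        rec = MotionRecording(120.0, {f: np.full(n, 10.0) for f in range(1, 6)},
                              {60: key}, 0.0)
        fingers = [1, 2, 1, 2, 1, 2, 1, 2]  # alternate to satisfy the stream invariant
        notes = _notes(onsets, fingers=fingers)
        kb = detect_key_bottoms(rec, notes)
        for j, o in enumerate(onsets):
            w = (t >= o - 250) & (t <= o + 250)
            assert kb[j] == pytest.approx(t[w][np.argmin(key[w])])

    def test_missing_key_series_reported(self):
        rec = _recording_with_dip(1000.0)
        notes = _notes([1000.0], fingers=[1], pitches=[72])
        with pytest.raises(ValueError, match="pitch 72"):
            detect_key_bottoms(rec, notes)


class TestBuildRegions:
    def test_thirteen_notes_give_twelve_regions_per_finger(self):
        kb = np.arange(13) * 500.0
        notes = _notes(kb, fingers=[1, 2, 3, 4, 5, 1, 2, 3, 4, 5, 1, 2, 3])
        regions = build_regions(kb, notes)
        for f in range(1, 6):
            assert sum(r.finger == f for r in regions) == 12

    def test_labels_for_finger_pressing_notes_one_and_six(self):
        """Finger pressing notes {1, 6} (1-based): region 5 attack, 6 keypress."""
        kb = np.arange(8) * 500.0
        fingers = [2, 1, 3, 4, 5, 2, 3, 4]  # finger 2 plays notes 1 and 6
        notes = _notes(kb, fingers=fingers)
        regions = {(r.note_index): r for r in build_regions(kb, notes) if r.finger == 2}
        assert regions[5].label == "attack"      # region ending at note 6's key bottom
        assert regions[6].label == "keypress"    # region starting at note 6's key bottom
        assert regions[1].label == "keypress"    # after its first keypress
        at_rest = [i for i, r in regions.items() if r.label == "at_rest"]
        assert at_rest == [2, 3, 4, 7]

    def test_single_finger_melody_alternates_attack_keypress(self):
        kb = np.arange(6) * 500.0
        notes = _notes(kb, fingers=[1] * 6)
        rs = [r for r in build_regions(kb, notes) if r.finger == 1]
        # consecutive same-finger notes: attack (of the next note) wins
        assert all(r.label == "attack" for r in rs)
        assert not any(r.label == "at_rest" for r in rs)

    def test_labels_agree_with_independent_rederivation(self, rng):
        """Label oracle: recompute from the note/finger table from scratch."""
        kb = np.sort(rng.uniform(0, 6000, 12))
        fingers = rng.integers(1, 6, 12)
        # the stream invariant forbids simultaneous same-finger onsets: jitter
        notes = _notes(kb, fingers=fingers)
        regions = build_regions(kb, notes)
        for r in regions:
            i = r.note_index - 1
            if r.finger == fingers[i + 1]:
                expect = "attack"
            elif r.finger == fingers[i]:
                expect = "keypress"
            else:
                expect = "at_rest"
            assert r.label == expect

    def test_regions_tile_interval_exactly(self):
        kb = np.array([0.0, 480.0, 1030.0, 1500.0])
        notes = _notes(kb, fingers=[1, 2, 3, 4])
        rs = [r for r in build_regions(kb, notes) if r.finger == 1]
        assert sum(r.duration_ms for r in rs) == pytest.approx(kb[-1] - kb[0])

    def test_unordered_key_bottoms_rejected(self):
        notes = _notes([0.0, 500.0], fingers=[1, 2])
        with pytest.raises(ValueError, match="strictly increasing"):
            build_regions([500.0, 0.0], notes)

    def test_regions_table_export(self):
        kb = np.arange(3) * 500.0
        notes = _notes(kb, fingers=[1, 2, 3])
        df = regions_table(build_regions(kb, notes), "perf1")
        assert set(df.columns) == {"performance_id", "finger", "note_index",
                                   "label", "start_ms", "end_ms"}
        assert len(df) == 2 * 5


class TestTimeNormalize:
    @pytest.fixture()
    def curve(self):
        t = np.arange(0, 2000.0, 1000.0 / 120.0)
        return smoothing.fit_smooth((t, np.sin(t / 200.0) * 10 + 10), lam=1e-10)

    def test_tau_zero_is_region_end(self, curve):
        region = EventRegion(1000.0, 1500.0, 1, 1, "attack")
        nc = time_normalize(curve, region, n_points=101)
        assert nc.position[0] == pytest.approx(
            float(smoothing.evaluate(curve, np.array([1500.0]), 0)[0]))
        assert nc.tau[0] == 0.0 and nc.tau[-1] == 1.0

    def test_output_length_independent_of_duration(self, curve):
        short = EventRegion(100.0, 220.0, 1, 1, "attack")
        long = EventRegion(300.0, 1800.0, 2, 1, "attack")
        assert len(time_normalize(curve, short, 101).velocity) == 101
        assert len(time_normalize(curve, long, 101).velocity) == 101

    def test_values_equal_direct_evaluation(self, curve):
        region = EventRegion(400.0, 900.0, 1, 3, "keypress")
        nc = time_normalize(curve, region, n_points=51)
        times = region.end_ms - nc.tau * region.duration_ms
        for d, arr in [(0, nc.position), (1, nc.velocity), (2, nc.acceleration)]:
            np.testing.assert_allclose(arr, smoothing.evaluate(curve, times, d),
                                       atol=1e-9)

    def test_region_shorter_than_three_samples_rejected(self, curve):
        region = EventRegion(500.0, 515.0, 1, 1, "attack")
        with pytest.raises(ValueError, match="shorter than 3 samples"):
            time_normalize(curve, region)

    def test_region_outside_domain_rejected(self, curve):
        region = EventRegion(1900.0, 2400.0, 1, 1, "attack")
        with pytest.raises(ValueError, match="outside"):
            time_normalize(curve, region)
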