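"""Kinematic checklist scoring: detection, segmentation, claps, points."""

import numpy as np
import pytest

from cpraqa.scoring import (CompressionEvent, DIMENSIONS, Thresholds,
                            UnscorableError, aggregate_items,
                            detect_compressions, detect_sync_claps,
                            compute_sync_offsets, overall_rating,
                            score_recording, segment_cycles)
from cpraqa.simulate import simulate_recording
from cpraqa.skeleton import PoseSequence

from conftest import clean_config, short_params, still_pose


def wrist_wave(graph, amp_m, rate_cpm=110.0, n=30, fps=30.0, still_s=2.0):
    """A still pose whose wrists oscillate sinusoidally below neutral."""
    f = rate_cpm / 60.0
    dur = still_s + n / f + 1.0
    T = int(dur * fps)
    seq = still_pose(graph, T, fps)
    t = np.arange(T) / fps
    active = (t >= still_s) & (t < still_s + n / f)
    h = np.where(active, -amp_m * 0.5 * (1 - np.cos(2 * np.pi * f * (t - still_s))), 0.0)
    for j in ("left_wrist", "right_wrist"):
        seq.data[:, graph.index(j), 1] += h
    return seq


class TestDetectCompressions:
    def test_constructed_signal_counts_exactly(self, graph17):
        seq = wrist_wave(graph17, 0.055, 110.0, n=30)
        ev = detect_compressions(seq, graph17)
        assert len(ev) == 30

    def test_flat_sequence_yields_no_events(self, graph17):
        assert detect_compressions(still_pose(graph17, 300), graph17) == []

    def test_subthreshold_jitter_yields_no_events(self, graph17):
        seq = wrist_wave(graph17, 0.005, 110.0, n=20)  # 0.5 cm < 2 cm prominence
        assert detect_compressions(seq, graph17) == []

    def test_depth_and_recoil_measured_against_neutral(self, graph17):
        rec, _ = simulate_recording(
            short_params(depth_cm=5.5, recoil_deficit_cm=1.5),
            clean_config(seed=8))
        ev = detect_compressions(rec.views["1"], graph17)
        depths = [e.depth_cm for e in ev]
        assert abs(np.mean(depths) - 5.5) < 0.1
        # inter-compression releases stop short of neutral by the deficit
        mids = [e.recoil_residual_cm for e in ev if e.recoil_residual_cm > 0.5]
        assert abs(np.mean(mids) - 1.5) < 0.15

    def test_missing_wrists_throughout_unscorable(self, graph17):
        seq = still_pose(graph17, 100)
        mask = np.zeros(seq.data.shape[:2], bool)
        for j in ("left_wrist", "right_wrist"):
            mask[:, graph17.index(j)] = True
        seq = PoseSequence("1", 30.0, seq.data, mask)
        with pytest.raises(UnscorableError):
            detect_compressions(seq, graph17)


class TestSegmentCycles:
    def _events(self, times):
        return [CompressionEvent(t, t + 0.2, 5.5, 5.5, 0.0) for t in times]

    def test_four_sets_of_thirty_with_pauses(self):
        times = []
        t = 0.0
        for _ in range(4):
            for _ in range(30):
                times.append(t)
                t += 0.55
            t += 5.0
        segs = segment_cycles(self._events(times), Thresholds(), fps=30.0)
        assert [s.n_compressions for s in segs] == [30, 30, 30, 30]
        assert all(a.end_frame < b.start_frame
                   for a, b in zip(segs, segs[1:]))

    def test_uninterrupted_block_is_one_segment(self):
        segs = segment_cycles(self._events(np.arange(25) * 0.5), fps=30.0)
        assert len(segs) == 1 and segs[0].n_compressions == 25

    def test_empty_events_empty_segments(self):
        assert segment_cycles([], Thresholds()) == []


class TestSyncClaps:
    def test_clap_times_recovered_within_one_frame(self, graph17):
        rec, _ = simulate_recording(short_params(), clean_config(seed=6))
        got = detect_sync_claps(rec.views["1"], graph17)
        want = rec.metadata["clap_times_s"]
        assert len(got) == len(want) == 2
        assert all(abs(g - w) <= 1 / 30.0 + 1e-9 for g, w in zip(got, want))

    def test_no_claps_configured_returns_empty_with_warning(self, graph17):
        rec, _ = simulate_recording(short_params(),
                                    clean_config(seed=6, include_claps=False))
        with pytest.warns(UserWarning, match="clap"):
            assert detect_sync_claps(rec.views["1"], graph17) == []

    def test_view_offset_difference_matches_injection(self, graph17):
        cfg = clean_config(seed=13)
        from dataclasses import replace
        from cpraqa.simulate import ViewConfig
        cfg = replace(cfg, views=(ViewConfig("1", 0.0, 0.0),
                                  ViewConfig("4", 0.0, 0.0)),
                      max_sync_offset_frames=3)
        rec, _ = simulate_recording(short_params(), cfg)
        offsets = compute_sync_offsets(rec.views, graph17, reference="1")
        injected = rec.sync_offsets
        assert offsets["4"] - offsets["1"] == injected["4"] - injected["1"]


class TestScoreCycleAndAggregate:
    def _score(self, graph, **defect):
        rec, gt = simulate_recording(short_params(**defect), clean_config(seed=21))
        cc = np.array(rec.metadata["chest_center"])
        return score_recording(rec.views["1"], graph, chest_center=cc), gt

    def test_nominal_all_points_awarded(self, graph17):
        score, _ = self._score(graph17)
        for c in score.cycles:
            assert all(c.points[d] == 1 for d in DIMENSIONS)

    def test_fast_rate_fails_only_rate_with_code(self, graph17):
        score, _ = self._score(graph17, rate_cpm=130.0)
        c = score.cycles[0]
        assert c.points["rate"] == 0 and c.codes["rate"] == ["too_fast"]
        assert all(c.points[d] == 1 for d in DIMENSIONS if d != "rate")

    def test_bent_variable_elbows_fail_arm(self, graph17):
        score, _ = self._score(graph17, elbow_flex_deg=30.0, elbow_var_deg=10.0)
        assert score.item_totals["arm"] == 0

    def test_aggregation_sums_and_overall_convention(self):
        from cpraqa.scoring import CycleScore
        good = CycleScore({d: 1 for d in DIMENSIONS}, {d: [] for d in DIMENSIONS}, {})
        bad_depth = CycleScore({**{d: 1 for d in DIMENSIONS}, "depth": 0},
                               {d: [] for d in DIMENSIONS}, {})
        agg = aggregate_items([good, bad_depth, good, bad_depth])
        assert agg.item_totals["depth"] == 2
        assert agg.item_totals["hand"] == 4
        assert agg.overall_per_cycle == ["Excellent", "Good", "Excellent", "Good"]

    def test_zero_scorable_cycles_is_an_error(self):
        from cpraqa.scoring import CycleScore
        with pytest.raises(UnscorableError):
            aggregate_items([CycleScore({}, {}, {}, scorable=False)])

    @pytest.mark.parametrize("points,label", [
        (6, "Excellent"), (5, "Good"), (4, "Borderline"),
        (3, "Poor"), (2, "Poor"), (1, "Unacceptable"), (0, "Unacceptable")])
    def test_overall_rating_convention(self, points, label):
        assert overall_rating(points) == label


class TestInvariances:
    def _transform(self, seq, rot_deg=0.0, shift=(0, 0, 0)):
        th = np.radians(rot_deg)
        R = np.array([[np.cos(th), 0, np.sin(th)],
                      [0, 1, 0],
                      [-np.sin(th), 0, np.cos(th)]])
        data = seq.data.copy()
        data[..., :3] = data[..., :3] @ R.T + np.asarray(shift)
        return PoseSequence(seq.view_id, seq.fps, data, seq.missing_mask.copy()), R

    def test_points_invariant_to_translation_and_vertical_rotation(self, graph17):
        rec, _ = simulate_recording(
            short_params(depth_cm=4.0, shoulder_lean_deg=15.0),
            clean_config(seed=30))
        seq = rec.views["1"]
        cc = np.array(rec.metadata["chest_center"])
        ref = score_recording(seq, graph17, chest_center=cc)
        moved, R = self._transform(seq, rot_deg=73.0, shift=(1.5, 0.2, -2.0))
        cc2 = R @ cc + np.array([1.5, 0.2, -2.0])
        got = score_recording(moved, graph17, chest_center=cc2)
        assert got.item_totals == ref.item_totals
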