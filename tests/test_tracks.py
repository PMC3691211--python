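"""Phase segmentation, dynamics summaries, comet origin, burst detection."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mtquant as mq
from mtquant.datatypes import Phase
from mtquant.synthetic import DynamicsParams, simulate_di_track, simulate_washout_trace
from mtquant.tracks import (
    PhaseSegmentation,
    classify_comet_origin,
    detect_time_zero,
    segment_phases,
    split_on_gaps,
    summarize_dynamics,
)

from conftest import circle_geometry

REF = (-1000.0, 0.0)


def straight_track(step_px, n=10, dt=3.0, px=0.1):
    x = 50.0 + step_px * np.arange(n)
    return mq.Track("t", np.arange(n), x, np.zeros(n), dt, px)


class TestSegmentPhases:
    def test_sub_threshold_steps_are_pause(self):
        seg = segment_phases(straight_track(2.0), direction_ref=REF)  # 0.2 um/frame
        assert np.all(seg.labels == int(Phase.PAUSE))

    def test_outward_steps_are_growth_with_correct_speed(self):
        seg = segment_phases(straight_track(5.0), direction_ref=REF)  # 0.5 um / 3 s
        assert np.all(seg.labels == int(Phase.GROWTH))
        np.testing.assert_allclose(seg.speeds_um_min, 10.0)

    def test_inward_steps_are_shrinkage(self):
        seg = segment_phases(straight_track(-5.0), direction_ref=REF)
        assert np.all(seg.labels == int(Phase.SHRINKAGE))

    def test_missing_direction_ref_is_an_error(self):
        with pytest.raises(ValueError, match="direction_ref"):
            segment_phases(straight_track(5.0))

    def test_frame_gaps_must_be_split_first(self):
        t = mq.Track("g", [0, 1, 3, 4], [0, 1, 2, 3], [0, 0, 0, 0], 3.0, 0.1)
        with pytest.raises(ValueError, match="gap"):
            segment_phases(t, direction_ref=REF)
        pieces = split_on_gaps(t)
        assert [p.n_frames for p in pieces] == [2, 2]
        for p in pieces:
            segment_phases(p, direction_ref=REF)

    def test_labels_match_simulator_truth(self):
        # |v| * dt >= 0.6 um/frame with 0.05 um jitter: labels must agree with
        # the recorded true states on intervals whose endpoints share a state
        # (mixed-phase intervals have no well-defined true label).
        agree = total = 0
        for seed in range(100):
            sim = simulate_di_track(
                DynamicsParams(k_catastrophe_per_min=0.5, k_rescue_per_min=0.5,
                               v_growth_um_min=12.0, v_shrink_um_min=18.0,
                               n_frames=101, seed=seed)
            )
            seg = segment_phases(sim.track, direction_ref=sim.direction_ref_px)
            pure = sim.true_states[:-1] == sim.true_states[1:]
            agree += int(np.sum(seg.labels[pure] == sim.true_states[:-1][pure]))
            total += int(np.sum(pure))
        assert agree / total >= 0.99


class TestSummarizeDynamics:
    def test_single_all_pause_track(self):
        seg = PhaseSegmentation(np.full(5, int(Phase.PAUSE)), np.zeros(5), 3.0)
        s = summarize_dynamics([seg])
        assert s.pct_pause == 100.0
        assert s.catastrophe_freq_per_min is not None  # pause time is at-risk time
        assert s.catastrophe_freq_per_min == 0.0
        s_total = summarize_dynamics([seg], denominator="total")
        assert s_total.rescue_freq_per_min == 0.0

    def test_toy_label_sequence_hand_count(self):
        # G G S S G at 3 s intervals: 1 catastrophe over 9 s of growth,
        # 1 rescue over 6 s of shrinkage.
        labels = [Phase.GROWTH, Phase.GROWTH, Phase.SHRINKAGE, Phase.SHRINKAGE, Phase.GROWTH]
        seg = PhaseSegmentation(np.array([int(p) for p in labels]),
                                np.array([10.0, 10.0, 15.0, 15.0, 10.0]), 3.0)
        s = summarize_dynamics([seg])
        assert s.catastrophe_freq_per_min == pytest.approx(1 / (9 / 60))
        assert s.rescue_freq_per_min == pytest.approx(1 / (6 / 60))
        assert s.pct_growth == pytest.approx(60.0)
        assert s.mean_growth_speed_um_min == pytest.approx(10.0)
        assert s.mean_shrink_speed_um_min == pytest.approx(15.0)

    def test_percentages_sum_to_exactly_100(self):
        rng = np.random.default_rng(0)
        segs = [
            PhaseSegmentation(rng.integers(0, 3, 37), rng.uniform(0, 20, 37), 3.0)
            for _ in range(25)
        ]
        s = summarize_dynamics(segs)
        assert s.pct_growth + s.pct_shrink + s.pct_pause == pytest.approx(100.0, abs=1e-9)

    def test_recovers_rates_from_simulated_tracks(self):
        # 200 ten-minute tracks; segmentations built from the simulator's true
        # state samples at 0.5 s isolate frequency estimation from tip
        # localization and keep the discretization bias (~(k_c+k_r)*dt/2)
        # well below the sampling error.
        segs = []
        for seed in range(200):
            sim = simulate_di_track(
                DynamicsParams(k_catastrophe_per_min=2.0, k_rescue_per_min=1.0,
                               frame_interval_s=0.5, n_frames=1201, seed=seed)
            )
            segs.append(PhaseSegmentation(sim.true_states[:-1],
                                          np.zeros(len(sim.true_states) - 1), 0.5))
        s = summarize_dynamics(segs)
        t_g = s.pct_growth / 100 * s.total_time_min
        t_s = s.pct_shrink / 100 * s.total_time_min
        se_cat = np.sqrt(s.catastrophe_freq_per_min * t_g) / t_g
        se_res = np.sqrt(s.rescue_freq_per_min * t_s) / t_s
        assert abs(s.catastrophe_freq_per_min - 2.0) < 3 * se_cat
        assert abs(s.rescue_freq_per_min - 1.0) < 3 * se_res

    def test_transition_bookkeeping_identity(self):
        # catastrophes - rescues must match the endpoint-state difference up to
        # the number of pause interludes.
        rng = np.random.default_rng(3)
        for _ in range(50):
            labels = rng.integers(0, 3, 60)
            seg = PhaseSegmentation(labels, np.zeros(60), 3.0)
            s = summarize_dynamics([seg], denominator="total")
            n_cat = round(s.catastrophe_freq_per_min * s.total_time_min)
            n_res = round(s.rescue_freq_per_min * s.total_time_min)
            endpoint = int(labels[-1] == Phase.SHRINKAGE) - int(labels[0] == Phase.SHRINKAGE)
            n_pause_runs = int(np.sum((labels[1:] == Phase.PAUSE) & (labels[:-1] != Phase.PAUSE)))
            n_pause_runs += int(labels[0] == Phase.PAUSE)
            assert abs((n_cat - n_res) - endpoint) <= n_pause_runs


class TestCometOrigin:
    def test_short_tracks_are_excluded(self):
        t = mq.Track("s", [0, 1, 2], [0, 5, 10], [0, 0, 0], 5.0, 0.1)
        assert classify_comet_origin(t, (0, 0)).origin == "excluded"

    def test_outward_track_from_centrosome_is_centrosomal(self):
        t = mq.Track("c", np.arange(5), 100 + 10 * np.arange(5), np.full(5, 100.0), 5.0, 0.1)
        assert classify_comet_origin(t, (100, 100)).origin == "centrosomal"

    def test_inward_track_near_centrosome_is_excluded(self):
        t = mq.Track("i", np.arange(5), 110 - 3 * np.arange(5), np.full(5, 100.0), 5.0, 0.1)
        call = classify_comet_origin(t, (100, 100))
        assert call.start_distance_um == pytest.approx(1.0)
        assert call.origin == "excluded"

    def test_ambiguity_band_is_excluded(self):
        t = mq.Track("b", np.arange(5), 130 + 5 * np.arange(5), np.full(5, 100.0), 5.0, 0.1)
        assert classify_comet_origin(t, (100, 100)).origin == "excluded"  # 3 um in [2, 4)

    def test_distant_start_is_non_centrosomal(self):
        t = mq.Track("n", np.arange(5), 160 + 5 * np.arange(5), np.full(5, 100.0), 5.0, 0.1)
        assert classify_comet_origin(t, (100, 100)).origin == "non_centrosomal"

    @given(st.floats(0, 2 * np.pi), st.floats(-50, 50), st.floats(-50, 50))
    def test_invariant_under_rigid_transforms(self, theta, tx, ty):
        geo = circle_geometry(center=(150, 150), radius=140)
        from mtquant.synthetic import simulate_comets

        pairs = simulate_comets(3, 3, (150, 150), geo, seed=8)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        c = np.array([150.0, 150.0])
        c_t = rot @ c + [tx, ty]
        for track, _ in pairs:
            pts = (rot @ np.vstack([track.x_px, track.y_px])).T + [tx, ty]
            moved = mq.Track(track.track_id, track.frames, pts[:, 0], pts[:, 1],
                             track.frame_interval_s, track.pixel_size_um)
            assert (
                classify_comet_origin(moved, tuple(c_t)).origin
                == classify_comet_origin(track, (150, 150)).origin
            )


class TestDetectTimeZero:
    def test_flat_trace_has_no_burst(self):
        assert detect_time_zero([(i, 100.0) for i in range(20)]) is None

    def test_step_trace_returns_step_frame(self):
        values = [10.0] * 7 + [100.0] * 5
        assert detect_time_zero(list(enumerate(values))) == 7

    def test_trace_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_time_zero([(0, 1.0), (1, 1.0)])

    def test_simulated_washout_onset_within_one_frame(self):
        for seed in range(100):
            trace = simulate_washout_trace(onset_frame=20, noise_sigma=2.0, seed=seed)
            found = detect_time_zero(trace)
            assert found is not None and abs(found - 20) <= 1
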