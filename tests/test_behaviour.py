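"""Heat map, occupancy budgets, rolling dispersion, weight-shift signature,
and the rule-based behaviour classifier."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import Polygon

import stalltrack as st
from stalltrack.behaviour import ClassifierParams
from stalltrack.tracks import BEHAVIOURS, TrackValidationError
from conftest import make_track


class TestPositionHeatmap:
    def test_single_frame(self):
        track = make_track(frames=[1], x=[75.0], y=[30.0])
        hm = st.position_heatmap(track, 50)
        assert hm.total_mass == 1
        assert hm.grid[0, 1] == 1 and hm.grid.sum() == 1

    def test_boundary_goes_to_higher_bin(self):
        track = make_track(frames=[1], x=[100.0], y=[0.0])
        hm = st.position_heatmap(track, 50)
        assert hm.grid[0, 2] == 1  # x=100 starts bin [100,150)

    def test_far_edge_in_last_bin(self):
        track = make_track(frames=[1], x=[2704.0], y=[1520.0])
        hm = st.position_heatmap(track, 50)
        assert hm.grid[-1, -1] == 1

    def test_mass_conservation(self, small_run):
        nose = small_run["tracks"]["nose"]
        hm = st.position_heatmap(nose, 50)
        assert hm.total_mass == nose.n_predicted == hm.grid.sum()

    def test_uniform_positions_uniform_bins(self):
        rng = np.random.default_rng(0)
        n = 10_000
        # exact bin tiling so every bin has equal expected mass
        track = make_track(
            frames=range(1, n + 1),
            x=rng.uniform(0, 2700, n),
            y=rng.uniform(0, 1500, n),
        )
        hm = st.position_heatmap(track, 300, width_px=2700, height_px=1500)
        chi = stats.chisquare(hm.grid.ravel())
        assert chi.pvalue > 0.001

    def test_bad_bin_size(self):
        with pytest.raises(TrackValidationError):
            st.position_heatmap(make_track(), 0)


class TestTimeInRegion:
    def test_whole_image_region(self):
        track = make_track(frames=range(1, 11), x=np.linspace(10, 2000, 10),
                           y=np.linspace(10, 1400, 10))
        whole = {"stall": Polygon([(0, 0), (2704, 0), (2704, 1520), (0, 1520)])}
        tb = st.time_in_region(track, whole)
        assert tb.percent["stall"] == pytest.approx(100.0)
        assert tb.percent["elsewhere"] == 0.0

    def test_shared_edge_counted_in_both_and_flagged(self):
        left = Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])
        right = Polygon([(100, 0), (200, 0), (200, 100), (100, 100)])
        track = make_track(frames=[1], x=[100.0], y=[50.0])
        tb = st.time_in_region(track, {"left": left, "right": right})
        assert tb.frames["left"] == tb.frames["right"] == 1
        assert tb.overlap_frames == 1

    def test_budget_conversion_to_minutes(self):
        track = make_track(frames=range(1, 481), x=np.full(480, 50.0),
                           y=np.full(480, 50.0))
        region = {"corner": Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])}
        tb = st.time_in_region(track, region, fps_tlv=2.0)
        assert tb.minutes["corner"] == pytest.approx(4.0)

    def test_generated_feeding_dwell_recovered(self):
        """Region occupancy recovers the chain's feeding share within 2 points."""
        m = np.array(
            [
                [0.9960, 0.0000, 0.0000, 0.0040],
                [0.0000, 0.9960, 0.0000, 0.0040],
                [0.0000, 0.0000, 0.9970, 0.0030],  # feeding dwell boosted
                [0.0150, 0.0150, 0.0300, 0.9400],
            ]
        )
        sc = st.build_scenario(
            {"n_frames": 20000, "seed": 17, "behaviour": {"transition_matrix": m}}
        )
        truth, labels = st.simulate_tracks(sc)
        nose = truth.to_track("nose")
        tb = st.time_in_region(nose, sc.geometry.regions, sc.fps_tlv)
        feeding_share = 100.0 * float(np.mean(labels.behaviour == "feeding"))
        assert tb.percent["feeding"] == pytest.approx(feeding_share, abs=2.0)

    def test_percent_conservation_disjoint(self, small_run):
        nose = small_run["tracks"]["nose"]
        geo = small_run["scenario"].geometry
        tb = st.time_in_region(nose, geo.regions)
        if tb.overlap_frames == 0:
            assert sum(tb.percent.values()) == pytest.approx(100.0, abs=1e-9)


class TestXySeries:
    def test_full_overlap_row_count(self, small_run):
        nose = small_run["tracks"]["nose"]
        joined = st.xy_series_with_behaviour(nose, small_run["labels"])
        assert len(joined) == len(nose)
        assert list(joined.columns) == ["frame", "x", "y", "behaviour"]

    def test_disjoint_ranges_raise(self):
        track = make_track(frames=[1, 2, 3])
        labels = st.BehaviourLabels(frames=np.array([10, 11]),
                                    behaviour=np.array(["rest", "rest"], dtype=object))
        with pytest.raises(TrackValidationError, match="share no frames"):
            st.xy_series_with_behaviour(track, labels)

    def test_join_then_split_recovers_inputs(self, small_run):
        nose = small_run["tracks"]["nose"]
        joined = st.xy_series_with_behaviour(nose, small_run["labels"])
        assert np.allclose(joined["x"].to_numpy(), nose.x, equal_nan=True)
        assert np.array_equal(
            joined["behaviour"].to_numpy(), small_run["labels"].behaviour
        )


class TestRollingDispersion:
    def test_constant_track_zero(self):
        track = make_track(frames=range(1, 301))
        v = st.rolling_dispersion(track, "y", 50)
        assert np.allclose(v.dropna(), 0.0)

    def test_sinusoid_variance_closed_form(self):
        n, amp, period = 2000, 12.0, 40
        t = np.arange(n)
        track = make_track(
            frames=t + 1, x=np.zeros(n), y=amp * np.sin(2 * np.pi * t / period)
        )
        v = st.rolling_dispersion(track, "y", 400)
        mid = v.iloc[500:1500]
        assert mid.mean() == pytest.approx(amp**2 / 2, rel=0.05)

    def test_low_support_missing(self):
        predicted = np.zeros(100, dtype=bool)
        predicted[:10] = True
        track = make_track(frames=range(1, 101),
                           x=np.where(predicted, 1.0, np.nan),
                           y=np.where(predicted, 1.0, np.nan), predicted=predicted)
        v = st.rolling_dispersion(track, "y", 60)
        assert v.iloc[60:].isna().all()


class TestWeightShifting:
    def _run(self, amplitude, seed=301, n=6000):
        sc = st.build_scenario(
            {"n_frames": n, "seed": seed,
             "behaviour": {"rest_y_oscillation_amplitude_px": amplitude}}
        )
        truth, labels = st.simulate_tracks(sc)
        tracks, _ = st.degrade_to_predictions(
            truth, sc.artifacts, seed=seed + 1, geometry=sc.geometry
        )
        return tracks["nose"], labels

    def test_zero_amplitude_not_flagged(self):
        nose, labels = self._run(0.0)
        assert not any(s.flagged for s in st.detect_weight_shifting(nose, labels))

    def test_oscillating_rest_flagged(self):
        nose, labels = self._run(8.0)
        segs = st.detect_weight_shifting(nose, labels)
        assert any(s.flagged for s in segs)
        flagged = [s for s in segs if s.flagged]
        assert all(s.variance_ratio > 3.0 for s in flagged)

    def test_oscillation_raises_rest_variance(self):
        nose_o, labels_o = self._run(8.0)
        nose_q, labels_q = self._run(0.0)
        vo = np.nanmax([s.y_variance_px2 for s in st.detect_weight_shifting(nose_o, labels_o)])
        vq = np.nanmax([s.y_variance_px2 for s in st.detect_weight_shifting(nose_q, labels_q)])
        assert vo > vq

    def test_infinite_threshold_no_flags(self):
        nose, labels = self._run(8.0)
        segs = st.detect_weight_shifting(
            nose, labels, variance_ratio_threshold=float("inf")
        )
        assert not any(s.flagged for s in segs)

    def test_no_rest_frames_empty(self):
        track = make_track(frames=range(1, 100))
        labels = st.BehaviourLabels(
            frames=np.arange(1, 100),
            behaviour=np.array(["feeding"] * 99, dtype=object),
        )
        assert st.detect_weight_shifting(track, labels) == []

    def test_median_rest_reference_isolates_unusual_bout(self):
        """With the relative reference, one oscillating bout among quiet
        bouts stands out within a single recording."""
        n = 3000
        rng = np.random.default_rng(5)
        y = 400.0 + rng.normal(0, 1.0, n)
        beh = np.array(["rest"] * n, dtype=object)
        # carve three rest bouts separated by feeding
        beh[900:1000] = "feeding"
        beh[1900:2000] = "feeding"
        t = np.arange(1000, 1900)
        y[1000:1900] += 10.0 * np.sin(2 * np.pi * t / 40)
        track = make_track(frames=range(1, n + 1), x=np.zeros(n), y=y)
        labels = st.BehaviourLabels(frames=np.arange(1, n + 1), behaviour=beh)
        segs = st.detect_weight_shifting(
            track, labels, baseline_variance_px2="median_rest",
            variance_ratio_threshold=5.0,
        )
        flagged = [(s.start_frame, s.end_frame) for s in segs if s.flagged]
        assert flagged == [(1001, 1900)]


class TestClassifyBehaviour:
    def test_stationary_high_nose_all_standing(self):
        n = 400
        rng = np.random.default_rng(2)
        x = 600.0 + rng.normal(0, 4, n)
        y = 400.0 + rng.normal(0, 4, n)
        tracks = {
            "nose": make_track("nose", range(1, n + 1), x, y),
            "withers": make_track("withers", range(1, n + 1), x - 250, y),
        }
        labels = st.classify_behaviour(tracks)
        assert set(labels.behaviour) == {"standing_observation"}

    def test_zero_move_threshold_everything_moves(self, small_run):
        params = ClassifierParams(move_threshold_px=0.0)
        labels = st.classify_behaviour(small_run["tracks"], params)
        assert set(labels.behaviour) == {"moving"}

    def test_default_scenario_agreement(self, small_run):
        labels = st.classify_behaviour(small_run["tracks"])
        agreement = float(
            np.mean(labels.behaviour == small_run["labels"].behaviour)
        )
        assert agreement >= 0.90

    def test_insufficient_nose_coverage_raises(self):
        predicted = np.zeros(100, dtype=bool)
        predicted[:10] = True
        nose = make_track("nose", range(1, 101),
                          np.where(predicted, 1.0, np.nan),
                          np.where(predicted, 1.0, np.nan), predicted)
        with pytest.raises(TrackValidationError, match="coverage"):
            st.classify_behaviour({"nose": nose})


class TestBehaviourTimeBudget:
    def test_480_feeding_frames_is_four_minutes(self):
        labels = st.BehaviourLabels(
            frames=np.arange(1, 481),
            behaviour=np.array(["feeding"] * 480, dtype=object),
        )
        tb = st.behaviour_time_budget(labels, fps_tlv=2.0)
        assert tb.minutes["feeding"] == pytest.approx(4.0)
        assert tb.percent["feeding"] == pytest.approx(100.0)

    def test_absent_classes_reported_zero(self):
        labels = st.BehaviourLabels(
            frames=np.array([1]), behaviour=np.array(["rest"], dtype=object)
        )
        tb = st.behaviour_time_budget(labels)
        assert set(tb.frames) == set(BEHAVIOURS)
        assert tb.percent["moving"] == 0.0

    def test_percents_sum_to_100(self, small_run):
        tb = st.behaviour_time_budget(small_run["labels"])
        assert sum(tb.percent.values()) == pytest.approx(100.0, abs=1e-9)
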