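"""Confusion classification, performance formulas, aggregation and the
version/marker statistical comparisons."""

import numpy as np
import pandas as pd
import pytest

import stalltrack as st
from stalltrack.tracks import TrackValidationError
from stalltrack.validation import ConfusionCounts, PerVideoMetrics
from conftest import make_track, make_truth


def brute_force_confusion(predicted, truth_rows, radius, window):
    """Independent per-frame oracle: dict-based scan, no vectorization."""
    truth = {f: (x, y, vis) for f, _m, x, y, vis in truth_rows}
    pred = {
        int(f): (x, y)
        for f, x, y, p in zip(predicted.frames, predicted.x, predicted.y, predicted.predicted)
        if p
    }
    tp = tn = fp = fn = 0
    for f in range(window[0], window[1] + 1):
        x, y, vis = truth[f]
        visible = vis != "not_visible"
        if f in pred:
            px, py = pred[f]
            if visible and ((px - x) ** 2 + (py - y) ** 2) ** 0.5 <= radius:
                tp += 1
            else:
                fp += 1
        elif visible:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


class TestPredictionRates:
    def test_ratio(self):
        predicted = np.zeros(1000, dtype=bool)
        predicted[:700] = True
        x = np.where(predicted, 5.0, np.nan)
        track = make_track(frames=range(1, 1001), x=x, y=x, predicted=predicted)
        pm, pm_ti = st.prediction_rates(track, st.VideoMeta(n_frames=1000))
        assert (pm, pm_ti) == (700, pytest.approx(0.7))

    def test_bounds(self):
        track = make_track(frames=[1, 2], predicted=[True, True])
        assert st.prediction_rates(track, st.VideoMeta(n_frames=2))[1] == 1.0
        none = make_track(frames=[1, 2], x=[np.nan] * 2, y=[np.nan] * 2,
                          predicted=[False, False])
        assert st.prediction_rates(none, st.VideoMeta(n_frames=2)) == (0, 0.0)


class TestClassifyConfusion:
    def test_exact_prediction_is_tp(self):
        truth = make_truth([(1, "nose", 50.0, 60.0, "visible")])
        track = make_track(frames=[1], x=[50.0], y=[60.0])
        c = st.classify_confusion(track, truth, 100.0, window=(1, 1))
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 0, 0, 0)

    def test_beyond_radius_is_fp_not_tp(self):
        truth = make_truth([(1, "nose", 50.0, 60.0, "visible")])
        track = make_track(frames=[1], x=[50.0 + 101.0], y=[60.0])
        c = st.classify_confusion(track, truth, 100.0, window=(1, 1))
        assert (c.TP, c.FP, c.FN) == (0, 1, 0)

    def test_hidden_unpredicted_is_tn(self):
        truth = make_truth([(1, "nose", None, None, "not_visible")])
        track = make_track(frames=[1], x=[np.nan], y=[np.nan], predicted=[False])
        c = st.classify_confusion(track, truth, 100.0, window=(1, 1))
        assert c.TN == 1 and c.total == 1

    def test_occluded_marker_counts_as_expected_predicted(self):
        truth = make_truth([(1, "nose", 10.0, 10.0, "occluded50")])
        track = make_track(frames=[1], x=[np.nan], y=[np.nan], predicted=[False])
        c = st.classify_confusion(track, truth, 100.0, window=(1, 1))
        assert c.FN == 1

    def test_frame_absent_everywhere_raises(self):
        truth = make_truth([(1, "nose", 10.0, 10.0, "visible")])
        track = make_track(frames=[1], x=[10.0], y=[10.0])
        with pytest.raises(TrackValidationError, match="absent"):
            st.classify_confusion(track, truth, 100.0, window=(1, 2))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        rows, px, py, pp = [], [], [], []
        for f in range(1, n + 1):
            hidden = rng.random() < 0.2
            x, y = rng.uniform(0, 2704), rng.uniform(0, 1520)
            rows.append((f, "nose", None if hidden else x, None if hidden else y,
                         "not_visible" if hidden else "visible"))
            if rng.random() < 0.8:
                pp.append(True)
                px.append(x + rng.normal(0, 80))
                py.append(y + rng.normal(0, 80))
            else:
                pp.append(False)
                px.append(np.nan)
                py.append(np.nan)
        truth = make_truth(rows)
        track = make_track(frames=range(1, n + 1), x=px, y=py, predicted=pp)
        c = st.classify_confusion(track, truth, 100.0, window=(1, n))
        assert (c.TP, c.TN, c.FP, c.FN) == brute_force_confusion(
            track, rows, 100.0, (1, n)
        )
        assert c.total == n


class TestPerformanceMetrics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (dict(TP=88, FN=12, FP=0, TN=0), ("sensitivity", 0.88)),
            (dict(TP=94, FP=6, FN=0, TN=0), ("error_rate", 0.06)),
            (dict(TP=50, TN=30, FP=10, FN=10), ("accuracy", 0.80)),
        ],
    )
    def test_formulas(self, counts, expected):
        sens, err, acc = st.performance_metrics(ConfusionCounts(**counts))
        got = {"sensitivity": sens, "error_rate": err, "accuracy": acc}[expected[0]]
        assert got == pytest.approx(expected[1], abs=1e-12)

    def test_zero_denominator_is_undefined(self):
        sens, err, acc = st.performance_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert np.isnan(sens) and np.isnan(err) and acc == 1.0

    def test_perfect_accuracy_iff_no_errors(self):
        _, _, acc = st.performance_metrics(ConfusionCounts(TP=9, TN=1, FP=0, FN=0))
        assert acc == 1.0
        _, _, acc2 = st.performance_metrics(ConfusionCounts(TP=9, TN=0, FP=1, FN=0))
        assert acc2 < 1.0


class TestAggregateMeanSd:
    def test_hand_computed(self):
        mean, sd, n = st.aggregate_mean_sd([0.7, 0.9])
        assert mean == pytest.approx(0.8)
        assert sd == pytest.approx(0.1414, abs=5e-5)
        assert n == 2

    def test_single_value(self):
        assert st.aggregate_mean_sd([0.5]) == (0.5, 0.0, 1)

    def test_undefined_excluded(self):
        mean, _, n = st.aggregate_mean_sd([0.5, float("nan"), 0.7])
        assert (mean, n) == (pytest.approx(0.6), 2)

    def test_all_undefined_raises(self):
        with pytest.raises(TrackValidationError):
            st.aggregate_mean_sd([float("nan")])

    def test_permutation_invariant(self):
        vals = [0.1, 0.4, 0.9, 0.3]
        a = st.aggregate_mean_sd(vals)
        b = st.aggregate_mean_sd(vals[::-1])
        assert a[0] == pytest.approx(b[0], abs=1e-12)
        assert a[1] == pytest.approx(b[1], abs=1e-12)
        assert a[2] == b[2]


def _metrics(video_id, marker, value):
    return PerVideoMetrics(
        video_id=video_id, marker=marker, PM=int(1000 * value), TI=1000,
        pm_ti=value, WP=int(100 * value), pct_wp=10 * value,
    )


class TestCompareVersions:
    # fixture values and the paired t-test oracle result frozen from an
    # independent statistics environment (R t.test, paired, two-sided)
    A = [0.70, 0.72, 0.65, 0.80, 0.77, 0.69, 0.74, 0.71]
    B = [0.68, 0.75, 0.66, 0.76, 0.74, 0.66, 0.70, 0.69]

    def test_identical_versions_null(self):
        va = [_metrics(f"v{i}", "nose", x) for i, x in enumerate(self.A)]
        res = st.compare_versions(va, va)
        for r in res:
            if not r.degenerate:
                assert r.t == pytest.approx(0.0, abs=1e-12)
                assert r.p == pytest.approx(1.0)

    def test_matches_reference_implementation(self):
        va = [_metrics(f"v{i}", "nose", x) for i, x in enumerate(self.A)]
        vb = [_metrics(f"v{i}", "nose", x) for i, x in enumerate(self.B)]
        res = {r.quantity: r for r in st.compare_versions(va, vb)}
        r = res["pm_ti"]
        assert r.t == pytest.approx(1.9855802013, abs=1e-6)
        assert r.p == pytest.approx(0.0874593426, abs=1e-6)
        assert r.df == 7
        assert r.mean_difference == pytest.approx(0.0175, abs=1e-12)
        assert not r.significant

    def test_constant_shift_degenerate(self):
        va = [_metrics(f"v{i}", "nose", 0.5) for i in range(10)]
        vb = [_metrics(f"v{i}", "nose", 0.6) for i in range(10)]
        res = {r.quantity: r for r in st.compare_versions(va, vb)}
        assert res["pm_ti"].degenerate

    def test_unmatched_videos_listed(self):
        va = [_metrics("a", "nose", 0.5), _metrics("b", "nose", 0.6)]
        vb = [_metrics("a", "nose", 0.5), _metrics("c", "nose", 0.6)]
        with pytest.raises(TrackValidationError, match="'b'.*'c'"):
            st.compare_versions(va, vb)


class TestMarkerAnova:
    G = {
        "nose": [0.88, 0.85, 0.91, 0.84],
        "tail": [0.80, 0.78, 0.83, 0.79],
        "withers": [0.86, 0.82, 0.84, 0.88],
    }

    def test_identical_groups_null(self):
        res = st.compare_markers_anova({m: [0.8, 0.8, 0.8] for m in ("n", "w", "t")})
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_reference_implementation(self):
        # oracle frozen from an independent statistics environment (R aov)
        res = st.compare_markers_anova(self.G, metric="sensitivity")
        assert res.F == pytest.approx(7.3125, abs=1e-6)
        assert res.p == pytest.approx(0.0129992446, abs=1e-6)
        assert (res.df_between, res.df_within) == (2, 9)
        assert res.significant

    def test_matches_hand_computed_sums_of_squares(self):
        groups = {k: np.array(v) for k, v in self.G.items()}
        all_vals = np.concatenate(list(groups.values()))
        grand = all_vals.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups.values())
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
        f_hand = (ss_between / 2) / (ss_within / 9)
        res = st.compare_markers_anova(self.G)
        assert res.F == pytest.approx(f_hand, abs=1e-9)

    def test_two_groups_f_equals_t_squared(self):
        two = {k: self.G[k] for k in ("nose", "tail")}
        res = st.compare_markers_anova(two)
        # equal-variance two-sample t from the same data
        from scipy import stats

        t = stats.ttest_ind(self.G["nose"], self.G["tail"], equal_var=True).statistic
        assert res.F == pytest.approx(t**2, abs=1e-9)
        assert t**2 == pytest.approx(3.6556307751**2, abs=1e-6)  # frozen oracle

    def test_insufficient_data_raises(self):
        with pytest.raises(TrackValidationError):
            st.compare_markers_anova({"nose": [0.5, 0.6]})


class TestParameterRecovery:
    def test_sensitivity_falls_with_dropout_and_error_rises_with_jumps(self, small_run):
        """Measured performance tracks the injected artifact rates."""
        truth = small_run["truth"]
        geo = small_run["scenario"].geometry
        sens_values, err_values = [], []
        for dropout, jumps in ((0.005, 0.5), (0.05, 5.0), (0.2, 20.0)):
            art = st.ArtifactSpec(dropout_rate=dropout, jump_rate_per_1000=jumps)
            tracks, _ = st.degrade_to_predictions(truth, art, seed=31, geometry=geo)
            c = st.classify_confusion(tracks["nose"], truth, 100.0, window=(1, 2000))
            sens, err, _ = st.performance_metrics(c)
            sens_values.append(sens)
            err_values.append(err)
        assert sens_values == sorted(sens_values, reverse=True)
        assert err_values == sorted(err_values)
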