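"""Detection-performance metrics for predicted marker tracks.

Robustness of a tracker version is summarised per video and marker by the
predicted-image count PM, its ratio to the total image count TI, the
wrongly-predicted count WP and the percentage 100*WP/PM.  Performance over
an evaluation window (conventionally the first and last 1000 images) is a
frame-by-frame confusion classification against annotated ground truth:

    TP  marker visible and predicted within the match radius
    TN  hidden marker correctly not predicted
    FP  predicted but hidden, or predicted farther than the match radius
    FN  visible but not predicted

with sensitivity TP/(TP+FN), error rate FP/(TP+FP) and accuracy
(TP+TN)/(TP+FP+TN+FN).  "Hidden" means the annotation class not_visible;
partially occluded markers carry annotated positions and count as
expected-predicted.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import GroundTruthTable, MarkerTrack, TrackValidationError, VideoMeta

#: maximum distance (px) at which a prediction matches an annotated
#: position; ~3.7% of the 2.7K image width, generous for coarse body-area
#: markers yet far below typical distractor mislabels.
DEFAULT_MATCH_RADIUS_PX = 100.0


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies for one marker over one evaluation window."""

    TP: int
    TN: int
    FP: int
    FN: int
    marker: str = ""
    window: str = "custom"

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise TrackValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class PerVideoMetrics:
    """Robustness and performance summary for one (video, marker) pair."""

    video_id: str
    marker: str
    PM: int
    TI: int
    pm_ti: float
    WP: int
    pct_wp: float  # 100 * WP / PM; NaN when PM == 0
    sensitivity: float = nan
    error_rate: float = nan
    accuracy: float = nan


def prediction_rates(track: MarkerTrack, meta: VideoMeta) -> tuple[int, float]:
    """PM (count of predicted frames) and the ratio PM/TI."""
    if meta.n_frames <= 0:
        raise TrackValidationError("TI (total images) must be positive")
    if len(track) and int(track.frames.max()) > meta.n_frames:
        raise TrackValidationError(
            f"track frame {int(track.frames.max())} exceeds TI={meta.n_frames}"
        )
    pm = track.n_predicted
    return pm, pm / meta.n_frames


def classify_confusion(
    predicted: MarkerTrack,
    truth: GroundTruthTable,
    match_radius_px: float = DEFAULT_MATCH_RADIUS_PX,
    window: tuple[int, int] | None = None,
    window_label: str = "custom",
) -> ConfusionCounts:
    """Frame-by-frame confusion classification over ``window`` (inclusive).

    Every frame of the window must appear in the ground truth or the
    predicted track; a frame present in neither raises.
    """
    sub = truth.for_marker(predicted.marker)
    track_frames = set(int(f) for f in predicted.frames)
    if window is None:
        if len(sub) == 0:
            raise TrackValidationError("no ground truth for marker and no window given")
        window = (int(sub.index.min()), int(sub.index.max()))
    lo, hi = window
    if lo > hi:
        raise TrackValidationError("window start must be <= end")

    pred_pos: dict[int, tuple[bool, float, float]] = {
        int(f): (bool(p), float(x), float(y))
        for f, x, y, p in zip(predicted.frames, predicted.x, predicted.y, predicted.predicted)
    }
    tp = tn = fp = fn = 0
    for frame in range(lo, hi + 1):
        in_truth = frame in sub.index
        if not in_truth and frame not in track_frames:
            raise TrackValidationError(
                f"frame {frame} absent from both ground truth and track"
            )
        visible = bool(in_truth and sub.at[frame, "visibility"] != "not_visible")
        has_pred, px, py = pred_pos.get(frame, (False, nan, nan))
        if has_pred:
            if visible and sqrt(
                (px - sub.at[frame, "x"]) ** 2 + (py - sub.at[frame, "y"]) ** 2
            ) <= match_radius_px:
                tp += 1
            else:
                fp += 1
        else:
            if visible:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(
        TP=tp, TN=tn, FP=fp, FN=fn, marker=predicted.marker, window=window_label
    )


def performance_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, error_rate, accuracy); NaN when a denominator is 0."""
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else nan
    err = c.FP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else nan
    acc = (c.TP + c.TN) / c.total if c.total > 0 else nan
    return sens, err, acc


def aggregate_mean_sd(values: list[float]) -> tuple[float, float, int]:
    """Mean and sample SD (n-1) over defined values; NaN entries excluded.

    Returns ``(mean, sd, n)``; a single defined value gets sd = 0.0.
    Raises when every value is undefined.
    """
    arr = np.asarray([v for v in values if not np.isnan(v)], dtype=float)
    if arr.size == 0:
        raise TrackValidationError("all values undefined; nothing to aggregate")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd, int(arr.size)


@dataclass(frozen=True)
class PairedComparison:
    """Two-sided paired t-test result for one (quantity, marker) cell."""

    quantity: str
    marker: str
    t: float
    df: int
    p: float
    mean_difference: float
    n: int
    significant: bool
    degenerate: bool = False  # zero variance of differences


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float, bool]:
    d = a - b
    n = len(d)
    if n < 2:
        raise TrackValidationError("paired t-test needs >= 2 pairs")
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, n - 1, 1.0, False
        return nan, n - 1, nan, True  # constant non-zero shift: undefined t
    res = stats.ttest_rel(a, b)
    return float(res.statistic), n - 1, float(res.pvalue), False


def compare_versions(
    v_a: list[PerVideoMetrics],
    v_b: list[PerVideoMetrics],
    quantities: tuple[str, ...] = ("PM", "WP", "pm_ti", "pct_wp"),
    paired: bool = True,
    alpha: float = 0.05,
) -> list[PairedComparison]:
    """Compare two tracker versions per quantity and marker.

    Default is a paired two-sided Student's t-test, pairing videos by
    ``video_id`` (the same recordings scored by both versions); pass
    ``paired=False`` for Welch's unpaired variant.  Videos present in only
    one version raise, listing the offenders.  No multiple-testing
    correction is applied; significance is judged at ``alpha``.
    """
    df_a = pd.DataFrame([m.__dict__ for m in v_a])
    df_b = pd.DataFrame([m.__dict__ for m in v_b])
    results: list[PairedComparison] = []
    for marker in sorted(set(df_a["marker"]) | set(df_b["marker"])):
        a_m = df_a[df_a["marker"] == marker].set_index("video_id")
        b_m = df_b[df_b["marker"] == marker].set_index("video_id")
        if paired:
            only_a = sorted(set(a_m.index) - set(b_m.index))
            only_b = sorted(set(b_m.index) - set(a_m.index))
            if only_a or only_b:
                raise TrackValidationError(
                    f"unmatched videos for marker {marker}: "
                    f"only in first={only_a}, only in second={only_b}"
                )
            b_m = b_m.loc[a_m.index]
        for q in quantities:
            a_vals = a_m[q].to_numpy(dtype=float)
            b_vals = b_m[q].to_numpy(dtype=float)
            ok = ~np.isnan(a_vals) & ~np.isnan(b_vals) if paired else None
            if paired:
                a_use, b_use = a_vals[ok], b_vals[ok]
                t, dof, p, degen = _paired_t(a_use, b_use)
                n = len(a_use)
                md = float(np.mean(a_use - b_use)) if n else nan
            else:
                a_use = a_vals[~np.isnan(a_vals)]
                b_use = b_vals[~np.isnan(b_vals)]
                res = stats.ttest_ind(a_use, b_use, equal_var=False)
                t, p = float(res.statistic), float(res.pvalue)
                dof = int(res.df) if hasattr(res, "df") else len(a_use) + len(b_use) - 2
                degen = bool(np.isnan(t))
                n = min(len(a_use), len(b_use))
                md = float(a_use.mean() - b_use.mean())
            results.append(
                PairedComparison(
                    quantity=q,
                    marker=marker,
                    t=t,
                    df=dof,
                    p=p,
                    mean_difference=md,
                    n=n,
                    significant=bool(p < alpha) if not np.isnan(p) else False,
                    degenerate=degen,
                )
            )
    return results


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA across marker groups for one performance metric."""

    metric: str
    F: float
    df_between: int
    df_within: int
    p: float
    significant: bool


def compare_markers_anova(
    groups: dict[str, list[float]], metric: str = "metric", alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA over per-video metric values grouped by marker.

    Undefined (NaN) values are dropped per group; needs at least two groups
    with at least two defined values each.
    """
    clean = {
        k: np.asarray([v for v in vals if not np.isnan(v)], dtype=float)
        for k, vals in groups.items()
    }
    clean = {k: v for k, v in clean.items() if len(v) >= 2}
    if len(clean) < 2:
        raise TrackValidationError(
            "ANOVA needs >= 2 groups with >= 2 defined values each"
        )
    arrays = list(clean.values())
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    if all(np.allclose(a.var(ddof=0), 0) for a in arrays) and np.allclose(
        np.var(np.concatenate(arrays), ddof=0), 0
    ):
        f_stat, p = 0.0, 1.0  # identical groups: no variance anywhere
    else:
        res = stats.f_oneway(*arrays)
        f_stat, p = float(res.statistic), float(res.pvalue)
    return AnovaResult(
        metric=metric,
        F=f_stat,
        df_between=k - 1,
        df_within=n_total - k,
        p=p,
        significant=bool(p < alpha),
    )
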