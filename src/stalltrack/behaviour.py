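"""Case-study analytics on marker trajectories: occupancy, heat maps,
behaviour overlays, the weight-shifting signature, and a rule-based
behaviour classifier.

The weight-shifting signature is an elevated short-window variance of the
nose marker's vertical coordinate during rest — unsettled standing with
frequent weight shifts and forelimb extension, visible as an oscillation of
the y pixel while the horse otherwise stands still.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, nan

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .tracks import (
    BEHAVIOURS,
    BehaviourLabels,
    MarkerTrack,
    TrackValidationError,
)


@dataclass
class HeatMap:
    """Occupancy counts of predicted positions on a square-bin grid.

    ``grid[iy, ix]`` counts positions with x in [ix*s, (ix+1)*s) and y in
    [iy*s, (iy+1)*s); positions on the far image edge land in the last bin.
    """

    bin_size_px: int
    grid: np.ndarray
    total_mass: int

    def __post_init__(self) -> None:
        if int(self.grid.sum()) != self.total_mass:
            raise TrackValidationError("heat-map mass does not equal its grid sum")


@dataclass
class TimeBudget:
    """Frames / minutes / percent spent per key (region or behaviour class).

    ``percent`` is relative to ``total_frames`` (the evaluated frames).  For
    a disjoint, exhaustive key set the percents sum to 100.  When regions
    overlap, a frame accrues to each containing region and the number of
    multiply-counted frames is reported in ``overlap_frames``.
    """

    frames: dict[str, int]
    minutes: dict[str, float]
    percent: dict[str, float]
    total_frames: int
    overlap_frames: int = 0


def position_heatmap(
    track: MarkerTrack,
    bin_size_px: int = 50,
    width_px: int = 2704,
    height_px: int = 1520,
) -> HeatMap:
    """Bin predicted positions into an axis-aligned square grid."""
    if bin_size_px <= 0:
        raise TrackValidationError("bin_size_px must be positive")
    nx = ceil(width_px / bin_size_px)
    ny = ceil(height_px / bin_size_px)
    x = track.x[track.predicted]
    y = track.y[track.predicted]
    ix = np.clip((x // bin_size_px).astype(int), 0, nx - 1)
    iy = np.clip((y // bin_size_px).astype(int), 0, ny - 1)
    grid = np.zeros((ny, nx), dtype=np.int64)
    np.add.at(grid, (iy, ix), 1)
    return HeatMap(bin_size_px=bin_size_px, grid=grid, total_mass=int(len(x)))


def time_in_region(
    track: MarkerTrack,
    regions: dict[str, Polygon],
    fps_tlv: float = 2.0,
) -> TimeBudget:
    """Occupancy budget of the predicted positions over named stall regions.

    Containment is boundary-inclusive; a frame inside several (overlapping)
    regions accrues to each of them.  An implicit "elsewhere" key collects
    frames in no region, so over disjoint regions the partition is
    exhaustive and percents sum to 100.
    """
    if fps_tlv <= 0:
        raise TrackValidationError("fps_tlv must be positive")
    for name, poly in regions.items():
        if not isinstance(poly, Polygon):
            poly = Polygon(poly)
            regions = {**regions, name: poly}
        if not poly.is_valid:
            raise TrackValidationError(f"region '{name}' is not a simple polygon")
    x = track.x[track.predicted]
    y = track.y[track.predicted]
    total = int(len(x))
    frames: dict[str, int] = {}
    membership = np.zeros(total, dtype=int)
    for name in regions:
        # intersects == inside-or-on-boundary for points vs polygons
        inside = shapely.intersects_xy(regions[name], x, y)
        frames[name] = int(inside.sum())
        membership += inside.astype(int)
    frames["elsewhere"] = int((membership == 0).sum())
    overlap = int((membership > 1).sum())
    minutes = {k: v / (fps_tlv * 60.0) for k, v in frames.items()}
    percent = {k: (100.0 * v / total if total else 0.0) for k, v in frames.items()}
    return TimeBudget(
        frames=frames,
        minutes=minutes,
        percent=percent,
        total_frames=total,
        overlap_frames=overlap,
    )


def xy_series_with_behaviour(
    track: MarkerTrack, labels: BehaviourLabels
) -> pd.DataFrame:
    """Inner-join the track with behaviour labels on frame.

    Returns columns ``frame, x, y, behaviour``; unpredicted frames carry
    missing coordinates.  Raises when the frame ranges do not overlap.
    """
    t = track.to_frame()[["frame", "x", "y"]]
    b = pd.DataFrame({"frame": labels.frames, "behaviour": labels.behaviour})
    joined = t.merge(b, on="frame", how="inner").sort_values("frame").reset_index(drop=True)
    if joined.empty:
        raise TrackValidationError("track and behaviour labels share no frames")
    return joined


def rolling_dispersion(
    track: MarkerTrack, axis: str = "y", window_frames: int = 120
) -> pd.Series:
    """Centred rolling sample variance of one coordinate, indexed by frame.

    Unpredicted frames contribute nothing; positions of a frame with fewer
    than window/2 supporting predictions are returned as missing.
    """
    if window_frames < 2:
        raise TrackValidationError("window_frames must be >= 2")
    if axis not in ("x", "y"):
        raise TrackValidationError("axis must be 'x' or 'y'")
    values = pd.Series(
        getattr(track, axis), index=track.frames, name=f"var_{axis}"
    ).where(pd.Series(track.predicted, index=track.frames))
    return values.rolling(
        window_frames, center=True, min_periods=max(2, window_frames // 2)
    ).var(ddof=1)


@dataclass(frozen=True)
class RestSegment:
    """A maximal run of rest frames with its weight-shift diagnostics."""

    start_frame: int
    end_frame: int
    y_variance_px2: float
    variance_ratio: float
    flagged: bool

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def detect_weight_shifting(
    track: MarkerTrack,
    labels: BehaviourLabels,
    window_frames: int = 120,
    variance_ratio_threshold: float = 3.0,
    baseline_variance_px2: float | str = 5.0,
    min_segment_frames: int = 60,
    detrend_window_frames: int = 41,
    outlier_px: float = 50.0,
    settle_trim_frames: int = 60,
) -> list[RestSegment]:
    """Flag rest bouts whose vertical nose variance betrays weight shifting.

    The rolling y-variance is computed over rest frames only (non-rest
    frames are masked out first, so locomotion bordering a bout cannot bleed
    into its windows).  Before the variance analysis, positions deviating
    more than ``outlier_px`` from a rolling median are rejected — residual
    teleport mislabels, which the QC stage reports upstream, would otherwise
    swamp the postural signal — and a centred rolling mean of
    ``detrend_window_frames`` is subtracted, removing slow drift (the horse
    settling into its resting spot) while the faster weight-shift
    oscillation passes through.  The first ``settle_trim_frames`` of every
    bout are excluded outright (the horse is still coming to rest there).
    Each maximal rest segment is summarised by the median of its rolling
    variance over the remaining frames; bouts with fewer than
    ``min_segment_frames`` frames of support are reported unflagged.
    The summary is compared with
    ``variance_ratio_threshold`` times a reference variance.  The default
    reference is an absolute quiet-posture baseline (postural sway plus
    localisation noise, in px^2), so a recording whose every rest bout
    oscillates is still detected; pass ``baseline_variance_px2="median_rest"``
    to use the track's own median rest y-variance instead, which isolates
    unusual bouts within one recording.

    Returns every rest segment with its ratio; no rest frames gives [].
    """
    rest_frames = labels.frames[labels.behaviour == "rest"]
    if len(rest_frames) == 0:
        return []
    segments: list[tuple[int, int]] = []
    start = prev = int(rest_frames[0])
    for f in rest_frames[1:]:
        f = int(f)
        if f != prev + 1:
            segments.append((start, prev))
            start = f
        prev = f
    segments.append((start, prev))

    rest_mask = pd.Series(labels.behaviour == "rest", index=labels.frames)
    keep = pd.Series(
        track.predicted & rest_mask.reindex(track.frames, fill_value=False).to_numpy(),
        index=track.frames,
    )
    for lo, _hi in segments:  # drop the settling transient at bout onset
        keep.loc[lo : lo + settle_trim_frames - 1] = False
    y = pd.Series(track.y, index=track.frames).where(keep)
    med = y.rolling(
        detrend_window_frames, center=True, min_periods=max(2, detrend_window_frames // 2)
    ).median()
    y = y.where((y - med).abs() <= outlier_px)
    trend = y.rolling(
        detrend_window_frames, center=True, min_periods=max(2, detrend_window_frames // 2)
    ).mean()
    var_y = (y - trend).rolling(
        window_frames, center=True, min_periods=max(2, window_frames // 2)
    ).var(ddof=1)

    if baseline_variance_px2 == "median_rest":
        reference = float(var_y.reindex(rest_frames).median())
    else:
        reference = float(baseline_variance_px2)
    if not np.isfinite(reference) or reference <= 0:
        raise TrackValidationError("weight-shift reference variance must be positive")

    out: list[RestSegment] = []
    for lo, hi in segments:
        support = int(keep.loc[lo:hi].sum())
        seg_var = var_y.loc[lo:hi].where(keep.loc[lo:hi]).dropna()
        seg_stat = float(seg_var.median()) if len(seg_var) else nan
        ratio = seg_stat / reference if np.isfinite(seg_stat) else nan
        flagged = (
            np.isfinite(ratio)
            and ratio > variance_ratio_threshold
            and support >= min_segment_frames
        )
        out.append(
            RestSegment(
                start_frame=lo,
                end_frame=hi,
                y_variance_px2=seg_stat,
                variance_ratio=ratio,
                flagged=bool(flagged),
            )
        )
    return out


@dataclass
class ClassifierParams:
    """Thresholds of the rule-based behaviour classifier.

    Defaults are calibrated on the default synthetic scenario (they are not
    derived from real horses): displacements in px/frame at 2 images/s on a
    2.7K image, the feeding line as the image row below which the nose is
    taken to be in the trough.
    """

    move_threshold_px: float = 18.0
    feeding_line_y_px: float = 1100.0
    rest_threshold_px: float = 3.5
    smooth_window_frames: int = 7
    min_duration_frames: int = 5


_CASCADE_PRIORITY = {"moving": 0, "feeding": 1, "rest": 2, "standing_observation": 3}


def classify_behaviour(
    tracks: dict[str, MarkerTrack],
    params: ClassifierParams | None = None,
) -> BehaviourLabels:
    """Rule-cascade ethogram classification from nose and withers tracks.

    Per frame, in cascade order: smoothed withers displacement above
    ``move_threshold_px`` -> moving; nose below the feeding line (larger y;
    the trough sits low in the image) -> feeding; smoothed nose displacement
    below ``rest_threshold_px`` -> rest; otherwise standing observation.
    Short runs are then absorbed into their neighbours (minimum-duration
    filter, ties toward the earlier cascade class).  Gaps in prediction are
    bridged by carrying the last position forward.

    Requires the nose track predicted on at least half of its frames.
    """
    params = params or ClassifierParams()
    if "nose" not in tracks:
        raise TrackValidationError("classifier needs a nose track")
    nose = tracks["nose"]
    if len(nose) == 0 or nose.n_predicted / len(nose) < 0.5:
        raise TrackValidationError(
            "insufficient nose coverage: need predictions on >= 50% of frames"
        )
    withers = tracks.get("withers", nose)

    def _smoothed_displacement(track: MarkerTrack) -> pd.Series:
        s = pd.DataFrame({"x": track.x, "y": track.y}, index=track.frames)
        s = s.where(pd.Series(track.predicted, index=track.frames), other=np.nan)
        s = s.ffill().bfill()
        disp = np.hypot(s["x"].diff(), s["y"].diff())
        disp.iloc[0] = disp.iloc[1] if len(disp) > 1 else 0.0
        return disp.rolling(
            params.smooth_window_frames, center=True, min_periods=1
        ).mean()

    nose_pos = pd.DataFrame({"x": nose.x, "y": nose.y}, index=nose.frames)
    nose_pos = nose_pos.where(pd.Series(nose.predicted, index=nose.frames)).ffill().bfill()
    disp_withers = _smoothed_displacement(withers).reindex(nose.frames).ffill().bfill()
    disp_nose = _smoothed_displacement(nose)

    labels = np.where(
        disp_withers.to_numpy() > params.move_threshold_px,
        "moving",
        np.where(
            nose_pos["y"].to_numpy() > params.feeding_line_y_px,
            "feeding",
            np.where(
                disp_nose.to_numpy() < params.rest_threshold_px,
                "rest",
                "standing_observation",
            ),
        ),
    ).astype(object)

    labels = _min_duration_filter(labels, params.min_duration_frames)
    return BehaviourLabels(frames=nose.frames, behaviour=labels)


def _min_duration_filter(labels: np.ndarray, min_frames: int) -> np.ndarray:
    """Absorb runs shorter than ``min_frames`` into a neighbouring class."""
    if min_frames <= 1 or len(labels) == 0:
        return labels
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        runs: list[tuple[int, int, str]] = []
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                runs.append((start, i - 1, labels[start]))
                start = i
        if len(runs) <= 1:
            break
        for k, (lo, hi, cls) in enumerate(runs):
            if hi - lo + 1 >= min_frames:
                continue
            neighbours = []
            if k > 0:
                neighbours.append(runs[k - 1][2])
            if k + 1 < len(runs):
                neighbours.append(runs[k + 1][2])
            neighbours = [c for c in neighbours if c != cls]
            if not neighbours:
                continue
            target = min(neighbours, key=lambda c: _CASCADE_PRIORITY[c])
            labels[lo : hi + 1] = target
            changed = True
            break  # recompute runs after each merge
    return labels


def behaviour_time_budget(labels: BehaviourLabels, fps_tlv: float = 2.0) -> TimeBudget:
    """Frames, minutes and percent per ethogram class (absent classes get 0)."""
    if len(labels) == 0:
        raise TrackValidationError("behaviour labels are empty")
    if fps_tlv <= 0:
        raise TrackValidationError("fps_tlv must be positive")
    total = len(labels)
    frames = {b: int((labels.behaviour == b).sum()) for b in BEHAVIOURS}
    minutes = {b: v / (fps_tlv * 60.0) for b, v in frames.items()}
    percent = {b: 100.0 * v / total for b, v in frames.items()}
    return TimeBudget(frames=frames, minutes=minutes, percent=percent, total_frames=total)
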