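"""Mislabel screening for marker tracks: teleport jumps and missing runs.

A jump is a displacement of more than 200 px between two consecutive
predicted frames — the signature of a detector latching onto a wrong object
(waterer, manure pile, a person's shoes).  The screening statistic

    ((X2 - X1) * (F2 - F1))^2 + ((Y2 - Y1) * (F2 - F1))^2

is reported verbatim for every flagged pair; thresholding itself uses the
Euclidean displacement, scaled by the frame gap when predictions are
missing in between (gap g > 1 flags when displacement > g * threshold,
allowing genuine motion to accumulate across the gap).

A missing run is a stretch of more than 30 consecutive frames where a
marker expected to be visible goes unpredicted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import GroundTruthTable, MarkerTrack, TrackValidationError

JUMP_THRESHOLD_PX = 200.0
MIN_MISSING_RUN = 30


@dataclass(frozen=True)
class QCSegment:
    """A flagged video interval needing visual inspection / re-annotation."""

    video_id: str
    marker: str
    start_frame: int
    end_frame: int
    reason: str  # "jump" or "missing_run"
    statistic_value: float = float("nan")  # squared-px screening statistic
    displacement_px: float = float("nan")

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise TrackValidationError("start_frame must be <= end_frame")
        if self.reason not in ("jump", "missing_run"):
            raise TrackValidationError("reason must be 'jump' or 'missing_run'")


def jump_statistic(
    x1: float, y1: float, frame1: int, x2: float, y2: float, frame2: int
) -> tuple[float, float]:
    """Screening statistic and Euclidean displacement for one frame pair.

    Returns ``(statistic, displacement_px)`` where the statistic is the
    squared-pixel quantity above and the displacement is
    sqrt((x2-x1)^2 + (y2-y1)^2).  Requires frame2 > frame1.
    """
    if frame2 <= frame1:
        raise TrackValidationError(f"frame2 ({frame2}) must be greater than frame1 ({frame1})")
    if not all(np.isfinite(v) for v in (x1, y1, x2, y2)):
        raise TrackValidationError("positions must be finite")
    gap = frame2 - frame1
    stat = ((x2 - x1) * gap) ** 2 + ((y2 - y1) * gap) ** 2
    disp = float(np.hypot(x2 - x1, y2 - y1))
    return float(stat), disp


def detect_jumps(
    track: MarkerTrack,
    threshold_px: float = JUMP_THRESHOLD_PX,
    video_id: str = "video",
    scale_threshold_by_gap: bool = True,
) -> list[QCSegment]:
    """Flag marker misplacements between successive predicted frames.

    Consecutive frames (gap 1) are flagged when displacement exceeds
    ``threshold_px`` (strictly).  Pairs separated by a prediction gap g > 1
    are flagged when displacement exceeds g * threshold_px; set
    ``scale_threshold_by_gap=False`` to apply the unscaled threshold to
    every successive pair instead.
    """
    f = track.predicted_frames()
    if len(f) < 2:
        return []
    x = track.x[track.predicted]
    y = track.y[track.predicted]
    gaps = np.diff(f).astype(float)
    disp = np.hypot(np.diff(x), np.diff(y))
    eff = threshold_px * gaps if scale_threshold_by_gap else threshold_px
    hits = np.flatnonzero(disp > eff)
    segments = []
    for i in hits:
        stat, d = jump_statistic(x[i], y[i], int(f[i]), x[i + 1], y[i + 1], int(f[i + 1]))
        segments.append(
            QCSegment(
                video_id=video_id,
                marker=track.marker,
                start_frame=int(f[i]),
                end_frame=int(f[i + 1]),
                reason="jump",
                statistic_value=stat,
                displacement_px=d,
            )
        )
    return segments


def detect_missing_runs(
    track: MarkerTrack,
    expected: GroundTruthTable | None = None,
    min_run: int = MIN_MISSING_RUN,
    video_id: str = "video",
) -> list[QCSegment]:
    """Flag runs of more than ``min_run`` consecutive unpredicted frames.

    Only frames where the marker is *expected* visible count toward a run;
    with ground truth supplied, frames annotated not_visible interrupt
    nothing and accrue nothing (they are excluded from run length).  Without
    ground truth every frame is treated as expected-visible — a conservative
    screening mode.
    """
    if len(track) == 0:
        return []
    if expected is not None:
        vis = expected.visible_mask(track.marker)
        expected_visible = vis.reindex(track.frames, fill_value=False).to_numpy()
    else:
        expected_visible = np.ones(len(track), dtype=bool)

    missing = expected_visible & ~track.predicted
    segments = []
    i = 0
    n = len(track)
    while i < n:
        if missing[i]:
            j = i
            while j + 1 < n and missing[j + 1]:
                j += 1
            run_len = j - i + 1
            if run_len > min_run:
                segments.append(
                    QCSegment(
                        video_id=video_id,
                        marker=track.marker,
                        start_frame=int(track.frames[i]),
                        end_frame=int(track.frames[j]),
                        reason="missing_run",
                    )
                )
            i = j + 1
        else:
            i += 1
    return segments


def wrongly_predicted_count(segments: list[QCSegment]) -> int:
    """WP: distinct predicted frames participating in >= 1 jump segment."""
    frames: set[tuple[str, int]] = set()
    for seg in segments:
        if seg.reason == "jump":
            frames.add((seg.marker, seg.start_frame))
            frames.add((seg.marker, seg.end_frame))
    return len(frames)


def qc_report(
    tracks: dict[str, MarkerTrack],
    ground_truth: GroundTruthTable | None = None,
    jump_threshold_px: float = JUMP_THRESHOLD_PX,
    min_missing_run: int = MIN_MISSING_RUN,
    video_id: str = "video",
) -> tuple[dict[str, int], pd.DataFrame]:
    """Screen all markers; return per-marker WP counts and the segment table.

    The table (columns ``video_id, marker, start_frame, end_frame, reason,
    statistic_value, displacement_px``) is sorted by start frame and is the
    hand-off artifact for visual inspection and re-annotation.
    """
    all_segments: list[QCSegment] = []
    wp: dict[str, int] = {}
    for marker in sorted(tracks):
        track = tracks[marker]
        jumps = detect_jumps(track, jump_threshold_px, video_id=video_id)
        runs = detect_missing_runs(
            track, ground_truth, min_run=min_missing_run, video_id=video_id
        )
        wp[marker] = wrongly_predicted_count(jumps)
        all_segments.extend(jumps)
        all_segments.extend(runs)
    table = pd.DataFrame(
        [seg.__dict__ for seg in all_segments],
        columns=[
            "video_id",
            "marker",
            "start_frame",
            "end_frame",
            "reason",
            "statistic_value",
            "displacement_px",
        ],
    ).sort_values(["start_frame", "marker", "reason"], kind="stable").reset_index(drop=True)
    return wp, table
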