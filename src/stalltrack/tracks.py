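"""Core in-memory containers for marker trajectories and annotations.

Coordinate convention: origin at the top-left image corner, x rightward,
y downward, sub-pixel float positions.  Frames are indexed from 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Tracked anatomical keypoints: nose (mouth + nostril area), withers
#: (highest point where the neck merges into the back), tail (tail base).
MARKERS = ("nose", "withers", "tail")

#: Ethogram classes, in their conventional coding order (1..4).
BEHAVIOURS = ("standing_observation", "rest", "feeding", "moving")

#: Annotation visibility classes for a marker in a frame.
VISIBILITY_CLASSES = ("visible", "occluded25", "occluded50", "occluded75", "not_visible")


class TrackValidationError(ValueError):
    """Raised when a trajectory/annotation table violates an invariant."""


@dataclass(frozen=True)
class VideoMeta:
    """Metadata of one time-lapse video.

    ``n_frames`` is the total image count (TI); ``fps_tlv`` the time-lapse
    acquisition rate in images per second (nominally 2).
    """

    video_id: str = "video"
    n_frames: int = 1
    fps_tlv: float = 2.0
    width_px: int = 2704
    height_px: int = 1520

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise TrackValidationError("n_frames must be positive")
        if self.fps_tlv <= 0:
            raise TrackValidationError("fps_tlv must be positive")
        if self.width_px <= 0 or self.height_px <= 0:
            raise TrackValidationError("image dimensions must be positive")


@dataclass
class MarkerTrack:
    """Frame-indexed pixel positions of one marker.

    ``predicted`` marks frames where the tracker emitted a position;
    positions on unpredicted frames are NaN and carry no meaning.
    """

    marker: str
    frames: np.ndarray  # int, strictly increasing
    x: np.ndarray       # float px
    y: np.ndarray       # float px
    predicted: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=bool)
        n = len(self.frames)
        if not (len(self.x) == len(self.y) == len(self.predicted) == n):
            raise TrackValidationError(
                f"{self.marker}: column lengths differ"
            )
        if n > 1 and not np.all(np.diff(self.frames) > 0):
            raise TrackValidationError(
                f"{self.marker}: frame indices must be strictly increasing"
            )
        if np.any(~np.isfinite(self.x[self.predicted])) or np.any(
            ~np.isfinite(self.y[self.predicted])
        ):
            raise TrackValidationError(
                f"{self.marker}: predicted frames must have finite coordinates"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_predicted(self) -> int:
        return int(self.predicted.sum())

    def predicted_frames(self) -> np.ndarray:
        return self.frames[self.predicted]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "marker": self.marker,
                "x": self.x,
                "y": self.y,
                "predicted": self.predicted,
            }
        )


@dataclass
class GroundTruthTable:
    """Per-frame, per-marker true positions with 5-level visibility.

    Backed by a DataFrame with columns ``frame, marker, x, y, visibility``.
    A position is present iff visibility != "not_visible".
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"frame", "marker", "x", "y", "visibility"}
        missing = required - set(self.data.columns)
        if missing:
            raise TrackValidationError(f"ground truth missing columns {sorted(missing)}")
        bad = set(self.data["visibility"]) - set(VISIBILITY_CLASSES)
        if bad:
            raise TrackValidationError(
                f"unknown visibility classes {sorted(bad)}; permitted: {VISIBILITY_CLASSES}"
            )
        if self.data.duplicated(["frame", "marker"]).any():
            dup = self.data[self.data.duplicated(["frame", "marker"])].iloc[0]
            raise TrackValidationError(
                f"duplicate (frame={dup['frame']}, marker={dup['marker']}) annotation"
            )
        hidden = self.data["visibility"] == "not_visible"
        has_pos = self.data["x"].notna() & self.data["y"].notna()
        if (hidden & has_pos).any():
            raise TrackValidationError("not_visible rows must not carry positions")
        if (~hidden & ~has_pos).any():
            raise TrackValidationError("rows with visibility != not_visible need positions")
        self.data = self.data.sort_values(["frame", "marker"]).reset_index(drop=True)

    def for_marker(self, marker: str) -> pd.DataFrame:
        return self.data[self.data["marker"] == marker].set_index("frame")

    def visible_mask(self, marker: str) -> pd.Series:
        """True where the marker was annotated with a position (incl. occluded)."""
        sub = self.for_marker(marker)
        return sub["visibility"] != "not_visible"

    def to_track(self, marker: str) -> MarkerTrack:
        """Ideal track of a marker: predicted wherever a true position exists."""
        sub = self.for_marker(marker)
        vis = (sub["visibility"] != "not_visible").to_numpy()
        return MarkerTrack(
            marker=marker,
            frames=sub.index.to_numpy(),
            x=np.where(vis, sub["x"].to_numpy(), np.nan),
            y=np.where(vis, sub["y"].to_numpy(), np.nan),
            predicted=vis,
        )


@dataclass
class BehaviourLabels:
    """Frame-indexed ethogram labels (one of the four classes per frame)."""

    frames: np.ndarray
    behaviour: np.ndarray  # str entries from BEHAVIOURS

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.behaviour = np.asarray(self.behaviour, dtype=object)
        if len(self.frames) != len(self.behaviour):
            raise TrackValidationError("frames and behaviour lengths differ")
        if len(np.unique(self.frames)) != len(self.frames):
            raise TrackValidationError("at most one behaviour label per frame")
        bad = set(self.behaviour) - set(BEHAVIOURS)
        if bad:
            raise TrackValidationError(
                f"unknown behaviour classes {sorted(bad)}; permitted: {BEHAVIOURS}"
            )

    def __len__(self) -> int:
        return len(self.frames)

    def as_series(self) -> pd.Series:
        return pd.Series(self.behaviour, index=self.frames, name="behaviour")
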