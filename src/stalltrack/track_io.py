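"""CSV readers/writers for trajectory, annotation and behaviour tables.

Dialect (fixed by this package; pose trackers differ and the upstream tool's
schema is not public — adapt other exports with a thin shim):

* track CSV:        header ``frame,marker,x,y,predicted``
* ground-truth CSV: header ``frame,marker,x,y,visibility``
* behaviour CSV:    header ``frame,behaviour`` (names or integer codes 1-4)

All files are UTF-8, comma-separated, "." decimal, frames indexed from 1.
Video metadata travels in ``# key=value`` comment lines above the header;
a YAML sidecar (``<path>.meta.yaml``) is honoured as an alternative.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tracks import (
    BEHAVIOURS,
    BehaviourLabels,
    GroundTruthTable,
    MarkerTrack,
    TrackValidationError,
    VideoMeta,
)

_FLOAT_FMT = "%.3f"

#: integer behaviour codes as conventionally used in scoring tools (1-based)
BEHAVIOUR_CODES = {i + 1: b for i, b in enumerate(BEHAVIOURS)}


def subsample_training_frames(
    n_available: int, stride: int = 10, limit: int = 2500
) -> list[int]:
    """1-based frame indices used to build an annotation training set.

    Selects every ``stride``-th frame among the first ``limit`` frames:
    multiples of the stride strictly below the limit and no larger than
    ``n_available``.  Under the defaults (every 10th of the first 2500)
    this yields frames 10, 20, ..., 2490 — 249 frames per video.
    """
    if n_available < 1 or stride < 1 or limit < 1:
        raise TrackValidationError("n_available, stride and limit must be >= 1")
    top = min(limit - 1, n_available)
    return list(range(stride, top + 1, stride))


def _meta_header_lines(meta: VideoMeta, extra: dict | None = None) -> list[str]:
    fields = {
        "video_id": meta.video_id,
        "n_frames": meta.n_frames,
        "fps_tlv": meta.fps_tlv,
        "width_px": meta.width_px,
        "height_px": meta.height_px,
    }
    if extra:
        fields.update(extra)
    return [f"# {k}={v}" for k, v in fields.items()]


def _read_header_meta(path: Path) -> dict:
    fields: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                fields[key.strip()] = value.strip()
    sidecar = Path(str(path) + ".meta.yaml")
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            fields.update(yaml.safe_load(fh) or {})
    return fields


def _meta_from_fields(fields: dict, fallback_frames: int) -> VideoMeta:
    return VideoMeta(
        video_id=str(fields.get("video_id", "video")),
        n_frames=int(fields.get("n_frames", fallback_frames)),
        fps_tlv=float(fields.get("fps_tlv", 2.0)),
        width_px=int(fields.get("width_px", 2704)),
        height_px=int(fields.get("height_px", 1520)),
    )


def _read_csv_checked(path: Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:  # pragma: no cover - message pass-through
        raise TrackValidationError(f"{path}: malformed CSV ({exc})") from exc
    if df.empty and not set(required) <= set(df.columns):
        return pd.DataFrame(columns=required)
    missing = set(required) - set(df.columns)
    if missing:
        raise TrackValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def _locate(path: Path, df: pd.DataFrame, row_positions: np.ndarray) -> str:
    """Human-readable line numbers for offending rows (1-based, incl. header)."""
    with open(path, encoding="utf-8") as fh:
        n_comment = 0
        for line in fh:
            if line.startswith("#"):
                n_comment += 1
            else:
                break
    lines = [int(p) + n_comment + 2 for p in row_positions]  # +header +1-based
    return ", ".join(f"line {ln}" for ln in lines)


def read_track_csv(path: str | Path) -> tuple[dict[str, MarkerTrack], VideoMeta]:
    """Read predicted marker tracks.

    Rows with missing coordinates (or ``predicted`` false) become
    unpredicted frames.  Duplicate (frame, marker) rows and malformed frame
    indices raise errors naming the file line.
    """
    path = Path(path)
    df = _read_csv_checked(path, ["frame", "marker", "x", "y", "predicted"])
    fields = _read_header_meta(path)
    if df.empty:
        return {}, _meta_from_fields(fields, 1)

    if not np.issubdtype(df["frame"].dtype, np.integer):
        bad = pd.to_numeric(df["frame"], errors="coerce")
        if bad.isna().any() or (bad != bad.round()).any():
            pos = np.flatnonzero(bad.isna() | (bad != bad.round()))[:3]
            raise TrackValidationError(
                f"{path}: non-integer frame index at {_locate(path, df, pos)}"
            )
        df["frame"] = bad.astype(np.int64)
    dup = df.duplicated(["frame", "marker"], keep=False)
    if dup.any():
        pos = np.flatnonzero(df.duplicated(["frame", "marker"]))[:3]
        first = df.iloc[pos[0]]
        raise TrackValidationError(
            f"{path}: duplicate (frame={first['frame']}, marker={first['marker']}) "
            f"at {_locate(path, df, pos)}"
        )

    pred = df["predicted"]
    if pred.dtype == object:
        pred = pred.astype(str).str.strip().str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        )
        if pred.isna().any():
            pos = np.flatnonzero(pred.isna())[:3]
            raise TrackValidationError(
                f"{path}: unparseable 'predicted' flag at {_locate(path, df, pos)}"
            )
    df["predicted"] = pred.astype(bool)
    df.loc[df["x"].isna() | df["y"].isna(), "predicted"] = False

    tracks: dict[str, MarkerTrack] = {}
    for marker, sub in df.groupby("marker", sort=True):
        sub = sub.sort_values("frame")
        tracks[str(marker)] = MarkerTrack(
            marker=str(marker),
            frames=sub["frame"].to_numpy(),
            x=np.where(sub["predicted"], sub["x"], np.nan),
            y=np.where(sub["predicted"], sub["y"], np.nan),
            predicted=sub["predicted"].to_numpy(),
        )
    meta = _meta_from_fields(fields, int(df["frame"].max()))
    return tracks, meta


def write_track_csv(
    tracks: dict[str, MarkerTrack],
    meta: VideoMeta,
    path: str | Path,
    extra_header: dict | None = None,
) -> None:
    """Write tracks deterministically: frame-major, markers alphabetical,
    fixed 3-decimal coordinate precision."""
    path = Path(path)
    frames = []
    for marker in sorted(tracks):
        frames.append(tracks[marker].to_frame())
    header = _meta_header_lines(meta, extra_header)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write("frame,marker,x,y,predicted\n")
        if frames:
            df = pd.concat(frames).sort_values(["frame", "marker"], kind="stable")
            for row in df.itertuples(index=False):
                x = "" if math.isnan(row.x) else _FLOAT_FMT % row.x
                y = "" if math.isnan(row.y) else _FLOAT_FMT % row.y
                fh.write(f"{row.frame},{row.marker},{x},{y},{str(bool(row.predicted)).lower()}\n")


def read_ground_truth_csv(path: str | Path) -> GroundTruthTable:
    """Read a frame x marker annotation table with 5-level visibility."""
    path = Path(path)
    df = _read_csv_checked(path, ["frame", "marker", "x", "y", "visibility"])
    if df.empty:
        return GroundTruthTable(pd.DataFrame(columns=["frame", "marker", "x", "y", "visibility"]))
    df["frame"] = df["frame"].astype(np.int64)
    return GroundTruthTable(df)


def write_ground_truth_csv(
    truth: GroundTruthTable, path: str | Path, meta: VideoMeta | None = None
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if meta is not None:
            fh.write("\n".join(_meta_header_lines(meta)) + "\n")
        fh.write("frame,marker,x,y,visibility\n")
        for row in truth.data.itertuples(index=False):
            x = "" if pd.isna(row.x) else _FLOAT_FMT % row.x
            y = "" if pd.isna(row.y) else _FLOAT_FMT % row.y
            fh.write(f"{row.frame},{row.marker},{x},{y},{row.visibility}\n")


def read_behaviour_csv(path: str | Path) -> BehaviourLabels:
    """Read frame-indexed ethogram labels.

    Accepts either class names or the conventional integer codes
    1=standing_observation, 2=rest, 3=feeding, 4=moving.
    """
    path = Path(path)
    df = _read_csv_checked(path, ["frame", "behaviour"])
    if df.empty:
        return BehaviourLabels(frames=np.array([], dtype=np.int64), behaviour=np.array([], dtype=object))
    values = df["behaviour"]
    if np.issubdtype(values.dtype, np.number):
        mapped = values.map(BEHAVIOUR_CODES)
        if mapped.isna().any():
            bad = sorted(set(values[mapped.isna()]))
            raise TrackValidationError(
                f"{path}: unknown behaviour codes {bad}; permitted codes: "
                f"{sorted(BEHAVIOUR_CODES)}"
            )
        values = mapped
    else:
        values = values.astype(str).str.strip()
        bad = sorted(set(values) - set(BEHAVIOURS))
        if bad:
            raise TrackValidationError(
                f"{path}: unknown behaviour classes {bad}; permitted: {list(BEHAVIOURS)}"
            )
    return BehaviourLabels(
        frames=df["frame"].to_numpy(dtype=np.int64),
        behaviour=values.to_numpy(dtype=object),
    )


def write_behaviour_csv(labels: BehaviourLabels, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("frame,behaviour\n")
        for f, b in zip(labels.frames, labels.behaviour):
            fh.write(f"{f},{b}\n")
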