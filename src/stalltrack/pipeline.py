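"""End-to-end orchestration: simulate -> degrade -> QC -> validate ->
case-study analytics, from one config, into a reproducible report bundle.

Every output CSV starts with ``# key=value`` comment lines recording the
seed and a hash of the effective configuration, so a bundle can be matched
to the run that produced it; reruns with identical (config, seed) are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import behaviour as bhv
from . import qc as qcmod
from . import simulate as sim
from . import track_io, validation
from .tracks import BehaviourLabels, GroundTruthTable, MarkerTrack, VideoMeta

log = logging.getLogger("stalltrack")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input mode: a synthetic ``scenario`` mapping, or explicit
    file paths (``tracks_path`` + optional ``truth_path``/``behaviour_path``).
    """

    scenario: dict[str, Any] | None = None
    tracks_path: str | None = None
    truth_path: str | None = None
    behaviour_path: str | None = None
    out_dir: str = "stalltrack_out"
    seed: int = 0
    n_videos: int = 8                 # synthetic videos per version
    jump_threshold_px: float = qcmod.JUMP_THRESHOLD_PX
    min_missing_run: int = qcmod.MIN_MISSING_RUN
    match_radius_px: float = validation.DEFAULT_MATCH_RADIUS_PX
    confusion_window: int = 1000      # first/last window length
    artifacts_b: dict[str, Any] | None = None  # second version for comparison
    classifier: dict[str, Any] | None = None
    bin_size_px: int = 50
    variance_window_frames: int = 120

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.tracks_path is None):
            raise ValueError("supply exactly one of: scenario config, tracks_path")

    def config_hash(self) -> str:
        # identifies the scientific configuration; the output location is
        # excluded so reruns into different directories hash identically
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "out_dir"},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _header(cfg: RunConfig, extra: dict | None = None) -> str:
    fields = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    if extra:
        fields.update(extra)
    return "".join(f"# {k}={v}\n" for k, v in fields.items())


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig, extra: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header(cfg, extra))
        df.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")


def _synthetic_videos(
    cfg: RunConfig, artifacts_override: dict[str, Any] | None = None
) -> list[tuple[str, dict[str, MarkerTrack], GroundTruthTable, BehaviourLabels, VideoMeta, list]]:
    """Simulate cfg.n_videos scenarios with per-video derived seeds."""
    videos = []
    base = dict(cfg.scenario or {})
    if artifacts_override is not None:
        base["artifacts"] = artifacts_override
    for i in range(cfg.n_videos):
        vc = dict(base)
        vc["seed"] = int((cfg.seed + 1) * 10_000 + i) % (2**31)
        vc["video_id"] = vc.get("video_id", "synthetic") + f"_{i:02d}"
        scenario = sim.build_scenario(vc)
        truth, labels = sim.simulate_tracks(scenario)
        tracks, art_log = sim.degrade_to_predictions(
            truth, scenario.artifacts, seed=scenario.seed + 1, geometry=scenario.geometry
        )
        meta = VideoMeta(
            video_id=scenario.video_id,
            n_frames=scenario.n_frames,
            fps_tlv=scenario.fps_tlv,
            width_px=scenario.geometry.width_px,
            height_px=scenario.geometry.height_px,
        )
        videos.append((scenario.video_id, tracks, truth, labels, meta, art_log))
    return videos


def _load_videos(cfg: RunConfig):
    tracks, meta = track_io.read_track_csv(cfg.tracks_path)
    truth = track_io.read_ground_truth_csv(cfg.truth_path) if cfg.truth_path else None
    labels = track_io.read_behaviour_csv(cfg.behaviour_path) if cfg.behaviour_path else None
    return [(meta.video_id, tracks, truth, labels, meta, [])]


def _per_video_metrics(
    video_id: str,
    tracks: dict[str, MarkerTrack],
    truth: GroundTruthTable | None,
    meta: VideoMeta,
    cfg: RunConfig,
) -> tuple[list[validation.PerVideoMetrics], pd.DataFrame, list[dict]]:
    wp, qc_table = qcmod.qc_report(
        tracks,
        truth,
        jump_threshold_px=cfg.jump_threshold_px,
        min_missing_run=cfg.min_missing_run,
        video_id=video_id,
    )
    metrics: list[validation.PerVideoMetrics] = []
    confusion_rows: list[dict] = []
    for marker in sorted(tracks):
        track = tracks[marker]
        pm, pm_ti = validation.prediction_rates(track, meta)
        sens = err = acc = float("nan")
        if truth is not None:
            w = min(cfg.confusion_window, meta.n_frames)
            windows = {"first1000": (1, w)}
            if meta.n_frames > w:
                windows["last1000"] = (meta.n_frames - w + 1, meta.n_frames)
            parts = []
            for label, win in windows.items():
                c = validation.classify_confusion(
                    track, truth, cfg.match_radius_px, window=win, window_label=label
                )
                parts.append(c)
                confusion_rows.append(
                    {
                        "video_id": video_id,
                        "marker": marker,
                        "window": label,
                        "TP": c.TP,
                        "TN": c.TN,
                        "FP": c.FP,
                        "FN": c.FN,
                    }
                )
            pooled = validation.ConfusionCounts(
                TP=sum(c.TP for c in parts),
                TN=sum(c.TN for c in parts),
                FP=sum(c.FP for c in parts),
                FN=sum(c.FN for c in parts),
                marker=marker,
                window="first+last",
            )
            sens, err, acc = validation.performance_metrics(pooled)
        metrics.append(
            validation.PerVideoMetrics(
                video_id=video_id,
                marker=marker,
                PM=pm,
                TI=meta.n_frames,
                pm_ti=pm_ti,
                WP=wp.get(marker, 0),
                pct_wp=100.0 * wp.get(marker, 0) / pm if pm else float("nan"),
                sensitivity=sens,
                error_rate=err,
                accuracy=acc,
            )
        )
    return metrics, qc_table, confusion_rows


def run_validation(cfg: RunConfig) -> dict[str, Any]:
    """Robustness + performance workflow; writes the validation bundle.

    Produces per-video metrics, the QC segment report, windowed confusion
    counts with performance metrics, and — when a second artifact version is
    configured — the paired version comparison and the across-marker ANOVA.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    videos = _synthetic_videos(cfg) if cfg.scenario is not None else _load_videos(cfg)
    log.info("validation: %d video(s) in", len(videos))

    all_metrics: list[validation.PerVideoMetrics] = []
    qc_tables, confusion_rows = [], []
    for video_id, tracks, truth, _labels, meta, _art in videos:
        m, qc_table, conf = _per_video_metrics(video_id, tracks, truth, meta, cfg)
        all_metrics.extend(m)
        qc_tables.append(qc_table)
        confusion_rows.extend(conf)

    metrics_df = pd.DataFrame([m.__dict__ for m in all_metrics])
    _write_csv(metrics_df, out / "per_video_metrics.csv", cfg)
    nonempty = [t for t in qc_tables if not t.empty] or qc_tables[:1]
    _write_csv(pd.concat(nonempty, ignore_index=True), out / "qc_report.csv", cfg)
    _write_csv(pd.DataFrame(confusion_rows), out / "confusion_counts.csv", cfg)

    results: dict[str, Any] = {
        "metrics": all_metrics,
        "metrics_df": metrics_df,
        "files": [out / "per_video_metrics.csv", out / "qc_report.csv", out / "confusion_counts.csv"],
    }

    anova_rows = []
    if metrics_df["sensitivity"].notna().any():
        for metric in ("sensitivity", "error_rate", "accuracy"):
            groups = {
                marker: metrics_df.loc[metrics_df["marker"] == marker, metric].tolist()
                for marker in sorted(metrics_df["marker"].unique())
            }
            try:
                res = validation.compare_markers_anova(groups, metric=metric)
            except Exception as exc:  # insufficient groups
                log.warning("ANOVA on %s skipped: %s", metric, exc)
                continue
            anova_rows.append(res.__dict__)
    if anova_rows:
        _write_csv(pd.DataFrame(anova_rows), out / "marker_anova.csv", cfg)
        results["files"].append(out / "marker_anova.csv")
        results["anova"] = anova_rows

    if cfg.artifacts_b is not None and cfg.scenario is not None:
        videos_b = _synthetic_videos(cfg, artifacts_override=cfg.artifacts_b)
        metrics_b: list[validation.PerVideoMetrics] = []
        for video_id, tracks, truth, _labels, meta, _art in videos_b:
            m, _, _ = _per_video_metrics(video_id, tracks, truth, meta, cfg)
            metrics_b.extend(m)
        comparisons = validation.compare_versions(all_metrics, metrics_b)
        comp_df = pd.DataFrame([c.__dict__ for c in comparisons])
        _write_csv(comp_df, out / "version_comparison.csv", cfg)
        results["comparison"] = comparisons
        results["files"].append(out / "version_comparison.csv")
    log.info("validation: %d metric rows out", len(metrics_df))
    return results


def run_case_study(cfg: RunConfig) -> dict[str, Any]:
    """Case-study analytics bundle for one recording.

    Writes: position scatter, heat-map grid, time-in-region budget, x/y
    series with behaviour overlay, weight-shift flags, and the behaviour
    time budget.  Without supplied behaviour labels the rule-based
    classifier provides them (provenance noted in the file headers).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.scenario is not None:
        scenario = sim.build_scenario({**cfg.scenario, "seed": cfg.scenario.get("seed", cfg.seed)})
        truth, labels = sim.simulate_tracks(scenario)
        tracks, _ = sim.degrade_to_predictions(
            truth, scenario.artifacts, seed=scenario.seed + 1, geometry=scenario.geometry
        )
        meta = VideoMeta(
            video_id=scenario.video_id,
            n_frames=scenario.n_frames,
            fps_tlv=scenario.fps_tlv,
            width_px=scenario.geometry.width_px,
            height_px=scenario.geometry.height_px,
        )
        regions = scenario.geometry.regions
        labels_provenance = "generator"
    else:
        (_, tracks, truth, labels, meta, _), = _load_videos(cfg)
        regions = sim.default_geometry().regions
        labels_provenance = "file" if labels is not None else "classifier"

    if labels is None:
        params = bhv.ClassifierParams(**(cfg.classifier or {}))
        labels = bhv.classify_behaviour(tracks, params)
        labels_provenance = "classifier"
    hdr = {"labels_provenance": labels_provenance, "video_id": meta.video_id}

    nose = tracks["nose"]
    scatter = nose.to_frame()[["frame", "x", "y"]]
    _write_csv(scatter, out / "position_scatter.csv", cfg, hdr)

    hm = bhv.position_heatmap(nose, cfg.bin_size_px, meta.width_px, meta.height_px)
    with open(out / "heatmap.csv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header(cfg, {**hdr, "bin_size_px": hm.bin_size_px, "total_mass": hm.total_mass}))
        pd.DataFrame(hm.grid).to_csv(fh, index=False, header=False, lineterminator="\n")

    budget = bhv.time_in_region(nose, regions, meta.fps_tlv)
    _write_csv(
        pd.DataFrame(
            {
                "region": list(budget.frames),
                "frames": list(budget.frames.values()),
                "minutes": list(budget.minutes.values()),
                "percent": list(budget.percent.values()),
            }
        ),
        out / "time_in_region.csv",
        cfg,
        hdr,
    )

    series = bhv.xy_series_with_behaviour(nose, labels)
    _write_csv(series, out / "xy_behaviour_series.csv", cfg, hdr)

    segs = bhv.detect_weight_shifting(nose, labels, window_frames=cfg.variance_window_frames)
    _write_csv(
        pd.DataFrame([s.__dict__ for s in segs],
                     columns=["start_frame", "end_frame", "y_variance_px2",
                              "variance_ratio", "flagged"]),
        out / "weight_shift_segments.csv",
        cfg,
        hdr,
    )

    tb = bhv.behaviour_time_budget(labels, meta.fps_tlv)
    _write_csv(
        pd.DataFrame(
            {
                "behaviour": list(tb.frames),
                "frames": list(tb.frames.values()),
                "minutes": list(tb.minutes.values()),
                "percent": list(tb.percent.values()),
            }
        ),
        out / "behaviour_time_budget.csv",
        cfg,
        hdr,
    )
    files = [
        out / "position_scatter.csv",
        out / "heatmap.csv",
        out / "time_in_region.csv",
        out / "xy_behaviour_series.csv",
        out / "weight_shift_segments.csv",
        out / "behaviour_time_budget.csv",
    ]
    log.info("case study: %d artifact file(s) out", len(files))
    return {
        "files": files,
        "region_budget": budget,
        "behaviour_budget": tb,
        "weight_shift_segments": segs,
        "labels": labels,
    }
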