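"""Synthetic stall scenarios: ground-truth horse tracks, behaviour labels,
and artifact-degraded "predicted" tracks.

The simulator emulates the statistical structure a pose tracker produces on
time-lapse video of a stabled horse: a three-marker body (nose, withers,
tail) moving through named stall regions under a four-state behaviour
Markov chain, degraded by detection dropouts, Gaussian localisation jitter,
teleport mislabels onto static distractor objects, and scheduled occlusion
of the tail marker while the horse faces the door.

All randomness flows through a single numpy Generator per seed, consumed in
a fixed order (labels -> positions -> visibility), so identical
(config, seed) pairs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .geometry import DEFAULT_DOOR_XY, StallGeometry, default_geometry
from .tracks import (
    BEHAVIOURS,
    MARKERS,
    BehaviourLabels,
    GroundTruthTable,
    MarkerTrack,
    TrackValidationError,
)

_STATE_INDEX = {s: i for i, s in enumerate(BEHAVIOURS)}


@dataclass
class StateKinematics:
    """Per-behaviour movement parameters.

    travel_speed_px : directed speed cap toward the preferred region (px/frame)
    jitter_sigma_px : isotropic white displacement noise (px/frame)
    preferred_region: region the state gravitates to; None = free wandering
    """

    travel_speed_px: float
    jitter_sigma_px: float
    preferred_region: str | None

    def __post_init__(self) -> None:
        if self.jitter_sigma_px < 0:
            raise TrackValidationError("jitter_sigma_px must be >= 0")
        if self.travel_speed_px < 0:
            raise TrackValidationError("travel_speed_px must be >= 0")


def _default_kinematics() -> dict[str, StateKinematics]:
    return {
        "standing_observation": StateKinematics(30.0, 5.0, "front"),
        "rest": StateKinematics(30.0, 0.25, "sidewall"),
        "feeding": StateKinematics(30.0, 2.0, "feeding"),
        "moving": StateKinematics(40.0, 6.0, None),
    }


def _default_transitions() -> np.ndarray:
    # Row-stochastic; stationary bouts last minutes, locomotion bouts ~15 s.
    # Stationary states exchange through "moving", mirroring a horse that
    # walks between its preferred spots.
    return np.array(
        [
            [0.9960, 0.0000, 0.0000, 0.0040],
            [0.0000, 0.9970, 0.0000, 0.0030],
            [0.0000, 0.0000, 0.9960, 0.0040],
            [0.0120, 0.0080, 0.0100, 0.9700],
        ]
    )


@dataclass
class BehaviourModel:
    """Four-state ethogram chain plus per-state kinematics.

    States are standing observation, sleeping/rest, feeding and moving.
    The rest state carries a sinusoidal vertical oscillation of the nose
    marker — the weight-shifting signature of unsettled standing.
    """

    transition_matrix: np.ndarray = field(default_factory=_default_transitions)
    kinematics: dict[str, StateKinematics] = field(default_factory=_default_kinematics)
    rest_y_oscillation_amplitude_px: float = 8.0
    rest_y_oscillation_period_frames: int = 40
    pull_rate: float = 0.15          # OU-style pull toward the state target
    neck_length_px: float = 250.0    # nose-withers distance
    back_length_px: float = 280.0    # withers-tail distance
    heading_min_speed_px: float = 15.0
    heading_alpha: float = 0.25      # EMA weight for heading updates

    def __post_init__(self) -> None:
        m = np.asarray(self.transition_matrix, dtype=float)
        if m.shape != (4, 4):
            raise TrackValidationError("transition matrix must be 4x4")
        for i, row in enumerate(m):
            if abs(row.sum() - 1.0) > 1e-9:
                raise TrackValidationError(
                    f"transition row {i} ({BEHAVIOURS[i]}) does not sum to 1"
                )
            if (row < 0).any():
                raise TrackValidationError(f"transition row {i} has negative entries")
        self.transition_matrix = m
        if set(self.kinematics) != set(BEHAVIOURS):
            raise TrackValidationError(
                f"kinematics must cover exactly the states {BEHAVIOURS}"
            )
        if self.rest_y_oscillation_amplitude_px < 0:
            raise TrackValidationError("oscillation amplitude must be >= 0")
        if self.rest_y_oscillation_period_frames <= 0:
            raise TrackValidationError("oscillation period must be positive")

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, k])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass
class ArtifactSpec:
    """Degradation model applied to ground truth to emulate tracker output.

    dropout_rate          : per-frame probability a dropout run starts
    dropout_run_mean      : mean geometric run length of a dropout (frames)
    jump_rate_per_1000    : expected teleport mislabels per 1000 frames
    jump_target           : "distractor" (static stall objects) or "uniform"
    jump_min_magnitude_px : minimum displacement of an injected teleport
    occlude_tail_facing_door : honour the scheduled tail occlusion
    noise_sigma_px        : Gaussian localisation jitter on predictions
    """

    dropout_rate: float = 0.01
    dropout_run_mean: float = 3.0
    jump_rate_per_1000: float = 1.0
    jump_target: str = "distractor"
    jump_min_magnitude_px: float = 250.0
    occlude_tail_facing_door: bool = True
    noise_sigma_px: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise TrackValidationError("dropout_rate must be in [0, 1]")
        if self.dropout_run_mean < 1.0:
            raise TrackValidationError("dropout_run_mean must be >= 1 frame")
        if self.jump_rate_per_1000 < 0:
            raise TrackValidationError("jump_rate_per_1000 must be >= 0")
        if self.jump_target not in ("distractor", "uniform"):
            raise TrackValidationError("jump_target must be 'distractor' or 'uniform'")
        if self.jump_min_magnitude_px <= 0:
            raise TrackValidationError("jump_min_magnitude_px must be positive")
        if self.noise_sigma_px < 0:
            raise TrackValidationError("noise_sigma_px must be >= 0")


@dataclass
class SyntheticScenario:
    """A fully specified synthetic recording: geometry, behaviour, artifacts."""

    geometry: StallGeometry = field(default_factory=default_geometry)
    behaviour: BehaviourModel = field(default_factory=BehaviourModel)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    n_frames: int = 28800            # 4 h at 2 images/s
    fps_tlv: float = 2.0
    seed: int = 0
    video_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise TrackValidationError("n_frames must be positive")
        if self.fps_tlv <= 0:
            raise TrackValidationError("fps_tlv must be positive")
        for state, kin in self.behaviour.kinematics.items():
            if kin.preferred_region is not None and kin.preferred_region not in self.geometry.regions:
                raise TrackValidationError(
                    f"state '{state}' prefers unknown region '{kin.preferred_region}'"
                )

    @property
    def duration_hours(self) -> float:
        return self.n_frames / (self.fps_tlv * 3600.0)


def build_scenario(config: dict[str, Any] | None = None) -> SyntheticScenario:
    """Build and validate a scenario from a (possibly partial) nested mapping.

    Every field falls back to its default; unknown keys raise.  The mapping
    mirrors the dataclass structure::

        {"n_frames": 28800, "seed": 1,
         "behaviour": {"transition_matrix": [...], "rest_y_oscillation_amplitude_px": 0},
         "artifacts": {"noise_sigma_px": 2.0}, ...}
    """
    config = dict(config or {})
    geometry = config.pop("geometry", None) or default_geometry()
    if isinstance(geometry, dict):
        geometry = StallGeometry(**geometry)

    beh_cfg = dict(config.pop("behaviour", {}) or {})
    kin_cfg = beh_cfg.pop("kinematics", None)
    behaviour = BehaviourModel(**beh_cfg)
    if kin_cfg:
        kin = dict(behaviour.kinematics)
        for state, params in kin_cfg.items():
            if state not in kin:
                raise TrackValidationError(f"unknown behaviour state '{state}'")
            kin[state] = StateKinematics(**params) if isinstance(params, dict) else params
        behaviour.kinematics = kin

    art_cfg = config.pop("artifacts", {}) or {}
    artifacts = ArtifactSpec(**art_cfg) if isinstance(art_cfg, dict) else art_cfg

    allowed = {"n_frames", "fps_tlv", "seed", "video_id"}
    unknown = set(config) - allowed
    if unknown:
        raise TrackValidationError(f"unknown scenario keys {sorted(unknown)}")
    return SyntheticScenario(
        geometry=geometry, behaviour=behaviour, artifacts=artifacts, **config
    )


def _sample_labels(scenario: SyntheticScenario, rng: np.random.Generator) -> np.ndarray:
    """State index per frame from the behaviour Markov chain."""
    m = scenario.behaviour.transition_matrix
    cum = np.cumsum(m, axis=1)
    pi = scenario.behaviour.stationary_distribution()
    u = rng.random(scenario.n_frames)
    states = np.empty(scenario.n_frames, dtype=np.int64)
    states[0] = int(np.searchsorted(np.cumsum(pi), u[0]))
    for t in range(1, scenario.n_frames):
        states[t] = int(np.searchsorted(cum[states[t - 1]], u[t]))
    return states


def _next_stationary_target(
    states: np.ndarray, scenario: SyntheticScenario
) -> list[tuple[float, float] | None]:
    """For each frame of a moving bout, the centroid the horse is walking to.

    Labels are simulated before positions, so each locomotion bout can head
    for the preferred region of the stationary state that follows it.
    """
    moving = _STATE_INDEX["moving"]
    geo = scenario.geometry
    kin = scenario.behaviour.kinematics
    out: list[tuple[float, float] | None] = [None] * len(states)
    nxt: tuple[float, float] | None = None
    for t in range(len(states) - 1, -1, -1):
        s = int(states[t])
        if s == moving:
            out[t] = nxt
        else:
            region = kin[BEHAVIOURS[s]].preferred_region
            nxt = geo.region_centroid(region) if region else None
    return out


def simulate_tracks(
    scenario: SyntheticScenario,
) -> tuple[GroundTruthTable, BehaviourLabels]:
    """Simulate ground-truth marker positions and behaviour labels.

    Returns one label per frame (frames indexed from 1) and a ground-truth
    table with nose/withers/tail positions and visibility classes.  The nose
    is the kinematic anchor: it is pulled toward the active state's region;
    withers and tail trail behind it along the (smoothed) heading, keeping
    nose-withers and withers-tail distances at the configured body lengths
    except where image-border clamping compresses them.
    """
    rng = np.random.default_rng(scenario.seed)
    beh = scenario.behaviour
    geo = scenario.geometry
    n = scenario.n_frames
    moving_idx = _STATE_INDEX["moving"]
    rest_idx = _STATE_INDEX["rest"]

    states = _sample_labels(scenario, rng)
    move_targets = _next_stationary_target(states, scenario)

    jitter = rng.standard_normal((n, 2))
    w, h = float(geo.width_px), float(geo.height_px)
    door = np.array(DEFAULT_DOOR_XY)

    # start at the preferred spot of the initial state (or stall centre)
    kin0 = beh.kinematics[BEHAVIOURS[int(states[0])]]
    if kin0.preferred_region:
        pos = np.array(geo.region_centroid(kin0.preferred_region))
    else:
        pos = np.array([w / 2.0, h / 2.0])
    heading = np.array([1.0, 0.0])
    waypoint: np.ndarray | None = None

    nose = np.empty((n, 2))
    withers = np.empty((n, 2))
    tail = np.empty((n, 2))
    tail_visible = np.ones(n, dtype=bool)
    rest_run = 0

    for t in range(n):
        s = int(states[t])
        kin = beh.kinematics[BEHAVIOURS[s]]
        if s == moving_idx:
            base = move_targets[t]
            if base is None:
                base = (w / 2.0, h / 2.0)
            base = np.array(base)
            if waypoint is None or np.linalg.norm(waypoint - pos) < 60.0:
                # orbit near the destination once reached
                ang = rng.random() * 2.0 * math.pi
                rad = 60.0 + rng.random() * 120.0
                waypoint = base + rad * np.array([math.cos(ang), math.sin(ang)])
            target = waypoint
        else:
            waypoint = None
            if kin.preferred_region:
                target = np.array(geo.region_centroid(kin.preferred_region))
            else:
                target = pos
        delta = target - pos
        dist = float(np.linalg.norm(delta))
        if dist > 1e-9:
            if s == moving_idx:
                # locomotion: full walking speed toward the waypoint
                speed = min(kin.travel_speed_px, dist)
            else:
                # stationary states: pull toward the spot, settling smoothly
                speed = min(kin.travel_speed_px, beh.pull_rate * dist)
            step = delta / dist * speed
        else:
            step = np.zeros(2)
        step = step + kin.jitter_sigma_px * jitter[t]
        new_pos = np.clip(pos + step, [0.0, 0.0], [w, h])
        vel = new_pos - pos
        speed = float(np.linalg.norm(vel))
        if speed > beh.heading_min_speed_px:
            blended = (1.0 - beh.heading_alpha) * heading + beh.heading_alpha * vel / speed
            norm = float(np.linalg.norm(blended))
            if norm > 1e-9:
                heading = blended / norm
        pos = new_pos

        nose_t = pos.copy()
        if s == rest_idx:
            rest_run += 1
            nose_t[1] += beh.rest_y_oscillation_amplitude_px * math.sin(
                2.0 * math.pi * rest_run / beh.rest_y_oscillation_period_frames
            )
        else:
            rest_run = 0
        withers_t = nose_t - heading * beh.neck_length_px
        tail_t = withers_t - heading * beh.back_length_px
        nose[t] = np.clip(nose_t, [0.0, 0.0], [w, h])
        withers[t] = np.clip(withers_t, [0.0, 0.0], [w, h])
        tail[t] = np.clip(tail_t, [0.0, 0.0], [w, h])

        to_door = door - withers[t]
        dn = float(np.linalg.norm(to_door))
        if dn > 1e-9 and float(np.dot(heading, to_door / dn)) > 0.55:
            tail_visible[t] = False  # horse faces the door; tail hidden

    # sprinkle partial-occlusion classes on otherwise-visible frames
    occ_u = rng.random((n, len(MARKERS)))
    occ_class = rng.integers(0, 3, size=(n, len(MARKERS)))
    occ_names = np.array(["occluded25", "occluded50", "occluded75"])

    frames = np.arange(1, n + 1, dtype=np.int64)
    records: dict[str, np.ndarray] = {}
    marker_xy = {"nose": nose, "withers": withers, "tail": tail}
    rows_frame, rows_marker, rows_x, rows_y, rows_vis = [], [], [], [], []
    for j, marker in enumerate(MARKERS):
        xy = marker_xy[marker]
        vis = np.full(n, "visible", dtype=object)
        partially = occ_u[:, j] < 0.02
        vis[partially] = occ_names[occ_class[partially, j]]
        x = xy[:, 0].copy()
        y = xy[:, 1].copy()
        if marker == "tail":
            hidden = ~tail_visible
            vis[hidden] = "not_visible"
            x[hidden] = np.nan
            y[hidden] = np.nan
        rows_frame.append(frames)
        rows_marker.append(np.full(n, marker, dtype=object))
        rows_x.append(x)
        rows_y.append(y)
        rows_vis.append(vis)

    truth = GroundTruthTable(
        pd.DataFrame(
            {
                "frame": np.concatenate(rows_frame),
                "marker": np.concatenate(rows_marker),
                "x": np.concatenate(rows_x),
                "y": np.concatenate(rows_y),
                "visibility": np.concatenate(rows_vis),
            }
        )
    )
    labels = BehaviourLabels(
        frames=frames, behaviour=np.array(BEHAVIOURS, dtype=object)[states]
    )
    return truth, labels


def degrade_to_predictions(
    truth: GroundTruthTable,
    artifacts: ArtifactSpec,
    seed: int,
    geometry: StallGeometry | None = None,
) -> tuple[dict[str, MarkerTrack], list[dict[str, Any]]]:
    """Corrupt ground truth into tracker-like predictions.

    Applies, per marker and in this order: Gaussian localisation jitter,
    dropout runs (geometric lengths), and teleport mislabels relocated onto
    distractor objects (or uniform positions) with displacement at least
    ``jump_min_magnitude_px``.  Hidden (not_visible) frames stay unpredicted
    unless a teleport lands there, which injects a false positive.

    Returns the predicted tracks and a complete artifact log, one entry per
    injected event, for recovery tests.
    """
    geometry = geometry or default_geometry()
    if artifacts.jump_min_magnitude_px > geometry.diagonal_px:
        raise TrackValidationError(
            "jump_min_magnitude_px exceeds the image diagonal; no valid teleport exists"
        )
    rng = np.random.default_rng(seed)
    w, h = float(geometry.width_px), float(geometry.height_px)
    distractors = list(geometry.distractors.items())
    log: list[dict[str, Any]] = []
    tracks: dict[str, MarkerTrack] = {}

    for marker in MARKERS:
        sub = truth.for_marker(marker)
        frames = sub.index.to_numpy()
        n = len(frames)
        visible = (sub["visibility"] != "not_visible").to_numpy()
        x = sub["x"].to_numpy(dtype=float).copy()
        y = sub["y"].to_numpy(dtype=float).copy()

        noise = rng.standard_normal((n, 2)) * artifacts.noise_sigma_px
        x[visible] = np.clip(x[visible] + noise[visible, 0], 0.0, w)
        y[visible] = np.clip(y[visible] + noise[visible, 1], 0.0, h)
        predicted = visible.copy()

        # dropout runs
        u_start = rng.random(n)
        i = 0
        while i < n:
            if predicted[i] and u_start[i] < artifacts.dropout_rate:
                run = 1 + int(rng.geometric(1.0 / artifacts.dropout_run_mean) - 1)
                run = max(run, 1)
                end = min(i + run, n)
                predicted[i:end] = False
                log.append(
                    {
                        "type": "dropout",
                        "marker": marker,
                        "frame": int(frames[i]),
                        "length": int(end - i),
                    }
                )
                i = end
            else:
                i += 1

        # teleport mislabels
        n_jumps = int(rng.poisson(artifacts.jump_rate_per_1000 * n / 1000.0))
        n_jumps = min(n_jumps, n)
        if n_jumps > 0:
            jump_frames = np.sort(rng.choice(n, size=n_jumps, replace=False))
            for idx in jump_frames:
                true_xy = (
                    (float(sub["x"].iloc[idx]), float(sub["y"].iloc[idx]))
                    if visible[idx]
                    else None
                )
                tx, ty = _draw_jump_target(
                    rng, artifacts, distractors, w, h, true_xy
                )
                disp = (
                    math.hypot(tx - true_xy[0], ty - true_xy[1])
                    if true_xy is not None
                    else float("nan")
                )
                x[idx], y[idx] = tx, ty
                was_hidden = not visible[idx]
                predicted[idx] = True
                log.append(
                    {
                        "type": "false_positive" if was_hidden else "jump",
                        "marker": marker,
                        "frame": int(frames[idx]),
                        "x": tx,
                        "y": ty,
                        "displacement_px": disp,
                    }
                )

        x[~predicted] = np.nan
        y[~predicted] = np.nan
        tracks[marker] = MarkerTrack(
            marker=marker, frames=frames, x=x, y=y, predicted=predicted
        )

    log.sort(key=lambda e: (e["frame"], e["marker"], e["type"]))
    return tracks, log


def _draw_jump_target(
    rng: np.random.Generator,
    artifacts: ArtifactSpec,
    distractors: list[tuple[str, tuple[float, float]]],
    w: float,
    h: float,
    true_xy: tuple[float, float] | None,
) -> tuple[float, float]:
    """A teleport destination at least jump_min_magnitude_px from the truth."""
    if artifacts.jump_target == "distractor" and distractors:
        order = rng.permutation(len(distractors))
        best = None
        best_d = -1.0
        for k in order:
            dx, dy = distractors[k][1]
            if true_xy is None:
                return (dx, dy)
            d = math.hypot(dx - true_xy[0], dy - true_xy[1])
            if d >= artifacts.jump_min_magnitude_px:
                return (dx, dy)
            if d > best_d:
                best, best_d = (dx, dy), d
        # all distractors too close (tiny geometries): fall through to uniform
    for _ in range(10_000):
        tx, ty = rng.random() * w, rng.random() * h
        if true_xy is None:
            return (tx, ty)
        if math.hypot(tx - true_xy[0], ty - true_xy[1]) >= artifacts.jump_min_magnitude_px:
            return (tx, ty)
    raise TrackValidationError("could not place a teleport satisfying jump_min_magnitude_px")
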