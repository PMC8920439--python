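"""Per-trajectory behavioral and morphological features.

Each accepted track is summarized into a fixed dialect of 21 natural-
swimming features (kinematics, vertical distribution, path geometry,
plane-specific morphology via the circularity classifier, and the six
locomotor-state occupancy probabilities) plus, when a stimulus schedule
is supplied, 12 stimulus-response features (pre/post mean speed, their
ratio, and signed vertical velocity for each of weak light, strong light
and vibration).

Speeds are mm/s (``px_per_mm`` required), angular velocities rad/s, and
the vertical axis is flipped so "up" in the water column is positive.
Time series are smoothed with a centered 3-point moving average before
kinematic differencing; stimulus features use unsmoothed displacements so
a step change in speed at a window boundary is not blurred across it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimulus import STIMULUS_LABELS, StimulusSchedule
from .tracking import Detection, SegmentationParams, Track

__all__ = [
    "FeatureParams", "Kinematics", "smooth_series", "kinematics", "classify_plane",
    "classify_states", "ethogram", "natural_features", "stimulus_features",
    "feature_table", "correlation_matrix", "ETHOGRAM_STATES", "NATURAL_FEATURES",
    "STIMULUS_FEATURES", "METADATA_COLUMNS",
]

ETHOGRAM_STATES = ("FwdRun", "Fwd", "FwdSlow", "Turn", "Spin", "Pause")

#: duration of the pre-stimulus comparison window, seconds (matches the
#: inter-stimulus spacing of the standard schedule)
PRE_WINDOW_S = 10.0


@dataclass
class FeatureParams:
    """Feature-extraction settings.

    Ethogram speed thresholds are in body lengths per second (body
    length = per-track median major axis), angular-velocity thresholds
    in rad/s.  ``arena_h_px`` is needed for the vertical-position
    features; without it they are reported missing.
    """

    window: int = 3
    px_per_mm: float = 10.0
    fps: float = 25.0
    pause_speed_max: float = 0.2    # BL/s
    slow_speed_max: float = 1.0     # BL/s
    run_speed_min: float = 2.0      # BL/s
    turn_angvel_min: float = math.pi / 2.0   # rad/s
    spin_angvel_min: float = 2.0 * math.pi   # rad/s
    arena_h_px: float | None = None

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("smoothing window must be odd and >= 1")
        if not (0.0 <= self.pause_speed_max < self.slow_speed_max < self.run_speed_min):
            raise ValueError("need 0 <= pause_speed_max < slow_speed_max < run_speed_min")
        if not (0.0 < self.turn_angvel_min < self.spin_angvel_min):
            raise ValueError("need 0 < turn_angvel_min < spin_angvel_min")
        if self.px_per_mm <= 0 or self.fps <= 0:
            raise ValueError("px_per_mm and fps must be positive")


def smooth_series(series, window: int = 3) -> np.ndarray:
    """Centered moving average; edges use the truncated window.

    [1, 2, 3, 4] with window 3 -> [1.5, 2, 3, 3.5].
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        return x
    half = window // 2
    csum = np.cumsum(np.concatenate([[0.0], x]))
    idx = np.arange(x.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, x.size)
    return (csum[hi] - csum[lo]) / (hi - lo)


@dataclass
class Kinematics:
    """Per-frame kinematics over the smoothing-valid region of a track.

    ``frames[i]`` is the frame index at which step ``i`` *ends*; arrays
    ``speed_mm_s`` and ``vert_vel_mm_s`` have one entry per step, and
    ``angvel_rad_s`` one entry per pair of consecutive steps.
    """

    frames: np.ndarray        # step end frames, length m
    speed_mm_s: np.ndarray    # length m
    vert_vel_mm_s: np.ndarray  # length m, up-positive
    angvel_rad_s: np.ndarray  # length m - 1
    raw_speed_mm_s: np.ndarray  # unsmoothed step speeds, length n_frames - 1
    raw_frames: np.ndarray      # end frames of unsmoothed steps
    raw_vert_vel_mm_s: np.ndarray


def kinematics(track: Track, params: FeatureParams | None = None) -> Kinematics:
    """Smoothed speed, angular velocity and vertical velocity of a track.

    Positions are smoothed with the centered moving average; the
    ``(window-1)/2`` edge samples whose window is truncated are then
    dropped so every reported step uses fully-smoothed endpoints.
    Gap-tolerant tracks may skip frames; rates divide by the actual
    frame interval.
    """
    if params is None:
        params = FeatureParams()
    n = track.n_frames
    if n < params.window or n < 2:
        raise ValueError(f"track has {n} detections; need at least max(window, 2) = {max(params.window, 2)}")
    frames = track.frames.astype(float)
    xy = track.xy
    half = params.window // 2

    sx = smooth_series(xy[:, 0], params.window)
    sy = smooth_series(xy[:, 1], params.window)
    sl = slice(half, n - half) if half else slice(None)
    vf, vx, vy = frames[sl], sx[sl], sy[sl]
    dt = np.diff(vf) / params.fps
    dx, dy = np.diff(vx), np.diff(vy)
    dist_px = np.hypot(dx, dy)
    speed = dist_px / params.px_per_mm / dt
    vert = -dy / params.px_per_mm / dt
    heading = np.arctan2(dy, dx)
    dh = (np.diff(heading) + np.pi) % (2 * np.pi) - np.pi
    angvel = dh / ((dt[1:] + dt[:-1]) / 2.0)

    rdt = np.diff(frames) / params.fps
    rdx, rdy = np.diff(xy[:, 0]), np.diff(xy[:, 1])
    raw_speed = np.hypot(rdx, rdy) / params.px_per_mm / rdt
    raw_vert = -rdy / params.px_per_mm / rdt

    return Kinematics(
        frames=vf[1:].astype(int),
        speed_mm_s=speed,
        vert_vel_mm_s=vert,
        angvel_rad_s=angvel,
        raw_speed_mm_s=raw_speed,
        raw_frames=frames[1:].astype(int),
        raw_vert_vel_mm_s=raw_vert,
    )


def classify_plane(detection: Detection, params: SegmentationParams | None = None) -> str:
    """Transverse (top view) vs sagittal (side view) body presentation.

    Normalized circularity above 0.92 reads as the near-circular top
    view, below 0.58 as the elongated side view; in between the frame
    is left unclassified and excluded from plane-specific size features.
    """
    if params is None:
        params = SegmentationParams()
    c = detection.circularity
    if c > params.transverse_circ_threshold:
        return "transverse"
    if c < params.sagittal_circ_threshold:
        return "sagittal"
    return "unclassified"


def classify_states(speed_bls, angvel_rad_s, params: FeatureParams | None = None) -> np.ndarray:
    """Locomotor-state cascade applied element-wise to aligned arrays.

    Order of precedence: Pause (speed at/below the pause threshold),
    Spin, Turn (by |angular velocity|), FwdRun, FwdSlow, Fwd (by speed).
    """
    if params is None:
        params = FeatureParams()
    speed = np.asarray(speed_bls, dtype=float)
    av = np.abs(np.asarray(angvel_rad_s, dtype=float))
    if speed.shape != av.shape:
        raise ValueError("speed and angular-velocity arrays must be aligned")
    out = np.full(speed.shape, "Fwd", dtype=object)
    out[speed <= params.slow_speed_max] = "FwdSlow"
    out[speed >= params.run_speed_min] = "FwdRun"
    out[av >= params.turn_angvel_min] = "Turn"
    out[av >= params.spin_angvel_min] = "Spin"
    out[speed <= params.pause_speed_max] = "Pause"
    return out


def _body_len_px(track: Track) -> float:
    return float(np.median([d.major for d in track.detections]))


def ethogram(track: Track, params: FeatureParams | None = None) -> tuple[np.ndarray, dict[str, float]]:
    """Per-frame locomotor states and their occupancy probabilities.

    Speed is normalized to body lengths/s using the per-track median
    major axis.  Probabilities are frame fractions over the six states
    and sum to 1.
    """
    if params is None:
        params = FeatureParams()
    kin = kinematics(track, params)
    body_len_mm = _body_len_px(track) / params.px_per_mm
    speed_bls = kin.speed_mm_s[1:] / max(body_len_mm, 1e-9)
    states = classify_states(speed_bls, kin.angvel_rad_s, params)
    if states.size == 0:
        raise ValueError("track too short to classify locomotor states")
    probs = {s: float(np.mean(states == s)) for s in ETHOGRAM_STATES}
    return states, probs


NATURAL_FEATURES = [
    "speed_mean_mm_s", "speed_median_mm_s", "speed_sd_mm_s",
    "angvel_mean_rad_s", "angvel_sd_rad_s",
    "vert_vel_abs_mean_mm_s", "vert_pos_mean_mm", "frac_upper_half",
    "ngdr", "path_len_mm",
    "transverse_area_px2", "sagittal_area_px2",
    "major_px", "minor_px", "aspect_ratio",
    "p_fwdrun", "p_fwd", "p_fwdslow", "p_turn", "p_spin", "p_pause",
]

STIMULUS_FEATURES = [
    f"{label}_{kind}"
    for label in STIMULUS_LABELS
    for kind in ("pre_speed_mm_s", "post_speed_mm_s", "resp_ratio", "vert_vel_mm_s")
]

METADATA_COLUMNS = ["track_id", "n_frames", "duration_s", "age_days", "cohort", "condition"]


def natural_features(track: Track, params: FeatureParams | None = None) -> dict[str, float]:
    """The 21 natural-swimming features of one track.

    Plane-specific sizes are means over frames whose presentation the
    circularity classifier resolves; with no resolved frames the field
    is missing (NaN) rather than zero.
    """
    if params is None:
        params = FeatureParams()
    kin = kinematics(track, params)
    xy = track.xy
    speed = kin.speed_mm_s
    av = np.abs(kin.angvel_rad_s)
    _, probs = ethogram(track, params)

    net = float(np.linalg.norm(xy[-1] - xy[0])) / params.px_per_mm
    gross = float(np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1])).sum()) / params.px_per_mm

    planes = np.array([classify_plane(d) for d in track.detections])
    areas = np.array([d.area for d in track.detections])

    def plane_area(name: str) -> float:
        sel = planes == name
        return float(areas[sel].mean()) if sel.any() else float("nan")

    if params.arena_h_px is not None:
        height_mm = (params.arena_h_px - xy[:, 1]) / params.px_per_mm
        vert_pos = float(height_mm.mean())
        frac_upper = float(np.mean(xy[:, 1] < params.arena_h_px / 2.0))
    else:
        vert_pos, frac_upper = float("nan"), float("nan")

    majors = np.array([d.major for d in track.detections])
    minors = np.array([d.minor for d in track.detections])

    return {
        "speed_mean_mm_s": float(speed.mean()),
        "speed_median_mm_s": float(np.median(speed)),
        "speed_sd_mm_s": float(speed.std()),
        "angvel_mean_rad_s": float(av.mean()) if av.size else float("nan"),
        "angvel_sd_rad_s": float(av.std()) if av.size else float("nan"),
        "vert_vel_abs_mean_mm_s": float(np.abs(kin.vert_vel_mm_s).mean()),
        "vert_pos_mean_mm": vert_pos,
        "frac_upper_half": frac_upper,
        "ngdr": net / gross if gross > 0 else float("nan"),
        "path_len_mm": gross,
        "transverse_area_px2": plane_area("transverse"),
        "sagittal_area_px2": plane_area("sagittal"),
        "major_px": float(majors.mean()),
        "minor_px": float(minors.mean()),
        "aspect_ratio": float((minors / majors).mean()),
        "p_fwdrun": probs["FwdRun"],
        "p_fwd": probs["Fwd"],
        "p_fwdslow": probs["FwdSlow"],
        "p_turn": probs["Turn"],
        "p_spin": probs["Spin"],
        "p_pause": probs["Pause"],
    }


def stimulus_features(
    track: Track,
    schedule: StimulusSchedule,
    params: FeatureParams | None = None,
) -> dict[str, float]:
    """Stimulus-response summaries: 4 fields per scheduled stimulus.

    For each stimulus: mean speed over the ``PRE_WINDOW_S`` seconds
    before onset, mean speed inside the window, their post/pre ratio,
    and mean signed vertical velocity (up-positive) inside the window.
    A step is attributed to the time of its end frame.  Windows the
    track does not cover yield missing values.
    """
    if params is None:
        params = FeatureParams()
    kin = kinematics(track, params)
    t_s = kin.raw_frames / params.fps
    out: dict[str, float] = {}
    by_label = {w.label: w for w in schedule.windows}
    for label in STIMULUS_LABELS:
        w = by_label.get(label)
        keys = [f"{label}_pre_speed_mm_s", f"{label}_post_speed_mm_s", f"{label}_resp_ratio", f"{label}_vert_vel_mm_s"]
        if w is None:
            out.update(dict.fromkeys(keys, float("nan")))
            continue
        pre = (t_s >= w.onset_s - PRE_WINDOW_S) & (t_s < w.onset_s)
        post = (t_s >= w.onset_s) & (t_s < w.offset_s)
        pre_speed = float(kin.raw_speed_mm_s[pre].mean()) if pre.any() else float("nan")
        post_speed = float(kin.raw_speed_mm_s[post].mean()) if post.any() else float("nan")
        ratio = post_speed / pre_speed if pre.any() and post.any() and pre_speed > 0 else float("nan")
        vert = float(kin.raw_vert_vel_mm_s[post].mean()) if post.any() else float("nan")
        out.update(zip(keys, [pre_speed, post_speed, ratio, vert]))
    return out


def feature_table(
    tracks,
    params: FeatureParams | None = None,
    schedule: StimulusSchedule | None = None,
    metadata: dict | None = None,
) -> pd.DataFrame:
    """One feature row per track; metadata columns are broadcast."""
    if params is None:
        params = FeatureParams()
    rows = []
    for tr in tracks:
        row: dict = {"track_id": tr.track_id, "n_frames": tr.n_frames, "duration_s": tr.duration_s(params.fps)}
        row.update(natural_features(tr, params))
        if schedule is not None:
            row.update(stimulus_features(tr, schedule, params))
        if metadata:
            row.update(metadata)
        rows.append(row)
    cols = ["track_id", "n_frames", "duration_s"] + NATURAL_FEATURES
    if schedule is not None:
        cols += STIMULUS_FEATURES
    if metadata:
        cols += [k for k in metadata if k not in cols]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def correlation_matrix(features: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between feature columns.

    Constant columns produce missing entries (their correlation is
    undefined), never zeros.  The matrix is symmetric with unit
    diagonal on non-constant columns.
    """
    if columns is None:
        columns = [c for c in features.columns if c in NATURAL_FEATURES + STIMULUS_FEATURES]
        if not columns:
            columns = [c for c in features.select_dtypes("number").columns if c not in METADATA_COLUMNS]
    if len(features) < 2:
        raise ValueError("need at least 2 rows to correlate")
    return features[columns].corr(method="pearson")
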