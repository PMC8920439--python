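"""Ground-truthed synthetic cohorts: trajectories, rendered video, lifespans.

The generator stands in for the physical rig.  It produces (a) correlated
random-walk swimming trajectories whose mean speed declines and body size
grows with age, with step-like speed responses and vertical phototactic
drift during scheduled stimulus windows, (b) rendered grayscale video of
bright oriented ellipses over a noisy background with static debris, and
(c) cohort lifespans drawn from a chosen parametric hazard.  Everything is
seeded and byte-reproducible, so downstream stages can be validated
against exact truth.

Conventions: image coordinates (x rightward, y downward); "up" in the
water column is therefore negative y.  Speeds are mm/s, lengths mm, ages
days, intensities 8-bit grayscale.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .stimulus import StimulusSchedule, default_schedule

__all__ = ["CohortConfig", "GroundTruth", "simulate_trajectories", "render_video", "simulate_survival"]

_HAZARD_FAMILIES = ("exponential", "weibull", "gompertz")

#: seconds of downward drift imposed after a light stimulus switches off
POST_LIGHT_DRIFT_S = 10.0


@dataclass
class CohortConfig:
    """Study-condition knobs for one synthetic cohort.

    Defaults describe a healthy adult cohort in a desk-scale arena:
    25 fps acquisition, ~5 mm/s baseline swimming that declines by
    0.05 mm/s per day of age, 1.5 mm neonate-adult body length growing
    0.03 mm/day, Gompertz mortality, and a 2x speed burst during
    stimulus windows.
    """

    n_animals: int = 20
    duration_s: float = 60.0
    fps: float = 25.0
    arena_w_px: int = 640
    arena_h_px: int = 480
    px_per_mm: float = 10.0
    baseline_speed: float = 5.0          # mm/s at age 0
    speed_age_slope: float = -0.05       # mm/s per day, <= 0
    baseline_body_len: float = 1.5       # mm at age 0
    growth_rate: float = 0.03            # mm/day, >= 0
    hazard_family: str = "gompertz"
    hazard_params: dict = field(default_factory=lambda: {"a": 0.002, "b": 0.08})
    stimulus_response_gain: float = 2.0  # speed multiplier inside stimulus windows
    noise_sd: float = 5.0                # rendering noise, intensity units
    n_debris: int = 5
    seed: int = 0
    # kinematic texture (free parameters of the random walk)
    speed_cv: float = 0.3                # per-frame speed coefficient of variation
    heading_sd: float = 0.3              # rad per frame, wrapped-Gaussian heading diffusion
    drift_strength: float = 0.25         # per-frame relaxation of heading toward up/down during light
    # body presentation (exercises the circularity plane classifier)
    p_transverse: float = 0.5
    transverse_aspect: float = 0.95
    sagittal_aspect: float = 0.22
    # rendering
    bg_level: float = 30.0
    animal_intensity: float = 200.0
    debris_intensity: float = 90.0
    min_separation_px: float | None = None  # soft collision avoidance when set

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        numeric = {
            "fps": self.fps, "duration_s": self.duration_s, "px_per_mm": self.px_per_mm,
            "baseline_speed": self.baseline_speed, "speed_age_slope": self.speed_age_slope,
            "baseline_body_len": self.baseline_body_len, "growth_rate": self.growth_rate,
            "stimulus_response_gain": self.stimulus_response_gain, "noise_sd": self.noise_sd,
            "speed_cv": self.speed_cv, "heading_sd": self.heading_sd,
        }
        for name, val in numeric.items():
            if not math.isfinite(float(val)):
                raise ValueError(f"CohortConfig.{name} must be finite, got {val!r}")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.arena_w_px <= 0 or self.arena_h_px <= 0:
            raise ValueError("arena dimensions must be > 0")
        if self.n_animals < 0:
            raise ValueError("n_animals must be >= 0")
        if self.stimulus_response_gain < 0:
            raise ValueError("stimulus_response_gain must be >= 0")
        if self.speed_age_slope > 0:
            raise ValueError("speed_age_slope must be <= 0 (speed declines with age)")
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")
        if self.hazard_family not in _HAZARD_FAMILIES:
            raise ValueError(f"hazard_family must be one of {_HAZARD_FAMILIES}, got {self.hazard_family!r}")

    def mean_speed_at(self, age_days: float) -> float:
        return max(0.0, self.baseline_speed + self.speed_age_slope * age_days)

    def body_len_at(self, age_days: float) -> float:
        return self.baseline_body_len + self.growth_rate * age_days

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        return cls(**json.loads(Path(path).read_text()))


TRAJ_COLUMNS = [
    "animal", "frame", "x_px", "y_px", "heading_rad",
    "body_len_px", "aspect", "speed_mm_s", "angvel_rad_s", "state",
]


@dataclass
class GroundTruth:
    """True per-frame trajectories, locomotor states, and death days."""

    traj: pd.DataFrame          # TRAJ_COLUMNS, one row per (animal, frame)
    death_day: np.ndarray       # days, one entry per animal
    age_days: float
    config: CohortConfig
    schedule: StimulusSchedule | None = None
    n_frames: int | None = None  # frames in the session; inferred from traj if omitted

    def __post_init__(self) -> None:
        if len(self.traj):
            x, y = self.traj["x_px"].to_numpy(), self.traj["y_px"].to_numpy()
            if (x < 0).any() or (x > self.config.arena_w_px).any() or (y < 0).any() or (y > self.config.arena_h_px).any():
                raise ValueError("trajectory coordinates fall outside the arena")
        if (np.asarray(self.death_day) <= 0).any():
            raise ValueError("death days must be positive")
        if self.n_frames is None:
            self.n_frames = int(self.traj["frame"].max()) + 1 if len(self.traj) else 0

    def positions(self, animal: int) -> np.ndarray:
        sub = self.traj[self.traj["animal"] == animal].sort_values("frame")
        return sub[["x_px", "y_px"]].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.traj.to_csv(path, index=False)


def _wrap_angle(a):
    """Wrap to (-pi, pi]."""
    return (np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi


def _bounce(pos: np.ndarray, direction: np.ndarray, step: float, lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One straight step of exact length, reflecting direction off walls.

    The heading component is flipped *before* moving whenever the
    proposed endpoint leaves the box, so displacement magnitude equals
    ``step`` except in the pathological corner case, where the endpoint
    is clamped.
    """
    d = direction.copy()
    for _ in range(4):
        prop = pos + step * d
        out_lo = prop < lo
        out_hi = prop > hi
        if not (out_lo.any() or out_hi.any()):
            return prop, d
        d = np.where(out_lo | out_hi, -d, d)
    return np.clip(pos + step * d, lo, hi), d


def simulate_trajectories(
    config: CohortConfig,
    age_days: float,
    schedule: StimulusSchedule | None = None,
) -> GroundTruth:
    """Simulate a recording session for a cohort at a given age.

    Each animal follows a correlated random walk: per-frame speed is
    gamma-distributed with mean ``max(0, baseline_speed +
    speed_age_slope * age)`` and CV ``speed_cv``; heading diffuses with
    wrapped-Gaussian increments of SD ``heading_sd``.  Inside stimulus
    windows speed is multiplied by ``stimulus_response_gain``; during
    light windows the heading additionally relaxes toward "up" and,
    for ``POST_LIGHT_DRIFT_S`` seconds after light-off, toward "down".
    Walls reflect.  Fully reproducible from ``config.seed``.
    """
    if not math.isfinite(age_days) or age_days < 0:
        raise ValueError(f"age_days must be finite and >= 0, got {age_days!r}")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 11, int(round(age_days * 1000))]))

    n = config.n_animals
    n_frames = int(round(config.duration_s * config.fps))
    mean_speed = config.mean_speed_at(age_days)
    body_len_mm = config.body_len_at(age_days)
    body_len_px = body_len_mm * config.px_per_mm

    margin = body_len_px / 2.0 + 2.0
    lo = np.array([margin, margin])
    hi = np.array([config.arena_w_px - margin, config.arena_h_px - margin])
    if (hi <= lo).any():
        raise ValueError("arena too small for the configured body length")

    pos = rng.uniform(lo, hi, size=(n, 2))
    if config.min_separation_px is not None and n > 1:
        # rejection-sample starts so the cohort begins fully separated
        for i in range(1, n):
            for _ in range(200):
                if np.linalg.norm(pos[:i] - pos[i], axis=1).min() >= config.min_separation_px:
                    break
                pos[i] = rng.uniform(lo, hi)
            else:
                raise ValueError("arena too crowded for the requested min_separation_px")
    heading = rng.uniform(-np.pi, np.pi, size=n)

    # pre-draw per-frame presentation and speed noise
    transverse = rng.random(size=(n, n_frames)) < config.p_transverse
    if config.speed_cv > 0:
        k = 1.0 / config.speed_cv**2
        speed_noise = rng.gamma(shape=k, scale=1.0 / k, size=(n, n_frames))
    else:
        speed_noise = np.ones((n, n_frames))

    light_offsets = []
    if schedule is not None:
        light_offsets = [w.offset_s for w in schedule.windows if w.is_light]

    xs = np.empty((n, n_frames))
    ys = np.empty((n, n_frames))
    heads = np.empty((n, n_frames))
    speeds = np.empty((n, n_frames))

    for t in range(n_frames):
        t_s = t / config.fps
        win = schedule.active(t_s) if schedule is not None else None
        gain = config.stimulus_response_gain if win is not None else 1.0
        drift_target = None
        if win is not None and win.is_light:
            drift_target = -np.pi / 2.0  # upward
        elif any(off <= t_s < off + POST_LIGHT_DRIFT_S for off in light_offsets):
            drift_target = np.pi / 2.0   # downward after light-off

        if drift_target is not None and config.drift_strength > 0:
            heading = heading + config.drift_strength * _wrap_angle(drift_target - heading)
        heading = _wrap_angle(heading + rng.normal(0.0, config.heading_sd, size=n))

        frame_speed = mean_speed * gain * speed_noise[:, t]       # mm/s
        step_px = frame_speed / config.fps * config.px_per_mm

        new_pos = np.empty_like(pos)
        direction = np.column_stack([np.cos(heading), np.sin(heading)])
        for i in range(n):
            p, d = _bounce(pos[i], direction[i], step_px[i], lo, hi)
            if config.min_separation_px is not None and n > 1:
                others = np.vstack([new_pos[:i], pos[i + 1:]])
                cur_min = float(np.linalg.norm(others - pos[i], axis=1).min())
                # a move is acceptable if it keeps full separation, or at
                # least does not worsen an existing squeeze
                floor = min(config.min_separation_px, cur_min)
                tries = 0
                while float(np.linalg.norm(others - p, axis=1).min()) < floor - 1e-9 and tries < 8:
                    ang = -heading[i] if tries == 0 else rng.uniform(-np.pi, np.pi)
                    d = np.array([np.cos(ang), np.sin(ang)])
                    p, d = _bounce(pos[i], d, step_px[i], lo, hi)
                    tries += 1
                if float(np.linalg.norm(others - p, axis=1).min()) < floor - 1e-9:
                    p, d = pos[i].copy(), direction[i]
            new_pos[i] = p
            heading[i] = math.atan2(d[1], d[0])

        xs[:, t], ys[:, t] = new_pos[:, 0], new_pos[:, 1]
        heads[:, t] = heading
        # realized speed (accounts for collision stalls/clamps)
        prev = pos
        disp = np.linalg.norm(new_pos - prev, axis=1)
        speeds[:, t] = disp * config.fps / config.px_per_mm
        pos = new_pos

    angvel = np.zeros((n, n_frames))
    if n_frames > 1:
        angvel[:, 1:] = _wrap_angle(np.diff(heads, axis=1)) * config.fps

    # true locomotor state from true kinematics (same cascade the feature
    # stage applies to tracked data)
    from .features import FeatureParams, classify_states

    fp = FeatureParams(px_per_mm=config.px_per_mm, fps=config.fps)
    speed_bls = speeds / max(body_len_mm, 1e-9)
    states = np.empty((n, n_frames), dtype=object)
    for i in range(n):
        states[i] = classify_states(speed_bls[i], angvel[i], fp)

    frames = np.tile(np.arange(n_frames), n)
    animals = np.repeat(np.arange(n), n_frames)
    aspect = np.where(transverse, config.transverse_aspect, config.sagittal_aspect)
    traj = pd.DataFrame({
        "animal": animals,
        "frame": frames,
        "x_px": xs.ravel(),
        "y_px": ys.ravel(),
        "heading_rad": heads.ravel(),
        "body_len_px": np.full(n * n_frames, body_len_px),
        "aspect": aspect.ravel(),
        "speed_mm_s": speeds.ravel(),
        "angvel_rad_s": angvel.ravel(),
        "state": states.ravel(),
    })

    death_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 13]))
    from .survival import sample_lifetimes

    death_day = sample_lifetimes(config.hazard_family, config.hazard_params, max(n, 1), death_rng)[:n]

    return GroundTruth(traj=traj, death_day=death_day, age_days=float(age_days),
                       config=config, schedule=schedule, n_frames=n_frames)


def truth_to_tracks(truth: GroundTruth):
    """Ground-truth trajectories as ideal Track objects (no rendering).

    Blob geometry is the analytic ellipse of the true body: area
    pi*a*b, Ramanujan perimeter, circularity 4*pi*A/P**2 of the smooth
    ellipse.  Useful for exercising the feature and clock stages at
    scale without the cost (and pixel noise) of render + segment.
    """
    from .tracking import Detection, Track

    tracks = []
    for animal, sub in truth.traj.groupby("animal"):
        tr = Track(track_id=int(animal))
        for row in sub.sort_values("frame").itertuples(index=False):
            a = row.body_len_px / 2.0
            b = a * row.aspect
            area = math.pi * a * b
            h = ((a - b) / (a + b)) ** 2
            perim = math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))
            tr.append(
                Detection(
                    frame=int(row.frame), x=row.x_px, y=row.y_px, area=area, perimeter=perim,
                    major=row.body_len_px, minor=row.body_len_px * row.aspect,
                    circularity=4.0 * math.pi * area / perim**2,
                )
            )
        tracks.append(tr)
    return tracks


def render_video(truth: GroundTruth, config: CohortConfig | None = None) -> np.ndarray:
    """Render a ground truth as an 8-bit grayscale frame stack (T, H, W).

    Animals are filled oriented ellipses (major axis along heading,
    minor/major ratio given by the per-frame presentation), composited
    over a flat background with static debris discs by max intensity;
    additive Gaussian noise with ``noise_sd`` is applied per frame.
    """
    if config is None:
        config = truth.config
    h, w = config.arena_h_px, config.arena_w_px
    n_frames = truth.n_frames

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 17]))
    background = np.full((h, w), config.bg_level, dtype=np.float64)
    for _ in range(config.n_debris):
        cy, cx = rng.uniform(5, h - 5), rng.uniform(5, w - 5)
        r = rng.uniform(1.5, 4.0)
        rr, cc = draw_disk((cy, cx), r, shape=(h, w))
        background[rr, cc] = np.maximum(background[rr, cc], config.debris_intensity)

    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    traj = truth.traj.sort_values(["frame", "animal"])
    by_frame = dict(tuple(traj.groupby("frame"))) if len(traj) else {}
    for t in range(n_frames):
        img = background.copy()
        sub = by_frame.get(t)
        if sub is not None:
            for row in sub.itertuples(index=False):
                a_major = row.body_len_px / 2.0
                a_minor = max(a_major * row.aspect, 1.0)
                rr, cc = draw_ellipse(
                    row.y_px, row.x_px, a_minor, a_major,
                    shape=(h, w), rotation=-row.heading_rad,
                )
                img[rr, cc] = np.maximum(img[rr, cc], config.animal_intensity)
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        frames[t] = np.clip(img, 0, 255).astype(np.uint8)
    return frames


def simulate_survival(
    config: CohortConfig,
    n: int,
    censor_time: float | None = None,
    censor_prob: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw ``n`` i.i.d. lifespans from the configured hazard family.

    Optional right-censoring: administrative at ``censor_time`` days,
    and/or independent random dropout with probability ``censor_prob``
    (dropout time uniform on (0, lifespan)).  Returns a tidy table with
    columns ``id``, ``time`` (days) and ``event`` (1 death, 0 censored).
    """
    from .survival import sample_lifetimes

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed if seed is None else seed), 19]))
    times = sample_lifetimes(config.hazard_family, config.hazard_params, n, rng)
    event = np.ones(n, dtype=int)
    if censor_prob > 0:
        drop = rng.random(n) < censor_prob
        times = np.where(drop, times * rng.uniform(0.0, 1.0, size=n), times)
        event = np.where(drop, 0, event)
    if censor_time is not None:
        late = times > censor_time
        times = np.where(late, censor_time, times)
        event = np.where(late, 0, event)
    times = np.maximum(times, 1e-9)
    return pd.DataFrame({"id": np.arange(n), "time": times, "event": event})
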