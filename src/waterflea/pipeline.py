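"""End-to-end orchestration: simulate -> track -> features -> survival/clock.

Each stage reads its upstream artifact from the output directory (or a
path supplied in the config), writes its own artifact atomically, and is
recorded in a run manifest carrying the config hash, package version,
timestamps and SHA-256 checksums of every input and output.  Re-running
a deterministic stage with the same config and inputs reproduces
identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clock import ClockConfig, PhenotypicClock
from .features import FeatureParams, feature_table
from .io import read_video, sha256_file, write_video
from .stimulus import StimulusSchedule, default_schedule
from .survival import LifespanModel
from .synthdata import CohortConfig, render_video, simulate_survival, simulate_trajectories
from .tracking import SegmentationParams, TrackingParams, track_video, tracks_to_dataframe, dataframe_to_tracks

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "STAGES"]

log = logging.getLogger("waterflea.pipeline")

STAGES = ("simulate", "track", "features", "survival", "clock")


@dataclass
class PipelineConfig:
    """One reproducible run: paths, stage parameter blocks, seed."""

    out_dir: str = "waterflea_run"
    seed: int = 0
    fps: float = 25.0
    px_per_mm: float = 10.0
    stride: int = 25
    age_days: float = 20.0
    cohort_n: int = 2000                     # lifespans drawn in the survival stage
    use_schedule: bool = True
    resume: bool = False
    log_level: str = "INFO"
    # optional external inputs; defaults point inside out_dir
    video_path: str | None = None
    tracks_path: str | None = None
    features_path: str | None = None
    survival_path: str | None = None
    # per-stage parameter blocks (forwarded to the dataclasses)
    cohort: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    tracking: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    clock: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def path(self, name: str) -> Path:
        override = getattr(self, f"{name}_path", None)
        defaults = {
            "video": "video.tif", "truth": "truth.csv", "tracks": "tracks.csv",
            "features": "features.csv", "survival": "survival.csv",
            "schedule": "schedule.json", "km": "km.csv",
            "survival_fits": "survival_fits.json", "clock_report": "clock_report.json",
            "manifest": "manifest.json",
        }
        if override:
            return Path(override)
        return Path(self.out_dir) / defaults[name]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    created: str
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, inputs: list[Path], outputs: list[Path], info: dict | None = None) -> None:
        self.stages[stage] = {
            "inputs": {str(p): sha256_file(p) for p in inputs if Path(p).exists()},
            "outputs": {str(p): sha256_file(p) for p in outputs},
            "finished": datetime.now(timezone.utc).isoformat(),
            **({"info": info} if info else {}),
        }

    def checksums(self) -> dict[str, str]:
        """Flat artifact -> sha map (timestamps excluded), for reproducibility checks."""
        out = {}
        for st in self.stages.values():
            out.update(st["outputs"])
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _atomic_write(path: Path, writer) -> None:
    """Write via a temp file + rename so partial output never clobbers."""
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix)
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        Path(tmp).unlink(missing_ok=True)
        raise


class StageError(RuntimeError):
    """A stage could not run (usually a missing upstream artifact)."""


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(f"stage '{stage}' requires missing input {path}")
    return path


def run_pipeline(config: PipelineConfig, stages=("simulate", "track", "features", "survival")) -> RunManifest:
    """Execute the requested stages in pipeline order, writing a manifest."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; expected subset of {STAGES}")
    stages = [s for s in STAGES if s in stages]

    manifest = RunManifest(config_hash=config.config_hash(), version=__version__,
                           created=datetime.now(timezone.utc).isoformat())
    cohort = CohortConfig(fps=config.fps, px_per_mm=config.px_per_mm, seed=config.seed, **config.cohort)
    schedule = default_schedule(cohort.duration_s) if config.use_schedule else None
    fparams = FeatureParams(px_per_mm=config.px_per_mm, fps=config.fps,
                            arena_h_px=cohort.arena_h_px, **config.features)

    for stage in stages:
        if stage == "simulate":
            video_p, truth_p, sched_p = config.path("video"), config.path("truth"), config.path("schedule")
            if config.resume and video_p.exists() and truth_p.exists():
                log.info("simulate: outputs exist, resuming past")
                continue
            truth = simulate_trajectories(cohort, config.age_days, schedule)
            frames = render_video(truth, cohort)
            _atomic_write(video_p, lambda p: write_video(frames, p))
            _atomic_write(truth_p, lambda p: truth.traj.to_csv(p, index=False))
            outputs = [video_p, truth_p]
            if schedule is not None:
                _atomic_write(sched_p, lambda p: schedule.to_json(p))
                outputs.append(sched_p)
            log.info("simulate: %d animals, %d frames -> %s", cohort.n_animals, truth.n_frames, video_p)
            manifest.record(stage, [], outputs, {"n_animals": cohort.n_animals, "n_frames": truth.n_frames})

        elif stage == "track":
            video_p = _require(config.path("video"), stage)
            tracks_p = config.path("tracks")
            if config.resume and tracks_p.exists():
                continue
            frames = read_video(video_p)
            seg = SegmentationParams(**config.segmentation)
            trk = TrackingParams(**config.tracking)
            tracks, _bg = track_video(frames, fps=config.fps, stride=config.stride, seg_params=seg, trk_params=trk)
            df = tracks_to_dataframe(tracks)
            _atomic_write(tracks_p, lambda p: df.to_csv(p, index=False))
            log.info("track: %d frames -> %d tracks (%d rows)", frames.shape[0], len(tracks), len(df))
            manifest.record(stage, [video_p], [tracks_p], {"n_tracks": len(tracks)})

        elif stage == "features":
            tracks_p = _require(config.path("tracks"), stage)
            feats_p = config.path("features")
            if config.resume and feats_p.exists():
                continue
            tracks = dataframe_to_tracks(pd.read_csv(tracks_p))
            sched_p = config.path("schedule")
            sched = StimulusSchedule.from_json(sched_p) if (config.use_schedule and sched_p.exists()) else None
            table = feature_table(tracks, fparams, sched, metadata={"age_days": config.age_days})
            _atomic_write(feats_p, lambda p: table.to_csv(p, index=False))
            log.info("features: %d tracks -> %d rows x %d cols", len(tracks), *table.shape)
            manifest.record(stage, [tracks_p], [feats_p], {"n_rows": len(table)})

        elif stage == "survival":
            surv_p = config.path("survival")
            inputs = []
            if surv_p.exists():
                records = pd.read_csv(surv_p)
                inputs.append(surv_p)
            else:
                records = simulate_survival(cohort, config.cohort_n)
                _atomic_write(surv_p, lambda p: records.to_csv(p, index=False))
            res = LifespanModel(records).fit()
            km_p, fits_p = config.path("km"), config.path("survival_fits")
            _atomic_write(km_p, lambda p: res.km.survival.to_csv(p, index=False))
            payload = {
                "n": res.km.n, "n_events": res.km.n_events, "km_median_days": res.km.median,
                "fits": {f.family: {"params": f.params, "ses": f.ses, "loglik": f.loglik, "aic": f.aic}
                         for f in res.fits.values()},
                "ranking": res.ranking.to_dict(orient="records") if res.ranking is not None else None,
                "failures": res.failures,
            }
            _atomic_write(fits_p, lambda p: p.write_text(json.dumps(payload, indent=2)))
            log.info("survival: n=%d, KM median=%s, best=%s", res.km.n, res.km.median, res.best_family)
            manifest.record(stage, inputs, [surv_p, km_p, fits_p] if not inputs else [km_p, fits_p],
                            {"km_median": res.km.median, "best_family": res.best_family})

        elif stage == "clock":
            feats_p = _require(config.path("features"), stage)
            report_p = config.path("clock_report")
            df = pd.read_csv(feats_p)
            if "age_days" not in df.columns or df["age_days"].nunique() < 2:
                raise StageError("stage 'clock' needs a features table with >= 2 distinct age_days values")
            cc = ClockConfig(seed=config.seed, **config.clock)
            res = PhenotypicClock.from_dataframe(df.drop(columns=["duration_s"], errors="ignore"), config=cc).fit()
            payload = {"metrics": res.metrics, "cv": res.cv_table.to_dict(orient="records"),
                       "model_family": cc.model_family, "n": int(len(df))}
            _atomic_write(report_p, lambda p: p.write_text(json.dumps(payload, indent=2)))
            log.info("clock: %s", res.summary())
            manifest.record(stage, [feats_p], [report_p], {"heldout_rmse": res.metrics["heldout_rmse"]})

    manifest.save(config.path("manifest"))
    return manifest
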