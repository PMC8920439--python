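"""File formats and table validation for the pipeline.

Video travels as multi-page 8-bit grayscale TIFF (AVI read/write is
supported when an ffmpeg-backed imageio plugin is available); tables are
UTF-8 comma-separated CSV with a header row and '.' decimal; stimulus
schedules and configs are JSON.  A trained clock persists as a zip
archive holding JSON metadata plus the pickled estimator state.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import pickle
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__ as _pkg_version
from .tracking import TRACK_COLUMNS

__all__ = [
    "read_video", "write_video", "sha256_file", "validate_tables",
    "save_clock", "load_clock", "SCHEMAS",
]


def write_video(frames: np.ndarray, path: str | Path) -> None:
    """Write a (T, H, W) uint8 stack as multi-page TIFF or AVI."""
    path = Path(path)
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("expected a (T, H, W) stack")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, frames.astype(np.uint8))
    elif path.suffix.lower() == ".avi":
        import imageio.v2 as imageio

        imageio.mimwrite(path, list(frames.astype(np.uint8)), fps=25)
    else:
        raise ValueError(f"unsupported video format {path.suffix!r} (use .tif/.tiff/.avi)")


def read_video(path: str | Path, invert: bool = False) -> np.ndarray:
    """Read a grayscale video stack; ``invert`` flips intensity polarity
    (for recordings with dark animals on a bright background)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(path)
    elif path.suffix.lower() == ".avi":
        import imageio.v2 as imageio

        frames = np.stack([np.asarray(f) for f in imageio.mimread(path, memtest=False)])
        if frames.ndim == 4:  # RGB -> gray
            frames = frames.mean(axis=-1).astype(np.uint8)
    else:
        raise ValueError(f"unsupported video format {path.suffix!r}")
    if frames.ndim == 2:
        frames = frames[None]
    if invert:
        frames = 255 - frames
    return frames


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# table schemas and validation

SCHEMAS: dict[str, dict] = {
    "tracks": {"required": TRACK_COLUMNS, "strict": False},
    "features": {"required": ["track_id"], "strict": False},
    "survival": {"required": ["id", "time", "event"], "strict": False},
    "census": {"required": ["day", "auto_count"], "strict": False},
    "ledger": {"required": ["day", "curated_count"], "strict": False},
}


def _violation(kind: str, message: str, rows=None) -> dict:
    v = {"kind": kind, "message": message}
    if rows is not None:
        v["rows"] = [int(r) for r in rows]
    return v


def validate_tables(path: str | Path, schema: str) -> list[dict]:
    """Schema + invariant check of a CSV table.

    Returns a machine-readable list of violations (empty = valid).
    Unreadable files yield an ``io_error`` violation, distinct from
    ``schema_mismatch`` and ``invariant`` kinds.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        return [_violation("io_error", f"cannot read {path}: {exc}")]

    spec = SCHEMAS[schema]
    out: list[dict] = []
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        out.append(_violation("schema_mismatch", f"missing columns: {missing}"))
        return out

    from .features import METADATA_COLUMNS, NATURAL_FEATURES, STIMULUS_FEATURES

    if schema == "features":
        known = set(METADATA_COLUMNS) | set(NATURAL_FEATURES) | set(STIMULUS_FEATURES) | {"track_id"}
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            out.append(_violation("schema_mismatch", f"unknown feature columns: {unknown}"))
    if schema == "tracks" and len(df):
        for col in ("frame", "x_px", "y_px", "area_px"):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                out.append(_violation("schema_mismatch", f"non-numeric values in {col}", bad[:20]))
        if not out:
            dup = df.duplicated(subset=["track_id", "frame"])
            if dup.any():
                out.append(_violation("invariant", "duplicate (track_id, frame) rows", df.index[dup][:20]))
            if (df["area_px"] <= 0).any():
                out.append(_violation("invariant", "non-positive blob areas", df.index[df["area_px"] <= 0][:20]))
    if schema == "survival" and len(df):
        bad_t = df.index[~(pd.to_numeric(df["time"], errors="coerce") > 0)]
        if len(bad_t):
            out.append(_violation("invariant", "event times must be positive", bad_t[:20]))
        bad_e = df.index[~df["event"].isin([0, 1])]
        if len(bad_e):
            out.append(_violation("invariant", "event must be 0 or 1", bad_e[:20]))
    if schema == "census" and len(df) > 1:
        col = "count" if "count" in df.columns else "auto_count"
        c = df.sort_values("day")[col].to_numpy()
        rising = np.where(np.diff(c) > 0)[0]
        if rising.size:
            out.append(_violation("invariant", "census counts increase between censuses", rising))
    return out


# ---------------------------------------------------------------------------
# clock persistence

def save_clock(results, path: str | Path) -> None:
    """Persist a fitted clock as a versioned zip (metadata + pickle)."""
    path = Path(path)
    meta = {
        "format": "waterflea-clock",
        "format_version": 1,
        "package_version": _pkg_version,
        "model_family": results.config.model_family,
        "feature_names": results.feature_names,
        "metrics": results.metrics,
        "seed": results.config.seed,
    }
    buf = _io.BytesIO()
    pickle.dump(results, buf)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=2))
        zf.writestr("state.pkl", buf.getvalue())


def load_clock(path: str | Path):
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("format") != "waterflea-clock":
            raise ValueError(f"{path} is not a clock archive")
        return pickle.loads(zf.read("state.pkl"))
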