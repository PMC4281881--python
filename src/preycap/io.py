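"""Readers and writers for the pipeline's on-disk artifacts.

Formats: multi-page 8-bit grayscale TIFF for videos and movies
(tifffile), JSON sidecars for tail-trace ground truth (frame → list of
[x, y] points, 0-based pixel coordinates, origin top-left), CSV tables
for bouts and feature matrices, and a versioned joblib archive for
trained classifiers.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import tifffile

from .classifier import TrainedClassifier
from .core import Bout, TailTrace
from .exceptions import SchemaError

MODEL_SCHEMA_VERSION = 1
TRACE_SCHEMA_VERSION = 1


def write_video(path, frames: np.ndarray) -> None:
    """Write a (T, H, W) stack as multi-page 8-bit grayscale TIFF."""
    data = np.clip(np.asarray(frames), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, data)


def read_video(path) -> np.ndarray:
    """Read a multi-page TIFF (or a directory of PNG frames) as (T, H, W)."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames in {path}")
        return np.stack([iio.imread(f) for f in files]).astype(float)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return data.astype(float)


def write_trace(path, trace: TailTrace) -> None:
    """Trace JSON sidecar: schema_version, frame_rate, tail_length_px,
    frames: list of [[x, y], ...] per frame (null for failed frames)."""
    frames = []
    for f in range(trace.n_frames):
        pts = trace.points[f]
        frames.append(None if not np.isfinite(pts).all() else pts.tolist())
    payload = {
        "schema_version": TRACE_SCHEMA_VERSION,
        "frame_rate": trace.frame_rate,
        "tail_length_px": trace.tail_length_px,
        "frames": frames,
    }
    Path(path).write_text(json.dumps(payload))


def read_trace(path) -> TailTrace:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != TRACE_SCHEMA_VERSION:
        raise SchemaError(f"unsupported trace schema in {path}")
    frames = payload["frames"]
    n_points = next(len(f) for f in frames if f is not None)
    pts = np.full((len(frames), n_points, 2), np.nan)
    for i, f in enumerate(frames):
        if f is not None:
            pts[i] = np.asarray(f, dtype=float)
    return TailTrace(
        points=pts,
        frame_rate=float(payload["frame_rate"]),
        tail_length_px=float(payload["tail_length_px"]),
    )


def write_bout_table(path, bouts: list[Bout], trial_id: str = "trial") -> None:
    rows = [
        {
            "trial_id": trial_id,
            "bout_id": i,
            "start_frame": b.start_frame,
            "end_frame": b.end_frame,
            "label": b.label or "",
        }
        for i, b in enumerate(bouts)
    ]
    pd.DataFrame(
        rows, columns=["trial_id", "bout_id", "start_frame", "end_frame", "label"]
    ).to_csv(path, index=False)


def read_bout_table(path) -> list[Bout]:
    df = pd.read_csv(path)
    return [
        Bout(int(r.start_frame), int(r.end_frame), label=(r.label if isinstance(r.label, str) and r.label else None))
        for r in df.itertuples()
    ]


def write_feature_table(path, features: pd.DataFrame, labels=None) -> None:
    out = features.copy()
    if labels is not None:
        out["label"] = labels
    out.to_csv(path, index=False)


def read_feature_table(path) -> tuple[pd.DataFrame, np.ndarray | None]:
    df = pd.read_csv(path)
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy()
    return df, labels


def save_model(path, clf: TrainedClassifier) -> None:
    """Versioned classifier archive (joblib) with a schema stamp."""
    joblib.dump({"schema_version": MODEL_SCHEMA_VERSION, "model": clf}, path)


def load_model(path) -> TrainedClassifier:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise SchemaError(f"unsupported model archive {path}")
    return payload["model"]


def write_movie(path, frames: np.ndarray) -> None:
    """Write a fluorescence stack as multi-page TIFF (float32 preserved)."""
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))


def read_movie(path) -> np.ndarray:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return data.astype(float)
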