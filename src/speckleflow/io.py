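"""Readers and writers for the package's on-disk formats.

Videos are stored as multi-page 8-bit grayscale TIFF (one page per frame)
with a JSON sidecar carrying the simulation parameters and ground-truth
condition; dataset manifests are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .conditions import FlowCondition
from .simulate import SimulationParams, SpeckleVideo

__all__ = ["write_video", "read_video", "write_manifest", "read_manifest",
           "write_dataset"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_video(video: SpeckleVideo, path) -> Path:
    """Write frames as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, video.frames, photometric="minisblack")
    meta = {
        "video_id": video.video_id,
        "fps": video.fps,
        "condition": video.condition.name,
        "params": video.params.to_dict(),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_video(path) -> SpeckleVideo:
    """Read a TIFF video and its sidecar back into a SpeckleVideo."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several format errors
        raise ValueError(f"{path} is not a readable TIFF video: {exc}") from exc
    frames = np.atleast_3d(np.asarray(frames))
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    params = SimulationParams.from_dict(meta["params"])
    return SpeckleVideo(
        frames=frames.astype(np.uint8),
        fps=float(meta["fps"]),
        params=params,
        condition=FlowCondition[meta["condition"]],
        video_id=meta.get("video_id", path.stem),
    )


def write_manifest(manifest: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_dataset(videos: list[SpeckleVideo], manifest: pd.DataFrame, out_dir) -> Path:
    """Write all videos plus a manifest (with a ``path`` column) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for video in videos:
        p = write_video(video, out_dir / f"{video.video_id}.tiff")
        paths.append(str(p.relative_to(out_dir)))
    manifest = manifest.copy()
    manifest["path"] = paths
    write_manifest(manifest, out_dir / "manifest.csv")
    return out_dir


def read_dataset(data_dir) -> tuple[list[SpeckleVideo], pd.DataFrame]:
    """Load a dataset directory written by :func:`write_dataset`."""
    data_dir = Path(data_dir)
    manifest = read_manifest(data_dir / "manifest.csv")
    videos = [read_video(data_dir / p) for p in manifest["path"]]
    return videos, manifest
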