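"""Video-to-training-sample preprocessing: normalise, chunk, split.

Raw 8-bit recordings are scaled to [0, 1], cut into overlapping 64-frame
chunks (stride 32), replicated to three identical channels, and split so
that the last-recorded video of every measurement cell is held out for
testing while 10% of the remaining chunks form a validation set.  Leakage
control is at video level: chunks of one video never straddle the
train/test boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeding import derive_seed
from .conditions import FlowCondition
from .simulate import SpeckleVideo

__all__ = [
    "Chunk",
    "DatasetSplit",
    "normalize",
    "chunk_video",
    "to_three_channel",
    "chunk_count",
    "build_split",
]

logger = logging.getLogger(__name__)

CHUNK_SIZE = 64
CHUNK_STRIDE = 32
VAL_FRACTION = 0.10


@dataclass
class Chunk:
    """One classifier input sample: a 64-frame window of one video.

    Frames are stored single-channel uint8 and materialised to the
    3 x 64 x H x W float32 tensor on demand (the three channels are
    identical), keeping memory bounded for large datasets.
    """

    raw_frames: np.ndarray          # uint8, size x H x W
    label: FlowCondition
    video_id: str
    start_frame: int
    split: str = "train"

    @property
    def n_frames(self) -> int:
        return self.raw_frames.shape[0]

    def to_tensor(self) -> np.ndarray:
        """Normalised three-channel tensor, shape (3, size, H, W) in [0, 1]."""
        return to_three_channel(normalize(self.raw_frames))


@dataclass
class DatasetSplit:
    """Train / validation / test chunk collections with the seed that made them."""

    train_chunks: list[Chunk]
    val_chunks: list[Chunk]
    test_chunks: list[Chunk]
    split_seed: int = 0

    def video_ids(self, part: str) -> set[str]:
        return {c.video_id for c in getattr(self, f"{part}_chunks")}


def normalize(frames: np.ndarray) -> np.ndarray:
    """Scale 8-bit gray values to [0, 1] by exact division by 255."""
    frames = np.asarray(frames)
    if frames.dtype != np.uint8 and (frames.min() < 0 or frames.max() > 255):
        raise ValueError("input values must lie in [0, 255]")
    return frames.astype(np.float32) / np.float32(255.0)


def chunk_count(n_frames: int, size: int = CHUNK_SIZE, stride: int = CHUNK_STRIDE) -> int:
    """Number of complete windows: floor((T - size)/stride) + 1, or 0 if T < size."""
    if n_frames < size:
        return 0
    return (n_frames - size) // stride + 1


def chunk_video(
    video: SpeckleVideo | np.ndarray,
    size: int = CHUNK_SIZE,
    stride: int = CHUNK_STRIDE,
    split: str = "train",
) -> list[Chunk]:
    """Cut a video into overlapping complete windows of ``size`` frames.

    Windows start at 0, stride, 2*stride, ...; a trailing partial window is
    dropped.  A video shorter than one window yields an empty list and a
    logged warning rather than an error.
    """
    if size < 1 or stride < 1:
        raise ValueError("size and stride must be >= 1")
    if isinstance(video, SpeckleVideo):
        frames, label, video_id = video.frames, video.condition, video.video_id
    else:
        frames = np.asarray(video)
        label, video_id = FlowCondition.ZERO, ""
    T = frames.shape[0]
    if T < size:
        logger.warning(
            "video %r has %d frames, shorter than one %d-frame chunk; skipped",
            video_id, T, size,
        )
        return []
    return [
        Chunk(
            raw_frames=frames[start : start + size],
            label=label,
            video_id=video_id,
            start_frame=start,
            split=split,
        )
        for start in range(0, T - size + 1, stride)
    ]


def to_three_channel(chunk: np.ndarray) -> np.ndarray:
    """Replicate a single-channel (T, H, W) chunk to three identical channels."""
    chunk = np.asarray(chunk)
    if chunk.ndim != 3:
        raise ValueError(
            f"expected single-channel (T, H, W) input, got shape {chunk.shape}"
        )
    return np.broadcast_to(chunk, (3, *chunk.shape)).copy()


def build_split(
    videos: list[SpeckleVideo],
    manifest: pd.DataFrame,
    split_seed: int = 0,
    size: int = CHUNK_SIZE,
    stride: int = CHUNK_STRIDE,
) -> DatasetSplit:
    """Chunk all videos and build the train/val/test split.

    All chunks of manifest rows flagged ``split="test"`` (the last-recorded
    video per measurement cell) go to test.  The remaining chunks are
    shuffled with ``split_seed`` and 10% (rounded) become validation.  Every
    measurement cell must contribute at least two videos so that both a
    training and a test video exist.
    """
    cells = manifest.groupby(
        ["diameter_mm", "depth_mm", "condition"], sort=False
    )
    for key, grp in cells:
        if len(grp) < 2:
            raise ValueError(
                f"measurement cell {key} has a single video; need >= 2 "
                "(training plus held-out test)"
            )
        if not (grp["split"] == "test").any():
            raise ValueError(f"measurement cell {key} has no test-flagged video")

    split_of = dict(zip(manifest["video_id"], manifest["split"]))
    test_chunks: list[Chunk] = []
    pool: list[Chunk] = []
    for video in videos:
        part = split_of.get(video.video_id, "train")
        chunks = chunk_video(video, size=size, stride=stride, split=part)
        (test_chunks if part == "test" else pool).extend(chunks)

    rng = np.random.default_rng(derive_seed(split_seed, "val-split"))
    order = rng.permutation(len(pool))
    n_val = round(VAL_FRACTION * len(pool))
    val_idx = set(order[:n_val].tolist())
    val_chunks, train_chunks = [], []
    for i, chunk in enumerate(pool):
        if i in val_idx:
            chunk.split = "val"
            val_chunks.append(chunk)
        else:
            train_chunks.append(chunk)
    return DatasetSplit(
        train_chunks=train_chunks,
        val_chunks=val_chunks,
        test_chunks=test_chunks,
        split_seed=split_seed,
    )
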