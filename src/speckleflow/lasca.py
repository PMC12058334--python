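"""Laser speckle contrast analysis (LASCA) with single-point calibration.

LASCA infers flow speed from the spatial contrast K = sigma/mu of the speckle
intensity: motion within the camera exposure blurs the pattern and lowers K,
so higher velocity means lower contrast.  The classical single-point scheme
calibrates a proportionality constant A from one reference recording with a
known velocity and then applies V = A / K^2 to subsequent recordings.

That relation implicitly assumes a fixed optical geometry.  The
``cross_depth_experiment`` below demonstrates its breakdown under defocused
imaging of vessels at different depths: the depth-dependent static scattering
and blur change K for reasons unrelated to velocity, so a calibration taken
at one depth systematically mis-estimates velocity at another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conditions import FlowCondition
from .simulate import SpeckleVideo

__all__ = [
    "ContrastResult",
    "LascaCalibration",
    "local_contrast",
    "video_mean_contrast",
    "calibrate_single_point",
    "estimate_velocity",
    "cross_depth_experiment",
]


@dataclass
class ContrastResult:
    """Per-window speckle contrast values of one frame."""

    contrast_map: np.ndarray  # K per non-overlapping window (NaN where excluded)
    mean_contrast: float
    window: int


@dataclass(frozen=True)
class LascaCalibration:
    """Single-point calibration V = A / K^2 with its reference point."""

    constant_A: float     # cm/s * contrast^2
    ref_velocity: float   # cm/s
    ref_contrast: float
    ref_depth: float      # mm

    def __post_init__(self):
        if self.constant_A <= 0 or self.ref_velocity <= 0 or self.ref_contrast <= 0:
            raise ValueError("calibration quantities must be positive")


def local_contrast(frame: np.ndarray, window: int = 7) -> ContrastResult:
    """Speckle contrast sigma/mu over non-overlapping square windows.

    The standard deviation is the population (divide-by-n) estimator.
    Windows with zero mean are excluded; the frame is cropped to a whole
    number of windows.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    if h < window or w < window:
        raise ValueError("frame smaller than the contrast window")
    nh, nw = h // window, w // window
    blocks = frame[: nh * window, : nw * window].reshape(nh, window, nw, window)
    mu = blocks.mean(axis=(1, 3))
    sd = blocks.std(axis=(1, 3))  # population std
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(mu > 0, sd / mu, np.nan)
    valid = np.isfinite(k)
    if not valid.any():
        raise ValueError("no window with non-zero mean intensity")
    return ContrastResult(
        contrast_map=k, mean_contrast=float(np.nanmean(k)), window=window
    )


def video_mean_contrast(video: SpeckleVideo | np.ndarray, window: int = 7) -> float:
    """Mean speckle contrast of a recording: per-frame contrast averaged over frames."""
    frames = video.frames if isinstance(video, SpeckleVideo) else np.asarray(video)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("video must contain at least one frame")
    return float(
        np.mean([local_contrast(f, window).mean_contrast for f in frames])
    )


def calibrate_single_point(
    ref_video: SpeckleVideo, known_velocity: float, window: int = 7
) -> LascaCalibration:
    """Calibrate A = V_ref * K_ref^2 from one recording with known velocity."""
    if known_velocity <= 0:
        raise ValueError("cannot calibrate on a zero-velocity reference")
    k = video_mean_contrast(ref_video, window)
    depth = ref_video.params.depth if isinstance(ref_video, SpeckleVideo) else float("nan")
    return LascaCalibration(
        constant_A=known_velocity * k * k,
        ref_velocity=known_velocity,
        ref_contrast=k,
        ref_depth=depth,
    )


def estimate_velocity(
    calibration: LascaCalibration, video: SpeckleVideo | np.ndarray, window: int = 7
) -> float:
    """Estimate velocity as V = A / K^2 under the calibration's geometry."""
    k = video_mean_contrast(video, window)
    if k <= 0:
        raise ValueError("video contrast is zero; velocity undefined")
    return calibration.constant_A / (k * k)


def cross_depth_experiment(
    videos: list[SpeckleVideo],
    manifest: pd.DataFrame,
    calibration_depth: float,
    test_depths: list[float],
    condition: FlowCondition = FlowCondition.MEDIUM,
    window: int = 7,
) -> tuple[pd.DataFrame, pd.DataFrame, LascaCalibration]:
    """Apply one single-point calibration across depths and tabulate the error.

    The calibration is built from the first train-split video of ``condition``
    at ``calibration_depth`` (its manifest velocity is the known reference).
    Every other video of the same condition at each requested depth is then
    processed with that calibration.

    Returns ``(table, summary, calibration)`` where ``table`` has one row per
    test video (depth_mm, true_velocity, estimated_velocity, rel_error) and
    ``summary`` aggregates mean signed and mean absolute relative error per
    depth.
    """
    by_id = {v.video_id: v for v in videos}
    sel = manifest[manifest["condition"] == condition.name]
    for depth in [calibration_depth, *test_depths]:
        if not (sel["depth_mm"] == depth).any():
            raise ValueError(f"dataset has no {condition.name} videos at depth {depth} mm")

    cal_rows = sel[(sel["depth_mm"] == calibration_depth) & (sel["split"] == "train")]
    if cal_rows.empty:
        raise ValueError(f"no train-split calibration video at depth {calibration_depth} mm")
    cal_row = cal_rows.iloc[0]
    calibration = calibrate_single_point(
        by_id[cal_row["video_id"]], float(cal_row["velocity_cm_s"]), window
    )

    rows = []
    for depth in test_depths:
        test_rows = sel[
            (sel["depth_mm"] == depth) & (sel["video_id"] != cal_row["video_id"])
        ]
        for _, r in test_rows.iterrows():
            v_true = float(r["velocity_cm_s"])
            v_hat = estimate_velocity(calibration, by_id[r["video_id"]], window)
            rows.append(
                dict(
                    depth_mm=depth,
                    true_velocity=v_true,
                    estimated_velocity=v_hat,
                    rel_error=(v_hat - v_true) / v_true,
                )
            )
    table = pd.DataFrame(rows)
    summary = (
        table.assign(abs_rel_error=table["rel_error"].abs())
        .groupby("depth_mm")[["rel_error", "abs_rel_error"]]
        .mean()
        .rename(columns={"rel_error": "mean_signed_rel_error",
                         "abs_rel_error": "mean_abs_rel_error"})
        .reset_index()
    )
    return table, summary, calibration
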