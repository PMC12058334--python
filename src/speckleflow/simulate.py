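"""Dynamic defocused-speckle video simulator for a flow phantom.

The simulator emulates high-speed recordings of secondary speckle produced by
coherent illumination of a tissue phantom with an embedded artificial artery.
Its output statistics encode the three experimental variables:

* **flow velocity** — the complex speckle field decorrelates with a time
  constant ``tau_c = decorrelation_scale / velocity``, realised as a
  first-order autoregressive (AR(1)) evolution of the field between exposure
  sub-steps.  Averaging several sub-steps inside one exposure converts motion
  into spatial-contrast loss, the mechanism LASCA exploits.
* **vessel depth** — deeper vessels contribute a larger statically scattered
  component (``static_fraction``) and a broader effective PSF (``blur_sigma``),
  both of which wash out the dynamic signal.
* **pulsation** — a 1 Hz raised-sine modulation of the instantaneous velocity
  plus a small whole-frame translation emulating mechanical coupling of the
  pulse emulator to the rig.

The speckle field itself is synthesised in the Fourier domain: a unit-variance
circular complex Gaussian random field is low-pass filtered by a circular
pupil whose radius (as a fraction of the Nyquist radius) sets the speckle
grain size, then inverse transformed.  This reproduces the statistics of the
free-space diffraction integral for a rough surface — fully developed,
polarised speckle with negative-exponential intensity and unit contrast —
without numerical integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ._seeding import derive_seed
from .conditions import FlowCondition, VELOCITY_RANGES, ConditionSpec
from .flow import pulsation_velocity

__all__ = [
    "SimulationParams",
    "SpeckleField",
    "SpeckleVideo",
    "DEPTH_STATIC_FRACTION",
    "DEPTH_BLUR_SIGMA",
    "full_scale_params",
    "desk_scale_params",
    "generate_field",
    "decorrelation_factor",
    "evolve_field",
    "render_frame",
    "simulate_video",
    "make_phantom_dataset",
]


# Depth-degradation model: fraction of statically scattered light and
# effective PSF width (pixels) versus depth of the vessel top below the
# surface.  Chosen to reproduce the qualitative contrast loss with depth
# while keeping every flow state distinguishable.
DEPTH_STATIC_FRACTION: dict[float, float] = {0.0: 0.2, 5.0: 0.5, 10.0: 0.7}
DEPTH_BLUR_SIGMA: dict[float, float] = {0.0: 0.0, 5.0: 1.0, 10.0: 2.0}

#: velocity (cm/s) times frame interval at which the field correlation drops
#: to 1/e per frame; default makes the restricted-flow midpoint of a 3 mm
#: vessel (5.5 cm/s) decorrelate with tau_c = 10 frame intervals at 300 fps.
DEFAULT_DECORRELATION_SCALE = 5.5 * 10.0 / 300.0  # cm

#: fixed quantisation gain: mean speckle intensity (1.0) maps to gray level 50,
#: so under 1% of the pixels of a unit-contrast exponential intensity saturate
#: at 255 and the rendered contrast stays close to the field contrast.
QUANT_GAIN = 50.0


@dataclass(frozen=True)
class SimulationParams:
    """Full generative description of one phantom recording."""

    height: int = 224
    width: int = 224
    fps: float = 300.0
    duration: float = 33.0
    wavelength: float = 532e-9          # m, illumination wavelength
    propagation_distance: float = 0.5   # m, object-to-sensor distance
    grain_radius: float = 0.5           # pupil radius / Nyquist radius
    velocity: float = 0.0               # cm/s, mean flow velocity
    depth: float = 0.0                  # mm, vessel top below surface
    diameter: float = 3.0               # mm, vessel inner diameter
    pulse_freq: float = 1.0             # Hz
    pulse_modulation: float = 0.3       # m in v(t) = v0*(1 + m sin)
    static_fraction: float | None = None   # beta(depth) if None
    blur_sigma: float | None = None        # sigma(depth) px if None
    decorrelation_scale: float = DEFAULT_DECORRELATION_SCALE  # cm
    exposure_substeps: int = 4
    translation_amplitude: float = 0.5  # px, residual 1 Hz rig motion
    noise_sigma: float = 0.5            # gray levels, sensor noise
    seed: int = 0
    bit_depth: int = 8

    def __post_init__(self):
        if self.velocity < 0:
            raise ValueError("velocity must be non-negative")
        if not 0.0 < self.grain_radius <= 1.0:
            raise ValueError(f"grain_radius must be in (0, 1], got {self.grain_radius}")
        if self.exposure_substeps < 1:
            raise ValueError("exposure_substeps must be >= 1")
        if not 0.0 <= self.pulse_modulation < 1.0:
            raise ValueError("pulse_modulation must be in [0, 1)")
        beta = self.resolved_static_fraction
        if not 0.0 <= beta < 1.0:
            raise ValueError(f"static_fraction must be in [0, 1), got {beta}")
        if self.resolved_blur_sigma < 0:
            raise ValueError("blur_sigma must be non-negative")
        if self.translation_amplitude < 0 or self.noise_sigma < 0:
            raise ValueError("translation_amplitude and noise_sigma must be >= 0")
        if self.decorrelation_scale <= 0:
            raise ValueError("decorrelation_scale must be positive")
        n = self.fps * self.duration
        if abs(n - round(n)) > 1e-6:
            raise ValueError(
                f"fps*duration must be an integer frame count, got {n}"
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration))

    @property
    def resolved_static_fraction(self) -> float:
        if self.static_fraction is not None:
            return self.static_fraction
        return DEPTH_STATIC_FRACTION.get(float(self.depth), 0.2)

    @property
    def resolved_blur_sigma(self) -> float:
        if self.blur_sigma is not None:
            return self.blur_sigma
        return DEPTH_BLUR_SIGMA.get(float(self.depth), 0.0)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        return cls(**d)


def full_scale_params(**overrides) -> SimulationParams:
    """The recording geometry of the phantom experiment: 224x224 @ 300 fps, 33 s."""
    return SimulationParams(**overrides)


def desk_scale_params(**overrides) -> SimulationParams:
    """Reduced geometry (64x64, 5 s) with identical statistics, for CPU work."""
    defaults = dict(height=64, width=64, duration=5.0)
    defaults.update(overrides)
    return SimulationParams(**defaults)


@dataclass
class SpeckleField:
    """Complex speckle amplitude over the pixel grid."""

    amplitude: np.ndarray  # complex128, H x W
    grain_radius: float

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.amplitude) ** 2


@dataclass
class SpeckleVideo:
    """Time-ordered stack of 8-bit frames plus provenance."""

    frames: np.ndarray  # uint8, T x H x W
    fps: float
    params: SimulationParams
    condition: FlowCondition
    video_id: str = ""

    def __post_init__(self):
        if self.frames.dtype != np.uint8:
            raise ValueError("frames must be uint8")
        if self.frames.ndim != 3:
            raise ValueError("frames must be T x H x W")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _pupil_mask(height: int, width: int, grain_radius: float) -> np.ndarray:
    """Circular low-pass mask in FFT coordinates; radius in Nyquist units."""
    fy = np.fft.fftfreq(height)[:, None]   # cycles/px in [-0.5, 0.5)
    fx = np.fft.fftfreq(width)[None, :]
    r = np.hypot(fy, fx) / 0.5             # 1.0 at the Nyquist frequency
    return (r <= grain_radius).astype(float)


def _raw_field(mask: np.ndarray, norm: float, rng: np.random.Generator) -> np.ndarray:
    h, w = mask.shape
    noise = rng.standard_normal((h, w)) + 1j * rng.standard_normal((h, w))
    return np.fft.ifft2(np.fft.fft2(noise) * mask) / norm


def generate_field(params: SimulationParams, rng: np.random.Generator) -> SpeckleField:
    """Draw one fully developed speckle field with unit mean intensity.

    The field is circular complex Gaussian (so its intensity is
    negative-exponential with contrast 1) and spatially correlated with a
    grain size inversely proportional to ``grain_radius``.  Normalisation is
    analytic — division by the expected RMS amplitude of the filtered noise —
    which preserves exact Gaussianity of the marginals.
    """
    if not 0.0 < params.grain_radius <= 1.0:
        raise ValueError("grain_radius must be in (0, 1]")
    mask = _pupil_mask(params.height, params.width, params.grain_radius)
    # E|a|^2 of the filtered unit-variance complex noise = 2*sum(mask)/N^2
    norm = math.sqrt(2.0 * mask.sum() / mask.size)
    amplitude = _raw_field(mask, norm, rng)
    return SpeckleField(amplitude=amplitude, grain_radius=params.grain_radius)


def decorrelation_factor(velocity: float, dt: float, decorrelation_scale: float) -> float:
    """Field correlation over a time step: rho = exp(-v*dt/k_v).

    ``decorrelation_scale`` (cm) maps velocity (cm/s) to the correlation time
    tau_c = k_v / v; rho(0) = 1 and rho decreases strictly with velocity.
    """
    if velocity < 0:
        raise ValueError("velocity must be non-negative")
    if dt <= 0 or decorrelation_scale <= 0:
        raise ValueError("dt and decorrelation_scale must be positive")
    return float(np.exp(-velocity * dt / decorrelation_scale))


def evolve_field(
    fld: SpeckleField, rho: float, rng: np.random.Generator
) -> SpeckleField:
    """One AR(1) step of the complex field: A' = rho*A + sqrt(1-rho^2)*eps.

    ``eps`` is an independent field with the same marginal distribution, so
    the stationary statistics (Gaussianity, grain size, unit mean intensity)
    are preserved for any rho in [0, 1].
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    if rho == 1.0:
        return fld
    h, w = fld.amplitude.shape
    mask = _pupil_mask(h, w, fld.grain_radius)
    norm = math.sqrt(2.0 * mask.sum() / mask.size)
    eps = _raw_field(mask, norm, rng)
    amplitude = rho * fld.amplitude + math.sqrt(1.0 - rho * rho) * eps
    return SpeckleField(amplitude=amplitude, grain_radius=fld.grain_radius)


def render_frame(
    dynamic_field: SpeckleField,
    static_field: SpeckleField,
    params: SimulationParams,
    substep_fields: Sequence[SpeckleField],
    shift_px: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one 8-bit frame from the intra-exposure field sub-steps.

    The exposure integrates the instantaneous intensity over the sub-step
    fields; a depth-dependent static speckle component is mixed in, the
    result is blurred by the effective PSF, translated by the pulsation-driven
    whole-frame displacement, corrupted with sensor noise, scaled by the fixed
    quantisation gain and clipped to [0, 255].
    """
    if len(substep_fields) == 0:
        raise ValueError("at least one exposure substep is required")
    beta = params.resolved_static_fraction
    intensity = np.mean([f.intensity for f in substep_fields], axis=0)
    intensity = (1.0 - beta) * intensity + beta * static_field.intensity
    sigma = params.resolved_blur_sigma
    if sigma > 0:
        intensity = ndimage.gaussian_filter(intensity, sigma, mode="wrap")
    if shift_px != (0.0, 0.0):
        intensity = ndimage.shift(intensity, shift_px, order=1, mode="grid-wrap")
    out = intensity * QUANT_GAIN
    if params.noise_sigma > 0:
        if rng is None:
            raise ValueError("rng required when noise_sigma > 0")
        out = out + rng.normal(0.0, params.noise_sigma, out.shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def simulate_video(
    params: SimulationParams, condition: FlowCondition | None = None, video_id: str = ""
) -> SpeckleVideo:
    """Simulate a full recording, deterministic given ``params.seed``.

    Each output frame averages ``exposure_substeps`` field states spanning the
    full inter-frame interval (100% exposure duty cycle); between sub-steps
    the field evolves by AR(1) with rho computed from the instantaneous
    pulsatile velocity.  Zero-velocity recordings keep a frozen field (rho=1)
    and differ across frames only through sensor noise and the residual
    mechanical translation.
    """
    rng = np.random.default_rng(params.seed)
    static_field = generate_field(params, rng)
    dyn = generate_field(params, rng)

    T = params.n_frames
    S = params.exposure_substeps
    dt_sub = 1.0 / (params.fps * S)
    frames = np.empty((T, params.height, params.width), dtype=np.uint8)
    static_case = params.velocity == 0.0

    for t in range(T):
        substeps = []
        for s in range(S):
            t_sub = (t * S + s) * dt_sub
            if static_case:
                substeps.append(dyn)
            else:
                v_inst = pulsation_velocity(
                    t_sub, params.velocity, params.pulse_modulation, params.pulse_freq
                )
                rho = decorrelation_factor(v_inst, dt_sub, params.decorrelation_scale)
                dyn = evolve_field(dyn, rho, rng)
                substeps.append(dyn)
        t_frame = (t + 0.5) / params.fps
        disp = params.translation_amplitude * math.sin(
            2.0 * math.pi * params.pulse_freq * t_frame
        )
        frames[t] = render_frame(
            dyn, static_field, params, substeps, shift_px=(disp, disp), rng=rng
        )

    if condition is None:
        condition = FlowCondition.ZERO if static_case else _infer_condition(params)
    return SpeckleVideo(
        frames=frames, fps=params.fps, params=params, condition=condition,
        video_id=video_id,
    )


def _infer_condition(params: SimulationParams) -> FlowCondition:
    ranges = VELOCITY_RANGES.get(float(params.diameter))
    if ranges:
        for cond, (lo, hi) in ranges.items():
            if lo <= params.velocity <= hi:
                return cond
    # fall back to nearest range midpoint
    mids = {c: ConditionSpec(c, 3.0).midpoint for c in FlowCondition}
    return min(mids, key=lambda c: abs(mids[c] - params.velocity))


DEFAULT_GRID: tuple[tuple[float, float], ...] = (
    (3.0, 0.0), (3.0, 5.0), (3.0, 10.0), (6.0, 0.0), (6.0, 5.0),
)


def make_phantom_dataset(
    grid_spec: Iterable[tuple[float, float]] = DEFAULT_GRID,
    seed: int = 0,
    base_params: SimulationParams | None = None,
    replicates: int = 3,
    conditions: Sequence[FlowCondition] = tuple(FlowCondition),
    velocity_sampling: str = "uniform",
) -> tuple[list[SpeckleVideo], pd.DataFrame]:
    """Simulate the full phantom measurement grid.

    For every (diameter, depth) cell and every flow condition, ``replicates``
    videos are recorded (default 3); the last replicate of each cell/condition
    is flagged ``split="test"`` in the manifest, mirroring the protocol of
    holding out the last-recorded video.  Velocities are drawn uniformly from
    the condition's range per video (``velocity_sampling="uniform"``) or
    pinned to the range midpoint (``"midpoint"``, used for calibration-style
    experiments that need a known reference velocity).

    Returns the videos and a manifest DataFrame with columns
    video_id, diameter_mm, depth_mm, velocity_cm_s, condition, split, seed.
    """
    grid = list(grid_spec)
    if not grid:
        raise ValueError("grid_spec must contain at least one (diameter, depth) cell")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if velocity_sampling not in ("uniform", "midpoint"):
        raise ValueError(f"unknown velocity_sampling {velocity_sampling!r}")
    if base_params is None:
        base_params = desk_scale_params()

    videos: list[SpeckleVideo] = []
    rows = []
    for diameter, depth in grid:
        for cond in conditions:
            lo, hi = VELOCITY_RANGES[float(diameter)][cond]
            for rep in range(replicates):
                video_id = f"d{diameter:g}mm_z{depth:g}mm_{cond.short}_r{rep}"
                vid_seed = derive_seed(seed, "video", video_id)
                vrng = np.random.default_rng(derive_seed(seed, "velocity", video_id))
                if velocity_sampling == "midpoint" or lo == hi:
                    velocity = 0.5 * (lo + hi)
                else:
                    velocity = float(vrng.uniform(lo, hi))
                params = replace(
                    base_params,
                    velocity=velocity, depth=depth, diameter=diameter, seed=vid_seed,
                )
                videos.append(simulate_video(params, condition=cond, video_id=video_id))
                rows.append(
                    dict(
                        video_id=video_id,
                        diameter_mm=diameter,
                        depth_mm=depth,
                        velocity_cm_s=velocity,
                        condition=cond.name,
                        split="test" if rep == replicates - 1 else "train",
                        seed=vid_seed,
                    )
                )
    manifest = pd.DataFrame(rows)
    return videos, manifest
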