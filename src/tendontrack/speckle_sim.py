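"""Synthetic ultrasound-like speckle sequences with known ground truth.

Frames are rendered from a field of point scatterers with continuous
coordinates: each frame shifts the scatterers by the cumulative ground-truth
displacement (so sub-pixel motion is exact), splats them bilinearly onto the
pixel grid and blurs with an anisotropic Gaussian point-spread (lateral
wider than axial, as in B-mode imaging). Speckle-like multiplicative
variation emerges from the random scatterer interference itself; additive
Gaussian sensor noise is applied afterwards. Out-of-plane motion cannot be
rendered in 2-D, so its footprint — frame-to-frame texture decorrelation —
is emulated by replacing, independently in every frame, a transient
fraction ``rho`` of a persistent base scatterer field. This models
reversible elevational jitter (tissue wobbling through the beam and back),
which bounds the decorrelation between any two frames; an irreversible
elevational sweep, which decorrelates frames cumulatively until nothing
matchable remains, is outside the operating range of interval-based
matching and is not what this test-bed emulates.

This is a tracking test-bed, not an RF/beamforming simulator: it reproduces
the statistics that matter to SAD matching and window-based optical flow
(speckle texture scale, sub-pixel translation, decorrelation, noise), not
physically calibrated B-mode intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .types import ImageSequence, Trajectory

__all__ = [
    "MotionProfile",
    "PhantomSpec",
    "render_sequence",
    "phantom_analog_spec",
    "tendon_analog_spec",
]

#: Elbow-scale pixel spacing (mm/px) used for the phantom analog by default.
ELBOW_PIXEL_SPACING = 0.075
#: Finger-scale pixel spacing (mm/px).
FINGER_PIXEL_SPACING = 0.0265


@dataclass
class MotionProfile:
    """Per-frame true cumulative displacement (dx, dy) in pixels."""

    cumulative: np.ndarray  # (T, 2)
    kind: str = "piecewise"

    def __post_init__(self) -> None:
        self.cumulative = np.asarray(self.cumulative, dtype=np.float64)
        if self.cumulative.ndim != 2 or self.cumulative.shape[1] != 2:
            raise ValueError("cumulative must have shape (T, 2)")
        if not np.allclose(self.cumulative[0], 0.0):
            raise ValueError("motion must start at (0, 0)")

    @property
    def n_frames(self) -> int:
        return self.cumulative.shape[0]

    @property
    def instantaneous(self) -> np.ndarray:
        inst = np.zeros_like(self.cumulative)
        inst[1:] = np.diff(self.cumulative, axis=0)
        return inst

    def to_trajectory(self) -> Trajectory:
        return Trajectory(self.cumulative.copy())

    @classmethod
    def constant_velocity(cls, n_frames: int, vx: float, vy: float = 0.0) -> "MotionProfile":
        k = np.arange(n_frames, dtype=np.float64)
        return cls(np.column_stack([k * vx, k * vy]), "constant_velocity")

    @classmethod
    def sinusoidal(cls, n_frames: int, amplitude: float, period: float) -> "MotionProfile":
        k = np.arange(n_frames, dtype=np.float64)
        dx = amplitude * np.sin(2.0 * np.pi * k / period)
        return cls(np.column_stack([dx, np.zeros(n_frames)]), "sinusoidal")

    @classmethod
    def triangle(cls, n_frames: int, amplitude: float, period: float) -> "MotionProfile":
        """Rise to ``amplitude`` over period/2 frames, fall back; reversals
        at period/2, 3*period/2, ..."""
        k = np.arange(n_frames, dtype=np.float64)
        phase = np.mod(k, period) / period
        tri = np.where(phase < 0.5, 2.0 * phase, 2.0 * (1.0 - phase))
        dx = amplitude * tri
        return cls(np.column_stack([dx, np.zeros(n_frames)]), "triangle")

    @classmethod
    def piecewise(cls, cumulative_x: np.ndarray, cumulative_y: np.ndarray | None = None) -> "MotionProfile":
        x = np.asarray(cumulative_x, dtype=np.float64)
        y = np.zeros_like(x) if cumulative_y is None else np.asarray(cumulative_y, dtype=np.float64)
        return cls(np.column_stack([x, y]), "piecewise")


@dataclass
class PhantomSpec:
    """Everything needed to render one synthetic sequence deterministically."""

    motion: MotionProfile
    width: int = 400
    height: int = 200
    density: float = 0.05  # scatterers per px^2
    blur_axial: float = 1.0  # Gaussian sigma along y (px)
    blur_lateral: float = 2.0  # Gaussian sigma along x (px)
    noise_sigma: float = 0.0  # additive, on [0, 1] intensities
    rho: float = 0.0  # fraction of scatterers resampled per frame
    seed: int = 0
    pixel_spacing: float = ELBOW_PIXEL_SPACING  # mm/px
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.motion.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.density <= 0:
            raise ValueError("density must be > 0")

    @property
    def n_frames(self) -> int:
        return self.motion.n_frames

    def replace(self, **changes) -> "PhantomSpec":
        return replace(self, **changes)


def _splat(xs: np.ndarray, ys: np.ndarray, amps: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear splat of point scatterers onto the pixel grid."""
    h, w = shape
    img = np.zeros((h + 1, w + 1), dtype=np.float64)
    x0 = np.floor(xs).astype(np.int64)
    y0 = np.floor(ys).astype(np.int64)
    fx = xs - x0
    fy = ys - y0
    ok = (x0 >= 0) & (x0 < w) & (y0 >= 0) & (y0 < h)
    x0, y0, fx, fy, a = x0[ok], y0[ok], fx[ok], fy[ok], amps[ok]
    np.add.at(img, (y0, x0), a * (1 - fx) * (1 - fy))
    np.add.at(img, (y0, x0 + 1), a * fx * (1 - fy))
    np.add.at(img, (y0 + 1, x0), a * (1 - fx) * fy)
    np.add.at(img, (y0 + 1, x0 + 1), a * fx * fy)
    return img[:h, :w]


def render_sequence(spec: PhantomSpec) -> tuple[ImageSequence, MotionProfile]:
    """Render the sequence described by ``spec``; bit-deterministic per seed."""
    from scipy import ndimage

    h, w = spec.height, spec.width
    motion = spec.motion.cumulative
    max_dx = float(np.max(np.abs(motion[:, 0])))
    max_dy = float(np.max(np.abs(motion[:, 1])))
    if max_dx >= w or max_dy >= h:
        raise ValueError("motion pushes the texture fully out of frame")

    pad_x = max_dx + 4.0 * spec.blur_lateral + 2.0
    pad_y = max_dy + 4.0 * spec.blur_axial + 2.0
    rng = np.random.default_rng(spec.seed)
    n_scat = int(round(spec.density * (w + 2 * pad_x) * (h + 2 * pad_y)))
    xs = rng.uniform(-pad_x, w + pad_x, n_scat)
    ys = rng.uniform(-pad_y, h + pad_y, n_scat)
    amps = rng.uniform(0.1, 1.0, n_scat)

    raw = np.empty((spec.n_frames, h, w), dtype=np.float64)
    for k in range(spec.n_frames):
        fx, fy, fa = xs, ys, amps
        if spec.rho > 0:
            # out-of-plane analog: a transient rho-fraction of the base
            # scatterer field is replaced, independently each frame
            # (reversible elevational jitter -> bounded partial
            # decorrelation, not a cumulative sweep)
            resample = rng.random(n_scat) < spec.rho
            n_new = int(resample.sum())
            if n_new:
                fx, fy, fa = xs.copy(), ys.copy(), amps.copy()
                fx[resample] = rng.uniform(-pad_x, w + pad_x, n_new)
                fy[resample] = rng.uniform(-pad_y, h + pad_y, n_new)
                fa[resample] = rng.uniform(0.1, 1.0, n_new)
        dx, dy = motion[k]
        img = _splat(fx + dx, fy + dy, fa, (h, w))
        raw[k] = ndimage.gaussian_filter(
            img, (spec.blur_axial, spec.blur_lateral), mode="constant"
        )

    hi = float(raw.max())
    if hi <= 0:
        raise ValueError("rendered sequence is empty; increase density")
    frames = raw / hi
    if spec.noise_sigma > 0:
        frames = frames + rng.normal(0.0, spec.noise_sigma, frames.shape)
    frames = np.clip(frames, 0.0, 1.0)
    seq = ImageSequence(
        frames, frame_rate=spec.frame_rate,
        pixel_spacing=(spec.pixel_spacing, spec.pixel_spacing),
    )
    return seq, spec.motion


def phantom_analog_spec(
    pixel_spacing: float = ELBOW_PIXEL_SPACING,
    *,
    total_mm: float = 5.0,
    n_frames: int = 206,
    noise_sigma: float = 0.02,
    rho: float = 0.05,
    seed: int = 0,
) -> PhantomSpec:
    """Constant-velocity analog of a motorized tissue-mimicking phantom scan.

    Defaults: 206 frames covering 5 mm total lateral travel (probe at
    0.5 mm/s for 10 s at ~30 fps); at the elbow scale of 0.075 mm/px that is
    66.67 px, i.e. ~0.325 px/frame, with mild noise and decorrelation.
    """
    total_px = total_mm / pixel_spacing
    motion = MotionProfile.constant_velocity(n_frames, total_px / (n_frames - 1))
    return PhantomSpec(
        motion=motion,
        noise_sigma=noise_sigma,
        rho=rho,
        seed=seed,
        pixel_spacing=pixel_spacing,
    )


def tendon_analog_spec(
    kind: str,
    *,
    amplitude_px: float = 30.0,
    period_frames: float = 60.0,
    n_frames: int = 120,
    pixel_spacing: float = FINGER_PIXEL_SPACING,
    noise_sigma: float = 0.02,
    rho: float = 0.02,
    seed: int = 0,
) -> PhantomSpec:
    """Oscillatory analog of in vivo flexion/extension sequences.

    ``kind`` is ``"sinusoidal"`` or ``"triangle"``; both include direction
    reversals, which exercise the direction voting and the failure mode of
    linear interpolation across a reversal.
    """
    if kind == "sinusoidal":
        motion = MotionProfile.sinusoidal(n_frames, amplitude_px, period_frames)
    elif kind == "triangle":
        motion = MotionProfile.triangle(n_frames, amplitude_px, period_frames)
    else:
        raise ValueError(f"unknown motion kind {kind!r}")
    return PhantomSpec(
        motion=motion,
        noise_sigma=noise_sigma,
        rho=rho,
        seed=seed,
        pixel_spacing=pixel_spacing,
    )
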