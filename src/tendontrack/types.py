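"""Core domain containers shared across the tracking pipeline.

Coordinate convention: 0-based pixel indices, ``x`` runs rightward along the
tendon (lateral) axis, ``y`` runs downward (depth). Rectangular regions are
anchored at their top-left corner. Displacements are signed, in pixels, with
positive ``dx`` meaning motion to the right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["ImageSequence", "Region", "Trajectory"]


@dataclass
class ImageSequence:
    """An ordered stack of single-channel frames with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity rasters, floating point in ``[0, 1]``.
    frame_rate : float
        Frames per second (B-mode video default: 30 fps).
    pixel_spacing : float or (float, float)
        Physical pixel size in mm/pixel; a scalar means isotropic, a pair is
        interpreted as ``(x, y)`` spacing.
    """

    frames: np.ndarray
    frame_rate: float = 30.0
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (T, H, W) stack, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("an image sequence needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if np.isscalar(self.pixel_spacing):
            self.pixel_spacing = (float(self.pixel_spacing), float(self.pixel_spacing))
        else:
            sx, sy = self.pixel_spacing
            self.pixel_spacing = (float(sx), float(sy))
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(height, width) of every frame."""
        return self.frames.shape[1], self.frames.shape[2]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, t: int) -> np.ndarray:
        return self.frames[t]


@dataclass(frozen=True)
class Region:
    """Axis-aligned rectangle tracked through a sequence (top-left anchored)."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        for name in ("x", "y", "width", "height"):
            v = getattr(self, name)
            if int(v) != v:
                raise ValueError(f"Region.{name} must be an integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.width < 3 or self.height < 3:
            raise ValueError("Region must be at least 3x3 pixels")

    @property
    def slices(self) -> tuple[slice, slice]:
        """Numpy (row, col) slices selecting the region from a frame."""
        return (slice(self.y, self.y + self.height), slice(self.x, self.x + self.width))

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + (self.width - 1) / 2.0, self.y + (self.height - 1) / 2.0)

    def translated(self, dx: int, dy: int) -> "Region":
        return Region(self.x + int(dx), self.y + int(dy), self.width, self.height)

    def inside(self, frame_shape: tuple[int, int], margin: int = 0) -> bool:
        """True if the region (padded by ``margin``) lies fully in a frame."""
        h, w = frame_shape
        return (
            self.x - margin >= 0
            and self.y - margin >= 0
            and self.x + self.width + margin <= w
            and self.y + self.height + margin <= h
        )

    def extract(self, frame: np.ndarray) -> np.ndarray:
        if not self.inside(frame.shape):
            raise ValueError(f"{self} does not fit inside frame of shape {frame.shape}")
        return frame[self.slices]


@dataclass
class Trajectory:
    """Per-frame displacement of a tracked region relative to frame 0.

    ``cumulative`` holds the (dx, dy) displacement of each frame relative to
    the first; ``is_anchor`` flags frames that ended a flow period (block
    matching was applied there). The first and final frames are always
    anchors. ``periods`` carries optional per-flow-period diagnostics.
    """

    cumulative: np.ndarray  # (T, 2) float, columns (dx, dy)
    is_anchor: np.ndarray | None = None  # (T,) bool
    periods: list[dict[str, Any]] = field(default_factory=list)
    truncated: bool = False

    def __post_init__(self) -> None:
        self.cumulative = np.atleast_2d(np.asarray(self.cumulative, dtype=np.float64))
        if self.cumulative.ndim != 2 or self.cumulative.shape[1] != 2:
            raise ValueError("cumulative must have shape (T, 2)")
        if self.cumulative.shape[0] < 1:
            raise ValueError("trajectory must cover at least one frame")
        if not np.allclose(self.cumulative[0], 0.0):
            raise ValueError("cumulative displacement at frame 0 must be (0, 0)")
        n = self.cumulative.shape[0]
        if self.is_anchor is None:
            self.is_anchor = np.zeros(n, dtype=bool)
            self.is_anchor[0] = True
            self.is_anchor[-1] = True
        else:
            self.is_anchor = np.asarray(self.is_anchor, dtype=bool)
            if self.is_anchor.shape != (n,):
                raise ValueError("is_anchor length must match trajectory length")

    @property
    def n_frames(self) -> int:
        return self.cumulative.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    @property
    def instantaneous(self) -> np.ndarray:
        """Frame-to-frame displacement deltas, (T, 2); row 0 is (0, 0)."""
        inst = np.zeros_like(self.cumulative)
        inst[1:] = np.diff(self.cumulative, axis=0)
        return inst

    @property
    def dx(self) -> np.ndarray:
        return self.cumulative[:, 0]

    @property
    def dy(self) -> np.ndarray:
        return self.cumulative[:, 1]

    @property
    def total_displacement_x(self) -> float:
        """Signed x displacement between first and final frame (pixels)."""
        return float(self.cumulative[-1, 0] - self.cumulative[0, 0])

    def to_dataframe(self) -> pd.DataFrame:
        inst = self.instantaneous
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames, dtype=int),
                "dx_px": self.cumulative[:, 0],
                "dy_px": self.cumulative[:, 1],
                "ddx_px": inst[:, 0],
                "ddy_px": inst[:, 1],
                "is_anchor": self.is_anchor.astype(bool),
            }
        )

    @classmethod
    def from_cumulative_x(cls, dx: np.ndarray, dy: np.ndarray | None = None) -> "Trajectory":
        dx = np.asarray(dx, dtype=np.float64)
        if dy is None:
            dy = np.zeros_like(dx)
        return cls(np.column_stack([dx, np.asarray(dy, dtype=np.float64)]))

    def plot(self, ax=None, pixel_spacing: float | None = None, **kwargs):
        """Plot the cumulative lateral displacement curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        scale = pixel_spacing if pixel_spacing is not None else 1.0
        unit = "mm" if pixel_spacing is not None else "px"
        ax.plot(np.arange(self.n_frames), self.dx * scale, **kwargs)
        anchors = np.flatnonzero(self.is_anchor)
        ax.plot(anchors, self.dx[anchors] * scale, "o", ms=3)
        ax.set_xlabel("frame")
        ax.set_ylabel(f"lateral displacement ({unit})")
        return ax
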