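"""Reading image sequences and writing trajectories / run reports.

Supported inputs: multi-page TIFF stacks, directories of numbered
single-channel images (PNG etc., sorted by filename), and — when an
ffmpeg-capable imageio backend is available — video containers. Color
frames are converted to luminance and intensities rescaled to [0, 1].
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ImageSequence, Trajectory

__all__ = [
    "load_sequence",
    "save_sequence_tiff",
    "save_trajectory",
    "load_trajectory",
    "save_run_report",
]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}

# Rec. 601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


def _to_gray(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame.astype(np.float64)
    if frame.ndim == 3 and frame.shape[-1] in (3, 4):
        return frame[..., :3].astype(np.float64) @ _LUMA
    raise ValueError(f"cannot interpret frame of shape {frame.shape} as an image")


def _normalize(frames: np.ndarray, dtype) -> np.ndarray:
    if np.issubdtype(dtype, np.integer):
        return frames / float(np.iinfo(dtype).max)
    # float input: assume already scaled; rescale only if clearly out of range
    m = frames.max()
    if m > 1.0:
        return frames / m
    return frames


def load_sequence(
    path,
    pixel_spacing: float | tuple[float, float] = 1.0,
    frame_rate: float = 30.0,
) -> ImageSequence:
    """Read a sequence from a TIFF stack, an image directory or a video.

    Raises ``IOError`` for unreadable files, ``ValueError`` for frames of
    inconsistent size or sequences with fewer than two frames.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")

    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise IOError(f"no image files found in directory {path}")
        raw = [np.asarray(iio.imread(f)) for f in files]
        dtype = raw[0].dtype
        gray = [_to_gray(r) for r in raw]
        shapes = {g.shape for g in gray}
        if len(shapes) != 1:
            raise ValueError(f"frames have inconsistent sizes: {sorted(shapes)}")
        frames = np.stack(gray)
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        try:
            arr = tifffile.imread(path)
        except Exception as err:  # noqa: BLE001 - surfaced as I/O error
            raise IOError(f"could not read TIFF {path}: {err}") from err
        arr = np.asarray(arr)
        dtype = arr.dtype
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim == 4:  # (T, H, W, C)
            frames = np.stack([_to_gray(f) for f in arr])
        else:
            frames = arr.astype(np.float64)
    else:
        import imageio.v3 as iio

        try:
            arr = iio.imread(path, index=None)
        except Exception as err:  # noqa: BLE001
            raise IOError(
                f"could not decode {path}; video containers need an "
                f"ffmpeg-capable imageio backend ({err})"
            ) from err
        arr = np.asarray(arr)
        dtype = arr.dtype
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim == 3 and arr.shape[-1] in (3, 4):
            arr = arr[None]
        if arr.ndim == 4:
            frames = np.stack([_to_gray(f) for f in arr])
        else:
            frames = arr.astype(np.float64)

    if frames.shape[0] < 2:
        raise ValueError(
            f"{path} contains {frames.shape[0]} frame(s); at least 2 required"
        )
    frames = _normalize(frames, dtype)
    return ImageSequence(frames, frame_rate=frame_rate, pixel_spacing=pixel_spacing)


def save_sequence_tiff(sequence: ImageSequence, path) -> None:
    """Write the sequence as a 16-bit multi-page TIFF stack."""
    import tifffile

    data = np.clip(sequence.frames, 0.0, 1.0)
    tifffile.imwrite(
        path, np.round(data * 65535).astype(np.uint16), photometric="minisblack"
    )


_TRAJ_COLUMNS = ["frame", "dx_px", "dy_px", "ddx_px", "ddy_px", "is_anchor"]


def save_trajectory(trajectory: Trajectory, path) -> None:
    """Write a trajectory CSV (full float precision, lossless round trip)."""
    if trajectory.n_frames < 1:
        raise ValueError("trajectory is empty")
    df = trajectory.to_dataframe()
    try:
        df.to_csv(path, index=False, columns=_TRAJ_COLUMNS)
    except OSError as err:
        raise IOError(f"could not write trajectory to {path}: {err}") from err


def load_trajectory(path) -> Trajectory:
    """Read a trajectory CSV (or a bare 2-column frame,x ground-truth file)."""
    df = pd.read_csv(path)
    if {"dx_px", "dy_px"}.issubset(df.columns):
        cum = df[["dx_px", "dy_px"]].to_numpy(dtype=np.float64)
        anchors = (
            df["is_anchor"].astype(bool).to_numpy()
            if "is_anchor" in df.columns
            else None
        )
        cum = cum - cum[0]
        return Trajectory(cum, anchors)
    if df.shape[1] >= 2:
        # bare point-coordinate format: frame index + x position (pixels)
        x = df.iloc[:, 1].to_numpy(dtype=np.float64)
        return Trajectory.from_cumulative_x(x - x[0])
    raise ValueError(f"unrecognized trajectory format in {path}")


def save_run_report(path, config, trajectory: Trajectory, **extra) -> None:
    """JSON run report: config echo, anchor frames, per-period diagnostics."""
    report = {
        "config": config.to_dict(),
        "n_frames": trajectory.n_frames,
        "truncated": bool(trajectory.truncated),
        "anchor_frames": np.flatnonzero(trajectory.is_anchor).tolist(),
        "periods": trajectory.periods,
    }
    report.update(extra)
    Path(path).write_text(json.dumps(report, indent=2))
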