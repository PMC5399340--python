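"""Trajectory error metrics and the four-method comparison harness.

Two metrics score a predicted trajectory against ground truth, both on the
lateral (x) axis only, since tendon motion is predominantly lateral:

* average absolute error  ``E_a = (1/N) * sum_t |d_GT,t - d_PA,t|``
  over instantaneous (frame-to-frame) displacements, in pixels (and mm via
  the pixel spacing);
* relative error  ``E_r = |(D_GT - D_PA) / D_GT| * 100%`` comparing the
  signed total displacement between the first and final frames.

``E_a`` can alternatively be computed on the cumulative displacement curves
(``mode="cumulative"``), which is what displacement-vs-frame plots show.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import TrackerConfig, VaNTable
from .optical_flow import calibrate_va_n, compute_flow_field
from .tracker import track, track_comparator
from .types import ImageSequence, Region, Trajectory

__all__ = [
    "ErrorReport",
    "average_absolute_error",
    "relative_error",
    "compare_methods",
    "calibrate_on_sequences",
    "ALL_METHODS",
]

ALL_METHODS = ("oftb", "of_only", "mkbm_only", "adaptive_mkbm")


def _x_series(traj, mode: str) -> np.ndarray:
    if isinstance(traj, Trajectory):
        cum = traj.cumulative[:, 0]
    else:
        arr = np.asarray(traj, dtype=np.float64)
        cum = arr[:, 0] if arr.ndim == 2 else arr
    if mode == "instantaneous":
        return np.diff(cum)
    if mode == "cumulative":
        return cum - cum[0]
    raise ValueError(f"unknown comparison mode {mode!r}")


@dataclass
class ErrorReport:
    """Error metrics for one predicted trajectory (x axis, pixels)."""

    e_a_px: float
    e_r_pct: float | None  # None when the ground-truth total is zero
    n_frames: int
    pixel_spacing: float = 1.0
    e_r_defined: bool = True
    per_method: dict[str, "ErrorReport"] = field(default_factory=dict)
    ranking: list[str] = field(default_factory=list)

    @property
    def e_a_mm(self) -> float:
        return self.e_a_px * self.pixel_spacing


def average_absolute_error(
    gt_trajectory,
    pred_trajectory,
    *,
    mode: str = "instantaneous",
) -> float:
    """Mean absolute lateral displacement error, in pixels."""
    gt = _x_series(gt_trajectory, mode)
    pred = _x_series(pred_trajectory, mode)
    if gt.size != pred.size:
        raise ValueError(
            f"trajectory length mismatch: {gt.size + 1} vs {pred.size + 1} frames"
        )
    if gt.size < 1:
        raise ValueError("trajectories must cover at least 2 frames")
    return float(np.mean(np.abs(gt - pred)))


def relative_error(gt_trajectory, pred_trajectory) -> float:
    """Relative total-displacement error in percent.

    Raises ``ValueError`` when the ground-truth total displacement is zero
    (the metric is undefined there).
    """
    gt = _x_series(gt_trajectory, "cumulative")
    pred = _x_series(pred_trajectory, "cumulative")
    if gt.size != pred.size:
        raise ValueError(
            f"trajectory length mismatch: {gt.size} vs {pred.size} frames"
        )
    d_gt = gt[-1]
    d_pa = pred[-1]
    if d_gt == 0:
        raise ValueError("relative error undefined: ground-truth total displacement is zero")
    return float(abs((d_gt - d_pa) / d_gt) * 100.0)


def calibrate_on_sequences(
    sequences_with_gt,
    region: Region,
    config: TrackerConfig | None = None,
    *,
    stride: int = 2,
    gt_tolerance: float = 0.02,
) -> VaNTable:
    """Fit a Va-N table from adjacent frame pairs of sequences with known
    motion (the standard calibration procedure: several hundred frame pairs
    with reference displacements).

    ``sequences_with_gt`` is an iterable of ``(ImageSequence, Trajectory)``;
    every ``stride``-th adjacent pair contributes one calibration record,
    with the flow region re-centred on the rounded ground-truth position.
    """
    config = config or TrackerConfig()
    records = []
    for seq, gt in sequences_with_gt:
        cum = gt.cumulative if isinstance(gt, Trajectory) else np.asarray(gt)
        inst = np.diff(cum[:, 0])
        for t in range(0, seq.n_frames - 1, stride):
            r = region.translated(int(round(cum[t, 0])), int(round(cum[t, 1])))
            if not r.inside(seq.frame_shape):
                continue
            ff = compute_flow_field(seq[t], seq[t + 1], r, config, frame_index=t)
            records.append((ff, float(inst[t])))
    return calibrate_va_n(records, config, gt_tolerance=gt_tolerance)


def _score(gt: Trajectory, pred: Trajectory, pixel_spacing: float, mode: str) -> ErrorReport:
    n = min(gt.n_frames, pred.n_frames)
    gt_c = Trajectory(gt.cumulative[:n].copy())
    pr_c = Trajectory(pred.cumulative[:n].copy())
    e_a = average_absolute_error(gt_c, pr_c, mode=mode)
    try:
        e_r = relative_error(gt_c, pr_c)
        defined = True
    except ValueError:
        e_r, defined = None, False
    return ErrorReport(e_a, e_r, n, pixel_spacing, e_r_defined=defined)


def compare_methods(
    sequence: ImageSequence,
    region: Region,
    config: TrackerConfig | None = None,
    gt: Trajectory | None = None,
    *,
    mode: str = "instantaneous",
) -> ErrorReport:
    """Run OFTB-MKBM plus the three comparators and score each against ``gt``.

    Returns an :class:`ErrorReport` whose ``per_method`` dict holds one
    entry per method and whose ``ranking`` lists methods from best to worst
    by ``E_a`` (ties broken by ``E_r``); the top-level metrics are the
    OFTB-MKBM ones.
    """
    config = config or TrackerConfig()
    if gt is None:
        raise ValueError("ground-truth trajectory is required")
    if gt.n_frames != sequence.n_frames:
        raise ValueError("ground truth must align with the sequence, frame for frame")
    spacing = sequence.pixel_spacing[0]

    trajectories = {"oftb": track(sequence, region, config)}
    for method in ("of_only", "mkbm_only", "adaptive_mkbm"):
        trajectories[method] = track_comparator(sequence, region, config, method)

    per_method = {
        name: _score(gt, traj, spacing, mode) for name, traj in trajectories.items()
    }
    ranking = sorted(
        per_method,
        key=lambda m: (
            per_method[m].e_a_px,
            per_method[m].e_r_pct if per_method[m].e_r_defined else np.inf,
        ),
    )
    top = per_method["oftb"]
    return ErrorReport(
        top.e_a_px,
        top.e_r_pct,
        top.n_frames,
        spacing,
        e_r_defined=top.e_r_defined,
        per_method=per_method,
        ranking=ranking,
    )
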