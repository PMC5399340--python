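"""OFTB-MKBM orchestration over a full image sequence.

The tracker alternates two regimes. Optical flow is run on every adjacent
frame pair, accumulating the signed horizontal region displacement ``Da``;
once ``|Da|`` reaches the threshold ``lambda_px`` the run of frames forms a
*flow period*. Block matching (MKBM) is then applied between the period's
endpoint frames only, so the template is re-extracted at a cadence where the
inter-frame displacement is large enough for integer matching to be
accurate and template drift from sub-pixel updates cannot build up. The
displacements of the frames inside the period are interpolated along the
optical-flow trend:

    d(t + i) = d_MKBM(t) + (d_OF(t+i) - d_OF(t)) *
               (d_MKBM(t+n) - d_MKBM(t)) / (d_OF(t+n) - d_OF(t))

so the endpoints equal the MKBM anchors exactly and the in-between shape
follows the flow. When the flow trend is degenerate (zero net flow over the
period) the interpolation falls back to linear in frame index and the
period is flagged. The comparator methods — plain chained optical flow,
per-frame MKBM, and "adaptive MKBM" (same anchors, linear interpolation) —
share this machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .config import TrackerConfig
from .mkbm import BlockDisplacement, extract_template, match_block
from .optical_flow import RegionDisplacement, compute_flow_field, region_displacement
from .types import ImageSequence, Region, Trajectory

__all__ = [
    "FlowPeriod",
    "PeriodResult",
    "accumulate_until_threshold",
    "interpolate_period",
    "track",
    "track_comparator",
    "COMPARATOR_METHODS",
]

COMPARATOR_METHODS = ("of_only", "mkbm_only", "adaptive_mkbm")

#: Optional hook replacing the per-pair optical-flow estimate; signature
#: (sequence, t, region, config) -> (dx, dy). Used to drive the period
#: segmentation with a known displacement source (tests, external flow).
FlowFn = Callable[[ImageSequence, int, Region, TrackerConfig], tuple[float, float]]


@dataclass
class FlowPeriod:
    """A run of frames whose accumulated flow displacement reached lambda."""

    start: int
    end: int
    d_of: np.ndarray  # (n+1, 2) cumulative OF displacement within the period
    displacements: list[RegionDisplacement] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.end - self.start

    @property
    def da(self) -> float:
        """Accumulated signed horizontal displacement over the period."""
        return float(self.d_of[-1, 0])


@dataclass
class PeriodResult:
    period: FlowPeriod
    mkbm: BlockDisplacement
    d_oftb: np.ndarray  # (n+1, 2) cumulative trajectory over the period
    linear_fallback: bool


def accumulate_until_threshold(
    sequence: ImageSequence,
    start_frame: int,
    region: Region,
    config: TrackerConfig | None = None,
    *,
    flow_fn: FlowFn | None = None,
    prev_direction: str | None = None,
) -> FlowPeriod:
    """Run per-pair optical flow from ``start_frame`` until ``|Da| >= lambda``
    or the sequence ends.

    The flow region follows the rounded cumulative optical-flow displacement
    within the period. Reaching the last frame before the threshold is a
    normal termination (final partial period).
    """
    config = config or TrackerConfig()
    if start_frame >= sequence.n_frames - 1:
        raise ValueError("start_frame must precede the last frame")

    d = [(0.0, 0.0)]
    displacements: list[RegionDisplacement] = []
    direction = prev_direction
    t = start_frame
    while t < sequence.n_frames - 1:
        offset = (int(round(d[-1][0])), int(round(d[-1][1])))
        cur = region.translated(*offset)
        if not cur.inside(sequence.frame_shape):
            warnings.warn(
                f"flow region left the frame at frame {t}; period truncated",
                stacklevel=2,
            )
            break
        if flow_fn is not None:
            dx, dy = flow_fn(sequence, t, cur, config)
        else:
            ff = compute_flow_field(
                sequence[t], sequence[t + 1], cur, config, frame_index=t
            )
            rd = region_displacement(ff, config=config, prev_direction=direction)
            displacements.append(rd)
            dx, dy = rd.dx, rd.dy
            if rd.direction in ("left", "right"):
                direction = rd.direction
        d.append((d[-1][0] + dx, d[-1][1] + dy))
        t += 1
        if abs(d[-1][0]) >= config.lambda_px:
            break
    return FlowPeriod(start_frame, t, np.array(d, dtype=np.float64), displacements)


def interpolate_period(
    d_of: np.ndarray,
    d_mkbm_start: float,
    d_mkbm_end: float,
    mode: str = "flow_trend",
) -> tuple[np.ndarray, bool]:
    """Interpolate per-frame displacements inside a flow period.

    ``d_of`` is the cumulative optical-flow series over the period
    (length n+1, first entry conventionally 0). Returns the interpolated
    cumulative series plus a flag marking the linear fallback (taken when
    the net flow over the period is exactly zero, or when ``mode`` is
    ``"linear"``). Endpoint values are set to the MKBM anchors exactly.
    """
    d_of = np.asarray(d_of, dtype=np.float64)
    if d_of.ndim != 1 or d_of.size < 2:
        raise ValueError("d_of must be a 1-D series covering i = 0..n with n >= 1")
    n = d_of.size - 1
    delta_of = d_of[-1] - d_of[0]
    delta_m = d_mkbm_end - d_mkbm_start
    fallback = False
    if mode == "linear" or delta_of == 0.0:
        fallback = delta_of == 0.0
        out = d_mkbm_start + (np.arange(n + 1) / n) * delta_m
    elif mode == "flow_trend":
        out = d_mkbm_start + (d_of - d_of[0]) * (delta_m / delta_of)
    else:
        raise ValueError(f"unknown interpolation mode {mode!r}")
    out[0] = d_mkbm_start
    out[-1] = d_mkbm_end
    return out, fallback


def _period_summary(pr: PeriodResult) -> dict:
    p = pr.period
    vas = [rd.va for rd in p.displacements if np.isfinite(rd.va)]
    ns = [rd.n_percent for rd in p.displacements if np.isfinite(rd.n_percent)]
    return {
        "start": p.start,
        "end": p.end,
        "n": p.n,
        "Da": p.da,
        "Va_mean": float(np.mean(vas)) if vas else None,
        "N_mean": float(np.mean(ns)) if ns else None,
        "mkbm_dx": pr.mkbm.dx,
        "mkbm_dy": pr.mkbm.dy,
        "fused_subblock": pr.mkbm.contributing_index,
        "linear_fallback": bool(pr.linear_fallback),
    }


def track(
    sequence: ImageSequence,
    initial_region: Region,
    config: TrackerConfig | None = None,
    *,
    flow_fn: FlowFn | None = None,
) -> Trajectory:
    """Track a region through the whole sequence with OFTB-MKBM.

    Returns the per-frame cumulative trajectory with flow-period endpoints
    flagged as anchors. If the region drifts against the frame border the
    track is truncated at the last valid frame with a warning.
    """
    config = config or TrackerConfig()
    if not initial_region.inside(sequence.frame_shape):
        raise ValueError("initial_region must lie inside the first frame")
    if not initial_region.inside(
        sequence.frame_shape, margin=max(config.search_range)
    ):
        warnings.warn(
            "initial_region leaves little margin for the search range; "
            "matches near the border will be clipped",
            stacklevel=2,
        )

    n_total = sequence.n_frames
    cum = np.zeros((n_total, 2))
    is_anchor = np.zeros(n_total, dtype=bool)
    is_anchor[0] = True
    periods: list[dict] = []

    region = initial_region
    template = extract_template(sequence[0], region, 0)
    t = 0
    truncated = False
    prev_direction: str | None = None
    while t < n_total - 1:
        period = accumulate_until_threshold(
            sequence, t, region, config, flow_fn=flow_fn,
            prev_direction=prev_direction,
        )
        if period.n == 0:
            truncated = True
            break
        for rd in period.displacements:
            if rd.direction in ("left", "right"):
                prev_direction = rd.direction
        predicted = (
            int(round(period.d_of[-1, 0])),
            int(round(period.d_of[-1, 1])),
        )
        try:
            fused = match_block(template, sequence[period.end], predicted, config)
        except IndexError:
            warnings.warn(
                f"search window left the frame at frame {period.end}; track truncated",
                stacklevel=2,
            )
            truncated = True
            break

        m_start_x, m_start_y = cum[t]
        m_end_x = m_start_x + fused.dx
        m_end_y = m_start_y + fused.dy
        interp_x, fb = interpolate_period(
            period.d_of[:, 0], m_start_x, m_end_x, config.interpolation_mode
        )
        # the flow trend drives only the lateral axis; depth is linear
        interp_y, _ = interpolate_period(
            period.d_of[:, 1], m_start_y, m_end_y, "linear"
        )
        cum[t : period.end + 1, 0] = interp_x
        cum[t : period.end + 1, 1] = interp_y
        is_anchor[period.end] = True

        result = PeriodResult(period, fused, np.column_stack([interp_x, interp_y]), fb)
        periods.append(_period_summary(result))

        new_region = region.translated(int(round(fused.dx)), int(round(fused.dy)))
        if not new_region.inside(sequence.frame_shape):
            warnings.warn(
                f"tracked region left the frame after frame {period.end}; "
                "track truncated",
                stacklevel=2,
            )
            t = period.end
            truncated = True
            break
        region = new_region
        template = extract_template(sequence[period.end], region, period.end)
        t = period.end

    last = t if truncated else n_total - 1
    is_anchor[last] = True
    traj = Trajectory(
        cum[: last + 1], is_anchor[: last + 1], periods, truncated=truncated
    )
    return traj


def _track_of_only(sequence, initial_region, config) -> Trajectory:
    n_total = sequence.n_frames
    cum = np.zeros((n_total, 2))
    region = initial_region
    prev_direction = None
    last = n_total - 1
    truncated = False
    for t in range(n_total - 1):
        offset = (int(round(cum[t, 0])), int(round(cum[t, 1])))
        cur = initial_region.translated(*offset)
        if not cur.inside(sequence.frame_shape):
            warnings.warn(
                f"flow region left the frame at frame {t}; track truncated",
                stacklevel=2,
            )
            last, truncated = t, True
            break
        ff = compute_flow_field(sequence[t], sequence[t + 1], cur, config, frame_index=t)
        rd = region_displacement(ff, config=config, prev_direction=prev_direction)
        if rd.direction in ("left", "right"):
            prev_direction = rd.direction
        cum[t + 1] = cum[t] + (rd.dx, rd.dy)
    return Trajectory(cum[: last + 1], truncated=truncated)


def _track_mkbm_only(sequence, initial_region, config) -> Trajectory:
    n_total = sequence.n_frames
    cum = np.zeros((n_total, 2))
    is_anchor = np.ones(n_total, dtype=bool)
    region = initial_region
    template = extract_template(sequence[0], region, 0)
    last = n_total - 1
    truncated = False
    for t in range(n_total - 1):
        try:
            fused = match_block(template, sequence[t + 1], (0, 0), config)
        except IndexError:
            warnings.warn(
                f"search window left the frame at frame {t + 1}; track truncated",
                stacklevel=2,
            )
            last, truncated = t, True
            break
        cum[t + 1] = cum[t] + (fused.dx, fused.dy)
        new_region = region.translated(int(round(fused.dx)), int(round(fused.dy)))
        if not new_region.inside(sequence.frame_shape):
            warnings.warn(
                f"tracked region left the frame after frame {t + 1}; track truncated",
                stacklevel=2,
            )
            last, truncated = t + 1, True
            break
        region = new_region
        template = extract_template(sequence[t + 1], region, t + 1)
    return Trajectory(cum[: last + 1], is_anchor[: last + 1], truncated=truncated)


def track_comparator(
    sequence: ImageSequence,
    initial_region: Region,
    config: TrackerConfig | None = None,
    method: str = "of_only",
) -> Trajectory:
    """Run one of the baseline methods used for comparison.

    ``of_only``
        chained per-pair optical-flow region displacement;
    ``mkbm_only``
        MKBM on every adjacent pair with per-frame template update (the
        regime where sub-pixel template drift accumulates);
    ``adaptive_mkbm``
        the same flow-period anchors as OFTB-MKBM but intermediate frames
        linearly interpolated in frame index.
    """
    config = config or TrackerConfig()
    if method == "of_only":
        return _track_of_only(sequence, initial_region, config)
    if method == "mkbm_only":
        return _track_mkbm_only(sequence, initial_region, config)
    if method == "adaptive_mkbm":
        return track(sequence, initial_region, config.replace(interpolation_mode="linear"))
    raise ValueError(f"unknown comparator method {method!r}; expected one of {COMPARATOR_METHODS}")
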