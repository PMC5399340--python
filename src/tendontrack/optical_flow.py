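"""Lucas-Kanade optical flow over a grid of flow points with direction
voting and the Va -> N top-fraction averaging rule.

The brightness-constancy constraint ``Ix*Vx + Iy*Vy = -It`` is solved by
least squares over a square window around each flow point (Lucas-Kanade).
Inside the tracking region a regular grid of flow points is evaluated
(43 x 13 points for the default 101x41 region, 17x17 window and 2-px step).
The per-pair region displacement is then formed by

1. dropping flow points whose local normal matrix is near-singular,
2. voting on the horizontal motion direction and keeping the majority class,
3. computing the index ``Va`` = mean |Vx| of the top 5% retained points,
4. looking up ``N`` (percent) in the Va-N calibration table, and
5. averaging the signed Vx (and Vy) of the top N% points ranked by |Vx|.

Step 3-5 exist because single-step optical flow is accurate for the
fastest-moving, best-textured points but pools many lagging points; the
calibrated N keeps just enough points to cancel noise without diluting the
estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import ndimage

from .config import TrackerConfig, VaNTable
from .types import Region

__all__ = [
    "FlowPoint",
    "FlowField",
    "RegionDisplacement",
    "lucas_kanade_point",
    "compute_flow_field",
    "classify_direction",
    "region_displacement",
    "calibrate_va_n",
]


@dataclass(frozen=True)
class FlowPoint:
    """Velocity estimate at one grid node (pixels/frame)."""

    x: int
    y: int
    vx: float
    vy: float
    valid: bool

    def __post_init__(self) -> None:
        if not self.valid:
            object.__setattr__(self, "vx", float("nan"))
            object.__setattr__(self, "vy", float("nan"))


@dataclass
class FlowField:
    """Grid of flow points for one adjacent frame pair.

    Stored as struct-of-arrays: ``xs``/``ys`` give the node coordinates and
    ``vx``/``vy``/``valid`` are (ny, nx) grids.
    """

    frame_index: int
    xs: np.ndarray  # (nx,) node x coordinates
    ys: np.ndarray  # (ny,) node y coordinates
    vx: np.ndarray  # (ny, nx)
    vy: np.ndarray  # (ny, nx)
    valid: np.ndarray  # (ny, nx) bool

    @property
    def n_points(self) -> int:
        return self.vx.size

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(ny, nx): rows x columns of flow points."""
        return self.vx.shape

    def iter_points(self) -> Iterator[FlowPoint]:
        for iy, y in enumerate(self.ys):
            for ix, x in enumerate(self.xs):
                yield FlowPoint(
                    int(x), int(y),
                    float(self.vx[iy, ix]), float(self.vy[iy, ix]),
                    bool(self.valid[iy, ix]),
                )

    def valid_velocities(self) -> tuple[np.ndarray, np.ndarray]:
        """(vx, vy) 1-D arrays over valid points only."""
        m = self.valid
        return self.vx[m], self.vy[m]


@dataclass
class RegionDisplacement:
    """Per-frame-pair displacement of the whole tracking region."""

    dx: float
    dy: float
    direction: str  # "left" | "right" | "none"
    n_points_used: int
    va: float
    n_percent: float

    def __post_init__(self) -> None:
        if self.direction not in ("left", "right", "none"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.direction == "left" and self.dx > 0:
            raise ValueError("direction 'left' requires dx <= 0")
        if self.direction == "right" and self.dx < 0:
            raise ValueError("direction 'right' requires dx >= 0")


def _presmooth(frame: np.ndarray, sigma: float) -> np.ndarray:
    if sigma > 0:
        return ndimage.gaussian_filter(frame.astype(np.float64), sigma)
    return frame.astype(np.float64)


def _gradients(f0: np.ndarray, f1: np.ndarray, sigma: float):
    """Central-difference spatial gradients of the first frame and the
    two-frame forward temporal difference (single-step Lucas-Kanade; the
    estimate saturates below the true value for large displacements, the
    behaviour the adaptive frame-interval design relies on)."""
    s0 = _presmooth(f0, sigma)
    s1 = _presmooth(f1, sigma)
    iy, ix = np.gradient(s0)
    it = s1 - s0
    return ix, iy, it


def _solve_2x2(sxx, sxy, syy, sxt, syt, eig_ratio):
    """Solve the LK normal equations; returns (vx, vy, valid) arrays.

    The system is ``[[Sxx, Sxy], [Sxy, Syy]] v = -[Sxt, Syt]``. A point is
    invalid when the smallest eigenvalue is <= eig_ratio times the largest
    (rank-deficient / aperture-limited texture) or the tensor vanishes.
    """
    tr = sxx + syy
    disc = np.sqrt(np.maximum((sxx - syy) ** 2 + 4.0 * sxy**2, 0.0))
    lmin = 0.5 * (tr - disc)
    lmax = 0.5 * (tr + disc)
    valid = (lmax > 1e-12) & (lmin > eig_ratio * lmax)
    det = sxx * syy - sxy**2
    with np.errstate(divide="ignore", invalid="ignore"):
        vx = (-sxt * syy + syt * sxy) / det
        vy = (-syt * sxx + sxt * sxy) / det
    vx = np.where(valid, vx, np.nan)
    vy = np.where(valid, vy, np.nan)
    return vx, vy, valid


def lucas_kanade_point(
    frame_t: np.ndarray,
    frame_t1: np.ndarray,
    center: tuple[int, int],
    window: int = 17,
    *,
    presmooth_sigma: float = 1.0,
    eig_ratio: float = 1e-6,
) -> FlowPoint:
    """Estimate the flow at a single point by windowed least squares.

    ``center`` is (x, y); the ``window`` x ``window`` footprint must lie
    fully inside both frames. This is the explicit stacked-system reference
    implementation; :func:`compute_flow_field` evaluates the same estimator
    for a whole grid using separable window sums.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    x, y = int(center[0]), int(center[1])
    half = window // 2
    h, w = frame_t.shape
    if frame_t.shape != frame_t1.shape:
        raise ValueError("frames must have identical shapes")
    if not (half <= x < w - half and half <= y < h - half):
        raise IndexError(
            f"window of size {window} at center ({x}, {y}) exceeds frame bounds {frame_t.shape}"
        )
    ix, iy, it = _gradients(frame_t, frame_t1, presmooth_sigma)
    sl = (slice(y - half, y + half + 1), slice(x - half, x + half + 1))
    a1 = ix[sl].ravel()
    a2 = iy[sl].ravel()
    b = it[sl].ravel()
    sxx = float(a1 @ a1)
    sxy = float(a1 @ a2)
    syy = float(a2 @ a2)
    sxt = float(a1 @ b)
    syt = float(a2 @ b)
    vx, vy, valid = _solve_2x2(
        np.float64(sxx), np.float64(sxy), np.float64(syy),
        np.float64(sxt), np.float64(syt), eig_ratio,
    )
    return FlowPoint(x, y, float(vx), float(vy), bool(valid))


def grid_positions(region: Region, window: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    """Flow-point coordinates inside ``region`` such that every window fits.

    The grid is inset by ``window // 2`` from the region border; a 101x41
    region with a 17x17 window and 2-px step yields 43 x 13 nodes.
    """
    margin = window // 2
    xs = np.arange(region.x + margin, region.x + region.width - margin, step)
    ys = np.arange(region.y + margin, region.y + region.height - margin, step)
    if xs.size == 0 or ys.size == 0:
        raise ValueError(
            f"region {region.width}x{region.height} too small for a single "
            f"flow point with window {window}"
        )
    return xs, ys


def compute_flow_field(
    frame_t: np.ndarray,
    frame_t1: np.ndarray,
    region: Region,
    config: TrackerConfig | None = None,
    *,
    frame_index: int = 0,
) -> FlowField:
    """Lucas-Kanade flow at every grid node inside ``region``.

    Window sums of the gradient products are computed with a uniform filter,
    which is exactly the stacked least-squares system of
    :func:`lucas_kanade_point` evaluated at all nodes at once.
    """
    config = config or TrackerConfig()
    if frame_t.shape != frame_t1.shape:
        raise ValueError("frames must have identical shapes")
    if not region.inside(frame_t.shape):
        raise ValueError(f"{region} not inside frame of shape {frame_t.shape}")
    window = config.of_window
    xs, ys = grid_positions(region, window, config.flow_grid_step)

    ix, iy, it = _gradients(frame_t, frame_t1, config.presmooth_sigma)
    area = float(window * window)

    def winsum(img: np.ndarray) -> np.ndarray:
        return ndimage.uniform_filter(img, size=window, mode="nearest") * area

    sxx = winsum(ix * ix)
    sxy = winsum(ix * iy)
    syy = winsum(iy * iy)
    sxt = winsum(ix * it)
    syt = winsum(iy * it)

    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    vx, vy, valid = _solve_2x2(
        sxx[yy, xx], sxy[yy, xx], syy[yy, xx],
        sxt[yy, xx], syt[yy, xx], config.eig_ratio,
    )
    return FlowField(frame_index, xs, ys, vx, vy, valid)


def classify_direction(vx: float) -> str:
    """Horizontal motion-direction vote of one flow point."""
    if not np.isfinite(vx):
        raise ValueError("vx must be finite")
    if vx < 0:
        return "left"
    if vx > 0:
        return "right"
    return "ignored"


def _top_k(n: int, fraction_percent: float) -> int:
    """ceil(n * percent/100), at least 1."""
    return max(1, math.ceil(n * fraction_percent / 100.0))


def region_displacement(
    flow_field: FlowField,
    va_n_table: VaNTable | None = None,
    config: TrackerConfig | None = None,
    *,
    prev_direction: str | None = None,
) -> RegionDisplacement:
    """Fuse a flow field into one region displacement via direction voting
    and the Va -> N averaging rule.

    ``prev_direction`` breaks an exact left/right vote tie in favour of the
    previous frame pair's direction; with no previous direction the result
    is flagged ``none`` with zero displacement.
    """
    config = config or TrackerConfig()
    table = va_n_table or config.va_n_table

    vx, vy = flow_field.valid_velocities()
    if vx.size == 0:
        return RegionDisplacement(0.0, 0.0, "none", 0, float("nan"), float("nan"))

    left = vx < 0
    right = vx > 0
    n_left = int(left.sum())
    n_right = int(right.sum())
    if n_left == 0 and n_right == 0:
        # every point voted "ignored" (exactly zero horizontal motion)
        return RegionDisplacement(0.0, 0.0, "none", 0, float("nan"), float("nan"))
    if n_left > n_right:
        direction = "left"
    elif n_right > n_left:
        direction = "right"
    elif prev_direction in ("left", "right"):
        direction = prev_direction
    else:
        return RegionDisplacement(0.0, 0.0, "none", 0, float("nan"), float("nan"))

    mask = left if direction == "left" else right
    rvx = vx[mask]
    rvy = vy[mask]
    mag = np.abs(rvx)
    order = np.argsort(-mag, kind="stable")

    k_va = _top_k(rvx.size, config.top_fraction * 100.0)
    va = float(mag[order[:k_va]].mean())
    n_percent = table.lookup(va)
    k = _top_k(rvx.size, n_percent)
    sel = order[:k]
    return RegionDisplacement(
        dx=float(rvx[sel].mean()),
        dy=float(rvy[sel].mean()),
        direction=direction,
        n_points_used=int(k),
        va=va,
        n_percent=float(n_percent),
    )


def _pava_decreasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators fit, non-increasing in index order."""
    y = list(map(float, y))
    w = list(map(float, w))
    vals: list[float] = []
    wts: list[float] = []
    counts: list[int] = []
    for yi, wi in zip(y, w):
        vals.append(yi)
        wts.append(wi)
        counts.append(1)
        while len(vals) > 1 and vals[-2] < vals[-1]:  # violation of decreasing
            v = (vals[-1] * wts[-1] + vals[-2] * wts[-2]) / (wts[-1] + wts[-2])
            c = counts[-1] + counts[-2]
            wt = wts[-1] + wts[-2]
            vals = vals[:-2] + [v]
            wts = wts[:-2] + [wt]
            counts = counts[:-2] + [c]
    out: list[float] = []
    for v, c in zip(vals, counts):
        out.extend([v] * c)
    return np.array(out)


def calibrate_va_n(
    records: Sequence[tuple[FlowField, float]],
    config: TrackerConfig | None = None,
    *,
    gt_tolerance: float = 0.05,
    max_knots: int = 8,
    prev_direction: str | None = None,
) -> VaNTable:
    """Fit a Va -> N calibration table from frame pairs with known motion.

    For each (flow field, ground-truth horizontal displacement) record the
    smallest percentage N whose top-N% |Vx|-ranked mean matches the ground
    truth within ``gt_tolerance`` pixels is found (falling back to the
    best-matching N when none is within tolerance). The (Va, N) samples are
    binned over Va and reduced to monotone non-increasing piecewise-linear
    knots.
    """
    config = config or TrackerConfig()
    if len(records) < 10:
        raise ValueError(
            f"calibration needs at least 10 frame pairs, got {len(records)}"
        )

    vas: list[float] = []
    ns: list[float] = []
    for flow_field, gt_dx in records:
        vx, _ = flow_field.valid_velocities()
        if vx.size == 0:
            continue
        left, right = vx < 0, vx > 0
        if left.sum() == 0 and right.sum() == 0:
            continue
        if left.sum() > right.sum():
            mask = left
        elif right.sum() > left.sum():
            mask = right
        else:
            mask = left if (prev_direction == "left") else right
        rvx = vx[mask]
        mag = np.abs(rvx)
        order = np.argsort(-mag, kind="stable")
        k_va = _top_k(rvx.size, config.top_fraction * 100.0)
        va = float(mag[order[:k_va]].mean())

        best_n, best_err = None, np.inf
        chosen = None
        for n_pct in range(1, 101):
            k = _top_k(rvx.size, float(n_pct))
            est = float(rvx[order[:k]].mean())
            err = abs(est - float(gt_dx))
            if err <= gt_tolerance:
                chosen = n_pct
                break
            if err < best_err:
                best_err, best_n = err, n_pct
        vas.append(va)
        ns.append(float(chosen if chosen is not None else best_n))

    if len(vas) < 10:
        raise ValueError("fewer than 10 usable calibration pairs after filtering")

    vas_arr = np.array(vas)
    ns_arr = np.array(ns)
    order = np.argsort(vas_arr, kind="stable")
    vas_arr, ns_arr = vas_arr[order], ns_arr[order]

    n_bins = min(max_knots, max(2, len(vas_arr) // 5))
    edges = np.quantile(vas_arr, np.linspace(0, 1, n_bins + 1))
    knot_va: list[float] = []
    knot_n: list[float] = []
    weights: list[float] = []
    for i in range(n_bins):
        lo, hi = edges[i], edges[i + 1]
        in_bin = (vas_arr >= lo) & (
            (vas_arr <= hi) if i == n_bins - 1 else (vas_arr < hi)
        )
        if not in_bin.any():
            continue
        knot_va.append(float(np.median(vas_arr[in_bin])))
        knot_n.append(float(np.median(ns_arr[in_bin])))
        weights.append(float(in_bin.sum()))

    # merge duplicate Va positions so knots stay strictly increasing
    merged: dict[float, tuple[float, float]] = {}
    for v, n_val, wt in zip(knot_va, knot_n, weights):
        if v in merged:
            n0, w0 = merged[v]
            merged[v] = ((n0 * w0 + n_val * wt) / (w0 + wt), w0 + wt)
        else:
            merged[v] = (n_val, wt)
    kv = np.array(sorted(merged))
    kn = np.array([merged[v][0] for v in kv])
    kw = np.array([merged[v][1] for v in kv])
    kn = _pava_decreasing(kn, kw)
    kn = np.clip(kn, 1.0, 100.0)
    return VaNTable(tuple(zip(kv, kn)))
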