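"""Multi-kernel block matching (MKBM) between two, possibly distant, frames.

The reference block is split into four overlapping sub-blocks (2x2 tiling,
adjacent sub-blocks sharing ``overlap`` pixels). Each sub-block is located
in the target frame by exhaustive integer-grid search minimising the mean
sum of absolute differences

    SAD = (1 / MN) * sum |T(i, j) - R(i, j)|

over a window ``predicted +- search_range``. The four candidate
displacements are fused by keeping the sub-block with the largest
horizontal displacement magnitude: tissue adjacent to the tendon is dragged
passively and moves *less*, so the fastest sub-block is the one riding the
tendon itself. A signed-max mode and the NCC-weighted average fusion of the
original multi-kernel scheme are available as alternatives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .config import TrackerConfig
from .types import Region

__all__ = [
    "BlockTemplate",
    "SubBlockMatch",
    "BlockDisplacement",
    "extract_template",
    "split_subblocks",
    "sad",
    "match_subblock",
    "fuse_displacements",
    "match_block",
]


@dataclass
class BlockTemplate:
    """Reference block extracted from a source frame."""

    pixels: np.ndarray  # (h, w)
    anchor: Region
    frame_index: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (self.anchor.height, self.anchor.width):
            raise ValueError(
                f"template pixels {self.pixels.shape} do not match anchor "
                f"{self.anchor.height}x{self.anchor.width}"
            )


@dataclass
class SubBlock:
    """One of the four overlapping kernels; offset is relative to the block."""

    pixels: np.ndarray
    offset: tuple[int, int]  # (dx, dy) of the sub-block's top-left in the block
    index: int  # 1..4, row-major (TL, TR, BL, BR)


@dataclass
class SubBlockMatch:
    index: int
    dx: int
    dy: int
    sad_score: float
    ncc: float | None = None
    refined: tuple[float, float] | None = None  # optional sub-pixel estimate

    def __post_init__(self) -> None:
        if self.sad_score < 0:
            raise ValueError("sad_score must be >= 0")


@dataclass
class BlockDisplacement:
    dx: float
    dy: float
    contributing_index: int | None
    matches: list[SubBlockMatch]


def extract_template(frame: np.ndarray, region: Region, frame_index: int = 0) -> BlockTemplate:
    return BlockTemplate(region.extract(frame).copy(), region, frame_index)


def split_subblocks(block: np.ndarray | BlockTemplate, overlap: int = 10) -> list[SubBlock]:
    """2x2 tiling of the block into sub-blocks sharing ``overlap`` pixels.

    Each half takes ``(size + overlap) / 2`` pixels, the left/top sub-blocks
    taking the extra pixel when that split is odd; the union always covers
    the full block and adjacent sub-blocks overlap by exactly ``overlap``
    pixels in each dimension.
    """
    pixels = block.pixels if isinstance(block, BlockTemplate) else np.asarray(block)
    h, w = pixels.shape
    if w <= overlap + 2 or h <= overlap + 2:
        raise ValueError(
            f"block {w}x{h} too small to split with overlap {overlap}"
        )

    def spans(size: int) -> list[tuple[int, int]]:
        first = math.ceil((size + overlap) / 2)
        second = size + overlap - first
        return [(0, first), (size - second, second)]

    subs: list[SubBlock] = []
    idx = 1
    for y0, sh in spans(h):
        for x0, sw in spans(w):
            subs.append(
                SubBlock(pixels[y0 : y0 + sh, x0 : x0 + sw], (x0, y0), idx)
            )
            idx += 1
    return subs


def sad(target: np.ndarray, reference: np.ndarray) -> float:
    """Mean sum of absolute differences between two same-shape blocks."""
    target = np.asarray(target, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if target.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: target {target.shape} vs reference {reference.shape}"
        )
    return float(np.mean(np.abs(target - reference)))


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float((a * a).sum()) * float((b * b).sum()))
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def match_subblock(
    sub_pixels: np.ndarray,
    target_frame: np.ndarray,
    origin: tuple[int, int],
    predicted: tuple[int, int] = (0, 0),
    search_range: tuple[int, int] = (20, 10),
    *,
    index: int = 0,
    compute_ncc: bool = False,
    subpixel_refine: bool = False,
) -> SubBlockMatch:
    """Exhaustive SAD search for one sub-block.

    ``origin`` is the sub-block's top-left in source-frame coordinates;
    candidate displacements span ``predicted +- search_range`` on the
    integer grid. Ties are broken by smallest displacement magnitude, then
    leftmost (smallest dx), then topmost (smallest dy). Candidates whose
    footprint leaves the target frame are clipped away with a warning; if
    nothing remains a bounds error is raised.
    """
    sub_pixels = np.asarray(sub_pixels, dtype=np.float64)
    sh, sw = sub_pixels.shape
    fh, fw = target_frame.shape
    ox, oy = int(origin[0]), int(origin[1])
    px, py = int(round(predicted[0])), int(round(predicted[1]))
    rx, ry = int(search_range[0]), int(search_range[1])

    dxs = np.arange(px - rx, px + rx + 1)
    dys = np.arange(py - ry, py + ry + 1)
    ok_x = (dxs + ox >= 0) & (dxs + ox + sw <= fw)
    ok_y = (dys + oy >= 0) & (dys + oy + sh <= fh)
    if not ok_x.all() or not ok_y.all():
        if not ok_x.any() or not ok_y.any():
            raise IndexError(
                "search window lies entirely outside the target frame"
            )
        warnings.warn(
            "search window clipped at the frame border", stacklevel=2
        )
        dxs, dys = dxs[ok_x], dys[ok_y]

    x0, y0 = int(dxs[0] + ox), int(dys[0] + oy)
    x1, y1 = int(dxs[-1] + ox + sw), int(dys[-1] + oy + sh)
    area = np.ascontiguousarray(target_frame[y0:y1, x0:x1], dtype=np.float64)
    windows = sliding_window_view(area, (sh, sw))
    # windows[j, i] is the candidate at displacement (dxs[i], dys[j])
    scores = np.abs(windows - sub_pixels[None, None]).mean(axis=(2, 3))

    gx, gy = np.meshgrid(dxs, dys)
    # lexsort uses the *last* key as primary: SAD, then displacement
    # magnitude, then leftmost (smallest dx), then topmost (smallest dy)
    flat = np.lexsort(
        (gy.ravel(), gx.ravel(), (gx**2 + gy**2).ravel(), scores.ravel())
    )
    best = flat[0]
    bj, bi = np.unravel_index(best, scores.shape)
    bdx, bdy = int(dxs[bi]), int(dys[bj])
    best_sad = float(scores[bj, bi])

    ncc_val = None
    if compute_ncc:
        patch = target_frame[oy + bdy : oy + bdy + sh, ox + bdx : ox + bdx + sw]
        ncc_val = _ncc(sub_pixels, patch)

    refined = None
    if subpixel_refine:
        refined = (
            bdx + _parabolic_offset(scores[bj, max(bi - 1, 0) : bi + 2], bi > 0, bi < scores.shape[1] - 1),
            bdy + _parabolic_offset(scores[max(bj - 1, 0) : bj + 2, bi], bj > 0, bj < scores.shape[0] - 1),
        )

    return SubBlockMatch(index, bdx, bdy, best_sad, ncc=ncc_val, refined=refined)


def _parabolic_offset(triple: np.ndarray, has_left: bool, has_right: bool) -> float:
    """Vertex offset of a parabola through three SAD samples, in [-0.5, 0.5]."""
    if not (has_left and has_right) or triple.size != 3:
        return 0.0
    s_m, s_0, s_p = float(triple[0]), float(triple[1]), float(triple[2])
    denom = s_m - 2.0 * s_0 + s_p
    if denom <= 0:
        return 0.0
    return float(np.clip(0.5 * (s_m - s_p) / denom, -0.5, 0.5))


def fuse_displacements(
    matches: list[SubBlockMatch], mode: str = "magnitude"
) -> BlockDisplacement:
    """Combine the four sub-block matches into one block displacement.

    ``magnitude`` (default) keeps the sub-block with the largest |dx| —
    passively dragged neighbouring tissue moves less than the tendon, so the
    fastest kernel tracks the tendon. ``signed`` keeps the largest signed
    dx. Ties are broken by lower SAD, then lower sub-block index.
    ``ncc_weighted`` averages all four displacements weighted by their
    (clamped-positive) normalized cross-correlation.
    """
    if len(matches) != 4:
        raise ValueError(f"expected exactly 4 sub-block matches, got {len(matches)}")
    if mode in ("magnitude", "signed"):
        if mode == "magnitude":
            key = lambda m: (-abs(m.dx), m.sad_score, m.index)
        else:
            key = lambda m: (-m.dx, m.sad_score, m.index)
        best = min(matches, key=key)
        return BlockDisplacement(float(best.dx), float(best.dy), best.index, list(matches))
    if mode == "ncc_weighted":
        weights = np.array([max(m.ncc if m.ncc is not None else 0.0, 0.0) for m in matches])
        if weights.sum() == 0:
            weights = np.ones(4)
        weights = weights / weights.sum()
        dx = float(sum(w * m.dx for w, m in zip(weights, matches)))
        dy = float(sum(w * m.dy for w, m in zip(weights, matches)))
        return BlockDisplacement(dx, dy, None, list(matches))
    raise ValueError(f"unknown fusion mode {mode!r}")


def match_block(
    template: BlockTemplate,
    target_frame: np.ndarray,
    predicted: tuple[int, int] = (0, 0),
    config: TrackerConfig | None = None,
) -> BlockDisplacement:
    """Full MKBM step: split, match each sub-block, fuse."""
    config = config or TrackerConfig()
    need_ncc = config.fusion_mode == "ncc_weighted"
    subs = split_subblocks(template, config.subblock_overlap)
    matches = [
        match_subblock(
            s.pixels,
            target_frame,
            (template.anchor.x + s.offset[0], template.anchor.y + s.offset[1]),
            predicted,
            config.search_range,
            index=s.index,
            compute_ncc=need_ncc,
            subpixel_refine=config.subpixel_refine,
        )
        for s in subs
    ]
    fused = fuse_displacements(matches, config.fusion_mode)
    if config.subpixel_refine and fused.contributing_index is not None:
        best = matches[fused.contributing_index - 1]
        if best.refined is not None:
            fused.dx, fused.dy = float(best.refined[0]), float(best.refined[1])
    return fused
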