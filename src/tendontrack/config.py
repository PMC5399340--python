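"""Tracker configuration and the Va-N calibration table.

All tunables of the OFTB-MKBM pipeline live in :class:`TrackerConfig` so a
whole run is reproducible from one config file. Defaults follow the settings
that work well for tendon B-mode sequences: accumulated-displacement
threshold ``lambda_px = 10`` pixels, a 17x17 Lucas-Kanade window, a 101x41
tracking region sampled by flow points every 2 pixels, and four matching
sub-blocks overlapping by 10 pixels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = ["VaNTable", "TrackerConfig", "DEFAULT_VA_N_KNOTS", "load_config"]


#: Placeholder calibration mapping Va (mean of the top-5% flow-point
#: displacement magnitudes, pixels) to N (percentage of top flow points to
#: average for the region displacement). Only the knot (1.5 -> 20) is an
#: established operating point; the rest is a monotone default that users
#: should recalibrate on their own sequences via ``calibrate_va_n``.
DEFAULT_VA_N_KNOTS: tuple[tuple[float, float], ...] = (
    (0.5, 60.0),
    (1.0, 35.0),
    (1.5, 20.0),
    (2.0, 10.0),
    (3.0, 5.0),
)


@dataclass(frozen=True)
class VaNTable:
    """Piecewise-linear map from the Va index to the top-N% averaging rule.

    Knots are ``(Va, N)`` pairs with strictly increasing Va and N in
    ``(0, 100]``; lookups outside the knot range are clamped to the end
    values.
    """

    knots: tuple[tuple[float, float], ...] = DEFAULT_VA_N_KNOTS

    def __post_init__(self) -> None:
        knots = tuple((float(v), float(n)) for v, n in self.knots)
        object.__setattr__(self, "knots", knots)
        if len(knots) < 1:
            raise ValueError("VaNTable needs at least one knot")
        va = np.array([k[0] for k in knots])
        n = np.array([k[1] for k in knots])
        if np.any(np.diff(va) <= 0):
            raise ValueError("Va knots must be strictly increasing")
        if np.any(n <= 0) or np.any(n > 100):
            raise ValueError("N values must lie in (0, 100]")

    @property
    def va(self) -> np.ndarray:
        return np.array([k[0] for k in self.knots])

    @property
    def n(self) -> np.ndarray:
        return np.array([k[1] for k in self.knots])

    def lookup(self, va: float) -> float:
        """N (percent) for a given Va; clamped outside the knot range."""
        return float(np.interp(va, self.va, self.n))

    def __call__(self, va: float) -> float:
        return self.lookup(va)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"va_px": self.va, "n_percent": self.n}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "VaNTable":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(tuple(zip(df["va_px"], df["n_percent"])))


_VALID_INTERPOLATION = ("flow_trend", "linear")
_VALID_FUSION = ("magnitude", "signed", "ncc_weighted")


@dataclass
class TrackerConfig:
    """Every tunable of the OFTB-MKBM pipeline.

    Attributes
    ----------
    lambda_px : float
        Accumulated-displacement threshold that closes a flow period
        (pixels; default 10).
    of_window : int
        Odd side length of the Lucas-Kanade least-squares window (default 17).
    flow_grid_step : int
        Spacing of flow points inside the region, pixels (default 2).
    region_size : (int, int)
        (width, height) of the tracking region; default (101, 41), which with
        a 17x17 window and 2-px grid step yields 43 x 13 flow points.
    subblock_overlap : int
        Shared pixels between adjacent matching sub-blocks (default 10).
    search_range : (int, int)
        Exhaustive SAD search half-range (+-x, +-y) around the predicted
        position (default (20, 10); exceeds lambda_px so the true
        displacement stays in range).
    top_fraction : float
        Fraction of retained flow points averaged to form the Va index
        (default 0.05, i.e. the top 5% by |Vx|).
    va_n_table : VaNTable
        Calibration mapping Va to the averaging percentage N.
    interpolation_mode : str
        ``flow_trend`` (scale intra-period displacements by the optical-flow
        trend) or ``linear`` (plain linear interpolation in frame index; the
        "adaptive MKBM" comparator behaviour).
    fusion_mode : str
        How the four sub-block matches combine: ``magnitude`` (keep the
        sub-block with the largest |dx|; rejects passively dragged
        neighbouring tissue), ``signed`` (largest signed dx) or
        ``ncc_weighted`` (normalized-cross-correlation weighted average).
    presmooth_sigma : float
        Gaussian blur applied to both frames before differentiation (pixels).
    eig_ratio : float
        Flow points whose 2x2 normal matrix has smallest/largest eigenvalue
        ratio below this are marked invalid (rank-deficient texture).
    subpixel_refine : bool
        Optional parabolic refinement of the SAD minimum (off by default;
        matching is integer-only).
    """

    lambda_px: float = 10.0
    of_window: int = 17
    flow_grid_step: int = 2
    region_size: tuple[int, int] = (101, 41)
    subblock_overlap: int = 10
    search_range: tuple[int, int] = (20, 10)
    top_fraction: float = 0.05
    va_n_table: VaNTable = field(default_factory=VaNTable)
    interpolation_mode: str = "flow_trend"
    fusion_mode: str = "magnitude"
    presmooth_sigma: float = 1.0
    eig_ratio: float = 1e-6
    subpixel_refine: bool = False

    def __post_init__(self) -> None:
        if self.lambda_px <= 0:
            raise ValueError("lambda_px must be > 0")
        if self.of_window < 3 or self.of_window % 2 == 0:
            raise ValueError("of_window must be an odd integer >= 3")
        if self.flow_grid_step < 1:
            raise ValueError("flow_grid_step must be >= 1")
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        w, h = self.region_size
        if w < 3 or h < 3:
            raise ValueError("region_size must be at least 3x3")
        self.region_size = (int(w), int(h))
        rx, ry = self.search_range
        if rx < 1 or ry < 1:
            raise ValueError("search_range entries must be >= 1")
        self.search_range = (int(rx), int(ry))
        if self.subblock_overlap < 0:
            raise ValueError("subblock_overlap must be >= 0")
        if self.interpolation_mode not in _VALID_INTERPOLATION:
            raise ValueError(
                f"interpolation_mode must be one of {_VALID_INTERPOLATION}"
            )
        if self.fusion_mode not in _VALID_FUSION:
            raise ValueError(f"fusion_mode must be one of {_VALID_FUSION}")
        if self.presmooth_sigma < 0:
            raise ValueError("presmooth_sigma must be >= 0")
        if isinstance(self.va_n_table, (list, tuple)):
            self.va_n_table = VaNTable(tuple(self.va_n_table))

    def replace(self, **changes) -> "TrackerConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["va_n_table"] = [list(k) for k in self.va_n_table.knots]
        d["region_size"] = list(self.region_size)
        d["search_range"] = list(self.search_range)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "TrackerConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(data)
        if "va_n_table" in kwargs and not isinstance(kwargs["va_n_table"], VaNTable):
            kwargs["va_n_table"] = VaNTable(
                tuple(tuple(k) for k in kwargs["va_n_table"])
            )
        for key in ("region_size", "search_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        try:
            return cls(**kwargs)
        except ValueError as err:
            raise ValueError(f"invalid tracker config: {err}") from err


def load_config(path) -> TrackerConfig:
    """Load a YAML key/value config; missing keys take the defaults above."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a key/value mapping")
    return TrackerConfig.from_dict(data)
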