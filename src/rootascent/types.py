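"""Shared containers for the 2D pipeline.

Coordinate convention, used throughout the toolkit: ``(row, col)``, 0-based,
row 0 at the top of the image.  A root therefore grows toward *larger* row
indices, and "ascending" means decreasing row.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# skeleton point classes (values stored in SkeletonGraph.classes)
BACKGROUND = 0
ENDPOINT = 1
JUNCTION = 2
NORMAL = 3
ISOLATED = 4

CLASS_NAMES = {
    BACKGROUND: "background",
    ENDPOINT: "endpoint",
    JUNCTION: "junction",
    NORMAL: "normal",
    ISOLATED: "isolated",
}


@dataclass
class RootImage:
    """A calibrated 2D raster (grayscale or RGB)."""

    pixels: np.ndarray
    mm_per_px: float = 1.0


@dataclass
class BinaryMask:
    """Binary root mask on the image grid; foreground (True) is the root class.

    ``polarity`` records which intensity class was mapped to foreground:
    ``root_bright`` for scans where roots appear white on dark background,
    ``root_dark`` for inverted setups.
    """

    grid: np.ndarray
    mm_per_px: float = 1.0
    polarity: str = "root_bright"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass
class SkeletonGraph:
    """1-px skeleton raster with a per-pixel class label.

    ``classes`` holds one of ENDPOINT / JUNCTION / NORMAL / ISOLATED on active
    pixels and BACKGROUND elsewhere; ``change_count`` holds the cyclic
    8-neighborhood transition count C (even, 0..8) on active pixels.
    ``labels`` are 8-connected component ids (1..n_components).
    """

    skeleton: np.ndarray
    classes: np.ndarray
    change_count: np.ndarray
    labels: np.ndarray
    n_components: int
    mm_per_px: float = 1.0

    def component_pixels(self, component_id: int) -> np.ndarray:
        return np.argwhere(self.labels == component_id)


@dataclass
class AdventitiousPath:
    """Ordered skeleton pixels of one adventitious root, bottom tip to top.

    ``pixels`` is an (N, 2) int array of (row, col); consecutive entries are
    8-adjacent, the first is the lowest point (start), the last the highest
    (breakpoint).
    """

    pixels: np.ndarray
    component_id: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int).reshape(-1, 2)

    @property
    def start(self) -> tuple[int, int]:
        return tuple(self.pixels[0])

    @property
    def breakpoint(self) -> tuple[int, int]:
        return tuple(self.pixels[-1])

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass
class Peak:
    """One radius-profile excursion above baseline + Th1 on one side."""

    side: str  # "left" | "right"
    start: int  # first path index of the run
    end: int  # last path index of the run (inclusive)
    height: float  # max radius above baseline within the run, px
    width: int  # run length along the path, px
    area: float  # sum of (radius - baseline) over the run, px^2
    klass: str  # "lateral" | "nodule"


@dataclass
class RadiusProfile:
    """Per-path-position left/right radii with peaks and thresholds.

    Radii are in pixels: the number of foreground pixels between the skeleton
    pixel (exclusive) and the first background pixel on that side, so the
    local diameter is ``r_left + r_right + 1``.
    """

    r_left: np.ndarray
    r_right: np.ndarray
    baseline_left: np.ndarray | None = None
    baseline_right: np.ndarray | None = None
    peaks: list[Peak] = field(default_factory=list)
    th1: float = 1.0
    th2: float | None = None

    def __len__(self) -> int:
        return len(self.r_left)

    @property
    def diameter_px(self) -> np.ndarray:
        return np.asarray(self.r_left, float) + np.asarray(self.r_right, float) + 1.0


@dataclass
class TraitRecord:
    """Phenotypic traits for one adventitious root at one timepoint.

    LLRL is read as "longest lateral root length" and TNN/PNN as total /
    on-primary nodule number; these acronym expansions are interpretations
    (see docs/methods.md).
    """

    arn: int = 1
    arl_mm: float = 0.0
    dia_mean_mm: float = 0.0
    dia_apical_mm: float = 0.0
    unbranched_apical_mm: float = 0.0
    lrn: int = 0
    llrl_mm: float = 0.0
    lateral_lengths_mm: list[float] = field(default_factory=list)
    tnn: int = 0
    pnn: int = 0
    projected_area_mm2: float = 0.0
    timestamp: object = None
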