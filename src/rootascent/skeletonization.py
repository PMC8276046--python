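"""Topology-preserving thinning and skeleton-point classification.

The root mask is thinned to a 1-px-wide skeleton by iterative deletion of
simple points (pixels whose removal does not change the number of foreground
components or background holes).  Every skeleton pixel is then classified
from its 8-neighborhood using a cyclic change count:

The eight neighbors of a pixel P are labeled P1..P8 clockwise, the direct
neighbors being P2, P4, P6, P8 and the diagonal neighbors P1, P3, P5, P7.
Walking the cycle P1 -> P2 -> ... -> P8 -> P1, each active/inactive
transition contributes 1 to the change count C, so C is even and equals
twice the number of maximal runs of active neighbors — i.e. twice the number
of branches meeting at P.  The class rule is:

=====  ==========
C      class
=====  ==========
0      isolated
2      endpoint   (one branch; includes tip patterns with two mutually
                   adjacent active neighbors)
4      normal     (exactly two branches)
>= 6   junction   (at least three branches of different directions)
=====  ==========
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import thin

from .errors import NotASkeletonError
from .types import (
    BACKGROUND,
    ENDPOINT,
    ISOLATED,
    JUNCTION,
    NORMAL,
    BinaryMask,
    SkeletonGraph,
)

# P1..P8 offsets, clockwise from the upper-left diagonal.  Diagonals are odd
# (P1, P3, P5, P7), direct neighbors even (P2, P4, P6, P8).
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1),  # P1
    (-1, 0),  # P2
    (-1, 1),  # P3
    (0, 1),  # P4
    (1, 1),  # P5
    (1, 0),  # P6
    (1, -1),  # P7
    (0, -1),  # P8
)

_STRUCT8 = np.ones((3, 3), dtype=bool)


def change_count(neighbors: Sequence[bool]) -> int:
    """Cyclic 0<->1 transition count C of the 8 neighbor states P1..P8.

    ``neighbors`` lists the neighbor states in the cyclic order of
    ``NEIGHBOR_OFFSETS``; Ch_i compares P_i with P_{i+1} and Ch_8 compares P8
    with P1.  C = 2 x (number of maximal runs of active neighbors).
    """
    n = [bool(v) for v in neighbors]
    if len(n) != 8:
        raise ValueError("expected 8 neighbor states")
    return sum(n[i] != n[(i + 1) % 8] for i in range(8))


def _neighbor_stack(skel: np.ndarray) -> np.ndarray:
    """(8, R, C) boolean stack of the P1..P8 neighbor planes.

    Out-of-image neighbors are inactive.
    """
    padded = np.pad(skel, 1, mode="constant", constant_values=False)
    planes = [
        padded[1 + dr : 1 + dr + skel.shape[0], 1 + dc : 1 + dc + skel.shape[1]]
        for dr, dc in NEIGHBOR_OFFSETS
    ]
    return np.stack(planes)


def change_count_map(skel: np.ndarray) -> np.ndarray:
    """Per-pixel change count C over the whole raster (uint8)."""
    stack = _neighbor_stack(np.asarray(skel, dtype=bool))
    c = np.zeros(skel.shape, dtype=np.uint8)
    for i in range(8):
        c += (stack[i] != stack[(i + 1) % 8]).astype(np.uint8)
    return c


def _has_2x2_block(skel: np.ndarray) -> np.ndarray:
    """Boolean map of upper-left corners of all-active 2x2 blocks."""
    return skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]


def _is_simple(skel: np.ndarray, r: int, c: int) -> bool:
    """True if deleting (r, c) preserves local topology.

    A pixel is simple iff its active 8-neighbors form exactly one 8-connected
    component and it has at least one inactive 4-neighbor (so no hole is
    created).
    """
    patch = np.zeros((3, 3), dtype=bool)
    rows, cols = skel.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                patch[dr + 1, dc + 1] = skel[rr, cc]
    center = patch.copy()
    center[1, 1] = False
    _, n = ndimage.label(center, structure=_STRUCT8)
    if n != 1:
        return False
    return not (patch[0, 1] and patch[2, 1] and patch[1, 0] and patch[1, 2])


def _dissolve_2x2(skel: np.ndarray) -> np.ndarray:
    """Delete simple points until no all-active 2x2 block remains."""
    skel = skel.copy()
    for _ in range(4 * skel.size):
        corners = np.argwhere(_has_2x2_block(skel))
        if corners.size == 0:
            return skel
        changed = False
        for r0, c0 in corners:
            for r, c in ((r0, c0), (r0, c0 + 1), (r0 + 1, c0), (r0 + 1, c0 + 1)):
                if skel[r, c] and _is_simple(skel, r, c):
                    skel[r, c] = False
                    changed = True
                    break
        if not changed:  # fully blocked; cannot thin further without breaking topology
            return skel
    return skel


def skeletonize(mask: BinaryMask | np.ndarray) -> np.ndarray:
    """Thin a binary mask to a 1-px skeleton, preserving topology.

    The boundary is eroded iteratively, clearing only pixels whose deletion
    does not modify the object's topology, until no further deletion is
    possible.  Foreground 8-connected component count and background
    4-connected hole count are invariant.  An empty mask yields an empty
    skeleton.
    """
    grid = mask.grid if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if not grid.any():
        return np.zeros_like(grid, dtype=bool)
    skel = thin(grid)
    if _has_2x2_block(skel).any():
        skel = _dissolve_2x2(skel)
    return skel


def classify_points(
    skeleton: np.ndarray, mm_per_px: float = 1.0, strict: bool = True
) -> SkeletonGraph:
    """Label every skeleton pixel as endpoint / junction / normal / isolated.

    Pure function of the skeleton raster.  With ``strict`` (default), an
    all-active 2x2 block raises :class:`NotASkeletonError` since the raster is
    then not 1 px wide.
    """
    skel = np.asarray(skeleton, dtype=bool)
    if strict and _has_2x2_block(skel).any():
        raise NotASkeletonError("not a skeleton: found an all-active 2x2 block")
    c = change_count_map(skel)
    classes = np.full(skel.shape, BACKGROUND, dtype=np.uint8)
    classes[skel & (c == 0)] = ISOLATED
    classes[skel & (c == 2)] = ENDPOINT
    classes[skel & (c == 4)] = NORMAL
    classes[skel & (c >= 6)] = JUNCTION
    c = np.where(skel, c, 0).astype(np.uint8)
    labels, n = ndimage.label(skel, structure=_STRUCT8)
    return SkeletonGraph(
        skeleton=skel,
        classes=classes,
        change_count=c,
        labels=labels,
        n_components=int(n),
        mm_per_px=mm_per_px,
    )


def count_components_and_holes(mask: np.ndarray) -> tuple[int, int]:
    """(8-connected foreground components, 4-connected background holes).

    Holes are background components that do not touch the image border.
    """
    mask = np.asarray(mask, dtype=bool)
    _, n_fg = ndimage.label(mask, structure=_STRUCT8)
    padded = np.pad(~mask, 1, mode="constant", constant_values=True)
    _, n_bg = ndimage.label(padded, structure=ndimage.generate_binary_structure(2, 1))
    return int(n_fg), int(n_bg - 1)
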