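"""The Ascending Path: isolating the adventitious-root skeleton.

A grapevine cutting's adventitious root runs from the stem down to its tip,
with lateral roots branching off.  On the skeleton, the adventitious root is
recovered by starting at the lowest skeleton point and walking upward,
always taking the most ascending branch at every junction, until the highest
point of the component is reached.  Junctions are recognized by the change
count C >= 6 of the point classification.

Branch choice uses a short lookahead (default 15 px) rather than a single
pixel, because 1-px decisions are noise-prone on jittery skeletons; ties are
broken deterministically (smaller column deviation from the current heading,
then smaller column).  Dead ends trigger depth-first backtracking, so the
traversal is total on trees.
"""
from __future__ import annotations

import numpy as np

from .errors import NoAscendingRouteError
from .skeletonization import NEIGHBOR_OFFSETS
from .types import AdventitiousPath, SkeletonGraph

Coord = tuple[int, int]


def find_anchors(pixels: np.ndarray) -> tuple[Coord, Coord]:
    """(start, breakpoint) anchors of one skeleton component.

    start = active pixel with the maximum row, breakpoint = active pixel with
    the minimum row; ties on the row are broken by minimum column.
    """
    pixels = np.asarray(pixels, dtype=int).reshape(-1, 2)
    if len(pixels) == 0:
        raise ValueError("empty component")
    order = np.lexsort((pixels[:, 1], pixels[:, 0]))  # row asc, then col asc
    breakpoint_ = tuple(pixels[order[0]])
    rows = pixels[:, 0]
    bottom = pixels[rows == rows.max()]
    start = tuple(bottom[np.argmin(bottom[:, 1])])
    return (int(start[0]), int(start[1])), (int(breakpoint_[0]), int(breakpoint_[1]))


def _active_neighbors(skel: np.ndarray, p: Coord) -> list[Coord]:
    rows, cols = skel.shape
    out = []
    for dr, dc in NEIGHBOR_OFFSETS:
        r, c = p[0] + dr, p[1] + dc
        if 0 <= r < rows and 0 <= c < cols and skel[r, c]:
            out.append((r, c))
    return out


def _lookahead_endpoint(
    skel: np.ndarray, visited: set[Coord], first: Coord, origin: Coord, depth: int
) -> Coord:
    """Endpoint of a greedy walk of up to ``depth`` steps into a branch.

    The walk starts with the step origin -> first and then always continues
    to the most ascending unvisited neighbor, without re-entering its own
    trace or pixels already on the main path.
    """
    local = {origin, first}
    cur = first
    for _ in range(depth - 1):
        cands = [
            q
            for q in _active_neighbors(skel, cur)
            if q not in local and q not in visited
        ]
        if not cands:
            break
        cands.sort(key=lambda q: (q[0], abs(q[1] - cur[1]), q[1]))
        cur = cands[0]
        local.add(cur)
    return cur


def trace_ascending(
    graph: SkeletonGraph | np.ndarray,
    start: Coord,
    breakpoint: Coord,
    lookahead: int = 15,
    component_id: int = 1,
) -> AdventitiousPath:
    """Walk the skeleton from ``start`` up to ``breakpoint``.

    At normal points the walk continues to the single unvisited neighbor; at
    junctions every unvisited outgoing branch is scored by a greedy lookahead
    of ``lookahead`` pixels and the branch whose lookahead endpoint has the
    smallest row is taken.  Reaching a dead end that is not the breakpoint
    backtracks to the last junction and takes the next-best branch.

    Returns a simple (no repeated pixel), 8-connected path.

    Raises
    ------
    NoAscendingRouteError
        If every branch from every junction is exhausted without reaching the
        breakpoint (possible on pathological loops).
    """
    skel = graph.skeleton if isinstance(graph, SkeletonGraph) else np.asarray(graph, bool)
    start = (int(start[0]), int(start[1]))
    breakpoint = (int(breakpoint[0]), int(breakpoint[1]))
    if not skel[start] or not skel[breakpoint]:
        raise ValueError("start/breakpoint must be active skeleton pixels")
    if start == breakpoint:
        return AdventitiousPath(np.array([start]), component_id)

    def ordered_candidates(cur: Coord, prev: Coord | None, visited: set[Coord]):
        cands = [q for q in _active_neighbors(skel, cur) if q not in visited]
        if len(cands) <= 1:
            return cands
        if prev is not None:
            heading_dc = cur[1] - prev[1]
        else:
            heading_dc = 0  # default heading: straight up

        def key(q: Coord):
            ep = _lookahead_endpoint(skel, visited, q, cur, lookahead)
            return (ep[0], abs((q[1] - cur[1]) - heading_dc), q[1], q[0])

        return sorted(cands, key=key)

    visited: set[Coord] = {start}
    path: list[Coord] = [start]
    # DFS stack of per-pixel candidate iterators (scored lazily on push)
    stack = [iter(ordered_candidates(start, None, visited))]
    while stack:
        if path[-1] == breakpoint:
            return AdventitiousPath(np.array(path), component_id)
        nxt = next((q for q in stack[-1] if q not in visited), None)
        if nxt is None:
            stack.pop()
            path.pop()
            continue
        visited.add(nxt)
        prev = path[-1]
        path.append(nxt)
        stack.append(iter(ordered_candidates(nxt, prev, visited)))
    raise NoAscendingRouteError(
        "no ascending route from start to breakpoint (branches exhausted)"
    )


def extract_adventitious_paths(
    graph: SkeletonGraph,
    lookahead: int = 15,
    min_component_px: int = 10,
    iterative: bool = False,
) -> list[AdventitiousPath]:
    """One Ascending Path per skeleton component (components below
    ``min_component_px`` pixels are ignored as debris).

    With ``iterative`` (an extension, off by default), after tracing a
    component the traced pixels are subtracted and any residual piece
    spanning at least half the component's height is re-anchored and traced
    as a further adventitious root of the same component — a heuristic for
    several adventitious roots merged into one connected skeleton.
    """
    from scipy import ndimage

    paths: list[AdventitiousPath] = []
    for comp_id in range(1, graph.n_components + 1):
        pixels = graph.component_pixels(comp_id)
        if len(pixels) < min_component_px:
            continue
        comp_mask = graph.labels == comp_id
        start, bp = find_anchors(pixels)
        path = trace_ascending(comp_mask, start, bp, lookahead, comp_id)
        paths.append(path)
        if iterative:
            span = pixels[:, 0].max() - pixels[:, 0].min()
            residual = comp_mask.copy()
            residual[tuple(path.pixels.T)] = False
            labels, n = ndimage.label(residual, structure=np.ones((3, 3), bool))
            for sub in range(1, n + 1):
                sub_px = np.argwhere(labels == sub)
                if len(sub_px) < min_component_px:
                    continue
                if sub_px[:, 0].max() - sub_px[:, 0].min() < span / 2:
                    continue
                s, b = find_anchors(sub_px)
                paths.append(trace_ascending(labels == sub, s, b, lookahead, comp_id))
    return paths
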