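"""Phenotypic trait extraction from pipeline outputs.

Traits per adventitious root and image: ARL (adventitious root length, mm),
DIA (local diameter profile summaries), LRN (lateral root number), LLRL
(longest lateral root length, mm — acronym expansion is our interpretation),
TNN/PNN (total / on-primary nodule number — interpretation; biologically
void for grapevine and default-off there), projected root area (mm^2) and
ARN (adventitious root number).  Lengths are geodesic along the skeleton
(1 per direct step, sqrt(2) per diagonal step); a pixel-count compatibility
mode reproduces plain pixel counting.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import UnsortedTimestampsError
from .skeletonization import NEIGHBOR_OFFSETS
from .types import AdventitiousPath, BinaryMask, Peak, SkeletonGraph, TraitRecord

SQRT2 = math.sqrt(2.0)


def geodesic_length_px(pixels: np.ndarray, pixel_count: bool = False) -> float:
    """Length of an ordered 8-connected pixel chain.

    Geodesic: 1 per direct step, sqrt(2) per diagonal step.  With
    ``pixel_count`` the literal number of steps (pixels - 1) is returned
    instead, mirroring plain pixel counting.
    """
    pixels = np.asarray(pixels, int).reshape(-1, 2)
    if len(pixels) < 2:
        return 0.0
    steps = np.abs(np.diff(pixels, axis=0))
    if pixel_count:
        return float(len(pixels) - 1)
    diagonal = (steps == 1).all(axis=1)
    return float(np.sum(np.where(diagonal, SQRT2, steps.max(axis=1))))


def main_traits(
    path: AdventitiousPath,
    diameter_px: np.ndarray,
    mask: BinaryMask,
    peaks: list[Peak] | None = None,
    apical_k: int = 20,
    pixel_count: bool = False,
) -> dict:
    """ARL, DIA summaries, projected area and the unbranched apical zone.

    The apical diameter is the mean local diameter over the last ``apical_k``
    positions toward the start (the root tip is the *lowest* point, path
    index 0).  The unbranched apical zone is the geodesic distance from the
    tip to the first lateral-class peak; without lateral peaks it spans the
    whole root.
    """
    mm = mask.mm_per_px
    diameter_px = np.asarray(diameter_px, float)
    arl_mm = geodesic_length_px(path.pixels, pixel_count) * mm
    k = min(apical_k, len(diameter_px))
    lateral_starts = [p.start for p in (peaks or []) if p.klass == "lateral"]
    if lateral_starts:
        first = min(lateral_starts)
        apical_zone = geodesic_length_px(path.pixels[: first + 1], pixel_count) * mm
    else:
        apical_zone = arl_mm
    return {
        "arl_mm": arl_mm,
        "dia_mean_mm": float(diameter_px.mean()) * mm,
        "dia_apical_mm": float(diameter_px[:k].mean()) * mm,
        "unbranched_apical_mm": apical_zone,
        "projected_area_mm2": float(mask.grid.sum()) * mm * mm,
    }


def _component_geodesic_length(
    pixels: np.ndarray, source: tuple[int, int], pixel_count: bool = False
) -> tuple[float, tuple[int, int]]:
    """Greatest geodesic distance from ``source`` within one component.

    Dijkstra over the 8-adjacency of the component's pixels with sqrt(2)
    diagonal weights (with ``pixel_count`` all steps weigh 1).  Returns the
    distance and the farthest pixel.
    """
    import heapq

    pix = {tuple(p) for p in np.asarray(pixels, int)}
    dist = {source: 0.0}
    heap = [(0.0, source)]
    while heap:
        d, p = heapq.heappop(heap)
        if d > dist.get(p, math.inf):
            continue
        for dr, dc in NEIGHBOR_OFFSETS:
            q = (p[0] + dr, p[1] + dc)
            if q not in pix:
                continue
            w = 1.0 if pixel_count or (dr == 0 or dc == 0) else SQRT2
            nd = d + w
            if nd < dist.get(q, math.inf):
                dist[q] = nd
                heapq.heappush(heap, (nd, q))
    far = max(dist, key=dist.get)
    return dist[far], far


def lateral_traits(
    graph: SkeletonGraph,
    path: AdventitiousPath,
    peaks: list[Peak] | None,
    mm_per_px: float = 1.0,
    mask: BinaryMask | None = None,
    match_tol: int = 10,
    min_lateral_px: int = 3,
    pixel_count: bool = False,
    count_nodules: bool = True,
) -> dict:
    """LRN, per-lateral lengths, LLRL and nodule counts.

    Lateral skeletons are the 8-connected components of (skeleton - path)
    that touch the path.  A component counts toward LRN when its attachment
    index falls within ``match_tol`` positions of a lateral-class peak (with
    no peak list supplied every touching component counts).  Each lateral
    length is the geodesic distance from its attachment to its farthest
    pixel, plus the attachment step and — when ``mask`` is given — the
    standard end-cap correction (the local mask half-width at the far tip,
    where thinning stops short of the boundary).  LLRL is the maximum.
    TNN/PNN are the nodule-class peak counts (all nodules seen here sit on
    the primary, so TNN == PNN).
    """
    comp_mask = graph.labels == path.component_id
    residual = comp_mask.copy()
    residual[tuple(path.pixels.T)] = False
    labels, n = ndimage.label(residual, structure=np.ones((3, 3), bool))
    path_index = {tuple(p): i for i, p in enumerate(path.pixels)}
    dt = None
    if mask is not None:
        dt = ndimage.distance_transform_edt(mask.grid)

    lateral_spans = [
        (p.start, p.end) for p in (peaks or []) if p.klass == "lateral"
    ]
    lengths_mm: list[float] = []
    for comp_id in range(1, n + 1):
        comp_px = np.argwhere(labels == comp_id)
        if len(comp_px) < min_lateral_px:
            continue
        attach_idx = None
        attach_px = None
        for p in map(tuple, comp_px):
            for dr, dc in NEIGHBOR_OFFSETS:
                i = path_index.get((p[0] + dr, p[1] + dc))
                if i is not None and (attach_idx is None or i < attach_idx):
                    attach_idx, attach_px = i, p
        if attach_idx is None:
            continue  # not adjacent to the path
        if peaks is not None and lateral_spans:
            matched = any(
                s - match_tol <= attach_idx <= e + match_tol for s, e in lateral_spans
            )
        elif peaks is not None:
            matched = False
        else:
            matched = True
        if not matched:
            continue
        length, far = _component_geodesic_length(comp_px, attach_px, pixel_count)
        length += 1.0  # attachment step onto the path
        if dt is not None:
            length += max(float(dt[far]) - 1.0, 0.0)  # end-cap beyond the skeleton tip
        lengths_mm.append(length * mm_per_px)
    nodule_count = sum(1 for p in (peaks or []) if p.klass == "nodule")
    if not count_nodules:
        nodule_count = 0
    return {
        "lrn": len(lengths_mm),
        "lateral_lengths_mm": sorted(lengths_mm, reverse=True),
        "llrl_mm": max(lengths_mm) if lengths_mm else 0.0,
        "tnn": nodule_count,
        "pnn": nodule_count,
    }


def compute_traits(
    graph: SkeletonGraph,
    path: AdventitiousPath,
    diameter_px: np.ndarray,
    mask: BinaryMask,
    peaks: list[Peak] | None = None,
    apical_k: int = 20,
    pixel_count: bool = False,
    count_nodules: bool = True,
    timestamp=None,
) -> TraitRecord:
    """Assemble a full :class:`TraitRecord` for one adventitious root."""
    m = main_traits(path, diameter_px, mask, peaks, apical_k, pixel_count)
    lat = lateral_traits(
        graph, path, peaks, mask.mm_per_px, mask=mask, pixel_count=pixel_count,
        count_nodules=count_nodules,
    )
    return TraitRecord(
        arn=1,
        arl_mm=m["arl_mm"],
        dia_mean_mm=m["dia_mean_mm"],
        dia_apical_mm=m["dia_apical_mm"],
        unbranched_apical_mm=m["unbranched_apical_mm"],
        lrn=lat["lrn"],
        llrl_mm=lat["llrl_mm"],
        lateral_lengths_mm=lat["lateral_lengths_mm"],
        tnn=lat["tnn"],
        pnn=lat["pnn"],
        projected_area_mm2=m["projected_area_mm2"],
        timestamp=timestamp,
    )


def growth_series(
    records: list[TraitRecord], expected_timestamps: list | None = None
) -> pd.DataFrame:
    """Per-timepoint trait table with inter-timepoint growth ratios.

    Rows are ordered by timestamp.  With ``expected_timestamps`` given,
    missing timepoints appear as flagged all-NaN rows and are skipped (never
    interpolated) when forming ratios: each ratio divides by the previous
    *present* timepoint.

    Raises :class:`UnsortedTimestampsError` when timestamps cannot be
    mutually ordered.
    """
    if not records:
        raise ValueError("need at least one record")
    try:
        records = sorted(records, key=lambda r: r.timestamp)
    except TypeError as exc:
        raise UnsortedTimestampsError(f"unsorted timestamps: {exc}") from exc
    rows = []
    present = {r.timestamp for r in records}
    timeline = list(expected_timestamps) if expected_timestamps else [
        r.timestamp for r in records
    ]
    try:
        timeline = sorted(set(timeline) | present)
    except TypeError as exc:
        raise UnsortedTimestampsError(f"unsorted timestamps: {exc}") from exc
    by_ts = {r.timestamp: r for r in records}
    for ts in timeline:
        r = by_ts.get(ts)
        if r is None:
            rows.append({"timestamp": ts, "missing": True})
        else:
            rows.append(
                {
                    "timestamp": ts,
                    "missing": False,
                    "arl_mm": r.arl_mm,
                    "projected_area_mm2": r.projected_area_mm2,
                    "lrn": r.lrn,
                    "llrl_mm": r.llrl_mm,
                    "dia_mean_mm": r.dia_mean_mm,
                }
            )
    table = pd.DataFrame(rows)
    ratios = np.full(len(table), np.nan)
    prev = None
    for i, row in table.iterrows():
        if row["missing"]:
            continue
        if prev is not None and table.loc[prev, "projected_area_mm2"] > 0:
            ratios[i] = row["projected_area_mm2"] / table.loc[prev, "projected_area_mm2"]
        prev = i
    table["area_ratio"] = ratios
    return table
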