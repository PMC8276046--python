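"""Adventitious-root reconstruction from the radius profile.

With the adventitious skeleton in hand, the root mask is bisected by the
path and each side is scanned perpendicular to the local path tangent until
the foreground/background boundary, giving a left and a right radius per
path position with 1-px accuracy.  Lateral roots and nodules show up as
peaks in these radius profiles; each peak is classified from its height,
width and area, then suppressed by an iterated band-limited filter clamped
between the two thresholds (baseline - Th1, baseline + Th1) around the local
baseline.  Stamping the filtered cross-sections back onto the grid yields
the adventitious root free of lateral information, with its local diameter
profile d(i) = r_left(i) + r_right(i) + 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import dilation

from .errors import NoConvergenceError, PathOffMaskError
from .types import AdventitiousPath, BinaryMask, Peak, RadiusProfile


@dataclass
class PeakParams:
    """Peak detection/classification parameters.

    th1 : lower threshold above the running-median baseline (px) that a
        radius excursion must exceed to count as a peak.
    baseline_window : running-median window along the path (positions); must
        exceed twice the widest expected peak or the median rides up inside
        wide nodule bulges.
    width_max_lateral : peaks at most this wide (px along the path) are
        lateral-root candidates; wider ones are nodule candidates.  Default
        12 px, sized for fine laterals at 300 dpi.
    height_min : minimum peak height (px) for a lateral.
    area_min : minimum peak area (px^2) for a nodule.
    mad_k : Th2 is reported as global median + mad_k * MAD of the radii.
    """

    th1: float = 1.0
    baseline_window: int = 61
    width_max_lateral: int = 12
    height_min: float = 3.0
    area_min: float = 40.0
    mad_k: float = 3.0
    max_iter: int = 10
    span_pad: int = 2  # suppression widens each peak span by this many positions


def path_normals(path: AdventitiousPath, halfwin: int = 3) -> np.ndarray:
    """Unit left-normal per path position, (N, 2) float.

    The tangent is estimated over +/-``halfwin`` path steps; the left normal
    is the perpendicular pointing toward smaller columns (for a near-vertical
    root this is the horizontal scan direction toward the left).
    """
    pts = path.pixels.astype(float)
    n = len(pts)
    normals = np.zeros((n, 2))
    for i in range(n):
        a = pts[max(i - halfwin, 0)]
        b = pts[min(i + halfwin, n - 1)]
        t = b - a
        norm = np.hypot(*t)
        if norm == 0:  # single-pixel path: treat as vertical
            t = np.array([1.0, 0.0])
            norm = 1.0
        t /= norm
        nv = np.array([-t[1], t[0]])
        if nv[1] > 0 or (nv[1] == 0 and nv[0] > 0):
            nv = -nv
        normals[i] = nv
    return normals


def _scan_radius(
    grid: np.ndarray, p: np.ndarray, direction: np.ndarray, max_radius: int
) -> int:
    """Foreground run length from ``p`` (exclusive) along ``direction``."""
    rows, cols = grid.shape
    for k in range(1, max_radius + 1):
        r = int(round(p[0] + k * direction[0]))
        c = int(round(p[1] + k * direction[1]))
        if not (0 <= r < rows and 0 <= c < cols) or not grid[r, c]:
            return k - 1
    return max_radius


def side_radii(
    mask: BinaryMask | np.ndarray,
    path: AdventitiousPath,
    max_radius: int | None = None,
    th1: float = 1.0,
) -> RadiusProfile:
    """Left/right radii of the root mask along the path, 1-px accuracy.

    Raises :class:`PathOffMaskError` if any path pixel is background.
    """
    grid = mask.grid if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if max_radius is None:
        max_radius = max(grid.shape)
    pts = path.pixels
    if not grid[tuple(pts.T)].all():
        bad = pts[~grid[tuple(pts.T)]][0]
        raise PathOffMaskError(f"path off mask at {tuple(bad)}")
    normals = path_normals(path)
    n = len(pts)
    r_left = np.zeros(n, dtype=int)
    r_right = np.zeros(n, dtype=int)
    for i in range(n):
        p = pts[i].astype(float)
        r_left[i] = _scan_radius(grid, p, normals[i], max_radius)
        r_right[i] = _scan_radius(grid, p, -normals[i], max_radius)
    return RadiusProfile(r_left=r_left, r_right=r_right, th1=th1)


def _running_median(values: np.ndarray, window: int) -> np.ndarray:
    window = max(1, min(window, len(values)))
    if window % 2 == 0:
        window -= 1
    if window < 1:
        window = 1
    return ndimage.median_filter(values.astype(float), size=window, mode="nearest")


def _find_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start, end) inclusive index pairs."""
    runs = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for s, e in zip(idx[::2], idx[1::2]):
        runs.append((int(s), int(e - 1)))
    return runs


def _peak_spans(excess: np.ndarray, th1: float) -> list[tuple[int, int]]:
    """Maximal runs above the baseline that somewhere exceed Th1.

    A peak must rise above baseline + Th1 to exist, but its extent runs to
    the baseline crossings on both sides (width at base), so suppression
    also flattens the flanks.
    """
    return [
        (s, e)
        for s, e in _find_runs(excess > 0)
        if excess[s : e + 1].max() > th1
    ]


def detect_classify_peaks(
    profile: RadiusProfile, params: PeakParams | None = None
) -> RadiusProfile:
    """Detect radius-profile peaks above baseline + Th1 and classify them.

    A peak is an excursion above the running-median baseline whose maximum
    exceeds baseline + Th1; its span extends to the baseline crossings.
    Height, width and area are measured against the baseline; a peak is a
    *lateral* if it is narrow (width <= ``width_max_lateral``) and tall
    enough (height >= ``height_min``), a *nodule* if wide and with enough
    area, and discarded otherwise.
    """
    params = params or PeakParams()
    if len(profile) == 0:
        raise ValueError("empty profile")
    peaks: list[Peak] = []
    baselines = {}
    for side, radii in (("left", profile.r_left), ("right", profile.r_right)):
        radii = np.asarray(radii, float)
        baseline = _running_median(radii, params.baseline_window)
        baselines[side] = baseline
        excess = radii - baseline
        for s, e in _peak_spans(excess, params.th1):
            height = float(excess[s : e + 1].max())
            width = e - s + 1
            area = float(excess[s : e + 1].sum())
            if width <= params.width_max_lateral and height >= params.height_min:
                klass = "lateral"
            elif width > params.width_max_lateral and area >= params.area_min:
                klass = "nodule"
            else:
                continue  # sub-threshold bump
            peaks.append(Peak(side, s, e, height, width, area, klass))
    all_r = np.concatenate([profile.r_left, profile.r_right]).astype(float)
    mad = float(np.median(np.abs(all_r - np.median(all_r))))
    th2 = float(np.median(all_r) + params.mad_k * mad)
    th2 = max(th2, params.th1 + 1.0)  # Th1 < Th2 by construction
    return RadiusProfile(
        r_left=np.asarray(profile.r_left),
        r_right=np.asarray(profile.r_right),
        baseline_left=baselines["left"],
        baseline_right=baselines["right"],
        peaks=peaks,
        th1=params.th1,
        th2=th2,
    )


def suppress_peaks(
    profile: RadiusProfile, params: PeakParams | None = None
) -> RadiusProfile:
    """Iteratively flatten all peaks into the band baseline +/- Th1.

    Within each detected peak span the radii are replaced by a linear
    interpolation between the radii just outside the span, clamped to
    [baseline - Th1, baseline + Th1]; peaks are re-detected on the filtered
    radii and the step repeats until no peak remains.  The total area above
    baseline never increases between iterations.

    Raises :class:`NoConvergenceError` if peaks persist after ``max_iter``
    iterations.  The returned profile carries the *originally* detected peaks
    (the ones that were suppressed) and the filtered radii as floats.
    """
    params = params or PeakParams()
    work = RadiusProfile(
        r_left=np.asarray(profile.r_left, float).copy(),
        r_right=np.asarray(profile.r_right, float).copy(),
        th1=params.th1,
    )
    original_peaks = list(profile.peaks)
    for _ in range(params.max_iter):
        detected = detect_classify_peaks(work, params)
        # suppression must remove *every* excursion above baseline + Th1,
        # including sub-threshold-classified ones, to reach a fixed point
        spans: dict[str, list[tuple[int, int]]] = {"left": [], "right": []}
        for side, radii in (("left", work.r_left), ("right", work.r_right)):
            baseline = (
                detected.baseline_left if side == "left" else detected.baseline_right
            )
            n = len(radii)
            spans[side] = [
                (max(s - params.span_pad, 0), min(e + params.span_pad, n - 1))
                for s, e in _peak_spans(np.asarray(radii) - baseline, params.th1)
            ]
        if not spans["left"] and not spans["right"]:
            return RadiusProfile(
                r_left=work.r_left,
                r_right=work.r_right,
                baseline_left=detected.baseline_left,
                baseline_right=detected.baseline_right,
                peaks=original_peaks,
                th1=params.th1,
                th2=detected.th2,
            )
        for side in ("left", "right"):
            radii = work.r_left if side == "left" else work.r_right
            baseline = (
                detected.baseline_left if side == "left" else detected.baseline_right
            )
            n = len(radii)
            for s, e in spans[side]:
                lo = radii[s - 1] if s > 0 else baseline[s]
                hi = radii[e + 1] if e + 1 < n else baseline[e]
                span = np.linspace(lo, hi, e - s + 3)[1:-1]
                b = baseline[s : e + 1]
                radii[s : e + 1] = np.clip(span, b - params.th1, b + params.th1)
    raise NoConvergenceError(f"peaks persist after {params.max_iter} iterations")


def reconstruct_root(
    mask: BinaryMask | np.ndarray,
    path: AdventitiousPath,
    filtered: RadiusProfile,
) -> tuple[BinaryMask, np.ndarray]:
    """(adventitious-only mask, diameter profile d in px).

    The adventitious mask is the union over path positions of the
    cross-section segments of length r_left(i) + 1 + r_right(i) stamped
    perpendicular to the path with the filtered radii, intersected with the
    1-px dilation of the original mask so reconstruction never invents
    foreground beyond boundary rounding.  Stamp centers follow a short
    median smoothing of the path (window 11), which undoes the 1-2 px
    centerline displacement thinning introduces at junctions without
    altering the reported path or diameters.
    """
    grid = mask.grid if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    mm = mask.mm_per_px if isinstance(mask, BinaryMask) else 1.0
    normals = path_normals(path)
    out = np.zeros_like(grid, dtype=bool)
    rows, cols = grid.shape
    r_left = np.asarray(filtered.r_left, float)
    r_right = np.asarray(filtered.r_right, float)
    centers = path.pixels.astype(float)
    if len(centers) >= 11:
        centers = np.column_stack(
            [
                ndimage.median_filter(centers[:, 0], size=11, mode="nearest"),
                ndimage.median_filter(centers[:, 1], size=11, mode="nearest"),
            ]
        )
    for i, p in enumerate(centers):
        # fractional filtered radii are floored: stamping stays conservative
        for direction, radius in ((normals[i], r_left[i]), (-normals[i], r_right[i])):
            for k in range(int(radius) + 1):
                r = int(round(p[0] + k * direction[0]))
                c = int(round(p[1] + k * direction[1]))
                if 0 <= r < rows and 0 <= c < cols:
                    out[r, c] = True
    out &= dilation(grid, np.ones((3, 3), bool))
    diameter = r_left + r_right + 1.0
    polarity = mask.polarity if isinstance(mask, BinaryMask) else "root_bright"
    return BinaryMask(out, mm, polarity), diameter
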