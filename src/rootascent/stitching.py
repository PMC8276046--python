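"""Two-half rhizotron scan stitching.

A rhizotron is taller than the scanner bed, so each acquisition yields an
upper and a lower scan sharing a common horizontal band.  Scale-invariant
keypoints are detected on the luminance of both halves, matched, and a
homography mapping bottom-half coordinates into the top-half frame is
estimated by RANSAC; the halves are then warped onto a union canvas and
averaged in the overlap band.

Homographies are reported in the toolkit's (row, col) convention: a 3x3
matrix H such that H @ (row, col, 1)^T of a bottom-half pixel gives its
(row, col) position in the top-half frame (after dehomogenization).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import ProjectiveTransform, warp

from .errors import (
    DegenerateGeometryError,
    EmptyOverlapError,
    InsufficientKeypointsError,
)
from .segmentation import luminance

# permutation swapping (x, y) <-> (row, col) homogeneous conventions
_P = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])


def rc_to_xy_matrix(h_rc: np.ndarray) -> np.ndarray:
    return _P @ h_rc @ _P


def xy_to_rc_matrix(h_xy: np.ndarray) -> np.ndarray:
    return _P @ h_xy @ _P


@dataclass
class ImagePair:
    """Top and bottom scan halves with the nominal overlap band height."""

    top: np.ndarray
    bottom: np.ndarray
    nominal_overlap_px: int = 0

    def __post_init__(self) -> None:
        if self.top.shape[1] != self.bottom.shape[1]:
            raise ValueError("halves must have equal column counts")
        if self.nominal_overlap_px < 0:
            raise ValueError("nominal_overlap_px must be >= 0")
        if self.nominal_overlap_px >= min(self.top.shape[0], self.bottom.shape[0]):
            raise ValueError("nominal_overlap_px must be smaller than each half")


@dataclass
class Alignment:
    """Estimated homography (bottom -> top frame, (row, col) convention)."""

    homography: np.ndarray
    inlier_src: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    inlier_dst: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    mean_reproj_error_px: float = 0.0
    n_matches: int = 0

    @property
    def n_inliers(self) -> int:
        return len(self.inlier_src)

    def to_dict(self) -> dict:
        return {
            "homography_rc": np.asarray(self.homography).tolist(),
            "n_matches": int(self.n_matches),
            "n_inliers": int(self.n_inliers),
            "mean_reproj_error_px": float(self.mean_reproj_error_px),
        }


def _detect(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    det = SIFT()
    try:
        det.detect_and_extract(np.asarray(luminance(image), dtype=float))
    except RuntimeError as exc:  # skimage raises when no keypoints survive
        raise InsufficientKeypointsError(f"insufficient keypoints: {exc}") from exc
    return det.keypoints, det.descriptors


def estimate_alignment(
    pair: ImagePair,
    min_matches: int = 12,
    reproj_tol: float = 2.0,
    seed: int = 0,
    max_trials: int = 1000,
) -> Alignment:
    """Estimate the bottom->top homography by keypoint matching + RANSAC.

    Deterministic for a fixed ``seed``.  Raises
    :class:`InsufficientKeypointsError` below ``min_matches`` matches and
    :class:`DegenerateGeometryError` when the inliers do not constrain a
    homography.
    """
    kp_top, desc_top = _detect(pair.top)
    kp_bot, desc_bot = _detect(pair.bottom)
    matches = match_descriptors(desc_bot, desc_top, cross_check=True, max_ratio=0.9)
    if len(matches) < min_matches:
        raise InsufficientKeypointsError(
            f"insufficient keypoints: {len(matches)} matches < {min_matches}"
        )
    src_xy = kp_bot[matches[:, 0]][:, ::-1]  # bottom, (x, y)
    dst_xy = kp_top[matches[:, 1]][:, ::-1]  # top, (x, y)
    model, inliers = ransac(
        (src_xy, dst_xy),
        ProjectiveTransform,
        min_samples=4,
        residual_threshold=reproj_tol,
        max_trials=max_trials,
        rng=seed,
    )
    if model is None or inliers is None or inliers.sum() < 4:
        raise DegenerateGeometryError("degenerate geometry: RANSAC found no model")
    h_xy = model.params
    if not np.all(np.isfinite(h_xy)) or abs(np.linalg.det(h_xy)) < 1e-12:
        raise DegenerateGeometryError("degenerate geometry: singular homography")
    residuals = model.residuals(src_xy, dst_xy)
    mean_err = float(residuals[inliers].mean())
    h_rc = xy_to_rc_matrix(h_xy)
    h_rc = h_rc / h_rc[2, 2]
    return Alignment(
        homography=h_rc,
        inlier_src=src_xy[inliers][:, ::-1],
        inlier_dst=dst_xy[inliers][:, ::-1],
        mean_reproj_error_px=mean_err,
        n_matches=int(len(matches)),
    )


def apply_homography_rc(h_rc: np.ndarray, points_rc: np.ndarray) -> np.ndarray:
    """Map (N, 2) (row, col) points through an rc-convention homography."""
    pts = np.asarray(points_rc, float).reshape(-1, 2)
    hom = np.column_stack([pts, np.ones(len(pts))])
    mapped = hom @ np.asarray(h_rc).T
    return mapped[:, :2] / mapped[:, 2:3]


def merge_halves(pair: ImagePair, alignment: Alignment) -> np.ndarray:
    """Warp the bottom half into the top frame and blend on a union canvas.

    The canvas is the union bounding box of the top half and the warped
    bottom half; the overlap band is blended by per-pixel averaging.  Raises
    :class:`EmptyOverlapError` when the warped halves do not intersect.
    """
    top = np.asarray(pair.top)
    bottom = np.asarray(pair.bottom)
    h_xy = rc_to_xy_matrix(np.asarray(alignment.homography, float))
    tf = ProjectiveTransform(matrix=h_xy)

    bh, bw = bottom.shape[:2]
    th, tw = top.shape[:2]
    corners_xy = np.array(
        [[0, 0], [bw - 1, 0], [bw - 1, bh - 1], [0, bh - 1]], float
    )
    warped_xy = tf(corners_xy)
    all_x = np.concatenate([warped_xy[:, 0], [0, tw - 1]])
    all_y = np.concatenate([warped_xy[:, 1], [0, th - 1]])
    # snap near-integer bounds before rounding outward, so exact translations
    # produce exact canvas sizes
    x0, y0 = np.floor(np.round(all_x.min(), 6)), np.floor(np.round(all_y.min(), 6))
    x1, y1 = np.ceil(np.round(all_x.max(), 6)), np.ceil(np.round(all_y.max(), 6))
    out_w, out_h = int(x1 - x0) + 1, int(y1 - y0) + 1

    offset = np.array([[1, 0, -x0], [0, 1, -y0], [0, 0, 1.0]])
    m = offset @ h_xy
    inv = ProjectiveTransform(matrix=np.linalg.inv(m))

    def _warp_channel(ch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w = warp(
            np.ones_like(ch, dtype=float),
            inv,
            output_shape=(out_h, out_w),
            order=1,
            cval=0.0,
            preserve_range=True,
        )
        v = warp(
            ch.astype(float),
            inv,
            output_shape=(out_h, out_w),
            order=1,
            cval=0.0,
            preserve_range=True,
        )
        return v, w

    r_off, c_off = int(-y0), int(-x0)
    channels = 1 if top.ndim == 2 else top.shape[2]
    out = np.zeros((out_h, out_w, channels), dtype=float)
    top3 = top.reshape(th, tw, channels)
    bot3 = bottom.reshape(bh, bw, channels)

    top_weight = np.zeros((out_h, out_w))
    top_weight[r_off : r_off + th, c_off : c_off + tw] = 1.0
    bot_vals = np.zeros_like(out)
    bot_weight = None
    for ch in range(channels):
        v, w = _warp_channel(bot3[..., ch])
        bot_vals[..., ch] = v
        bot_weight = w
    overlap = (top_weight > 0.5) & (bot_weight > 0.5)
    if not overlap.any():
        raise EmptyOverlapError("empty overlap: warped halves do not intersect")

    weight_sum = top_weight + bot_weight
    for ch in range(channels):
        top_vals = np.zeros((out_h, out_w))
        top_vals[r_off : r_off + th, c_off : c_off + tw] = top3[..., ch]
        num = top_vals * top_weight + bot_vals[..., ch]
        with np.errstate(invalid="ignore"):
            out[..., ch] = np.where(weight_sum > 0, num / np.maximum(weight_sum, 1e-12), 0)
    out = out[..., 0] if channels == 1 else out
    if np.issubdtype(top.dtype, np.integer):
        info = np.iinfo(top.dtype)
        out = np.clip(np.round(out), info.min, info.max).astype(top.dtype)
    return out
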