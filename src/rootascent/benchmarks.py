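"""Seeded end-to-end accuracy benchmarks on synthetic ground truth.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stages and measures accuracy against the generator's truth.  The same
routines back the acceptance tests and the standalone acceptance script.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from skimage.morphology import dilation

from . import segmentation
from . import skeletonization as sk
from .ascending_path import extract_adventitious_paths
from .reconstruction import (
    detect_classify_peaks,
    reconstruct_root,
    side_radii,
    suppress_peaks,
)
from .stitching import apply_homography_rc, estimate_alignment
from .synth import (
    WELL_SEPARATED,
    LateralSpec,
    RootSpec,
    TrunkSpec,
    fixture_specs,
    render_root,
    split_for_stitching,
)
from .traits import compute_traits


def diameter_bench_specs(seed: int, n_roots: int = 10) -> list[RootSpec]:
    """Noiseless near-vertical roots with known width profiles.

    Mirrors the rhizotron geometry: adventitious roots run top to bottom
    with gentle curvature; half of them carry three 45-degree laterals.
    """
    radii = [2, 3, 4, 3, 2, 4, 3, 3, 2, 4]
    amps = [0, 0, 0, 6, 8, 5, 0, 7, 6, 0]
    tapers = [0, 0, 0, 0, 0, 0, 1, 0, 0, 1]
    specs = []
    for k in range(n_roots):
        rad, amp, taper = radii[k % 10], amps[k % 10], tapers[k % 10]
        col = 130
        if amp > 0:
            cps = [(20, col), (110, col + amp), (200, col - amp), (290, col + amp), (370, col)]
        else:
            cps = [(20, col), (370, col)]
        lats = (
            [
                LateralSpec(
                    s=s, side=("left" if j % 2 else "right"), angle_deg=45.0, length_px=35.0
                )
                for j, s in enumerate((0.25, 0.55, 0.8))
            ]
            if k % 2 == 1
            else []
        )
        specs.append(
            RootSpec(
                trunks=[
                    TrunkSpec(
                        control_points=cps,
                        radius_top=rad,
                        radius_tip=max(rad - taper, 1),
                        laterals=lats,
                    )
                ],
                seed=seed + k,
            )
        )
    return specs


def diameter_accuracy(seed: int = 1, n_roots: int = 10, branch_margin: float = 5.0) -> dict:
    """Local-diameter error of the reconstructed root vs the true width.

    For each noiseless synthetic root the full chain segmentation ->
    skeletonization -> Ascending Path -> side radii -> peak suppression is
    run and the filtered diameter profile d(i) = r_left + r_right + 1 is
    compared to the generator's width at the nearest truth-skeleton pixel.
    Excluded positions (where a 1-px-scale local width is undefined):
    farther than 1.5 px from the truth skeleton, within ``branch_margin`` px
    of a branch point, on the rounded end caps, or within 3 positions of a
    discrete width step.

    Returns max error, the fraction of positions within 1 px, and counts.
    """
    errors = []
    for spec in diameter_bench_specs(seed, n_roots):
        img, truth = render_root(spec)
        mask = segmentation.segment(img)
        graph = sk.classify_points(sk.skeletonize(mask))
        path = extract_adventitious_paths(graph)[0]
        profile = detect_classify_peaks(side_radii(mask, path))
        filtered = suppress_peaks(profile)
        d = filtered.diameter_px
        chain = truth.main_skeletons[0]
        w = truth.widths[0].astype(float)
        dist, idx = cKDTree(chain).query(path.pixels)
        rad_max = int(w.max()) // 2
        keep = (dist <= 1.5) & (idx > rad_max + 2) & (idx < len(chain) - 1 - (rad_max + 2))
        if len(truth.branch_points):
            bdist, _ = cKDTree(truth.branch_points).query(path.pixels)
            keep &= bdist > branch_margin
        steps = np.flatnonzero(np.diff(w) != 0)
        for s in steps:
            keep &= np.abs(idx - s) > 3
        errors.append(np.abs(d[keep] - w[idx[keep]]))
    err = np.concatenate(errors)
    return {
        "max_error_px": float(err.max()),
        "frac_within_1px": float((err <= 1.0).mean()),
        "n_positions": int(len(err)),
        "n_roots": n_roots,
    }


def stitch_bench_image(seed: int) -> np.ndarray:
    """A textured root scan for keypoint matching (keypoints need texture)."""
    spec = RootSpec(
        image_size=(320, 240),
        trunks=[
            TrunkSpec(
                control_points=[(16, 120), (90, 132), (180, 108), (300, 124)],
                radius_top=3,
                radius_tip=2,
                laterals=[
                    LateralSpec(s=0.3, side="left", angle_deg=45, length_px=35),
                    LateralSpec(s=0.6, side="right", angle_deg=50, length_px=40),
                ],
            )
        ],
        background_texture=12.0,
        noise_sd=3.0,
        seed=seed,
    )
    img, _ = render_root(spec)
    return img


def stitching_accuracy(
    seed: int = 1, n_pairs: int = 20, overlap_px: int = 60, warp_px: float = 1.5
) -> dict:
    """Mean inlier reprojection error over seeded synthetic split pairs.

    Each pair is a textured synthetic scan split in two overlapping halves,
    the bottom one resampled through a mild perspective warp; alignment is
    re-estimated and the RANSAC inlier residuals and the corner error
    against the true homography are recorded.
    """
    errs, corner_errs = [], []
    for k in range(n_pairs):
        img = stitch_bench_image(seed + 1000 + k)
        pair, h_true = split_for_stitching(img, overlap_px, warp_px=warp_px, seed=seed + k)
        alignment = estimate_alignment(pair, seed=seed + k)
        errs.append(alignment.mean_reproj_error_px)
        corners = np.array(
            [[0, 0], [0, pair.bottom.shape[1] - 1], [overlap_px, 0],
             [overlap_px, pair.bottom.shape[1] - 1]],
            float,
        )
        est = apply_homography_rc(alignment.homography, corners)
        true = apply_homography_rc(h_true, corners)
        corner_errs.append(float(np.linalg.norm(est - true, axis=1).max()))
    return {
        "mean_inlier_reproj_error_px": float(np.mean(errs)),
        "max_pair_error_px": float(np.max(errs)),
        "mean_corner_error_px": float(np.mean(corner_errs)),
        "n_pairs": n_pairs,
    }


def path_recovery(seed: int = 1) -> dict:
    """Ascending Path and reconstruction quality over the fixture suite.

    Reports the fraction of traced path pixels on the 1-px-dilated true main
    skeleton, whether LRN was exact on every well-separated-lateral spec,
    and the worst lateral-pixel leakage into the reconstructed mask.
    """
    specs = fixture_specs()
    on = tot = 0
    lrn_exact = True
    worst_leak = 0.0
    arl_errs, llrl_errs = [], []
    for name, spec in specs.items():
        img, truth = render_root(spec)
        mask = segmentation.segment(img)
        graph = sk.classify_points(sk.skeletonize(mask))
        paths = extract_adventitious_paths(graph)
        truth_skel = np.zeros_like(mask.grid)
        for chain in truth.main_skeletons:
            truth_skel[tuple(chain.T)] = True
        truth_dil = dilation(truth_skel, np.ones((3, 3), bool))
        lrn = 0
        llrl = 0.0
        arl = 0.0
        leak_px = 0
        for path in paths:
            on += int(truth_dil[tuple(path.pixels.T)].sum())
            tot += len(path)
            profile = detect_classify_peaks(side_radii(mask, path))
            filtered = suppress_peaks(profile)
            adv, d = reconstruct_root(mask, path, filtered)
            rec = compute_traits(graph, path, d, mask, profile.peaks)
            lrn += rec.lrn
            llrl = max(llrl, rec.llrl_mm)
            arl += rec.arl_mm
            leak_px += int((adv.grid & truth.lateral_pixels).sum())
        t = truth.traits
        if name in WELL_SEPARATED and lrn != t["lrn"]:
            lrn_exact = False
        if t["lateral_lengths_mm"]:
            worst_leak = max(worst_leak, leak_px / truth.lateral_pixels.sum())
            llrl_errs.append(abs(llrl - t["llrl_mm"]) / t["llrl_mm"])
        arl_errs.append(abs(arl - sum(t["arl_mm"])) / sum(t["arl_mm"]))
    return {
        "path_pixel_accuracy": on / tot,
        "lrn_exact_on_well_separated": lrn_exact,
        "max_lateral_leakage": worst_leak,
        "max_arl_rel_error": max(arl_errs),
        "max_llrl_rel_error": max(llrl_errs),
        "n_specs": len(specs),
    }
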