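"""Synthetic root imagery with exact ground truth.

No root-scan dataset accompanies the method, so every pipeline stage is
exercised on generated data: a dark background carrying a brighter branched
root object — one or more near-vertical main (adventitious) roots running
top to bottom, laterals branching off downward, optional nodule-like
ellipses — plus split scan pairs with a known homography and 3D
transmission stacks with a sand-like background (~0.8) containing
lower-transmission root voxels (0.2-0.4).

Widths are realized by stamping discs along the rasterized polyline, which
guarantees 8-connected masks and makes the horizontal width of a vertical
trunk exactly 2*radius + 1 px; anti-aliasing is off so noiseless masks are
exact.  All randomness is fixed by the spec's seed, and identical specs
render byte-identical images.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np
from scipy import interpolate
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.transform import ProjectiveTransform, warp

from .errors import OverlapTooSmallError, RootExitsCanvasError
from .stitching import ImagePair, xy_to_rc_matrix
from .traits import geodesic_length_px
from .types import BinaryMask


@dataclass
class LateralSpec:
    """One lateral root: branch position s in (0, 1) along the trunk, side
    ('left'/'right'), angle from vertical in degrees (pointing downward and
    outward), length and stamp radius in px."""

    s: float
    side: str = "right"
    angle_deg: float = 45.0
    length_px: float = 40.0
    radius_px: int = 1


@dataclass
class NoduleSpec:
    """Nodule-like ellipse centered on the trunk at position s, with
    (row, col) semi-axes in px."""

    s: float
    semi_axes: tuple[float, float] = (8.0, 8.0)


@dataclass
class TrunkSpec:
    """One main (adventitious) root: top-anchored descending control points
    and a linear radius taper from radius_top to radius_tip (true local
    width = 2*radius + 1)."""

    control_points: list[tuple[float, float]]
    radius_top: int = 3
    radius_tip: int = 3
    laterals: list[LateralSpec] = field(default_factory=list)
    nodules: list[NoduleSpec] = field(default_factory=list)


@dataclass
class RootSpec:
    image_size: tuple[int, int] = (400, 260)
    trunks: list[TrunkSpec] = field(default_factory=list)
    background_level: float = 20.0
    root_level: float = 200.0
    noise_sd: float = 0.0
    blur_sigma: float = 0.0
    background_texture: float = 0.0
    mm_per_px: float = 1.0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "RootSpec":
        trunks = [
            TrunkSpec(
                control_points=[tuple(p) for p in t["control_points"]],
                radius_top=t.get("radius_top", 3),
                radius_tip=t.get("radius_tip", 3),
                laterals=[LateralSpec(**l) for l in t.get("laterals", [])],
                nodules=[
                    NoduleSpec(s=nd["s"], semi_axes=tuple(nd["semi_axes"]))
                    for nd in t.get("nodules", [])
                ],
            )
            for t in d["trunks"]
        ]
        keys = {
            k: d[k]
            for k in (
                "background_level",
                "root_level",
                "noise_sd",
                "blur_sigma",
                "background_texture",
                "mm_per_px",
                "seed",
            )
            if k in d
        }
        return cls(image_size=tuple(d["image_size"]), trunks=trunks, **keys)

    @classmethod
    def from_json(cls, text: str) -> "RootSpec":
        return cls.from_dict(json.loads(text))


@dataclass
class GroundTruth:
    """Exact truth rasters and traits for one rendered scene."""

    mask: BinaryMask
    main_skeletons: list[np.ndarray]  # ordered (N, 2) chains, top -> bottom
    widths: list[np.ndarray]  # true local width per chain pixel
    lateral_chains: list[np.ndarray]  # ordered chains, trunk -> tip
    lateral_pixels: np.ndarray  # bool raster of lateral-only foreground
    nodule_pixels: np.ndarray  # bool raster of nodule-only foreground
    branch_points: np.ndarray  # (K, 2) trunk pixels where laterals attach
    traits: dict = field(default_factory=dict)


def _rasterize_polyline(points: np.ndarray) -> np.ndarray:
    """8-connected integer pixel chain along a float polyline.

    The curve is sampled every ~2 px and consecutive samples are joined by
    Bresenham lines, so the chain's geodesic length tracks the Euclidean
    curve length (within the usual <= 8% digitization excess) instead of
    accumulating axis-aligned staircase steps.
    """
    from skimage.draw import line as draw_line

    points = np.asarray(points, float)
    segs = np.diff(points, axis=0)
    lengths = np.hypot(segs[:, 0], segs[:, 1])
    total = lengths.sum()
    n = max(int(np.ceil(total / 2.0)) + 1, 2)
    t = np.linspace(0, 1, n)
    cum = np.concatenate([[0], np.cumsum(lengths)]) / max(total, 1e-9)
    rows = np.interp(t, cum, points[:, 0])
    cols = np.interp(t, cum, points[:, 1])
    anchors = np.round(np.column_stack([rows, cols])).astype(int)
    keep = np.ones(len(anchors), bool)
    keep[1:] = np.abs(np.diff(anchors, axis=0)).max(axis=1) > 0
    anchors = anchors[keep]
    chain = [anchors[0]]
    for a, b in zip(anchors[:-1], anchors[1:]):
        rr, cc = draw_line(a[0], a[1], b[0], b[1])
        chain.extend(np.column_stack([rr, cc])[1:])
    return np.array(chain, dtype=int)


def _trunk_curve(trunk: TrunkSpec) -> np.ndarray:
    pts = np.asarray(trunk.control_points, float)
    if len(pts) < 2:
        raise ValueError("trunk needs at least 2 control points")
    if len(pts) == 2:
        return pts
    # arclength-parameterized smooth curve through the control points
    d = np.hypot(*np.diff(pts, axis=0).T)
    t = np.concatenate([[0], np.cumsum(d)])
    t /= t[-1]
    k = min(3, len(pts) - 1)
    spl_r = interpolate.make_interp_spline(t, pts[:, 0], k=k)
    spl_c = interpolate.make_interp_spline(t, pts[:, 1], k=k)
    tt = np.linspace(0, 1, max(int(t[-1] * 4), 200))
    return np.column_stack([spl_r(tt), spl_c(tt)])


def _stamp_chain(mask: np.ndarray, chain: np.ndarray, radii: np.ndarray) -> None:
    for (r, c), rad in zip(chain, radii):
        rr, cc = draw_disk((r, c), float(rad) + 0.5, shape=mask.shape)
        mask[rr, cc] = True


def _check_bounds(chain: np.ndarray, radii: np.ndarray, shape: tuple[int, int]) -> None:
    rad = np.asarray(radii)
    if (
        (chain[:, 0] - rad < 0).any()
        or (chain[:, 0] + rad >= shape[0]).any()
        or (chain[:, 1] - rad < 0).any()
        or (chain[:, 1] + rad >= shape[1]).any()
    ):
        raise RootExitsCanvasError("root exits canvas")


def render_root(spec: RootSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a grayscale uint8 root image and its exact ground truth."""
    shape = tuple(spec.image_size)
    rng = np.random.default_rng(spec.seed)
    trunk_mask = np.zeros(shape, bool)
    lateral_mask = np.zeros(shape, bool)
    nodule_mask = np.zeros(shape, bool)

    main_skeletons, widths_list, lateral_chains, branch_pts = [], [], [], []
    lateral_truth_lengths: list[float] = []
    for trunk in spec.trunks:
        chain = _rasterize_polyline(_trunk_curve(trunk))
        arclen = np.concatenate(
            [[0], np.cumsum(np.hypot(*np.diff(chain, axis=0).T.astype(float)))]
        )
        frac = arclen / max(arclen[-1], 1e-9)
        radii = np.round(
            trunk.radius_top + (trunk.radius_tip - trunk.radius_top) * frac
        ).astype(int)
        _check_bounds(chain, radii, shape)
        _stamp_chain(trunk_mask, chain, radii)
        main_skeletons.append(chain)
        widths_list.append(2 * radii + 1)

        for lat in trunk.laterals:
            i = int(round(lat.s * (len(chain) - 1)))
            origin = chain[i].astype(float)
            branch_pts.append(chain[i])
            # insertion angle is relative to the local trunk tangent, as on
            # real roots; positive rotation swings the downward tangent
            # toward the requested side
            j0, j1 = max(i - 4, 0), min(i + 4, len(chain) - 1)
            tangent = (chain[j1] - chain[j0]).astype(float)
            tangent /= max(np.hypot(*tangent), 1e-9)
            a = np.deg2rad(lat.angle_deg)
            sgn = -1.0 if lat.side == "left" else 1.0
            direction = np.array(
                [
                    tangent[0] * np.cos(a) - sgn * tangent[1] * np.sin(a),
                    sgn * tangent[0] * np.sin(a) + tangent[1] * np.cos(a),
                ]
            )
            if lat.side == "left" and direction[1] > 0:
                direction[1] = -direction[1]
            if lat.side == "right" and direction[1] < 0:
                direction[1] = -direction[1]
            end = origin + direction * lat.length_px
            lchain = _rasterize_polyline(np.array([origin, end]))
            lradii = np.full(len(lchain), int(lat.radius_px))
            _check_bounds(lchain, lradii, shape)
            _stamp_chain(lateral_mask, lchain, lradii)
            lateral_chains.append(lchain)
            lateral_truth_lengths.append(geodesic_length_px(lchain) * spec.mm_per_px)

        for nod in trunk.nodules:
            i = int(round(nod.s * (len(chain) - 1)))
            r, c = chain[i]
            rr, cc = draw_ellipse(
                r, c, nod.semi_axes[0], nod.semi_axes[1], shape=shape
            )
            nodule_mask[rr, cc] = True

    mask = trunk_mask | lateral_mask | nodule_mask
    lateral_only = lateral_mask & ~trunk_mask
    nodule_only = nodule_mask & ~trunk_mask & ~lateral_mask

    img = np.full(shape, spec.background_level, float)
    if spec.background_texture > 0:
        tex = gaussian_filter(rng.normal(0.0, 1.0, shape), sigma=4.0)
        tex *= spec.background_texture / max(tex.std(), 1e-9)
        img += tex
    img[mask] = spec.root_level
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    arl = [geodesic_length_px(ch) * spec.mm_per_px for ch in main_skeletons]
    traits = {
        "arn": len(spec.trunks),
        "arl_mm": arl,
        "lrn": len(lateral_chains),
        "lateral_lengths_mm": lateral_truth_lengths,
        "llrl_mm": max(lateral_truth_lengths) if lateral_truth_lengths else 0.0,
        "tnn": sum(len(t.nodules) for t in spec.trunks),
        "projected_area_mm2": float(mask.sum()) * spec.mm_per_px**2,
    }
    truth = GroundTruth(
        mask=BinaryMask(mask, spec.mm_per_px),
        main_skeletons=main_skeletons,
        widths=widths_list,
        lateral_chains=lateral_chains,
        lateral_pixels=lateral_only,
        nodule_pixels=nodule_only,
        branch_points=(
            np.array(branch_pts) if branch_pts else np.empty((0, 2), int)
        ),
        traits=traits,
    )
    return img, truth


def split_for_stitching(
    image: np.ndarray,
    overlap_px: int,
    warp_px: float = 0.0,
    seed: int = 0,
) -> tuple[ImagePair, np.ndarray]:
    """Split an image into two overlapping halves with a known homography.

    The bottom half is optionally resampled through a small perspective
    transform whose corner displacements are uniform in [-warp_px, warp_px].
    Returns the pair and the true homography (bottom -> top frame, (row, col)
    convention, matching :class:`Alignment`).
    """
    if overlap_px < 16:
        raise OverlapTooSmallError("overlap too small: need at least 16 px")
    image = np.asarray(image)
    rows, cols = image.shape[:2]
    if overlap_px >= rows:
        raise OverlapTooSmallError("overlap too small relative to image height")
    h_top = (rows + overlap_px) // 2
    off = h_top - overlap_px
    h_bot = rows - off
    top = image[:h_top].copy()

    t_off = np.array([[1.0, 0, 0], [0, 1.0, off], [0, 0, 1.0]])  # xy convention
    if warp_px > 0:
        rng = np.random.default_rng(seed)
        src = np.array([[0, 0], [cols - 1, 0], [cols - 1, h_bot - 1], [0, h_bot - 1]], float)
        dst = src + rng.uniform(-warp_px, warp_px, src.shape)
        w = ProjectiveTransform.from_estimate(src, dst)
        if not w:
            raise RuntimeError("could not build perturbation transform")
        h_xy = t_off @ w.params
        bottom = warp(
            image.astype(float),
            ProjectiveTransform(matrix=h_xy),
            output_shape=(h_bot,) + image.shape[1:],
            order=1,
            mode="edge",
            preserve_range=True,
        )
        bottom = np.clip(np.round(bottom), 0, 255).astype(image.dtype)
    else:
        h_xy = t_off
        bottom = image[off:].copy()
    h_rc = xy_to_rc_matrix(h_xy)
    return ImagePair(top, bottom, overlap_px), h_rc / h_rc[2, 2]


@dataclass
class TomoSpec:
    """A sand-filled cylindrical sample holder with root tubes inside.

    Transmission values: open beam outside the holder = 1.0, sand ~0.8, root
    voxels uniform in [0.2, 0.4] pre-noise — the contrast regime of neutron
    radiographs of roots in sand.
    """

    shape: tuple[int, int, int] = (80, 96, 96)
    sample_radius: float = 40.0
    sand_level: float = 0.8
    root_trans: tuple[float, float] = (0.2, 0.4)
    roots: list[dict] = field(
        default_factory=lambda: [{"radius": 4.0, "wobble": 6.0}]
    )
    noise_sd: float = 0.0
    voxel_edge_mm: float = 0.1
    seed: int = 0


def render_tomo_stack(spec: TomoSpec):
    """Render a transmission stack and the exact root voxel set.

    Returns ``(TomoStack, truth_root_voxels: bool array)``.
    """
    from .tomo import TomoStack

    ns, nr, nc = spec.shape
    rng = np.random.default_rng(spec.seed)
    rr, cc = np.mgrid[0:nr, 0:nc]
    cr, ccen = (nr - 1) / 2, (nc - 1) / 2
    inside = (rr - cr) ** 2 + (cc - ccen) ** 2 <= spec.sample_radius**2

    vol = np.ones(spec.shape, float)
    vol[:, inside] = spec.sand_level
    root = np.zeros(spec.shape, bool)
    for tube in spec.roots:
        radius = float(tube.get("radius", 4.0))
        wobble = float(tube.get("wobble", 6.0))
        phase = rng.uniform(0, 2 * np.pi)
        z = np.arange(ns)
        path_r = cr + wobble * np.sin(2 * np.pi * z / ns + phase)
        path_c = ccen + wobble * np.cos(2 * np.pi * z / ns + phase)
        for k in range(ns):
            d2 = (rr - path_r[k]) ** 2 + (cc - path_c[k]) ** 2
            root[k] |= (d2 <= radius**2) & inside
    lo, hi = spec.root_trans
    vol[root] = rng.uniform(lo, hi, int(root.sum()))
    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, spec.shape)
    return TomoStack(vol, voxel_edge_mm=spec.voxel_edge_mm), root


def render_radiograph(
    shape: tuple[int, int] = (120, 160),
    ob_level: float = 200.0,
    sand_band: tuple[int, int] = (40, 120),
    sand_trans: float = 0.8,
    root_cols: tuple[int, int] = (70, 90),
    root_trans: float = 0.3,
    n_spikes: int = 0,
    noise_sd: float = 0.0,
    n_open_beam: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Synthetic neutron radiograph in raw counts plus open-beam frames.

    Columns in ``sand_band`` hold sand at ``sand_trans``; within it,
    ``root_cols`` hold a root at ``root_trans``; everything else is open
    beam.  ``n_spikes`` isolated max-value pixels emulate gamma hits.
    Returns ``(frame, open_beam_frames, truth_transmission)``.
    """
    rng = np.random.default_rng(seed)
    trans = np.ones(shape, float)
    trans[:, sand_band[0] : sand_band[1]] = sand_trans
    trans[:, root_cols[0] : root_cols[1]] = root_trans
    frame = ob_level * trans
    if noise_sd > 0:
        frame = frame + rng.normal(0.0, noise_sd, shape)
    if n_spikes > 0:
        idx = rng.choice(frame.size, size=n_spikes, replace=False)
        frame.ravel()[idx] = frame.max() + 10 * 50.0
    obs = [
        np.full(shape, ob_level)
        + (rng.normal(0.0, noise_sd, shape) if noise_sd > 0 else 0.0)
        for _ in range(n_open_beam)
    ]
    return frame, obs, trans


def fixture_specs() -> dict[str, RootSpec]:
    """The named 12-spec fixture suite shipped with the package."""
    text = resources.files("rootascent.fixtures").joinpath("root_specs.json").read_text()
    data = json.loads(text)
    return {name: RootSpec.from_dict(d) for name, d in data.items()}


#: fixture names whose laterals are mutually well separated (LRN is exact there)
WELL_SEPARATED = (
    "straight_five_laterals",
    "curved_laterals",
    "long_laterals",
    "tapered_laterals",
)
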