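"""One-command orchestration of the 2D root-phenotyping pipeline.

Runs (optionally) stitch, then segment -> skeletonize/classify -> Ascending
Path -> reconstruction -> traits, writing a trait CSV, per-stage rasters, a
QC overlay (path in red, residual laterals in green) and a JSON run log.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from . import segmentation
from . import skeletonization as sk
from .ascending_path import extract_adventitious_paths
from .reconstruction import (
    PeakParams,
    detect_classify_peaks,
    reconstruct_root,
    side_radii,
    suppress_peaks,
)
from .stitching import ImagePair, estimate_alignment, merge_halves
from .traits import compute_traits
from .types import ENDPOINT, JUNCTION

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the 2D pipeline; JSON round-trip stable."""

    mm_per_px: float = 1.0
    polarity: str = "auto"
    min_object_px: int = 20
    lookahead: int = 15
    min_component_px: int = 20
    nominal_overlap_px: int = 100
    peak_params: PeakParams = field(default_factory=PeakParams)
    apical_k: int = 20
    pixel_count: bool = False
    count_nodules: bool = True
    seed: int = 0
    keep_intermediates: bool = True

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be > 0")
        if self.polarity not in ("auto", "bright", "dark"):
            raise ValueError(f"invalid polarity {self.polarity!r}")
        for name in ("min_object_px", "lookahead", "min_component_px", "apical_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if isinstance(self.peak_params, dict):
            self.peak_params = PeakParams(**self.peak_params)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


def run_pipeline(
    config: PipelineConfig, inputs: list[str | Path], outdir: str | Path
) -> pd.DataFrame:
    """Execute the pipeline on one image (or a top/bottom pair) and write
    traits.csv, per-stage rasters, an overlay PNG and run.json to ``outdir``.

    Returns the trait table (one row per adventitious root).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: dict = {
        "version": __version__,
        "inputs": [str(p) for p in inputs],
        "config": json.loads(config.to_json()),
        "stages": [],
    }
    if len(inputs) not in (1, 2):
        raise ValueError("expected one image or a top/bottom pair")
    images = [iio.imread(p) for p in inputs]

    if len(images) == 2:
        pair = ImagePair(images[0], images[1], config.nominal_overlap_px)
        alignment = estimate_alignment(pair, seed=config.seed)
        merged = merge_halves(pair, alignment)
        run_log["stages"].append({"stage": "stitch", **alignment.to_dict()})
        if config.keep_intermediates:
            iio.imwrite(outdir / "merged.png", _to_u8(merged))
    else:
        merged = images[0]

    mask = segmentation.segment(
        merged,
        min_object_px=config.min_object_px,
        polarity=config.polarity,
        mm_per_px=config.mm_per_px,
    )
    run_log["stages"].append(
        {"stage": "segment", "foreground_px": int(mask.grid.sum()), "polarity": mask.polarity}
    )
    skel = sk.skeletonize(mask)
    graph = sk.classify_points(skel, mm_per_px=config.mm_per_px)
    run_log["stages"].append(
        {
            "stage": "skeleton",
            "skeleton_px": int(skel.sum()),
            "components": graph.n_components,
            "endpoints": int((graph.classes == ENDPOINT).sum()),
            "junctions": int((graph.classes == JUNCTION).sum()),
        }
    )
    paths = extract_adventitious_paths(
        graph, lookahead=config.lookahead, min_component_px=config.min_component_px
    )
    run_log["stages"].append({"stage": "trace", "n_paths": len(paths)})

    rows = []
    overlay = np.stack([_to_u8(merged if merged.ndim == 2 else merged[..., 0])] * 3, axis=-1)
    for i, path in enumerate(paths):
        profile = detect_classify_peaks(side_radii(mask, path), config.peak_params)
        filtered = suppress_peaks(profile, config.peak_params)
        adv, diameter = reconstruct_root(mask, path, filtered)
        record = compute_traits(
            graph,
            path,
            diameter,
            mask,
            profile.peaks,
            apical_k=config.apical_k,
            pixel_count=config.pixel_count,
            count_nodules=config.count_nodules,
        )
        row = asdict(record)
        row["root_id"] = i + 1
        row["n_peaks"] = len(profile.peaks)
        del row["lateral_lengths_mm"]
        del row["arn"]
        rows.append(row)
        if config.keep_intermediates:
            iio.imwrite(outdir / f"adventitious_{i + 1}.png", _mask_u8(adv.grid))
        residual = (graph.labels == path.component_id) & skel
        overlay[residual] = (0, 200, 0)
        overlay[tuple(path.pixels.T)] = (230, 30, 30)
    table = pd.DataFrame(rows)
    table.insert(0, "arn", len(paths))
    table = table.loc[:, ~table.columns.duplicated()]

    if config.keep_intermediates:
        iio.imwrite(outdir / "mask.png", _mask_u8(mask.grid))
        iio.imwrite(outdir / "skeleton.png", _mask_u8(skel))
        iio.imwrite(outdir / "overlay.png", overlay)
    table.to_csv(outdir / "traits.csv", index=False)
    run_log["stages"].append({"stage": "traits", "n_roots": len(paths)})
    (outdir / "run.json").write_text(json.dumps(run_log, indent=1))
    return table


def _to_u8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.dtype == np.uint8:
        return image
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        return np.zeros(image.shape, np.uint8)
    return np.round((image - lo) / (hi - lo) * 255).astype(np.uint8)


def _mask_u8(mask: np.ndarray) -> np.ndarray:
    return (np.asarray(mask, bool) * np.uint8(255))
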