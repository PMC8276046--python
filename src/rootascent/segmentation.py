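"""Root/background segmentation by automatic histogram thresholding.

Rhizotron scans show roots as a bright branched object on a dark substrate,
so a single global threshold on the (assumed bimodal) gray-level histogram
separates the two classes.  Otsu's criterion — maximize the between-class
variance over all candidate thresholds — picks that threshold automatically.
"""
from __future__ import annotations

import logging

import numpy as np
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .errors import DegenerateHistogramError, EmptyForegroundError
from .types import BinaryMask

log = logging.getLogger(__name__)


def luminance(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) raster to a single luminance channel.

    Grayscale input is returned unchanged.  RGB input is converted with the
    standard Rec. 601 weights and rescaled to the input's value range.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        gray = rgb2gray(image[..., :3])  # float in [0, 1]
        if np.issubdtype(image.dtype, np.integer):
            scale = float(np.iinfo(image.dtype).max)
            return np.round(gray * scale).astype(image.dtype)
        return gray
    raise ValueError(f"expected 2D or RGB raster, got shape {image.shape}")


def otsu_threshold(image: np.ndarray) -> int | float:
    """Return the threshold maximizing between-class variance of the histogram.

    For integer images in [0, 255] the returned value is an integer ``t`` and
    the foreground convention is ``image > t``.  Ties are broken toward the
    smallest maximizing threshold.

    Raises
    ------
    DegenerateHistogramError
        If the image is constant (fewer than 2 distinct gray levels).
    """
    image = luminance(np.asarray(image))
    if image.size == 0 or image.min() == image.max():
        raise DegenerateHistogramError(
            "degenerate histogram: image has fewer than 2 distinct gray levels"
        )
    if np.issubdtype(image.dtype, np.integer) and image.min() >= 0 and image.max() <= 255:
        counts = np.bincount(image.ravel().astype(np.intp), minlength=256)
        lo = int(np.flatnonzero(counts)[0])
        hi = int(np.flatnonzero(counts)[-1])
        t = threshold_otsu(hist=(counts[lo : hi + 1], np.arange(lo, hi + 1)))
        return int(t)
    return float(threshold_otsu(image))


def binarize_clean(
    image: np.ndarray,
    threshold: float,
    min_object_px: int = 20,
    polarity: str = "auto",
    mm_per_px: float = 1.0,
) -> BinaryMask:
    """Binarize at ``threshold`` and drop connected components below a size.

    Parameters
    ----------
    threshold : scalar within the image value range; pixels strictly above it
        form the bright class.
    min_object_px : components (8-connectivity) smaller than this are removed;
        0 leaves the thresholded mask untouched.  Default 20 px, sized for
        scanner debris at 300 dpi.
    polarity : "auto" picks the brighter class as roots (roots are white on
        rhizotron scans); "bright"/"dark" force the choice for inverted
        setups.
    """
    image = luminance(np.asarray(image))
    bright = image > threshold
    if polarity not in ("auto", "bright", "dark"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if polarity == "dark":
        fg = ~bright
        pol = "root_dark"
    else:
        fg = bright
        pol = "root_bright"
    if not fg.any():
        raise EmptyForegroundError("empty foreground: no pixel passes the threshold")
    if fg.all():
        log.warning("empty background: every pixel passed the threshold")
    if min_object_px > 0:
        # components strictly smaller than min_object_px are removed
        fg = remove_small_objects(fg, max_size=min_object_px - 1, connectivity=2)
        if not fg.any():
            raise EmptyForegroundError(
                "empty foreground: all components below min_object_px"
            )
    return BinaryMask(grid=fg, mm_per_px=mm_per_px, polarity=pol)


def segment(
    image: np.ndarray,
    min_object_px: int = 20,
    polarity: str = "auto",
    mm_per_px: float = 1.0,
) -> BinaryMask:
    """Otsu threshold followed by :func:`binarize_clean` (convenience)."""
    t = otsu_threshold(image)
    return binarize_clean(
        image, t, min_object_px=min_object_px, polarity=polarity, mm_per_px=mm_per_px
    )
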