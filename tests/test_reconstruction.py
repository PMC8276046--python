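import numpy as np
import pytest
from skimage.morphology import dilation

from rootascent.errors import PathOffMaskError
from rootascent.reconstruction import (
    PeakParams,
    detect_classify_peaks,
    reconstruct_root,
    side_radii,
    suppress_peaks,
)
from rootascent.types import AdventitiousPath, BinaryMask, RadiusProfile
from rootascent.benchmarks import diameter_accuracy


def test_symmetric_band_radii(vertical_band):
    mask, path = vertical_band
    prof = side_radii(mask, AdventitiousPath(path))
    assert (prof.r_left == 3).all() and (prof.r_right == 3).all()
    assert (prof.diameter_px == 7).all()


def test_boundary_pixel_has_zero_outer_radius():
    mask = np.zeros((20, 20), bool)
    mask[5:15, 5:10] = True  # band cols 5..9
    path = AdventitiousPath(np.array([(r, 5) for r in range(14, 4, -1)]))
    prof = side_radii(mask, path)
    assert (prof.r_left == 0).all()  # path on the left edge
    assert (prof.r_right == 4).all()


def test_path_off_mask_raises(vertical_band):
    mask, path = vertical_band
    bad = path.copy()
    bad[3] = (0, 0)
    with pytest.raises(PathOffMaskError):
        side_radii(mask, AdventitiousPath(bad))


def _profile(r_left, r_right):
    return RadiusProfile(np.asarray(r_left), np.asarray(r_right))


def test_constant_profile_has_no_peaks_and_is_fixed_point():
    prof = _profile(np.full(101, 3), np.full(101, 3))
    det = detect_classify_peaks(prof)
    assert det.peaks == []
    filt = suppress_peaks(det)
    assert (filt.r_left == 3).all() and (filt.r_right == 3).all()


def test_lateral_peak_detected_and_centered():
    r = np.full(101, 3)
    r[48:52] = 8  # narrow tall excursion at ~50
    det = detect_classify_peaks(_profile(np.full(101, 3), r))
    laterals = [p for p in det.peaks if p.klass == "lateral"]
    assert len(laterals) == 1
    p = laterals[0]
    assert p.side == "right"
    assert abs((p.start + p.end) / 2 - 50) <= 2
    assert p.height >= 3


def test_wide_shallow_nodule_peak():
    r = np.full(121, 3.0)
    r[40:65] = 6.0  # width 25 > 12, area 75 > 40
    det = detect_classify_peaks(_profile(r, np.full(121, 3.0)))
    assert [p.klass for p in det.peaks] == ["nodule"]


def test_subthreshold_bump_discarded():
    r = np.full(101, 3)
    r[50] = 4  # height 1 == Th1, never exceeds it
    det = detect_classify_peaks(_profile(r, np.full(101, 3)))
    assert det.peaks == []


def test_rectangular_peak_clamped_into_band():
    r = np.full(101, 3.0)
    r[40:48] = 9.0  # height 6 over baseline 3
    det = detect_classify_peaks(_profile(r, np.full(101, 3.0)))
    filt = suppress_peaks(det)
    assert (filt.r_left[40:48] >= 2).all() and (filt.r_left[40:48] <= 4).all()
    assert detect_classify_peaks(filt).peaks == []


def test_overlapping_peaks_converge():
    r = np.full(151, 4.0)
    r[60:75] = 9.0
    r[70:85] = 11.0
    det = detect_classify_peaks(_profile(r, np.full(151, 4.0)))
    filt = suppress_peaks(det)
    assert detect_classify_peaks(filt).peaks == []


def test_suppression_never_increases_area_above_baseline():
    rng = np.random.default_rng(0)
    r = np.full(200, 5.0) + rng.integers(0, 2, 200)
    r[30:40] += 6
    r[100:130] += 4
    prof = detect_classify_peaks(_profile(r, np.full(200, 5.0)))
    before = np.clip(np.asarray(prof.r_left, float) - prof.baseline_left, 0, None).sum()
    filt = suppress_peaks(prof)
    refd = detect_classify_peaks(filt)
    after = np.clip(np.asarray(refd.r_left, float) - refd.baseline_left, 0, None).sum()
    assert after <= before + 1e-9


def test_band_reconstruction_is_exact(vertical_band):
    mask, path_px = vertical_band
    path = AdventitiousPath(path_px)
    prof = detect_classify_peaks(side_radii(mask, path))
    filt = suppress_peaks(prof)
    adv, d = reconstruct_root(BinaryMask(mask), path, filt)
    assert (d == 7).all()
    assert np.array_equal(adv.grid, mask)


def test_reconstruction_contract_invariants(suite):
    from rootascent.segmentation import segment
    from rootascent.skeletonization import classify_points, skeletonize
    from rootascent.ascending_path import extract_adventitious_paths

    img, truth = suite["straight_five_laterals"]
    mask = segment(img)
    graph = classify_points(skeletonize(mask))
    path = extract_adventitious_paths(graph)[0]
    prof = detect_classify_peaks(side_radii(mask, path))
    filt = suppress_peaks(prof)
    adv, d = reconstruct_root(mask, path, filt)
    assert len(d) == len(path) and (d >= 1).all()
    assert not (adv.grid & ~dilation(mask.grid, np.ones((3, 3), bool))).any()
    # reconstructed root carries almost no lateral pixels
    leak = (adv.grid & truth.lateral_pixels).sum() / truth.lateral_pixels.sum()
    assert leak <= 0.02


def test_root_without_laterals_reconstructs_to_original(suite):
    from rootascent.segmentation import segment
    from rootascent.skeletonization import classify_points, skeletonize
    from rootascent.ascending_path import extract_adventitious_paths

    img, _ = suite["straight_bare"]
    mask = segment(img)
    graph = classify_points(skeletonize(mask))
    path = extract_adventitious_paths(graph)[0]
    filt = suppress_peaks(detect_classify_peaks(side_radii(mask, path)))
    adv, _ = reconstruct_root(mask, path, filt)
    # equal within a 1-px boundary band
    missed = mask.grid & ~dilation(adv.grid, np.ones((3, 3), bool))
    extra = adv.grid & ~dilation(mask.grid, np.ones((3, 3), bool))
    # end caps beyond the skeleton's reach are the only tolerated misses
    assert extra.sum() == 0
    assert missed.sum() <= 40


def test_diameter_tracks_true_width_within_one_px():
    report = diameter_accuracy(seed=11, n_roots=4)
    assert report["frac_within_1px"] >= 0.95
    assert report["max_error_px"] <= 1.0


def test_th1_lower_than_th2():
    prof = detect_classify_peaks(_profile(np.full(50, 3), np.full(50, 3)))
    assert prof.th1 < prof.th2
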