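import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from rootascent.errors import NotASkeletonError
from rootascent.skeletonization import (
    NEIGHBOR_OFFSETS,
    change_count,
    change_count_map,
    classify_points,
    count_components_and_holes,
    skeletonize,
)
from rootascent.types import ENDPOINT, ISOLATED, JUNCTION, NORMAL


def run_count(neighbors) -> int:
    """Independent oracle: maximal cyclic runs of active neighbors, counted
    by their inactive->active rises (the all-active ring has no delimited
    run and counts 0, matching zero transitions)."""
    n = [bool(v) for v in neighbors]
    return sum(1 for i in range(8) if n[i] and not n[i - 1])


@pytest.mark.parametrize("config", range(256))
def test_change_count_matches_run_count_oracle(config):
    neighbors = [(config >> i) & 1 for i in range(8)]
    c = change_count(neighbors)
    assert c % 2 == 0 and 0 <= c <= 8
    assert c == 2 * run_count(neighbors)


def test_single_active_neighbor_gives_c2():
    assert change_count([0, 1, 0, 0, 0, 0, 0, 0]) == 2


def test_no_active_neighbors_gives_c0():
    assert change_count([0] * 8) == 0


def _patch(centers):
    """5x5 raster with the given active pixels."""
    m = np.zeros((5, 5), bool)
    for r, c in centers:
        m[r, c] = True
    return m


def test_point_classification_cases():
    # endpoint: one active neighbor
    m = _patch([(2, 2), (2, 3)])
    g = classify_points(m)
    assert g.classes[2, 2] == ENDPOINT
    # interior of a straight line: two opposite neighbors, C = 4
    m = _patch([(2, 1), (2, 2), (2, 3)])
    g = classify_points(m)
    assert g.classes[2, 2] == NORMAL and g.change_count[2, 2] == 4
    # T-junction: C = 6; X-cross: C = 8
    m = _patch([(2, 2), (1, 2), (2, 1), (2, 3)])
    g = classify_points(m)
    assert g.classes[2, 2] == JUNCTION and g.change_count[2, 2] == 6
    m = _patch([(2, 2), (1, 2), (3, 2), (2, 1), (2, 3)])
    g = classify_points(m)
    assert g.classes[2, 2] == JUNCTION and g.change_count[2, 2] == 8
    # isolated pixel
    g = classify_points(_patch([(2, 2)]))
    assert g.classes[2, 2] == ISOLATED


def test_thin_line_is_unchanged():
    m = np.zeros((30, 9), bool)
    m[2:28, 4] = True
    assert np.array_equal(skeletonize(m), m)


def test_rectangle_skeleton_is_central_column():
    m = np.zeros((61, 15), bool)
    m[5:56, 5:10] = True  # 51 x 5 vertical rectangle, center col 7
    s = skeletonize(m)
    px = np.argwhere(s)
    assert len(px) >= 47
    assert (np.abs(px[:, 1] - 7) <= 1).all()


@pytest.mark.parametrize("seed", range(12))
def test_topology_preserved_on_random_masks(seed):
    rng = np.random.default_rng(seed)
    m = gaussian_filter(rng.normal(size=(64, 64)), 3) > 0.04
    s = skeletonize(m)
    assert (s <= m).all()  # skeleton is a subset of the mask
    assert count_components_and_holes(s) == count_components_and_holes(m)


def test_ring_skeleton_has_no_endpoints():
    rr, cc = np.mgrid[0:41, 0:41]
    d2 = (rr - 20) ** 2 + (cc - 20) ** 2
    ring = (d2 <= 15**2) & (d2 >= 9**2)
    g = classify_points(skeletonize(ring))
    assert (g.classes == ENDPOINT).sum() == 0
    assert g.skeleton.sum() > 0


def test_tree_skeleton_has_an_endpoint():
    m = np.zeros((40, 40), bool)
    m[5:35, 20] = True
    m[20, 20:32] = True
    g = classify_points(skeletonize(m))
    assert (g.classes == ENDPOINT).sum() >= 2


def test_change_count_consistency_on_random_skeleton():
    rng = np.random.default_rng(1)
    m = gaussian_filter(rng.normal(size=(50, 50)), 3) > 0.05
    s = skeletonize(m)
    cmap = change_count_map(s)
    for r, c in np.argwhere(s):
        nb = []
        for dr, dc in NEIGHBOR_OFFSETS:
            rr, cc = r + dr, c + dc
            nb.append(bool(s[rr, cc]) if 0 <= rr < 50 and 0 <= cc < 50 else False)
        assert cmap[r, c] == 2 * run_count(nb)


def test_classification_is_pure():
    rng = np.random.default_rng(2)
    m = gaussian_filter(rng.normal(size=(40, 40)), 3) > 0.05
    s = skeletonize(m)
    g1, g2 = classify_points(s), classify_points(s)
    assert np.array_equal(g1.classes, g2.classes)


def test_2x2_block_rejected():
    m = np.zeros((6, 6), bool)
    m[2:4, 2:4] = True
    with pytest.raises(NotASkeletonError):
        classify_points(m)


def test_empty_mask_gives_empty_skeleton():
    assert skeletonize(np.zeros((8, 8), bool)).sum() == 0
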