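"""Dice and surface-distance metrics against brute-force oracles."""

import numpy as np
import pytest

from conftest import make_label
from multiatlas.errors import DegenerateInputError, GeometryError
from multiatlas.metrics import SurfaceSet, asd, dice, evaluate_pair, extract_surface, hausdorff, hd95


def _brute_force_surface(mask):
    """Oracle: exhaustive 6-neighbour scan for boundary voxels."""
    fg = mask.voxels.astype(bool)
    pts = []
    for idx in np.argwhere(fg):
        boundary = False
        for d in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            n = idx + d
            if np.any(n < 0) or np.any(n >= fg.shape) or not fg[tuple(n)]:
                boundary = True
                break
        if boundary:
            pts.append(idx)
    return mask.index_to_physical(np.array(pts))


def _brute_distances(a, b):
    """Oracle: all-pairs nearest-neighbour distances, both directions."""
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return d.min(axis=1), d.min(axis=0)


def _random_mask_pair(rng, shape=(12, 12, 12), spacing=(0.7, 0.9, 1.1)):
    while True:
        a = rng.random(shape) > 0.8
        b = rng.random(shape) > 0.8
        if a.any() and b.any():
            return make_label(a.astype(np.uint8), spacing), make_label(b.astype(np.uint8), spacing)


class TestDice:
    def test_identical_masks(self):
        a = make_label((np.random.default_rng(0).random((5, 5, 5)) > 0.5).astype(np.uint8))
        assert dice(a, a) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), np.uint8)
        b = np.zeros((4, 4, 4), np.uint8)
        a[0], b[2] = 1, 1
        assert dice(make_label(a), make_label(b)) == 0.0

    def test_half_overlap_arithmetic(self):
        a = np.zeros((4, 4, 4), np.uint8)
        b = np.zeros((4, 4, 4), np.uint8)
        a.flat[:8] = 1
        b.flat[4:12] = 1
        assert dice(make_label(a), make_label(b)) == pytest.approx(0.5)

    def test_both_empty_is_one_with_warning(self):
        e = make_label(np.zeros((3, 3, 3), np.uint8))
        with pytest.warns(UserWarning):
            assert dice(e, e) == 1.0

    def test_grid_mismatch(self):
        a = make_label(np.ones((3, 3, 3), np.uint8), spacing=(1, 1, 1))
        b = make_label(np.ones((3, 3, 3), np.uint8), spacing=(2, 2, 2))
        with pytest.raises(GeometryError):
            dice(a, b)


class TestSurface:
    def test_single_voxel(self):
        m = np.zeros((5, 5, 5), np.uint8)
        m[2, 2, 2] = 1
        surf = extract_surface(make_label(m, spacing=(0.5, 0.5, 0.5)))
        assert np.allclose(surf.points, [[1.0, 1.0, 1.0]])

    def test_solid_cube_shell_count(self):
        m = np.zeros((8, 8, 8), np.uint8)
        m[2:6, 2:6, 2:6] = 1
        assert len(extract_surface(make_label(m))) == 4**3 - 2**3

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a, _ = _random_mask_pair(rng)
            got = extract_surface(a).points
            want = _brute_force_surface(a)
            assert np.array_equal(
                got[np.lexsort(got.T)], want[np.lexsort(want.T)]
            )

    def test_empty_mask_raises(self):
        with pytest.raises(DegenerateInputError):
            extract_surface(make_label(np.zeros((3, 3, 3), np.uint8)))


class TestDistances:
    def test_identical_surfaces_zero(self):
        m = np.zeros((6, 6, 6), np.uint8)
        m[2:4, 2:4, 2:4] = 1
        lab = make_label(m)
        assert hausdorff(lab, lab) == 0.0
        assert hd95(lab, lab) == 0.0
        assert asd(lab, lab) == 0.0

    def test_singletons_along_axis(self):
        # two voxels 7 steps apart at 0.5 mm spacing -> 3.5 mm
        a = np.zeros((10, 3, 3), np.uint8)
        b = np.zeros((10, 3, 3), np.uint8)
        a[1, 1, 1], b[8, 1, 1] = 1, 1
        la, lb = make_label(a, (0.5, 0.5, 0.5)), make_label(b, (0.5, 0.5, 0.5))
        assert hausdorff(la, lb) == pytest.approx(3.5)
        assert asd(la, lb) == pytest.approx(3.5)

    def test_parallel_plates_asd(self):
        a = np.zeros((8, 5, 5), np.uint8)
        b = np.zeros((8, 5, 5), np.uint8)
        a[2], b[5] = 1, 1
        la, lb = make_label(a, (1.5, 1.5, 1.5)), make_label(b, (1.5, 1.5, 1.5))
        assert asd(la, lb) == pytest.approx(4.5)  # 3 voxels x 1.5 mm

    def test_random_masks_match_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b = _random_mask_pair(rng)
            sa, sb = extract_surface(a), extract_surface(b)
            da, db = _brute_distances(sa.points, sb.points)
            pooled = np.concatenate([da, db])
            assert hausdorff(a, b) == pytest.approx(pooled.max(), abs=1e-9)
            assert asd(a, b) == pytest.approx(pooled.mean(), abs=1e-9)
            assert hd95(a, b) == pytest.approx(np.percentile(pooled, 95), abs=1e-9)
            assert hd95(a, b) <= hausdorff(a, b) + 1e-12

    def test_hd95_percentile_rule_on_constructed_multiset(self):
        # distances {1 mm x19, 10 mm x1}: sort-based linear-interpolation oracle
        a = SurfaceSet(np.zeros((1, 3)))
        pts = np.zeros((19, 3))
        pts[:, 0] = 1.0
        far = np.array([[10.0, 0.0, 0.0]])
        b = SurfaceSet(np.vstack([pts + np.linspace(0, 1e-9, 19)[:, None] * 0, far]))
        # pooled distances: b->a gives {1}x19 and {10}x1; a->b gives {1}
        d = np.sort(np.array([1.0] * 19 + [10.0] + [1.0]))
        pos = 0.95 * (len(d) - 1)
        lo = int(np.floor(pos))
        expected = d[lo] + (pos - lo) * (d[lo + 1] - d[lo])
        assert hd95(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = _random_mask_pair(rng)
        assert hausdorff(a, b) == hausdorff(b, a)
        assert hd95(a, b) == hd95(b, a)
        assert asd(a, b) == asd(b, a)

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        m = (rng.random((8, 8, 8)) > 0.8).astype(np.uint8)
        m[0] = m[-1] = 0
        n = (rng.random((8, 8, 8)) > 0.8).astype(np.uint8)
        n[0] = n[-1] = 0
        if not (m.any() and n.any()):
            pytest.skip("degenerate draw")
        a, b = make_label(m), make_label(n)
        at = make_label(np.roll(m, 1, axis=0))
        bt = make_label(np.roll(n, 1, axis=0))
        assert dice(a, b) == dice(at, bt)
        assert hausdorff(a, b) == pytest.approx(hausdorff(at, bt), abs=1e-12)
        assert hd95(a, b) == pytest.approx(hd95(at, bt), abs=1e-12)
        assert asd(a, b) == pytest.approx(asd(at, bt), abs=1e-12)

    def test_distances_scale_with_spacing(self):
        rng = np.random.default_rng(5)
        a, b = _random_mask_pair(rng, spacing=(1.0, 1.0, 1.0))
        a2 = make_label(a.voxels, spacing=(2.0, 2.0, 2.0))
        b2 = make_label(b.voxels, spacing=(2.0, 2.0, 2.0))
        assert hd95(a2, b2) == pytest.approx(2 * hd95(a, b), abs=1e-12)
        assert asd(a2, b2) == pytest.approx(2 * asd(a, b), abs=1e-12)


def test_evaluate_pair_contracts():
    rng = np.random.default_rng(6)
    m = (rng.random((6, 6, 6)) > 0.6).astype(np.uint8)
    lab = make_label(m)
    rep = evaluate_pair(lab, lab)
    assert (rep.dice, rep.hd95, rep.asd) == (1.0, 0.0, 0.0)

    empty = make_label(np.zeros((6, 6, 6), np.uint8))
    rep = evaluate_pair(empty, lab)
    assert rep.dice == 0.0
    assert rep.empty_prediction
    assert np.isnan(rep.hd95) and np.isnan(rep.asd)
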