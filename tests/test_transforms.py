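"""Cubic B-spline basis, FFD evaluation, and transform composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multiatlas.errors import DomainError, ValidationError
from multiatlas.transforms import (
    AffineTransform,
    BSplineTransform,
    TransformChain,
    bspline_basis,
    bspline_displacement,
    bspline_grid_for_domain,
    load_chain,
    save_chain,
)


def _triple_loop_displacement(t: BSplineTransform, p: np.ndarray) -> np.ndarray:
    """Independent oracle: explicit 4×4×4 tensor-product sum of the basis polynomials."""
    rel = (p - t.grid_origin) / t.grid_spacing
    f = np.floor(rel).astype(int)
    u = rel - f
    i = f - 1
    out = np.zeros(3)
    for m in range(4):
        for n in range(4):
            for l in range(4):
                w = bspline_basis(m, u[0]) * bspline_basis(n, u[1]) * bspline_basis(l, u[2])
                out += w * t.displacements[i[0] + m, i[1] + n, i[2] + l]
    return out


def _random_ffd(rng, spacing=(4.0, 5.0, 6.0), shape=(8, 7, 9)) -> BSplineTransform:
    return BSplineTransform(
        np.array([-1.0, -1.0, -1.0]),
        np.asarray(spacing),
        shape,
        rng.normal(0, 2, size=tuple(shape) + (3,)),
    )


class TestBasis:
    def test_values_at_zero(self):
        # the four cubic polynomials at u=0: 1/6, 4/6, 1/6, 0
        assert bspline_basis(0, 0.0) == pytest.approx(1 / 6, abs=1e-15)
        assert bspline_basis(1, 0.0) == pytest.approx(4 / 6, abs=1e-15)
        assert bspline_basis(2, 0.0) == pytest.approx(1 / 6, abs=1e-15)
        assert bspline_basis(3, 0.0) == 0.0

    def test_limit_at_one(self):
        assert bspline_basis(3, 1 - 1e-12) == pytest.approx(1 / 6, rel=1e-9)

    @pytest.mark.parametrize("u", [0.0, 0.25, 0.5, 0.99])
    def test_partition_of_unity(self, u):
        assert sum(bspline_basis(m, u) for m in range(4)) == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=1.0, exclude_max=True))
    @settings(max_examples=200, derandomize=True)
    def test_partition_of_unity_everywhere(self, u):
        assert sum(bspline_basis(m, u) for m in range(4)) == pytest.approx(1.0, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            bspline_basis(4, 0.5)
        with pytest.raises(DomainError):
            bspline_basis(0, 1.0)

    def test_partition_of_unity_3d(self):
        rng = np.random.default_rng(0)
        uvw = rng.random((1000, 3))
        total = np.zeros(1000)
        for m in range(4):
            for n in range(4):
                for l in range(4):
                    total += (
                        bspline_basis(m, uvw[:, 0])
                        * bspline_basis(n, uvw[:, 1])
                        * bspline_basis(l, uvw[:, 2])
                    )
        assert np.allclose(total, 1.0, atol=1e-12)


class TestFFD:
    def test_zero_displacements(self):
        t = BSplineTransform.zero((-5, -5, -5), (5, 5, 5), (6, 6, 6))
        pts = np.random.default_rng(0).uniform(2, 8, size=(20, 3))
        assert np.allclose(t.displacement(pts), 0.0)

    def test_uniform_displacement_translates(self):
        # partition of unity: equal control displacements act as a translation
        shape = (6, 6, 6)
        d = np.array([1.5, -2.0, 0.25])
        t = BSplineTransform((-5, -5, -5), (5, 5, 5), shape, np.tile(d, shape + (1,)))
        pts = np.random.default_rng(1).uniform(2, 8, size=(50, 3))
        assert np.allclose(t.displacement(pts), d, atol=1e-10)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(3)
        t = _random_ffd(rng)
        pts = rng.uniform(8, 18, size=(100, 3))
        fast = t.displacement(pts)
        slow = np.array([_triple_loop_displacement(t, p) for p in pts])
        assert np.abs(fast - slow).max() < 1e-10

    def test_linear_in_control_displacements(self):
        rng = np.random.default_rng(4)
        t1 = _random_ffd(rng)
        t2 = _random_ffd(rng)
        a, b = 0.3, -1.7
        t3 = BSplineTransform(
            t1.grid_origin,
            t1.grid_spacing,
            t1.grid_shape,
            a * t1.displacements + b * t2.displacements,
        )
        pts = rng.uniform(8, 18, size=(40, 3))
        assert np.allclose(
            t3.displacement(pts),
            a * t1.displacement(pts) + b * t2.displacement(pts),
            atol=1e-10,
        )

    def test_outside_support_raises(self):
        t = BSplineTransform.zero((0, 0, 0), (5, 5, 5), (6, 6, 6))
        with pytest.raises(DomainError):
            t.displacement(np.array([-20.0, 0.0, 0.0]))

    def test_module_level_wrapper(self):
        rng = np.random.default_rng(5)
        t = _random_ffd(rng)
        p = np.array([10.0, 10.0, 10.0])
        assert np.allclose(bspline_displacement(t, p), t.displacement(p))

    def test_grid_for_domain_covers_domain(self):
        go, gs, shape = bspline_grid_for_domain((0, 0, 0), (31.5, 31.5, 31.5), 5.0)
        t = BSplineTransform.zero(go, gs, shape)
        corners = np.array(
            [[x, y, z] for x in (0, 31.5) for y in (0, 31.5) for z in (0, 31.5)]
        )
        t.displacement(corners)  # must not raise


class TestChain:
    def test_empty_chain_is_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        assert np.allclose(TransformChain().map_points(pts), pts)

    def test_composition_order_ffd_first(self):
        # [affine, ffd] applies the FFD to the input point, then the affine
        aff = AffineTransform(2 * np.eye(3), np.zeros(3), np.zeros(3))
        shape = (6, 6, 6)
        d = np.array([1.0, 0.0, 0.0])
        ffd = BSplineTransform((-5, -5, -5), (5, 5, 5), shape, np.tile(d, shape + (1,)))
        p = np.array([[3.0, 3.0, 3.0]])
        out = TransformChain([aff, ffd]).map_points(p)
        assert np.allclose(out, 2 * (p + d))

    def test_singular_affine_rejected(self):
        with pytest.raises(ValidationError):
            AffineTransform(np.zeros((3, 3)), np.zeros(3), np.zeros(3))

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        aff = AffineTransform(np.eye(3) + 0.01 * rng.normal(size=(3, 3)), rng.normal(size=3), np.zeros(3))
        ffd = _random_ffd(rng)
        chain = TransformChain([aff, ffd])
        path = tmp_path / "chain.json"
        save_chain(chain, path)
        loaded = load_chain(path)
        pts = rng.uniform(8, 18, size=(20, 3))
        assert np.allclose(loaded.map_points(pts), chain.map_points(pts), atol=1e-12)
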