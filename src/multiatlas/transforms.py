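"""Spatial transforms: affine maps and cubic B-spline free-form deformations.

All transforms act on physical (mm) coordinates. A :class:`TransformChain`
maps points of the *fixed* image's physical space into the *moving* image's
physical space — the resampling convention, where the warped output at fixed
voxel ``x`` is the moving image sampled at ``T(x)``.

The free-form deformation (FFD) displaces a regular grid of control points
and interpolates the displacement field with uniform cubic B-splines: for a
point with per-axis grid offset ``u ∈ [0, 1)`` between control cells the
displacement is the tensor-product sum over the 4×4×4 surrounding control
points weighted by the cubic basis polynomials

    B0(u) = (1 − u)³ / 6
    B1(u) = (3u³ − 6u² + 4) / 6
    B2(u) = (−3u³ + 3u² + 3u + 1) / 6
    B3(u) = u³ / 6

which form a partition of unity, so a uniform control displacement translates
every interior point rigidly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "bspline_basis",
    "AffineTransform",
    "BSplineTransform",
    "TransformChain",
    "bspline_displacement",
    "bspline_grid_for_domain",
    "save_chain",
    "load_chain",
]


def bspline_basis(m: int, u):
    """Evaluate the m-th uniform cubic B-spline basis polynomial at ``u``.

    Parameters
    ----------
    m : int
        Basis index in {0, 1, 2, 3}.
    u : float or array
        Relative position within the control cell, ``0 <= u < 1``.
    """
    if m not in (0, 1, 2, 3):
        raise DomainError(f"B-spline basis index must be in 0..3, got {m}")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u >= 1):
        raise DomainError("relative grid position u must satisfy 0 <= u < 1")
    if m == 0:
        return (1.0 - u) ** 3 / 6.0
    if m == 1:
        return (3.0 * u**3 - 6.0 * u**2 + 4.0) / 6.0
    if m == 2:
        return (-3.0 * u**3 + 3.0 * u**2 + 3.0 * u + 1.0) / 6.0
    return u**3 / 6.0


def _basis_matrix(u: np.ndarray) -> np.ndarray:
    """All four cubic basis weights for an array of offsets; shape (n, 4).

    Unchecked fast path used by the vectorized evaluators.
    """
    u = np.asarray(u, dtype=float)
    u2 = u * u
    u3 = u2 * u
    out = np.empty(u.shape + (4,), dtype=float)
    out[..., 0] = (1.0 - u) ** 3 / 6.0
    out[..., 1] = (3.0 * u3 - 6.0 * u2 + 4.0) / 6.0
    out[..., 2] = (-3.0 * u3 + 3.0 * u2 + 3.0 * u + 1.0) / 6.0
    out[..., 3] = u3 / 6.0
    return out


@dataclass
class AffineTransform:
    """Affine map ``p ↦ M (p − c) + c + t`` on physical coordinates.

    ``center`` (c) is the rotation center, typically the fixed image's
    physical center, so that rotation parameters do not couple strongly with
    translation during optimization.
    """

    matrix: np.ndarray
    translation: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) <= 1e-9:
            raise ValidationError("affine matrix is singular (|det| <= 1e-9)")

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3), np.asarray(center, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.center) @ self.matrix.T + self.center + self.translation

    def to_dict(self) -> dict:
        return {
            "type": "affine",
            "matrix": self.matrix.ravel().tolist(),
            "translation": self.translation.tolist(),
            "center": self.center.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(np.asarray(d["matrix"]).reshape(3, 3), d["translation"], d["center"])


def bspline_grid_for_domain(origin, extent_mm, spacing_mm) -> tuple[np.ndarray, np.ndarray, tuple[int, int, int]]:
    """Control-grid geometry covering a physical box plus the cubic support margin.

    Returns ``(grid_origin, grid_spacing, grid_shape)`` such that every point
    of ``[origin, origin + extent_mm]`` has its full 4×4×4 control-point
    support inside the grid.
    """
    origin = np.asarray(origin, dtype=float)
    extent = np.asarray(extent_mm, dtype=float)
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,)).astype(float)
    if np.any(spacing <= 0):
        raise ValidationError("grid spacing must be strictly positive")
    ncell = np.maximum(1, np.ceil(extent / spacing).astype(int))
    # one spare cell on each end keeps floor(t)-1 in range at the exact domain
    # boundary, including when a point lands on a grid plane
    grid_origin = origin - spacing
    grid_shape = tuple(int(n) + 4 for n in ncell)
    return grid_origin, spacing, grid_shape


@dataclass
class BSplineTransform:
    """Cubic free-form deformation: ``p ↦ p + d(p)``.

    ``displacements`` has shape ``grid_shape + (3,)`` holding a mm 3-vector
    per control point. The displacement at a physical point is the
    tensor-product B-spline interpolation of the control displacements over
    the 4×4×4 surrounding control points; points whose support extends past
    the grid are outside the supported domain.
    """

    grid_origin: np.ndarray
    grid_spacing: np.ndarray
    grid_shape: tuple
    displacements: np.ndarray
    order: int = field(default=3)

    def __post_init__(self) -> None:
        self.grid_origin = np.asarray(self.grid_origin, dtype=float).reshape(3)
        self.grid_spacing = np.asarray(self.grid_spacing, dtype=float).reshape(3)
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if np.any(self.grid_spacing <= 0):
            raise ValidationError("grid spacing must be strictly positive")
        if self.order != 3:
            raise ValidationError("only cubic (order 3) B-spline FFDs are supported")
        self.displacements = np.asarray(self.displacements, dtype=float).reshape(
            self.grid_shape + (3,)
        )
        if min(self.grid_shape) < 4:
            raise ValidationError("FFD grid needs at least 4 control points per axis")

    @classmethod
    def zero(cls, grid_origin, grid_spacing, grid_shape) -> "BSplineTransform":
        shape = tuple(int(n) for n in grid_shape)
        return cls(grid_origin, grid_spacing, shape, np.zeros(shape + (3,)))

    # -- support lookup ---------------------------------------------------
    def _cell_coords(self, points: np.ndarray):
        """Per-point support start index i (floor(t)-1) and offset u in [0,1)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        t = (pts - self.grid_origin) / self.grid_spacing
        f = np.floor(t).astype(np.int64)
        u = t - f
        i = f - 1
        shape = np.asarray(self.grid_shape)
        if np.any(i < 0) or np.any(i + 3 > shape - 1):
            raise DomainError("point outside the supported FFD domain")
        return i, u

    def support_weights(self, points: np.ndarray):
        """Flat control-point indices and tensor weights of each point's support.

        Returns ``(flat_idx, weights)`` of shape (n, 64) each, with
        ``displacement(p) = Σ_k weights[p,k] · φ[flat_idx[p,k]]``. Used by the
        evaluator and by the registration optimizer's sparse updates.
        """
        i, u = self._cell_coords(points)
        wx = _basis_matrix(u[:, 0])
        wy = _basis_matrix(u[:, 1])
        wz = _basis_matrix(u[:, 2])
        ny, nz = self.grid_shape[1], self.grid_shape[2]
        off = np.arange(4, dtype=np.int64)
        ix = i[:, 0:1] + off  # (n,4)
        iy = i[:, 1:2] + off
        iz = i[:, 2:3] + off
        flat = (
            (ix[:, :, None, None] * ny + iy[:, None, :, None]) * nz
            + iz[:, None, None, :]
        )
        w = wx[:, :, None, None] * wy[:, None, :, None] * wz[:, None, None, :]
        n = flat.shape[0]
        return flat.reshape(n, 64), w.reshape(n, 64)

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Displacement vector(s) in mm at physical point(s).

        Evaluated with scipy's B-spline interpolation of the control grid
        (``prefilter=False`` treats the displacements as spline
        *coefficients*), which is algebraically identical to the explicit
        4×4×4 tensor-product sum over the basis polynomials.
        """
        single = np.asarray(points).ndim == 1
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        self._cell_coords(pts)  # bounds check
        t = ((pts - self.grid_origin) / self.grid_spacing).T
        from scipy import ndimage as _ndi

        disp = np.empty((pts.shape[0], 3))
        for ax in range(3):
            disp[:, ax] = _ndi.map_coordinates(
                self.displacements[..., ax], t, order=3, prefilter=False, mode="nearest"
            )
        return disp[0] if single else disp

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts + self.displacement(pts)

    def to_dict(self) -> dict:
        return {
            "type": "bspline",
            "grid_origin": self.grid_origin.tolist(),
            "grid_spacing": self.grid_spacing.tolist(),
            "grid_shape": list(self.grid_shape),
            "displacements": self.displacements.ravel().tolist(),
            "order": self.order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BSplineTransform":
        shape = tuple(d["grid_shape"])
        return cls(
            d["grid_origin"],
            d["grid_spacing"],
            shape,
            np.asarray(d["displacements"]).reshape(shape + (3,)),
        )


def bspline_displacement(transform: BSplineTransform, point) -> np.ndarray:
    """Displacement of the FFD at a physical point (module-level convenience)."""
    return transform.displacement(point)


@dataclass
class TransformChain:
    """Ordered transform composition mapping fixed-space points to moving space.

    Transforms are stored coarse-to-fine, ``[affine, bspline]``, and compose
    like functions: the *last* entry is applied first, so the FFD acts on
    fixed-domain points (where its control grid is defined) and the affine
    maps the deformed point into the moving image. An empty chain is the
    identity.
    """

    transforms: list = field(default_factory=list)

    def map_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        for t in reversed(self.transforms):
            pts = t.apply(pts)
        return pts

    def to_dict(self) -> dict:
        return {"type": "chain", "transforms": [t.to_dict() for t in self.transforms]}

    @classmethod
    def from_dict(cls, d: dict) -> "TransformChain":
        out = []
        for td in d["transforms"]:
            if td["type"] == "affine":
                out.append(AffineTransform.from_dict(td))
            elif td["type"] == "bspline":
                out.append(BSplineTransform.from_dict(td))
            else:
                raise ValidationError(f"unknown transform type {td['type']!r}")
        return cls(out)


def save_chain(chain: TransformChain, path) -> None:
    with open(path, "w") as fh:
        json.dump(chain.to_dict(), fh)


def load_chain(path) -> TransformChain:
    with open(path) as fh:
        return TransformChain.from_dict(json.load(fh))
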