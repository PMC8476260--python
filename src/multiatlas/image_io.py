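"""Volumes, label maps, and geometry-aware file I/O.

Images are stored with voxel axes ordered (x, y, z), matching the order of
the ``spacing``/``origin`` metadata: the physical position of voxel index
``(i, j, k)`` is ``origin + direction @ (spacing * index)``, all in mm.
NIfTI-1 (.nii/.nii.gz) and MetaImage (.mha/.mhd) are read and written through
SimpleITK so full spacing/origin/direction metadata round-trips; SimpleITK's
(z, y, x) array order is transposed at the boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import ConfigError, FormatError, GeometryError, ValidationError

__all__ = [
    "Volume",
    "LabelMap",
    "Atlas",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "resample_to_reference",
    "load_atlas_dir",
]

_GEOMETRY_TOL = 1e-6

_INTERP_ORDERS = {"nearest": 0, "linear": 1, "cubic-bspline": 3}


@dataclass
class _Grid3D:
    """Shared geometry contract for volumes and label maps."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def _validate_geometry(self) -> None:
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValidationError("voxel array must be non-empty and 3-D")
        if np.any(self.spacing <= 0):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6) or abs(
            abs(np.linalg.det(self.direction)) - 1.0
        ) > 1e-6:
            raise ValidationError("direction matrix must be orthonormal (|det| = 1)")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def index_to_physical_matrix(self) -> np.ndarray:
        return self.direction @ np.diag(self.spacing)

    def index_to_physical(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.index_to_physical_matrix.T + self.origin

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.index_to_physical_matrix)
        return (pts - self.origin) @ inv.T

    @property
    def physical_extent(self) -> np.ndarray:
        """Edge-to-edge extent along each voxel axis, in mm."""
        return self.spacing * (np.asarray(self.shape) - 1)

    def same_geometry(self, other: "_Grid3D", tol: float = _GEOMETRY_TOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


@dataclass
class Volume(_Grid3D):
    """3-D scalar image (CT-like arbitrary intensity units) with mm geometry."""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self._validate_geometry()

    def with_voxels(self, voxels: np.ndarray) -> "Volume":
        return Volume(np.asarray(voxels), self.spacing.copy(), self.origin.copy(), self.direction.copy())


@dataclass
class LabelMap(_Grid3D):
    """Binary segmentation sharing a Volume's geometry; values restricted to {0, 1}."""

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        bad = np.setdiff1d(np.unique(arr), [0, 1])
        if bad.size:
            raise ValidationError(f"label map contains non-binary values {bad.tolist()}")
        self.voxels = arr.astype(np.uint8)
        self._validate_geometry()

    def with_voxels(self, voxels: np.ndarray) -> "LabelMap":
        return LabelMap(voxels, self.spacing.copy(), self.origin.copy(), self.direction.copy())

    @property
    def foreground_count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class Atlas:
    """A paired gray volume and expert label map: transferable prior anatomy."""

    id: str
    gray: Volume
    label: LabelMap

    def __post_init__(self) -> None:
        if not self.gray.same_geometry(self.label):
            raise GeometryError(f"atlas {self.id!r}: gray and label geometry differ")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_SUPPORTED_EXT = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_ext(path: str) -> None:
    name = str(path).lower()
    if not any(name.endswith(e) for e in _SUPPORTED_EXT):
        raise FormatError(
            f"unsupported format for {path!r}: expected one of {_SUPPORTED_EXT}"
        )


def read_volume(path) -> Volume:
    """Read a NIfTI or MetaImage file into a :class:`Volume`.

    Integer voxel types are preserved losslessly; geometry comes from the
    header.
    """
    _check_ext(path)
    if not os.path.exists(str(path)) and not os.path.exists(str(path).replace(".mhd", ".raw")):
        raise FormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps all reader failures here
        raise FormatError(f"could not read {path!r} as NIfTI/MetaImage: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"{path!r} is {img.GetDimension()}-D; only 3-D volumes are supported")
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return Volume(
        arr,
        np.asarray(img.GetSpacing()),
        np.asarray(img.GetOrigin()),
        np.asarray(img.GetDirection()).reshape(3, 3),
    )


def _to_sitk(grid: _Grid3D, dtype=None) -> sitk.Image:
    arr = grid.voxels if dtype is None else grid.voxels.astype(dtype)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    img.SetDirection(tuple(float(d) for d in grid.direction.ravel()))
    return img


def write_volume(vol: Volume, path) -> None:
    _check_ext(path)
    sitk.WriteImage(_to_sitk(vol), str(path))


def read_labelmap(path) -> LabelMap:
    """Read a binary label map; any stored value other than 0/1 is an error.

    No silent thresholding: floats are accepted only if exactly integral.
    """
    vol = read_volume(path)
    arr = vol.voxels
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.round(arr)):
            raise ValidationError(f"label file {path!r} contains non-integer values")
        arr = np.round(arr).astype(np.int64)
    bad = np.setdiff1d(np.unique(arr), [0, 1])
    if bad.size:
        raise ValidationError(
            f"label file {path!r} contains values other than 0/1: {bad.tolist()}"
        )
    return LabelMap(arr, vol.spacing, vol.origin, vol.direction)


def write_labelmap(label: LabelMap, path) -> None:
    """Write a label map using unsigned 8-bit storage."""
    _check_ext(path)
    sitk.WriteImage(_to_sitk(label, dtype=np.uint8), str(path))


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def sample_at_physical(vol: _Grid3D, points: np.ndarray, interpolation: str, cval: float):
    """Interpolate a volume at arbitrary physical points.

    Returns ``(values, in_domain)`` where ``in_domain`` flags points whose
    continuous index lies inside the voxel lattice; values outside get
    ``cval``. Cubic sampling uses an interpolating cubic B-spline
    (spline prefilter), the third-order B-spline interpolation family.
    """
    if interpolation not in _INTERP_ORDERS:
        raise ConfigError(
            f"unknown interpolation {interpolation!r}; expected one of {sorted(_INTERP_ORDERS)}"
        )
    order = _INTERP_ORDERS[interpolation]
    idx = vol.physical_to_index(points)
    shape = np.asarray(vol.shape, dtype=float)
    in_domain = np.all((idx >= -0.5) & (idx <= shape - 0.5), axis=1) if order == 0 else np.all(
        (idx >= 0.0) & (idx <= shape - 1.0), axis=1
    )
    vals = ndimage.map_coordinates(
        vol.voxels.astype(float), idx.T, order=order, mode="grid-constant", cval=cval
    )
    vals[~in_domain] = cval
    return vals, in_domain


def resample_to_reference(vol, ref: _Grid3D, interpolation: str = "linear"):
    """Resample a Volume (or LabelMap, nearest only) onto a reference grid.

    Sampling is done in physical space; out-of-domain voxels are filled with
    the input's minimum intensity for gray volumes and 0 for labels.
    """
    is_label = isinstance(vol, LabelMap)
    if is_label and interpolation != "nearest":
        raise ConfigError("label maps must be resampled with 'nearest' interpolation")
    if interpolation not in _INTERP_ORDERS:
        raise ConfigError(
            f"unknown interpolation {interpolation!r}; expected one of {sorted(_INTERP_ORDERS)}"
        )
    cval = 0.0 if is_label else float(vol.voxels.min())
    ref_idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in ref.shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    pts = ref.index_to_physical(ref_idx)
    vals, _ = sample_at_physical(vol, pts, interpolation, cval)
    out = vals.reshape(ref.shape)
    if is_label:
        return LabelMap(np.round(out).astype(np.uint8), ref.spacing, ref.origin, ref.direction)
    return Volume(out, ref.spacing, ref.origin, ref.direction)


# ---------------------------------------------------------------------------
# atlas directories
# ---------------------------------------------------------------------------


def load_atlas_dir(path, side: str | None = None) -> list[Atlas]:
    """Load all atlases from a directory of ``{id}_gray`` + ``{id}_label`` pairs.

    With ``side`` given, label files are ``{id}_label_{side}.nii.gz``;
    otherwise ``{id}_label.nii.gz``. Atlases are returned sorted by id.
    """
    suffix = f"_label_{side}" if side else "_label"
    atlases = []
    for name in sorted(os.listdir(str(path))):
        low = name.lower()
        if "_gray" not in low or not any(low.endswith(e) for e in _SUPPORTED_EXT):
            continue
        stem = name[: low.index("_gray")]
        ext = name[low.index("_gray") + len("_gray"):]
        label_path = os.path.join(str(path), f"{stem}{suffix}{ext}")
        if not os.path.exists(label_path):
            continue
        gray = read_volume(os.path.join(str(path), name))
        label = read_labelmap(label_path)
        atlases.append(Atlas(stem, gray, label))
    if not atlases:
        raise ValidationError(f"no gray/label atlas pairs found in {path!r} (side={side!r})")
    return atlases
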