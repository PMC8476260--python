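"""Synthetic skull-base phantom cohort with ground truth.

Clinical multi-atlas work on the foramen ovale rests on private CT cohorts,
so this module generates a stand-in: a bright ellipsoidal bone shell on a
soft-tissue interior over an air background, pierced by two oblique
cylindrical channels (left/right foramen-like canals, few-mm diameter).
Ground-truth labels mark the bone removed by each channel. Acquisition is
emulated by additive Gaussian noise followed by slight Gaussian smoothing
(noise first — the smoothing models the cohort's post-processing step).

A cohort applies an independent random smooth B-spline deformation (the
inter-subject anatomy model) plus fresh noise to each member, and splits
members into an atlas set and a held-out test set with known truth. All
outputs are pure functions of spec + seed, bitwise reproducible.

What the phantom does NOT emulate: real skull geometry, CT physics (beam
hardening, streaks), scanner-dependent intensity calibration, or rater
disagreement in the manual labels. Pipeline results on the phantom validate
the machinery, not clinical accuracy.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .fusion import DecisionStack
from .image_io import LabelMap, Volume, sample_at_physical, write_labelmap, write_volume
from .transforms import BSplineTransform, TransformChain, bspline_grid_for_domain

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "Phantom",
    "make_phantom",
    "random_deformation",
    "make_cohort",
    "simulate_raters",
]


@dataclass
class PhantomSpec:
    """Geometry and intensity model of one synthetic skull-base volume.

    Defaults give a 64³ volume at 0.5 mm isotropic spacing (32 mm field of
    view) with a ~3 mm-thick bone shell and two 1.5 mm-radius canals —
    foramen-scale structures of a few hundred voxels each. Intensities are
    CT-like (air ≈ −1000, soft tissue ≈ 40, bone ≈ 1400 arbitrary HU-like
    units).
    """

    shape: tuple = (64, 64, 64)
    spacing: tuple = (0.5, 0.5, 0.5)
    shell_radii_mm: tuple = (12.0, 10.0, 9.0)
    shell_thickness_mm: float = 3.0
    foramen_radius_mm: float = 1.5
    foramen_offset_mm: float = 6.0
    foramen_tilt_deg: float = 20.0
    intensity_air: float = -1000.0
    intensity_soft: float = 40.0
    intensity_bone: float = 1400.0
    noise_sigma: float = 30.0
    smoothing_sigma_mm: float = 0.4
    seed: int = 0


@dataclass
class CohortSpec:
    """Cohort layout: atlas/test split and the inter-subject deformation model."""

    n_atlases: int = 20
    n_tests: int = 10
    deformation_grid_mm: float = 10.0
    deformation_max_mm: float = 3.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_atlases < 1 or self.n_tests < 0:
            raise ValidationError("cohort needs n_atlases >= 1 and n_tests >= 0")
        if self.deformation_max_mm >= 0.4 * self.deformation_grid_mm:
            raise ValidationError(
                "deformation_max_mm must stay below 0.4 × grid spacing "
                "(invertibility-safe smooth warps)"
            )


@dataclass
class Phantom:
    gray: Volume
    left: LabelMap
    right: LabelMap

    def __iter__(self):
        return iter((self.gray, self.left, self.right))


def _mm_grids(spec: PhantomSpec):
    sp = np.asarray(spec.spacing, dtype=float)
    axes = [np.arange(n) * s for n, s in zip(spec.shape, sp)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _channel_mask(spec: PhantomSpec, side: int):
    """Voxels within foramen_radius of the side's oblique canal axis.

    The axis pierces the lower shell wall at lateral offset ±foramen_offset,
    tilted ``foramen_tilt_deg`` from the z axis in the xz plane.
    """
    x, y, z = _mm_grids(spec)
    center = np.asarray(spec.spacing) * (np.asarray(spec.shape) - 1) / 2.0
    rx, ry, rz = spec.shell_radii_mm
    x0 = side * spec.foramen_offset_mm
    # z of the lower outer-shell wall above (x0, y=0)
    zwall = -rz * np.sqrt(max(1e-9, 1.0 - (x0 / rx) ** 2))
    p0 = center + np.array([x0, 0.0, zwall])
    th = np.deg2rad(spec.foramen_tilt_deg)
    axis = np.array([np.sin(th) * side, 0.0, np.cos(th)])
    dx, dy, dz = x - p0[0], y - p0[1], z - p0[2]
    t = dx * axis[0] + dy * axis[1] + dz * axis[2]
    d2 = (dx - t * axis[0]) ** 2 + (dy - t * axis[1]) ** 2 + (dz - t * axis[2]) ** 2
    return d2 <= spec.foramen_radius_mm**2


def make_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Deterministic synthetic volume + left/right canal truth labels."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    sp = np.asarray(spec.spacing, dtype=float)
    center = sp * (np.asarray(spec.shape) - 1) / 2.0
    x, y, z = _mm_grids(spec)
    radii = np.asarray(spec.shell_radii_mm, dtype=float)
    if np.any(radii >= center):
        raise ValidationError("shell does not fit inside the volume")
    inner = radii - spec.shell_thickness_mm
    if np.any(inner <= spec.foramen_radius_mm):
        raise ValidationError("shell too thin for the requested foramen radius")

    def ellipsoid(r):
        return (
            ((x - center[0]) / r[0]) ** 2
            + ((y - center[1]) / r[1]) ** 2
            + ((z - center[2]) / r[2]) ** 2
        ) <= 1.0

    outer = ellipsoid(radii)
    shell = outer & ~ellipsoid(inner)
    gray = np.full(spec.shape, spec.intensity_air, dtype=float)
    gray[outer] = spec.intensity_soft
    gray[shell] = spec.intensity_bone

    labels = {}
    for name, side in (("left", -1), ("right", +1)):
        channel = _channel_mask(spec, side)
        lab = channel & shell
        count = int(lab.sum())
        if count < 20:
            raise ValidationError(
                f"{name} foramen label has only {count} voxels; enlarge the canal"
            )
        border = np.zeros(spec.shape, dtype=bool)
        border[[0, -1], :, :] = border[:, [0, -1], :] = border[:, :, [0, -1]] = True
        if (lab & border).any():
            raise ValidationError(f"{name} foramen touches the volume border")
        gray[channel & outer] = spec.intensity_soft  # carve the canal
        labels[name] = lab
    if (labels["left"] & labels["right"]).any():
        raise ValidationError("left and right foramen labels overlap")

    if spec.noise_sigma > 0:
        gray = gray + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    if spec.smoothing_sigma_mm > 0:
        gray = ndimage.gaussian_filter(gray, sigma=spec.smoothing_sigma_mm / sp)

    origin = np.zeros(3)
    vol = Volume(gray, sp, origin)
    return Phantom(
        vol,
        LabelMap(labels["left"].astype(np.uint8), sp, origin),
        LabelMap(labels["right"].astype(np.uint8), sp, origin),
    )


def random_deformation(
    cohort: CohortSpec, seed: int, domain: tuple | None = None
) -> BSplineTransform:
    """Random smooth FFD with i.i.d. uniform control displacements in ±max.

    ``domain`` is ``(origin_mm, extent_mm)``; by default the default
    phantom's physical extent (plus margin) is used.
    """
    if cohort.deformation_max_mm < 0:
        raise ValidationError("deformation_max_mm must be >= 0")
    if domain is None:
        spec = PhantomSpec()
        sp = np.asarray(spec.spacing)
        domain = (-sp, sp * (np.asarray(spec.shape) + 1))
    go, gs, gshape = bspline_grid_for_domain(domain[0], domain[1], cohort.deformation_grid_mm)
    rng = np.random.default_rng(seed)
    disp = rng.uniform(
        -cohort.deformation_max_mm, cohort.deformation_max_mm, size=gshape + (3,)
    )
    return BSplineTransform(go, gs, gshape, disp)


def _sample_label(label: LabelMap, mapped_pts: np.ndarray, ref: Volume) -> LabelMap:
    vals, _ = sample_at_physical(label, mapped_pts, "nearest", 0.0)
    return LabelMap(
        np.round(vals.reshape(ref.shape)).astype(np.uint8), ref.spacing, ref.origin, ref.direction
    )


def _single_component(label: LabelMap) -> bool:
    _, n = ndimage.label(label.voxels, structure=ndimage.generate_binary_structure(3, 1))
    return n == 1


def _member_seed(cohort_seed: int, index: int, attempt: int = 0) -> int:
    ss = np.random.SeedSequence(entropy=cohort_seed, spawn_key=(index, attempt))
    return int(ss.generate_state(1)[0] % 2**31)


def make_cohort(cohort: CohortSpec | None = None, spec: PhantomSpec | None = None, out_dir=None):
    """Write an atlas directory + test directory of deformed phantom members.

    Each member is the (noise-free) base phantom warped by its own random
    FFD, then given fresh noise and smoothing; truth labels are propagated
    through the same warp. Files are NIfTI (.nii.gz) named
    ``{id}_gray`` / ``{id}_label_left`` / ``{id}_label_right`` under
    ``atlas/`` and ``tests/``, with a ``manifest.csv`` listing ids, roles,
    seeds and deformation magnitudes. Returns the manifest DataFrame.
    """
    cohort = cohort or CohortSpec()
    spec = spec or PhantomSpec()
    if out_dir is None:
        raise ValidationError("make_cohort needs an output directory")
    clean = replace(spec, noise_sigma=0.0, smoothing_sigma_mm=0.0)
    base = make_phantom(clean)
    sp = np.asarray(spec.spacing)
    domain = (base.gray.origin - sp, base.gray.physical_extent + 2 * sp)
    ref_idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in base.gray.shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    ref_pts = base.gray.index_to_physical(ref_idx)

    atlas_dir = os.path.join(str(out_dir), "atlas")
    test_dir = os.path.join(str(out_dir), "tests")
    os.makedirs(atlas_dir, exist_ok=True)
    os.makedirs(test_dir, exist_ok=True)
    rows = []
    total = cohort.n_atlases + cohort.n_tests
    for i in range(total):
        role = "atlas" if i < cohort.n_atlases else "test"
        member_id = f"{role}{i:03d}" if role == "atlas" else f"{role}{i - cohort.n_atlases:03d}"
        for attempt in range(10):
            seed_i = _member_seed(cohort.seed, i, attempt)
            ffd = random_deformation(cohort, seed_i, domain=domain)
            # map the grid once per member; gray and both labels share it
            mapped = TransformChain([ffd]).map_points(ref_pts)
            left = _sample_label(base.left, mapped, base.gray)
            right = _sample_label(base.right, mapped, base.gray)
            if (
                left.foreground_count
                and right.foreground_count
                and _single_component(left)
                and _single_component(right)
            ):
                break
            logger.warning(
                "member %s: warped label not a single 6-connected component; "
                "regenerating with a fresh seed",
                member_id,
            )
        gvals, _ = sample_at_physical(base.gray, mapped, "cubic-bspline", float(base.gray.voxels.min()))
        gray = base.gray.with_voxels(gvals.reshape(base.gray.shape))
        noise_rng = np.random.default_rng(seed_i + 1)
        arr = gray.voxels + noise_rng.normal(0.0, spec.noise_sigma, size=gray.shape)
        if spec.smoothing_sigma_mm > 0:
            arr = ndimage.gaussian_filter(arr, sigma=spec.smoothing_sigma_mm / sp)
        gray = gray.with_voxels(arr)

        target = atlas_dir if role == "atlas" else test_dir
        write_volume(gray, os.path.join(target, f"{member_id}_gray.nii.gz"))
        write_labelmap(left, os.path.join(target, f"{member_id}_label_left.nii.gz"))
        write_labelmap(right, os.path.join(target, f"{member_id}_label_right.nii.gz"))
        mags = np.linalg.norm(ffd.displacements.reshape(-1, 3), axis=1)
        rows.append(
            {
                "id": member_id,
                "role": role,
                "seed": seed_i,
                "max_displacement_mm": float(mags.max()),
                "mean_displacement_mm": float(mags.mean()),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(str(out_dir), "manifest.csv"), index=False)
    return manifest


def simulate_raters(
    truth: LabelMap, p: float, q: float, R: int, seed: int = 0
) -> DecisionStack:
    """R independent raters with sensitivity p and specificity q against truth.

    Each rater reports each foreground voxel with probability p and flips
    each background voxel on with probability 1 − q, independently.
    """
    if not (0.0 < p <= 1.0) or not (0.0 < q <= 1.0):
        raise ValidationError("sensitivity and specificity must lie in (0, 1]")
    if R < 1:
        raise ValidationError("need at least one rater")
    rng = np.random.default_rng(seed)
    fg = truth.voxels.astype(bool)
    decisions, ids = [], []
    for j in range(R):
        u = rng.random(truth.shape)
        vote = np.where(fg, u < p, u >= q)
        decisions.append(truth.with_voxels(vote.astype(np.uint8)))
        ids.append(f"rater{j:02d}")
    return DecisionStack(decisions, ids)
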