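"""Coarse-to-fine intensity registration: affine, then cubic B-spline FFD.

Both stages optimize a stochastically sampled normalized mutual information
(NMI) by gradient ascent over a Gaussian image pyramid (factor-2 smoothing +
decimation per level). NMI is the Studholme form

    NMI = (H_fixed + H_moving) / H_joint

computed from a bins×bins joint histogram over a fresh random draw of fixed
voxels each iteration; intensities are min–max binned per image per pyramid
level. Identical images give NMI = 2, independent ones approach 1.

The optimizer is stochastic gradient ascent with the decaying gain
``a / (A + t)^alpha`` on a normalized gradient direction. The affine stage
estimates its 12-parameter gradient by central finite differences, all
parameters evaluated on the same sample draw so the paired evaluations
share (and cancel) the sampling noise. The FFD stage uses an analytic
gradient: the moving-value axis of the joint histogram is binned with a
linear Parzen window, making the sampled NMI differentiable in each
sample's moving intensity, and the chain rule through the moving image's
spatial gradient and each sample's 4×4×4 tensor-product support weights
yields the gradient for every control displacement in one pass; a momentum
average tames the per-draw noise.

At the end of every pyramid level the candidate parameters are kept only if
they do not degrade a fixed-seed NMI evaluation, so the registration never
returns a transform worse (under that evaluation) than its starting point.

The fixed→moving map composes as ``affine(ffd(x))``: the FFD deforms
fixed-domain points, where its control grid is defined, and the affine then
carries them into the moving image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError, OptimizationError, OverlapError
from .image_io import LabelMap, Volume, sample_at_physical
from .transforms import (
    AffineTransform,
    BSplineTransform,
    TransformChain,
    bspline_grid_for_domain,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RegistrationConfig",
    "PRESETS",
    "gaussian_pyramid",
    "nmi",
    "register_affine",
    "register_bspline",
    "warp",
    "warp_label",
]


@dataclass
class RegistrationConfig:
    """All tunables of the two-stage registration.

    The ``paper`` preset mirrors the published parameterization (4×1000
    affine, 5×3000 FFD iterations, 5 mm finest grid, factor-2 pyramid, 2000
    metric samples); the ``desk`` preset is scaled for small phantom volumes
    so a full cohort runs in minutes on one CPU.
    """

    affine_levels: int = 2
    affine_iters_per_level: int = 100
    bspline_levels: int = 3
    bspline_iters_per_level: int = 200
    grid_spacing_mm: float = 5.0
    pyramid_factor: int = 2
    metric_samples: int = 2000
    histogram_bins: int = 32
    step_a: float = 2.0
    step_big_a: float = 20.0
    step_alpha: float = 0.602
    affine_step_a: float = 3.0
    affine_step_big_a: float = 30.0
    momentum: float = 0.95
    grad_eps_mm: float = 0.4
    grad_smooth_vox: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "affine_levels",
            "affine_iters_per_level",
            "bspline_levels",
            "bspline_iters_per_level",
            "pyramid_factor",
            "metric_samples",
            "histogram_bins",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.grid_spacing_mm <= 0:
            raise ConfigError("grid_spacing_mm must be > 0")


PRESETS = {
    # published parameterization: full-size clinical CT, ~30 min/case
    "paper": dict(
        affine_levels=4,
        affine_iters_per_level=1000,
        bspline_levels=5,
        bspline_iters_per_level=3000,
        grid_spacing_mm=5.0,
        metric_samples=2000,
    ),
    # small-volume phantom scale: minutes per cohort on one CPU
    "desk": dict(
        affine_levels=2,
        affine_iters_per_level=150,
        bspline_levels=3,
        bspline_iters_per_level=200,
        grid_spacing_mm=5.0,
        metric_samples=2000,
    ),
}


def make_config(preset: str | None = None, **overrides) -> RegistrationConfig:
    """A RegistrationConfig from a named preset plus keyword overrides."""
    if preset is None:
        return RegistrationConfig(**overrides)
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; expected one of {sorted(PRESETS)}")
    kw = dict(PRESETS[preset])
    kw.update(overrides)
    return RegistrationConfig(**kw)


# ---------------------------------------------------------------------------
# pyramid
# ---------------------------------------------------------------------------


def gaussian_pyramid(vol: Volume, levels: int, factor: int = 2) -> list[Volume]:
    """Multiresolution pyramid, coarse→fine; the finest level is the input.

    Each decimation smooths with a Gaussian of sigma = factor/2 voxels
    (anti-aliasing) and keeps every ``factor``-th voxel, scaling spacing by
    ``factor`` so the physical extent is preserved to within one voxel.
    Levels that would leave fewer than 4 voxels on some axis are clamped
    with a warning.
    """
    if levels < 1:
        raise ConfigError("levels must be >= 1")
    max_levels = 1
    size = min(vol.shape)
    while size // factor >= 4 and max_levels < levels:
        size = -(-size // factor)
        max_levels += 1
    if max_levels < levels:
        logger.warning(
            "clamping pyramid levels from %d to %d (coarsest level needs >= 4 voxels/axis)",
            levels,
            max_levels,
        )
        levels = max_levels
    pyramid = [vol]
    current = vol
    for _ in range(levels - 1):
        smoothed = ndimage.gaussian_filter(current.voxels.astype(float), sigma=factor / 2.0)
        dec = smoothed[::factor, ::factor, ::factor]
        current = Volume(
            dec, current.spacing * factor, current.origin.copy(), current.direction.copy()
        )
        pyramid.append(current)
    return pyramid[::-1]


# ---------------------------------------------------------------------------
# sampled NMI
# ---------------------------------------------------------------------------


def _entropies(joint: np.ndarray, bins: int) -> tuple[float, float, float]:
    """(H_fixed, H_moving, H_joint) of a flat joint-count array."""
    total = joint.sum()
    pj = joint / total
    nz = pj > 0
    h12 = float(-(pj[nz] * np.log(pj[nz])).sum())
    pf = pj.reshape(bins, bins).sum(axis=1)
    pm = pj.reshape(bins, bins).sum(axis=0)
    nzf, nzm = pf > 0, pm > 0
    h1 = float(-(pf[nzf] * np.log(pf[nzf])).sum())
    h2 = float(-(pm[nzm] * np.log(pm[nzm])).sum())
    return h1, h2, h12


def _bin_values(vals: np.ndarray, lo: float, hi: float, bins: int) -> np.ndarray:
    if hi <= lo:
        return np.zeros(vals.shape, dtype=np.int64)
    b = ((vals - lo) / (hi - lo) * bins).astype(np.int64)
    return np.clip(b, 0, bins - 1)


class _SampledNMI:
    """Sampled-NMI evaluation state for one (fixed level, moving) pair.

    Precomputes what is reusable across metric evaluations: flattened fixed
    intensities, per-image min–max ranges, and the moving image's
    physical→index map. ``evaluate`` draws nothing — callers pass sample
    voxel indices so schedules stay seedable and reproducible.
    """

    def __init__(self, fixed: Volume, moving: Volume, bins: int):
        self.fixed = fixed
        self.moving = moving
        self.bins = bins
        self.fvals = fixed.voxels.ravel().astype(float)
        self.flo, self.fhi = float(self.fvals.min()), float(self.fvals.max())
        self.mlo, self.mhi = float(moving.voxels.min()), float(moving.voxels.max())
        self.mvox = moving.voxels.astype(float)
        self.minv = np.linalg.inv(moving.index_to_physical_matrix)
        self.morigin = moving.origin
        self.mshape = np.asarray(moving.shape, dtype=float)
        self._mgrad = None  # lazy ∂I/∂(world mm), 3 volumes
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in fixed.shape], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        self.points = fixed.index_to_physical(idx)

    def draw(self, rng: np.random.Generator, n: int):
        """Uniform fixed-voxel sample: (physical points, fixed bin indices)."""
        sel = rng.integers(0, self.fvals.size, size=n)
        fb = _bin_values(self.fvals[sel], self.flo, self.fhi, self.bins)
        return self.points[sel], fb

    def moving_index(self, mapped_pts: np.ndarray) -> np.ndarray:
        return (mapped_pts - self.morigin) @ self.minv.T

    def sample_moving(self, mapped_pts: np.ndarray):
        """Linear interpolation of the moving image; returns (values, in_domain)."""
        idx = self.moving_index(mapped_pts)
        ok = np.all((idx >= 0.0) & (idx <= self.mshape - 1.0), axis=1)
        vals = np.zeros(len(idx))
        if ok.any():
            vals[ok] = ndimage.map_coordinates(self.mvox, idx[ok].T, order=1, mode="nearest")
        return vals, ok

    def sample_moving_grad(
        self, mapped_pts: np.ndarray, ok: np.ndarray, smooth_vox: float = 1.0
    ) -> np.ndarray:
        """World-space intensity gradient ∇I_m (mm⁻¹ units) at mapped points.

        The gradient is taken on a lightly Gaussian-smoothed copy of the
        moving image (``smooth_vox`` voxels): acquisition noise otherwise
        contributes spurious gradients in flat regions that swamp the true
        edge signal in the stochastic metric gradient.
        """
        if self._mgrad is None:
            src = (
                ndimage.gaussian_filter(self.mvox, smooth_vox) if smooth_vox > 0 else self.mvox
            )
            gax = np.gradient(src, *self.moving.spacing)
            d = self.moving.direction
            # world gradient = direction · axis gradient
            self._mgrad = [sum(d[a, b] * gax[b] for b in range(3)) for a in range(3)]
        idx = self.moving_index(mapped_pts)
        out = np.zeros((len(idx), 3))
        if ok.any():
            coords = idx[ok].T
            for a in range(3):
                out[ok, a] = ndimage.map_coordinates(
                    self._mgrad[a], coords, order=1, mode="nearest"
                )
        return out

    def joint_hist(self, fb: np.ndarray, mb: np.ndarray, ok: np.ndarray) -> np.ndarray:
        return np.bincount(
            fb[ok] * self.bins + mb[ok], minlength=self.bins * self.bins
        ).astype(float)

    def nmi_from_hist(self, joint: np.ndarray) -> float:
        h1, h2, h12 = _entropies(joint, self.bins)
        if h12 == 0.0:
            return 2.0  # single occupied joint bin: treat as perfectly co-informative
        return (h1 + h2) / h12

    def evaluate(self, pts: np.ndarray, fb: np.ndarray, mapped_pts: np.ndarray, min_overlap: float = 0.5) -> float:
        vals, ok = self.sample_moving(mapped_pts)
        if ok.mean() < min_overlap:
            raise OverlapError(
                f"only {100 * ok.mean():.0f}% of metric samples map inside the moving image"
            )
        mb = _bin_values(vals, self.mlo, self.mhi, self.bins)
        return self.nmi_from_hist(self.joint_hist(fb, mb, ok))

    def evaluate_batch(self, fb: np.ndarray, mapped_batch: np.ndarray, min_overlap: float) -> np.ndarray:
        """NMI for B candidate mappings of the same sample draw, vectorized.

        ``mapped_batch`` has shape (B, n, 3); one interpolation call and one
        bincount serve all candidates.
        """
        b, n, _ = mapped_batch.shape
        idx = self.moving_index(mapped_batch.reshape(-1, 3))
        ok = np.all((idx >= 0.0) & (idx <= self.mshape - 1.0), axis=1)
        vals = np.zeros(b * n)
        if ok.any():
            vals[ok] = ndimage.map_coordinates(self.mvox, idx[ok].T, order=1, mode="nearest")
        mb = _bin_values(vals, self.mlo, self.mhi, self.bins)
        nb = self.bins * self.bins
        block = np.repeat(np.arange(b), n)
        codes = (block * nb + np.tile(fb, b) * self.bins + mb)[ok]
        hists = np.bincount(codes, minlength=b * nb).reshape(b, nb).astype(float)
        out = np.empty(b)
        ok2 = ok.reshape(b, n)
        for i in range(b):
            if ok2[i].mean() < min_overlap:
                raise OverlapError(
                    f"only {100 * ok2[i].mean():.0f}% of metric samples map inside the moving image"
                )
            out[i] = self.nmi_from_hist(hists[i])
        return out


def _soft_nmi_and_sample_grad(state: "_SampledNMI", fb: np.ndarray, mvals: np.ndarray, ok: np.ndarray):
    """Sampled NMI with a linear Parzen window on the moving-intensity axis.

    Returns ``(nmi, g)`` where ``g[i] = ∂NMI/∂v_i`` for each in-domain
    sample's moving intensity v_i (zero for out-of-domain samples). The
    fixed axis stays hard-binned (it never moves during optimization), so
    only the moving marginal and the joint entropy carry gradient.
    """
    bins = state.bins
    n = int(ok.sum())
    if n == 0:
        raise OverlapError("no metric samples inside the moving image")
    span = max(state.mhi - state.mlo, 1e-12)
    s = bins / span
    bpos = np.clip((mvals[ok] - state.mlo) * s - 0.5, 1e-6, bins - 1 - 1e-6)
    k0 = np.minimum(bpos.astype(np.int64), bins - 2)
    f = bpos - k0
    fbo = fb[ok]
    joint = np.zeros(bins * bins)
    np.add.at(joint, fbo * bins + k0, (1.0 - f) / n)
    np.add.at(joint, fbo * bins + k0 + 1, f / n)
    pm = joint.reshape(bins, bins).sum(axis=0)
    pf = joint.reshape(bins, bins).sum(axis=1)
    nzj, nzm, nzf = joint > 0, pm > 0, pf > 0
    h12 = float(-(joint[nzj] * np.log(joint[nzj])).sum())
    h2 = float(-(pm[nzm] * np.log(pm[nzm])).sum())
    h1 = float(-(pf[nzf] * np.log(pf[nzf])).sum())
    value = 2.0 if h12 == 0 else (h1 + h2) / h12
    # ∂H/∂v_i: moving sample i shifts mass 1/n between bins (k0, k0+1)
    eps = 1e-12
    lj0 = np.log(np.maximum(joint[fbo * bins + k0], eps))
    lj1 = np.log(np.maximum(joint[fbo * bins + k0 + 1], eps))
    lm0 = np.log(np.maximum(pm[k0], eps))
    lm1 = np.log(np.maximum(pm[k0 + 1], eps))
    dh12 = (s / n) * (lj0 - lj1)
    dh2 = (s / n) * (lm0 - lm1)
    g = np.zeros(ok.shape)
    if h12 > 0:
        g[ok] = (dh2 * h12 - (h1 + h2) * dh12) / h12**2
    return value, g


def nmi(
    fixed: Volume,
    moving: Volume,
    chain: TransformChain | None = None,
    samples: int = 2000,
    bins: int = 32,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Sampled normalized mutual information (H1 + H2) / H12.

    Draws ``samples`` fixed-grid voxels uniformly at random (seeded via
    ``rng``), maps them through ``chain`` (identity if None), interpolates
    the moving image linearly, and evaluates NMI on a bins×bins joint
    histogram. Raises :class:`OverlapError` if fewer than half the samples
    land inside the moving image.
    """
    if samples < bins:
        raise ConfigError("need at least as many samples as histogram bins")
    rng = np.random.default_rng(rng)
    chain = chain or TransformChain()
    state = _SampledNMI(fixed, moving, bins)
    pts, fb = state.draw(rng, samples)
    return state.evaluate(pts, fb, chain.map_points(pts))


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------


def _gain(cfg: RegistrationConfig, t: int) -> float:
    return cfg.step_a / (cfg.step_big_a + t + 1.0) ** cfg.step_alpha


def _affine_gain(cfg: RegistrationConfig, t: int) -> float:
    # the finite-difference affine gradient is low-noise, so it tolerates a
    # larger, slower-decaying gain than the stochastic FFD gradient
    return cfg.affine_step_a / (cfg.affine_step_big_a + t + 1.0) ** cfg.step_alpha


def _affine_from_params(q: np.ndarray, center: np.ndarray, scale: float) -> AffineTransform:
    mat = np.eye(3) + q[:9].reshape(3, 3) / scale
    return AffineTransform(mat, q[9:], center)


def _check_finite(value: float, stage: str, level: int, it: int) -> None:
    if not np.isfinite(value):
        raise OptimizationError(
            f"{stage} metric became non-finite at level {level}, iteration {it}"
        )


def register_affine(
    fixed: Volume, moving: Volume, cfg: RegistrationConfig | None = None
) -> AffineTransform:
    """Multiresolution affine registration maximizing sampled NMI.

    Parameters are the 9 entries of the linear part (scaled by the fixed
    domain radius so all 12 parameters share mm units) plus the mm
    translation; the rotation center is the fixed image's physical center.
    """
    cfg = cfg or RegistrationConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    eval_rng_seed = int(np.random.default_rng(cfg.rng_seed + 1).integers(2**31))
    pyr_f = gaussian_pyramid(fixed, cfg.affine_levels, cfg.pyramid_factor)
    pyr_m = gaussian_pyramid(moving, cfg.affine_levels, cfg.pyramid_factor)
    center = fixed.index_to_physical((np.asarray(fixed.shape) - 1) / 2.0)[0]
    scale = 0.5 * float(np.linalg.norm(fixed.physical_extent))
    q = np.zeros(12)
    eps = cfg.grad_eps_mm
    for level, (flev, mlev) in enumerate(zip(pyr_f, pyr_m)):
        state = _SampledNMI(flev, mlev, cfg.histogram_bins)
        q_start = q.copy()
        for t in range(cfg.affine_iters_per_level):
            # central differences per parameter, all on the SAME sample draw:
            # the paired evaluations share sampling noise, so the difference
            # is the low-variance macroscopic metric slope
            pts, fb = state.draw(rng, cfg.metric_samples)
            mapped = np.empty((24, len(pts), 3))
            for j in range(12):
                for si, sign in enumerate((+1.0, -1.0)):
                    qp = q.copy()
                    qp[j] += sign * eps
                    mapped[2 * j + si] = _affine_from_params(qp, center, scale).apply(pts)
            vals = state.evaluate_batch(fb, mapped, min_overlap=0.2)
            grad = (vals[0::2] - vals[1::2]) / (2 * eps)
            gnorm = float(np.linalg.norm(grad))
            _check_finite(gnorm, "affine", level, t)
            if gnorm > 0:
                q += _affine_gain(cfg, t) * grad / gnorm
        # keep-better safeguard under a fixed evaluation seed
        q = _keep_better_affine(state, q_start, q, center, scale, cfg, eval_rng_seed, level)
    return _affine_from_params(q, center, scale)


def _keep_better_affine(state, q_start, q_end, center, scale, cfg, seed, level):
    ev = np.random.default_rng(seed + level)
    pts, fb = state.draw(ev, 2 * cfg.metric_samples)
    v0 = state.evaluate(pts, fb, _affine_from_params(q_start, center, scale).apply(pts), min_overlap=0.2)
    v1 = state.evaluate(pts, fb, _affine_from_params(q_end, center, scale).apply(pts), min_overlap=0.2)
    logger.info("affine level %d: NMI %.4f -> %.4f", level, v0, v1)
    return q_end if v1 >= v0 else q_start


def _ffd_grid_levels(fixed: Volume, cfg: RegistrationConfig, levels: int) -> list[float]:
    """Finest-first doubling grid schedule, coarsest capped at the domain extent."""
    max_spacing = float(max(fixed.physical_extent))
    out = []
    for lev in range(levels):  # lev 0 = coarsest
        s = cfg.grid_spacing_mm * 2 ** (levels - 1 - lev)
        out.append(min(s, max_spacing))
    return out


def register_bspline(
    fixed: Volume,
    moving: Volume,
    init: AffineTransform | None = None,
    cfg: RegistrationConfig | None = None,
) -> BSplineTransform:
    """Multiresolution FFD registration composed after an affine initialization.

    The control grid always covers the fixed-image physical domain with a
    full cubic-support margin; its spacing halves per level down to
    ``cfg.grid_spacing_mm``, and each new level's control displacements are
    seeded by evaluating the previous level's FFD at the new control
    points. The optimized map is ``x ↦ init(x + d(x))``.
    """
    cfg = cfg or RegistrationConfig()
    init = init or AffineTransform.identity(
        fixed.index_to_physical((np.asarray(fixed.shape) - 1) / 2.0)[0]
    )
    rng = np.random.default_rng(cfg.rng_seed + 7)
    eval_rng_seed = int(np.random.default_rng(cfg.rng_seed + 8).integers(2**31))
    pyr_f = gaussian_pyramid(fixed, cfg.bspline_levels, cfg.pyramid_factor)
    pyr_m = gaussian_pyramid(moving, cfg.bspline_levels, cfg.pyramid_factor)
    levels = len(pyr_f)
    spacings = _ffd_grid_levels(fixed, cfg, levels)
    domain_origin = fixed.origin - fixed.spacing  # half-voxel slack either side
    domain_extent = fixed.physical_extent + 2 * fixed.spacing
    ffd: BSplineTransform | None = None
    for level in range(levels):
        go, gs, gshape = bspline_grid_for_domain(domain_origin, domain_extent, spacings[level])
        new = BSplineTransform.zero(go, gs, gshape)
        if ffd is not None:
            cp_idx = np.stack(
                np.meshgrid(*[np.arange(n) for n in gshape], indexing="ij"), axis=-1
            ).reshape(-1, 3)
            cp_pts = cp_idx * gs + go
            # approximate refinement: previous displacement field sampled at
            # the new control points (clamped into the old grid's support)
            lo = ffd.grid_origin + ffd.grid_spacing
            hi = ffd.grid_origin + (np.asarray(ffd.grid_shape) - 3) * ffd.grid_spacing
            cp_clamped = np.clip(cp_pts, lo, hi - 1e-9)
            new.displacements = ffd.displacement(cp_clamped).reshape(gshape + (3,))
        ffd = new
        ffd = _optimize_ffd_level(
            pyr_f[level], pyr_m[level], init, ffd, cfg, rng, eval_rng_seed, level
        )
    return ffd


def _optimize_ffd_level(flev, mlev, init, ffd, cfg, rng, eval_seed, level):
    state = _SampledNMI(flev, mlev, cfg.histogram_bins)
    amat = init.matrix
    phi_start = ffd.displacements.copy()
    phi_flat = ffd.displacements.reshape(-1, 3)
    momentum = np.zeros_like(phi_flat)
    ncp = phi_flat.shape[0]
    for t in range(cfg.bspline_iters_per_level):
        pts, fb = state.draw(rng, cfg.metric_samples)
        disp = ffd.displacement(pts)
        mapped = init.apply(pts + disp)
        mvals, ok = state.sample_moving(mapped)
        if ok.mean() < 0.2:
            raise OverlapError("FFD optimization lost image overlap")
        value, g = _soft_nmi_and_sample_grad(state, fb, mvals, ok)
        _check_finite(value, "bspline", level, t)
        gradm = state.sample_moving_grad(mapped, ok, cfg.grad_smooth_vox)
        # ∂v_i/∂φ_{c,ax} = (Mᵀ∇I)_ax · w_{i,c}  (the FFD acts before the affine)
        coeff = g[:, None] * (gradm @ amat)  # (n, 3)
        sup_idx, sup_w = ffd.support_weights(pts)
        flat_idx = sup_idx.ravel()
        grad = np.empty_like(phi_flat)
        for ax in range(3):
            grad[:, ax] = np.bincount(
                flat_idx, weights=(coeff[:, ax : ax + 1] * sup_w).ravel(), minlength=ncp
            )
        _check_finite(float(np.abs(grad).sum()), "bspline", level, t)
        momentum = cfg.momentum * momentum + (1 - cfg.momentum) * grad
        mnorm = float(np.linalg.norm(momentum))
        if mnorm > 0:
            phi_flat += _gain(cfg, t) * momentum / mnorm
    # keep-better safeguard under a fixed evaluation seed
    ev = np.random.default_rng(eval_seed + level)
    pts, fb = state.draw(ev, 2 * cfg.metric_samples)
    chain_end = TransformChain([init, ffd])
    v1 = state.evaluate(pts, fb, chain_end.map_points(pts), min_overlap=0.2)
    ffd_start = BSplineTransform(ffd.grid_origin, ffd.grid_spacing, ffd.grid_shape, phi_start)
    v0 = state.evaluate(pts, fb, TransformChain([init, ffd_start]).map_points(pts), min_overlap=0.2)
    logger.info("bspline level %d: NMI %.4f -> %.4f", level, v0, v1)
    return ffd if v1 >= v0 else ffd_start


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------


def warp(
    vol: Volume,
    chain: TransformChain,
    reference: Volume,
    interpolation: str = "cubic-bspline",
    cval: float | None = None,
) -> Volume:
    """Resample ``vol`` through the fixed→moving chain onto the reference grid.

    Gray images default to cubic B-spline interpolation (the final-result
    convention; the optimizer itself samples linearly). Out-of-domain voxels
    get ``cval`` (default: the input's minimum intensity).
    """
    ref_idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in reference.shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    pts = chain.map_points(reference.index_to_physical(ref_idx))
    fill = float(vol.voxels.min()) if cval is None else cval
    vals, _ = sample_at_physical(vol, pts, interpolation, fill)
    return Volume(vals.reshape(reference.shape), reference.spacing, reference.origin, reference.direction)


def warp_label(label: LabelMap, chain: TransformChain, reference: Volume) -> LabelMap:
    """Propagate a binary label with nearest-neighbor interpolation (stays binary)."""
    ref_idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in reference.shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    pts = chain.map_points(reference.index_to_physical(ref_idx))
    vals, _ = sample_at_physical(label, pts, "nearest", 0.0)
    return LabelMap(
        np.round(vals.reshape(reference.shape)).astype(np.uint8),
        reference.spacing,
        reference.origin,
        reference.direction,
    )
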