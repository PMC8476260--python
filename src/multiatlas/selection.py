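"""Atlas selection by normalized cross-correlation (NCC) against the fixed image.

NCC between the fixed image TI and a moving image FI over their n shared
voxels is the mean-centered, variance-normalized correlation

    NCC = Σ (TI_i − TI̅)(FI_i − FI̅) / sqrt(Σ (TI_i − TI̅)² · Σ (FI_i − FI̅)²)

bounded in [−1, 1] and invariant to positive affine intensity rescaling —
the property that makes it robust to nonstandard intensity calibration
between scanners. Atlases are ranked by NCC after a direct (identity
alignment) resample onto the fixed grid, restricted to voxels inside both
image domains, and the top k (default 10) are passed on to registration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DegenerateInputError, GeometryError, ValidationError
from .image_io import Atlas, Volume, sample_at_physical

logger = logging.getLogger(__name__)

__all__ = ["SimilarityScore", "ncc", "rank_atlases", "select_top_k"]


@dataclass
class SimilarityScore:
    atlas_id: str
    ncc: float


def _ncc_arrays(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise GeometryError("NCC requires equally sized voxel sets")
    if a.size < 2:
        raise DegenerateInputError("NCC needs at least 2 voxels")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da @ da) * (db @ db))
    if denom == 0.0:
        raise DegenerateInputError("NCC undefined for a constant image (zero variance)")
    return float(np.clip((da @ db) / denom, -1.0, 1.0))


def ncc(fixed: Volume, moving: Volume, mask: np.ndarray | None = None) -> float:
    """Normalized cross-correlation of two volumes on a common grid.

    The caller resamples ``moving`` onto ``fixed``'s grid first; ``mask``
    optionally restricts the comparison (e.g. to the overlap of both
    domains).
    """
    if fixed.shape != moving.shape:
        raise GeometryError(
            f"volumes must share a grid for NCC: {fixed.shape} vs {moving.shape}"
        )
    a, b = fixed.voxels, moving.voxels
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        a, b = a[mask], b[mask]
    return _ncc_arrays(a, b)


def rank_atlases(fixed: Volume, atlases: list[Atlas]) -> list[SimilarityScore]:
    """Rank atlases by NCC to the fixed image, best first.

    Each atlas gray volume is resampled onto the fixed grid (linear,
    identity alignment); the correlation runs over voxels inside both
    domains. Ties are broken by atlas id so the ranking is deterministic.
    """
    if not atlases:
        raise ValidationError("rank_atlases needs at least one atlas")
    fid = np.stack(
        np.meshgrid(*[np.arange(n) for n in fixed.shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    pts = fixed.index_to_physical(fid)
    fvals = fixed.voxels.ravel().astype(float)
    scores = []
    for atlas in atlases:
        vals, in_dom = sample_at_physical(atlas.gray, pts, "linear", cval=0.0)
        if in_dom.sum() < 2:
            raise GeometryError(
                f"atlas {atlas.id!r} does not overlap the fixed image domain"
            )
        scores.append(SimilarityScore(atlas.id, _ncc_arrays(fvals[in_dom], vals[in_dom])))
    scores.sort(key=lambda s: (-s.ncc, s.atlas_id))
    return scores


def select_top_k(ranked: list[SimilarityScore], k: int) -> list[str]:
    """Ids of the k best-ranked atlases (order preserved, clipped with a warning)."""
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    if k > len(ranked):
        logger.warning(
            "requested k=%d atlases but only %d are ranked; using all", k, len(ranked)
        )
    return [s.atlas_id for s in ranked[:k]]
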