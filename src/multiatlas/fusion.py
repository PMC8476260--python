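"""Label fusion: majority vote, STAPLE, and SIMPLE.

Each propagated atlas label acts as a weak classifier voting per voxel.

* Majority vote (MV): foreground iff strictly more than half the raters say
  foreground; an even split is background (conservative for a small
  puncture-target structure).
* STAPLE: EM jointly estimating a consensus probability map W and per-rater
  performance (sensitivity p_j, specificity q_j). E-step, with a fixed
  foreground prior π and rater decisions d_ij:

      W_i ∝ π Π_j p_j^{d_ij} (1−p_j)^{1−d_ij}
      vs (1−π) Π_j q_j^{1−d_ij} (1−q_j)^{d_ij}

  M-step: p_j = Σ_i W_i d_ij / Σ_i W_i,
          q_j = Σ_i (1−W_i)(1−d_ij) / Σ_i (1−W_i).
  Products run in log space; the consensus is W ≥ 0.5. By default the EM
  statistics are restricted to the union of all rater foregrounds dilated by
  a few voxels — a tiny foreground in a huge background otherwise pins
  specificity at ~1 and washes out the rater weighting.
* SIMPLE: starts from the majority vote, repeatedly scores every retained
  rater by Dice against the current estimate, discards clear under-performers
  (Dice < mean − alpha·std, never dropping below ``min_keep``, worst first),
  and re-fuses the remainder by majority vote until stable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, GeometryError, ValidationError
from .image_io import LabelMap
from .metrics import dice

logger = logging.getLogger(__name__)

__all__ = ["DecisionStack", "FusionResult", "majority_vote", "staple", "simple_fuse"]

_PQ_CLAMP = 1e-5


@dataclass
class DecisionStack:
    """R binary rater/atlas decisions on one common grid."""

    decisions: list
    atlas_ids: list

    def __post_init__(self) -> None:
        if len(self.decisions) < 1:
            raise ValidationError("a decision stack needs at least one rater")
        if len(self.atlas_ids) != len(self.decisions):
            raise ValidationError("atlas_ids and decisions must have equal length")
        ref = self.decisions[0]
        for d in self.decisions[1:]:
            if not ref.same_geometry(d):
                raise GeometryError("all decision maps must share one grid")

    def __len__(self) -> int:
        return len(self.decisions)

    @property
    def array(self) -> np.ndarray:
        """Stacked boolean votes, shape (R,) + grid shape."""
        return np.stack([d.voxels.astype(bool) for d in self.decisions])

    @property
    def grid(self) -> LabelMap:
        return self.decisions[0]


@dataclass
class FusionResult:
    fused: LabelMap
    posterior: np.ndarray | None = None
    performance: dict | None = None
    iterations: int = 0
    converged: bool = True
    method: str = ""
    audit: list = field(default_factory=list)
    log_likelihood: list = field(default_factory=list)


def majority_vote(stack: DecisionStack) -> FusionResult:
    """Per-voxel majority: foreground iff votes > R/2 (even ties → background)."""
    votes = stack.array
    r = votes.shape[0]
    fused = (votes.sum(axis=0) * 2) > r
    return FusionResult(
        fused=stack.grid.with_voxels(fused.astype(np.uint8)), method="mv"
    )


def _staple_roi(votes: np.ndarray, dilate_vox: int | None) -> np.ndarray:
    union = votes.any(axis=0)
    if dilate_vox is None:
        return np.ones(union.shape, dtype=bool)
    # Euclidean dilation by `dilate_vox` voxels via a distance transform
    return ndimage.distance_transform_edt(~union) <= dilate_vox


def staple(
    stack: DecisionStack,
    tol: float = 1e-6,
    max_iter: int = 50,
    prior: float | str = "auto",
    roi_dilation_vox: int | None = 10,
) -> FusionResult:
    """Simultaneous truth and performance level estimation (binary EM).

    Returns the thresholded consensus, the per-voxel posterior W, per-rater
    (sensitivity, specificity), and the iteration count. ``prior`` is the
    foreground prior π, held fixed during EM; ``"auto"`` uses the stack's
    mean foreground fraction over the ROI. Initialization p_j = q_j = 0.9999.
    """
    if len(stack) < 2:
        raise ValidationError("STAPLE needs at least two raters")
    votes = stack.array
    roi = _staple_roi(votes, roi_dilation_vox)
    d = votes[:, roi].astype(float)  # (R, N)
    r, n = d.shape
    if d.sum() == 0 or (1 - d).sum() == 0:
        raise DegenerateInputError(
            "STAPLE needs both foreground and background votes in the stack"
        )
    if prior == "auto":
        pi = float(d.mean())
    else:
        pi = float(prior)
        if not 0.0 < pi < 1.0:
            raise ValidationError(f"foreground prior must lie in (0,1), got {pi}")

    p = np.full(r, 0.9999)
    q = np.full(r, 0.9999)
    w = np.full(n, pi)
    log_pi, log_1mpi = np.log(pi), np.log1p(-pi)
    prev_ll = -np.inf
    ll_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lp, l1p = np.log(p), np.log1p(-p)
        lq, l1q = np.log(q), np.log1p(-q)
        # log P(d_i | T=1), log P(d_i | T=0) per voxel
        loga = log_pi + l1p.sum() + (lp - l1p) @ d
        logb = log_1mpi + lq.sum() + (l1q - lq) @ d
        w_new = 1.0 / (1.0 + np.exp(logb - loga))
        ll = float(np.logaddexp(loga, logb).sum())
        if ll < prev_ll - 1e-9:
            logger.warning("STAPLE log-likelihood decreased at iteration %d", it)
        prev_ll = ll
        ll_trace.append(ll)
        delta = float(np.abs(w_new - w).mean())
        w = w_new
        sw = w.sum()
        p = np.clip((d @ w) / sw, _PQ_CLAMP, 1 - _PQ_CLAMP)
        q = np.clip(((1 - d) @ (1 - w)) / (n - sw), _PQ_CLAMP, 1 - _PQ_CLAMP)
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"STAPLE did not converge within {max_iter} iterations (mean |dW|={delta:.2e})",
            stacklevel=2,
        )
    posterior = np.zeros(votes.shape[1:], dtype=float)
    posterior[roi] = w
    fused = stack.grid.with_voxels((posterior >= 0.5).astype(np.uint8))
    performance = {
        aid: (float(pj), float(qj)) for aid, pj, qj in zip(stack.atlas_ids, p, q)
    }
    return FusionResult(
        fused=fused,
        posterior=posterior,
        performance=performance,
        iterations=it,
        converged=converged,
        method="staple",
        log_likelihood=ll_trace,
    )


def simple_fuse(
    stack: DecisionStack,
    alpha: float = 2.0,
    max_rounds: int = 5,
    min_keep: int = 3,
) -> FusionResult:
    """Selective iterative fusion: discard poor raters, re-fuse by majority.

    Each round scores every retained rater by Dice against the current
    estimate and discards those below mean − alpha·std, worst first, never
    going below ``min_keep`` raters. ``alpha = inf`` never discards, so the
    result equals the plain majority vote. The audit trail records each
    round's per-rater Dice and keep/discard flags.
    """
    if min_keep < 2:
        raise ValidationError("min_keep must be >= 2")
    if len(stack) < min_keep:
        raise ValidationError(f"need at least min_keep={min_keep} raters, got {len(stack)}")
    if not any(d.foreground_count for d in stack.decisions):
        raise DegenerateInputError("all atlases are empty; nothing to fuse")

    kept = list(range(len(stack)))
    estimate = majority_vote(stack).fused
    audit = []
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty-vs-empty Dice is a valid score here
            scores = np.array([dice(stack.decisions[j], estimate) for j in kept])
        thr = scores.mean() - alpha * scores.std()
        below = [j for j, s in zip(kept, scores) if s < thr]
        # ranked discard: drop the worst scorers first, stop at min_keep
        below.sort(key=lambda j: scores[kept.index(j)])
        discard = below[: max(0, len(kept) - min_keep)]
        audit.append(
            {
                "round": rounds,
                "scores": {stack.atlas_ids[j]: float(s) for j, s in zip(kept, scores)},
                "threshold": float(thr) if np.isfinite(thr) else None,
                "discarded": [stack.atlas_ids[j] for j in discard],
            }
        )
        if not discard:
            break
        kept = [j for j in kept if j not in discard]
        sub = DecisionStack(
            [stack.decisions[j] for j in kept], [stack.atlas_ids[j] for j in kept]
        )
        estimate = majority_vote(sub).fused
    return FusionResult(
        fused=estimate,
        performance={stack.atlas_ids[j]: "kept" for j in kept},
        iterations=rounds,
        method="simple",
        audit=audit,
    )
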