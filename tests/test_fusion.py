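"""Majority vote, STAPLE EM, and SIMPLE selective fusion."""

import itertools

import numpy as np
import pytest

from conftest import make_label
from multiatlas.errors import DegenerateInputError, GeometryError, ValidationError
from multiatlas.fusion import DecisionStack, majority_vote, simple_fuse, staple
from multiatlas.phantom import simulate_raters


def _stack(arrays, spacing=(1.0, 1.0, 1.0)):
    return DecisionStack(
        [make_label(np.asarray(a, dtype=np.uint8), spacing) for a in arrays],
        [f"r{i}" for i in range(len(arrays))],
    )


def _vote_stack(votes):
    """One-voxel stack from a tuple of 0/1 votes."""
    return _stack([np.full((1, 1, 1), v) for v in votes])


class TestMajorityVote:
    @pytest.mark.parametrize(
        "votes,expected",
        [((1, 1, 0), 1), ((1, 0, 0), 0), ((1, 1, 0, 0), 0), ((1,) * 5 + (0,) * 5, 0), ((1, 0), 0)],
    )
    def test_vote_patterns_and_tie_rule(self, votes, expected):
        assert majority_vote(_vote_stack(votes)).fused.voxels.item() == expected

    def test_single_rater_returns_input(self):
        rng = np.random.default_rng(0)
        m = (rng.random((5, 5, 5)) > 0.5).astype(np.uint8)
        out = majority_vote(_stack([m]))
        assert np.array_equal(out.fused.voxels, m)

    @pytest.mark.parametrize("r", [3, 5])
    def test_matches_exhaustive_enumeration(self, r):
        # oracle: all 2^r vote patterns, one voxel per pattern
        patterns = np.array(list(itertools.product([0, 1], repeat=r)), dtype=np.uint8)
        arrays = [patterns[:, j].reshape(-1, 1, 1) for j in range(r)]
        fused = majority_vote(_stack(arrays)).fused.voxels.ravel()
        expected = np.array([1 if sum(p) * 2 > r else 0 for p in patterns])
        assert np.array_equal(fused, expected)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        arrays = [(rng.random((4, 4, 4)) > 0.5).astype(np.uint8) for _ in range(5)]
        a = majority_vote(_stack(arrays)).fused.voxels
        b = majority_vote(_stack(arrays[::-1])).fused.voxels
        assert np.array_equal(a, b)

    def test_mismatched_grids(self):
        a = make_label(np.zeros((3, 3, 3), np.uint8), (1, 1, 1))
        b = make_label(np.zeros((3, 3, 3), np.uint8), (2, 2, 2))
        with pytest.raises(GeometryError):
            DecisionStack([a, b], ["a", "b"])


class TestStaple:
    def _generative(self, seed=0, n=(50, 50, 40), p=0.90, q=0.95, r=10):
        truth = np.zeros(n, np.uint8)
        truth[:, :, : int(n[2] * 0.3)] = 1  # 30% foreground
        tl = make_label(truth)
        stack = simulate_raters(tl, p, q, r, seed=seed)
        return tl, stack

    def test_unanimous_foreground_posterior_near_one(self):
        arrays = [np.ones((2, 2, 2), np.uint8) for _ in range(5)]
        arrays = [a.copy() for a in arrays]
        for a in arrays:
            a[0, 0, 0] = 0  # keep background present
        res = staple(_stack(arrays), prior=0.3, roi_dilation_vox=None)
        assert res.posterior[1, 1, 1] > 0.99
        assert res.fused.voxels[1, 1, 1] == 1

    def test_perfect_raters_fixed_point(self):
        rng = np.random.default_rng(2)
        m = (rng.random((6, 6, 6)) > 0.6).astype(np.uint8)
        res = staple(_stack([m] * 4), roi_dilation_vox=None)
        for pj, qj in res.performance.values():
            assert pj >= 0.999 and qj >= 0.999
        assert np.array_equal(res.fused.voxels, m)

    def test_generative_parameter_recovery(self):
        # Monte-Carlo check of the EM estimates on 1e5 voxels
        tl, stack = self._generative()
        res = staple(stack)
        truth = tl.voxels.astype(bool)
        acc_fused = (res.fused.voxels.astype(bool) == truth).mean()
        for j, (aid, (pj, qj)) in enumerate(res.performance.items()):
            assert pj == pytest.approx(0.90, abs=0.02)
            assert qj == pytest.approx(0.95, abs=0.02)
            acc_j = (stack.decisions[j].voxels.astype(bool) == truth).mean()
            assert acc_fused > acc_j
        assert res.converged

    def test_log_likelihood_monotone(self):
        _, stack = self._generative(seed=3, n=(20, 20, 20))
        res = staple(stack)
        ll = np.asarray(res.log_likelihood)
        assert np.all(np.diff(ll) >= -1e-9)

    def test_posterior_bounds(self):
        _, stack = self._generative(seed=4, n=(15, 15, 15), r=6)
        res = staple(stack)
        assert np.all(res.posterior >= 0.0) and np.all(res.posterior <= 1.0)

    def test_permutation_invariance_of_posterior(self):
        _, stack = self._generative(seed=5, n=(12, 12, 12), r=5)
        res1 = staple(stack)
        perm = [3, 1, 4, 0, 2]
        stack2 = DecisionStack(
            [stack.decisions[i] for i in perm], [stack.atlas_ids[i] for i in perm]
        )
        res2 = staple(stack2)
        assert np.abs(res1.posterior - res2.posterior).max() < 1e-10

    def test_needs_two_raters_and_mixed_votes(self):
        m = np.ones((3, 3, 3), np.uint8)
        with pytest.raises(ValidationError):
            staple(_stack([m]))
        with pytest.raises(DegenerateInputError):
            staple(_stack([m, m]), roi_dilation_vox=None)


class TestSimple:
    def test_identical_atlases_fixed_point(self):
        rng = np.random.default_rng(6)
        m = (rng.random((5, 5, 5)) > 0.5).astype(np.uint8)
        res = simple_fuse(_stack([m] * 5))
        assert np.array_equal(res.fused.voxels, m)
        assert all(not r["discarded"] for r in res.audit)

    def test_inverted_atlas_discarded_first_round(self):
        rng = np.random.default_rng(7)
        truth = np.zeros((10, 10, 10), np.uint8)
        truth[3:7, 3:7, 3:7] = 1
        tl = make_label(truth)
        stack = simulate_raters(tl, 0.95, 0.95, 9, seed=1)
        inverted = tl.with_voxels(1 - truth)
        bad = DecisionStack(stack.decisions + [inverted], stack.atlas_ids + ["inverted"])
        res = simple_fuse(bad)
        assert "inverted" in res.audit[0]["discarded"]
        assert "inverted" not in res.performance

    def test_alpha_infinity_equals_majority_vote(self):
        rng = np.random.default_rng(8)
        arrays = [(rng.random((6, 6, 6)) > 0.5).astype(np.uint8) for _ in range(7)]
        stack = _stack(arrays)
        res = simple_fuse(stack, alpha=np.inf, max_rounds=5)
        assert np.array_equal(res.fused.voxels, majority_vote(stack).fused.voxels)
        assert all(not r["discarded"] for r in res.audit)

    def test_min_keep_respected(self):
        rng = np.random.default_rng(9)
        truth = np.zeros((8, 8, 8), np.uint8)
        truth[2:6, 2:6, 2:6] = 1
        tl = make_label(truth)
        good = simulate_raters(tl, 0.95, 0.95, 3, seed=2)
        noise = [
            tl.with_voxels((rng.random(truth.shape) > 0.5).astype(np.uint8)) for _ in range(4)
        ]
        stack = DecisionStack(good.decisions + noise, good.atlas_ids + [f"n{i}" for i in range(4)])
        res = simple_fuse(stack, alpha=0.5, max_rounds=10, min_keep=3)
        assert len(res.performance) >= 3

    def test_all_empty_degenerate(self):
        e = np.zeros((3, 3, 3), np.uint8)
        with pytest.raises(DegenerateInputError):
            simple_fuse(_stack([e] * 4))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(10)
        truth = np.zeros((8, 8, 8), np.uint8)
        truth[2:6, 2:6, 2:6] = 1
        stack = simulate_raters(make_label(truth), 0.9, 0.95, 6, seed=3)
        res1 = simple_fuse(stack)
        perm = [5, 0, 3, 1, 4, 2]
        stack2 = DecisionStack(
            [stack.decisions[i] for i in perm], [stack.atlas_ids[i] for i in perm]
        )
        res2 = simple_fuse(stack2)
        assert np.array_equal(res1.fused.voxels, res2.fused.voxels)
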