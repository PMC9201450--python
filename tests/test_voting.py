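"""Voting aggregators and weak/mixed losses against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from patchvote._tensor import Tensor
from patchvote.voting import (LossSpec, PatchHead, VotingSpec, downsample_mask,
                              focal_weak_loss, mixed_loss,
                              naive_lse_reference, soft_dice, vote,
                              vote_adaptive_lse, vote_average, vote_lse,
                              vote_max)

grids = arrays(np.float64, st.tuples(st.integers(1, 6), st.integers(1, 6)),
               elements=st.floats(0.0, 1.0, allow_nan=False))


class TestLseVoting:
    def test_uniform_grid_is_fixed_point(self):
        for r in (0.5, 8.0, 50.0):
            assert vote_lse(np.full((3, 4), 0.5), r) == pytest.approx(0.5)

    def test_two_patch_hand_value(self):
        expected = naive_lse_reference(np.array([0.2, 0.8]), 8.0)
        assert vote_lse([0.2, 0.8], 8.0) == pytest.approx(expected, abs=1e-12)
        assert vote_lse([0.2, 0.8], 8.0) == pytest.approx(0.71439, abs=1e-5)

    def test_limits_mean_and_max(self):
        grid = np.array([0.2, 0.8])
        assert vote_lse(grid, 1e-3) == pytest.approx(0.5, abs=1e-3)
        assert vote_lse(grid, 1e4) == pytest.approx(0.8, abs=1e-3)

    @settings(max_examples=200, deadline=None)
    @given(grids, st.floats(0.1, 50.0))
    def test_stable_equals_naive_summation(self, grid, r):
        assert vote_lse(grid, r) == pytest.approx(
            naive_lse_reference(grid, r), abs=1e-6)

    @settings(max_examples=100, deadline=None)
    @given(grids, st.floats(0.1, 40.0))
    def test_bracketed_by_mean_and_max_and_monotone_in_r(self, grid, r):
        v = vote_lse(grid, r)
        assert grid.mean() - 1e-9 <= v <= grid.max() + 1e-9
        assert vote_lse(grid, r + 1.0) >= v - 1e-9

    def test_invalid_r_raises(self):
        with pytest.raises(ValueError):
            vote_lse([0.5], 0.0)


class TestAdaptiveLseVoting:
    def test_uniform_grid_reduces_to_lse(self):
        grid = np.full((2, 3), 0.7)
        assert vote_adaptive_lse(grid, 8.0, 0.6) == pytest.approx(
            vote_lse(grid, 8.0))

    def test_hand_value_with_exclusion(self):
        # grid [0.2, 0.8], t=0.6: 0.2 < 0.48 is excluded, normalizer stays 2
        expected = (6.4 - np.log(2)) / 8
        assert vote_adaptive_lse([0.2, 0.8], 8.0, 0.6) == pytest.approx(
            expected, abs=1e-5)

    def test_vanishing_threshold_recovers_lse(self, rng):
        grid = rng.uniform(size=(4, 4))
        assert vote_adaptive_lse(grid, 8.0, 1e-9) == pytest.approx(
            vote_lse(grid, 8.0), abs=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(grids, st.floats(0.5, 20.0), st.floats(0.01, 1.0))
    def test_never_exceeds_plain_lse(self, grid, r, t):
        assert vote_adaptive_lse(grid, r, t) <= vote_lse(grid, r) + 1e-9

    def test_gradient_gate(self):
        g = Tensor(np.array([0.2, 0.5, 0.8]), requires_grad=True)
        vote_adaptive_lse(g, 8.0, 0.8).backward()
        assert g.grad[0] == 0 and g.grad[1] == 0  # excluded patches
        assert g.grad[2] > 0


class TestSimpleVoting:
    def test_definitions(self):
        assert vote_average([0.2, 0.8]) == pytest.approx(0.5)
        assert vote_max([0.2, 0.8]) == pytest.approx(0.8)

    def test_single_patch_degenerate(self):
        for f in (vote_average, vote_max):
            assert f(np.array([[0.37]])) == pytest.approx(0.37)
        assert vote_lse(np.array([[0.37]]), 8.0) == pytest.approx(0.37)

    @settings(max_examples=200, deadline=None)
    @given(grids)
    def test_ordering_mean_lse_max(self, grid):
        lse = vote_lse(grid, 8.0)
        assert vote_average(grid) - 1e-9 <= lse <= vote_max(grid) + 1e-9

    @settings(max_examples=60, deadline=None)
    @given(grids, st.integers(0, 2 ** 31 - 1))
    def test_permutation_invariance(self, grid, seed):
        perm = np.random.default_rng(seed).permutation(grid.size)
        shuffled = grid.ravel()[perm].reshape(grid.shape)
        spec = VotingSpec(mode="adaptive_lse", r=8.0, t=0.6)
        for mode in ("average", "max", "lse", "adaptive_lse"):
            spec2 = VotingSpec(mode=mode)
            assert vote(shuffled, spec2) == pytest.approx(vote(grid, spec2),
                                                          abs=1e-9)


class TestFocalWeakLoss:
    def test_gamma_zero_is_balanced_cross_entropy(self):
        spec = LossSpec(alpha=0.5, gamma=0.0)
        assert focal_weak_loss([0.5], [1], spec) == pytest.approx(
            0.5 * np.log(2), abs=1e-6)

    def test_hand_values_at_canonical_parameters(self):
        spec = LossSpec(alpha=0.6, gamma=2.0)
        assert focal_weak_loss([0.9], [1], spec) == pytest.approx(6.32e-4, abs=1e-6)
        assert focal_weak_loss([0.9], [0], spec) == pytest.approx(0.74604, abs=1e-5)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0.01, 0.99), st.integers(0, 1))
    def test_non_negative_and_gamma0_equals_weighted_ce(self, p, y):
        spec = LossSpec(alpha=0.6, gamma=0.0)
        loss = focal_weak_loss([p], [y], spec)
        ce = -0.6 * y * np.log(p) - 0.4 * (1 - y) * np.log(1 - p)
        assert loss >= 0
        assert loss == pytest.approx(ce, rel=1e-9)

    def test_batch_reduction_is_mean_over_samples(self):
        spec = LossSpec(alpha=0.6, gamma=2.0)
        a = focal_weak_loss([[0.9], [0.3]], [[1], [0]], spec)
        b = (focal_weak_loss([0.9], [1], spec) + focal_weak_loss([0.3], [0], spec)) / 2
        assert a == pytest.approx(b, rel=1e-12)

    def test_extreme_probabilities_are_clamped_finite(self):
        spec = LossSpec()
        assert np.isfinite(focal_weak_loss([1.0], [0], spec))
        assert np.isfinite(focal_weak_loss([0.0], [1], spec))


class TestPatchHead:
    def test_output_in_unit_interval_and_shape(self, rng):
        head = PatchHead(12, n_classes=3, hidden=8, rng=np.random.default_rng(0))
        out = head(Tensor(rng.normal(size=(2, 12, 4, 4))))
        assert out.shape == (2, 3, 4, 4)
        assert (out.data > 0).all() and (out.data < 1).all()

    def test_zero_weights_give_half_probability(self):
        head = PatchHead(5, hidden=4, rng=np.random.default_rng(0))
        for p in head.parameters():
            p.data[:] = 0
        out = head(Tensor(np.random.default_rng(1).normal(size=(1, 5, 2, 2))))
        np.testing.assert_allclose(out.data, 0.5)


class TestMixedLoss:
    def _setup(self, probs, mask):
        grids = Tensor(np.asarray(probs)[None, None], requires_grad=True)
        image = Tensor(np.array([[0.9]]))
        labels = np.array([[1.0]])
        return grids, image, labels, [mask]

    def test_dice_term_hand_values(self):
        spec = LossSpec(supervision="mixed", dice_smooth=0.0)
        probs = Tensor(np.array([[1.0, 0.0], [0.0, 0.0]]))
        same = np.array([[1, 0], [0, 0]])
        other = np.array([[0, 1], [0, 0]])
        assert float(soft_dice(probs, same, 0.0).data) == pytest.approx(0.0)
        assert float(soft_dice(probs, other, 0.0).data) == pytest.approx(1.0)

    def test_all_background_with_smoothing_scores_zero_dice(self):
        probs = Tensor(np.zeros((2, 2)))
        assert float(soft_dice(probs, np.zeros((2, 2)), 1.0).data) == pytest.approx(0.0)

    def test_perfect_prediction_drives_both_terms_to_zero(self):
        spec = LossSpec(supervision="mixed")
        mask = np.zeros((32, 32), dtype=bool)
        mask[:16, :16] = True  # exactly one positive patch
        probs = np.full((2, 2), 1e-6)
        probs[0, 0] = 1 - 1e-6
        grids, image, labels, masks = self._setup(probs, mask)
        loss = mixed_loss(grids, image, labels, masks, spec)
        assert float(loss.data) < 1e-3

    def test_unmasked_batch_falls_back_to_weak_loss(self, caplog):
        spec = LossSpec(supervision="mixed")
        grids = Tensor(np.full((1, 1, 2, 2), 0.5))
        image = Tensor(np.array([[0.5]]))
        labels = np.array([[1.0]])
        import logging
        with caplog.at_level(logging.WARNING, logger="patchvote.voting"):
            loss = mixed_loss(grids, image, labels, [None], spec)
        weak = focal_weak_loss(image, labels, spec)
        assert float(loss.data) == pytest.approx(float(weak.data))
        assert any("no masked sample" in r.message for r in caplog.records)

    def test_downsample_majority_rule(self):
        mask = np.zeros((32, 32))
        mask[:16, :8] = 1    # 50% of the top-left patch -> positive
        mask[16:24, :8] = 1  # 25% of the bottom-left patch -> negative
        out = downsample_mask(mask, patch=16)
        assert out.tolist() == [[True, False], [False, False]]
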