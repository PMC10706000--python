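"""Alignment and generation losses against explicit summation oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from graphgpt import (
    GenerationCondition,
    barlow_twins_loss,
    cross_correlation,
    encode,
    generation_loss,
)
from graphgpt.losses import combine
from graphgpt.nn import Tensor


def brute_force_cross_correlation(za, zb):
    """Two-loop evaluation: C_ij = sum_b za[b,i] zb[b,j] / (||za_i|| ||zb_j||)."""
    d = za.shape[1]
    c = np.zeros((d, d))
    for i in range(d):
        for j in range(d):
            num = sum(za[b, i] * zb[b, j] for b in range(za.shape[0]))
            c[i, j] = num / (
                np.sqrt(sum(za[b, i] ** 2 for b in range(za.shape[0])))
                * np.sqrt(sum(zb[b, j] ** 2 for b in range(zb.shape[0])))
            )
    return c


class TestCrossCorrelation:
    def test_identical_unit_columns_give_unit_diagonal(self, rng):
        za = rng.normal(size=(6, 4))
        za /= np.linalg.norm(za, axis=0)
        c = cross_correlation(za, za, standardize=False)
        np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-12)

    def test_sign_flip_gives_negative_diagonal(self, rng):
        za = rng.normal(size=(5, 3))
        c = cross_correlation(za, -za, standardize=False)
        np.testing.assert_allclose(np.diag(c), -1.0, atol=1e-12)

    def test_random_pair_matches_two_loop_oracle(self, rng):
        za = rng.normal(size=(4, 3))
        zb = rng.normal(size=(4, 3))
        c = cross_correlation(za, zb, standardize=False)
        np.testing.assert_allclose(c, brute_force_cross_correlation(za, zb), atol=1e-6)
        # standardized mode equals the oracle applied to centered embeddings
        c_std = cross_correlation(za, zb, standardize=True)
        np.testing.assert_allclose(
            c_std,
            brute_force_cross_correlation(za - za.mean(0), zb - zb.mean(0)),
            atol=1e-6,
        )

    def test_zero_norm_column_error_names_dimension(self, rng):
        za = rng.normal(size=(4, 3))
        za[:, 1] = 0.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            cross_correlation(za, rng.normal(size=(4, 3)), standardize=False)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        arrays(np.float64, (5, 4), elements=st.floats(-10, 10)),
        arrays(np.float64, (5, 4), elements=st.floats(-10, 10)),
    )
    def test_entries_bounded_by_cauchy_schwarz(self, za, zb):
        if np.any(np.linalg.norm(za, axis=0) < 1e-6) or np.any(
            np.linalg.norm(zb, axis=0) < 1e-6
        ):
            return
        c = cross_correlation(za, zb, standardize=False)
        assert (np.abs(c) <= 1.0 + 1e-9).all()


class TestBarlowTwins:
    def test_identity_gives_zero(self):
        assert barlow_twins_loss(np.eye(7)) == 0.0

    def test_zero_matrix_counts_diagonal_terms(self):
        assert barlow_twins_loss(np.zeros((5, 5))) == pytest.approx(5.0)

    def test_single_off_diagonal_weighs_lambda(self):
        c = np.eye(4)
        c[0, 1] = 1.0
        assert barlow_twins_loss(c, lam=0.005) == pytest.approx(0.005)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(arrays(np.float64, (4, 4), elements=st.floats(-3, 3)))
    def test_nonnegative_and_zero_iff_identity(self, c):
        loss = barlow_twins_loss(c)
        assert loss >= 0.0
        if loss == 0.0:
            np.testing.assert_allclose(c, np.eye(4))


class TestGenerationLoss:
    def test_confident_correct_predictions_give_zero(self):
        targets = np.array([[1, 2, 0]])
        logits = np.full((1, 3, 4), -1e4)
        for t, tgt in enumerate(targets[0]):
            logits[0, t, tgt] = 1e4
        assert generation_loss(logits, targets, np.ones((1, 3), bool)) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_logits_give_log_vocab(self):
        v = 11
        logits = np.zeros((2, 5, v))
        targets = np.zeros((2, 5), dtype=int)
        assert generation_loss(logits, targets, np.ones((2, 5), bool)) == pytest.approx(np.log(v))

    def test_masking_matches_per_position_oracle(self, rng):
        logits = rng.normal(size=(2, 4, 6))
        targets = rng.integers(0, 6, size=(2, 4))
        mask = rng.random((2, 4)) > 0.4
        mask[0, 0] = True
        expected_terms = []
        for b in range(2):
            for t in range(4):
                if mask[b, t]:
                    row = logits[b, t]
                    logp = row - np.log(np.exp(row - row.max()).sum()) - row.max()
                    expected_terms.append(-logp[targets[b, t]])
        assert generation_loss(logits, targets, mask) == pytest.approx(np.mean(expected_terms))

    def test_all_masked_raises(self, rng):
        with pytest.raises(ValueError):
            generation_loss(rng.normal(size=(1, 3, 4)), np.zeros((1, 3), int), np.zeros((1, 3), bool))


class TestTotalLoss:
    def test_additivity(self):
        breakdown = combine(0.3, 1.2)
        assert breakdown.total == pytest.approx(1.5)
        assert breakdown.total == breakdown.alignment + breakdown.generation

    def test_tensor_path_preserves_gradients(self, rng):
        a = Tensor(rng.normal(size=(3, 2)), requires_grad=True)
        c = cross_correlation(a, Tensor(rng.normal(size=(3, 2))), standardize=False)
        total = combine(barlow_twins_loss(c), (a**2).sum())
        total.backward()
        assert a.grad is not None and np.isfinite(a.grad).all()

    def test_gradient_of_total_is_sum_of_component_gradients(self, rng):
        """Finite-difference check that d(L_BT + L_ground)/dw matches the sum
        of the components' own gradients on a tiny differentiable path."""
        w = rng.normal(size=(3, 2))
        zb_base = rng.normal(size=(3, 2))
        logits_base = rng.normal(size=(1, 2, 4))
        targets = np.array([[1, 3]])
        mask = np.ones((1, 2), bool)

        def l_bt(wa):
            c = cross_correlation(wa, zb_base, standardize=False)
            return barlow_twins_loss(c)

        def l_ground(wa):
            return generation_loss(logits_base + wa[0, 0], targets, mask)

        wt = Tensor(w.copy(), requires_grad=True)
        c = cross_correlation(wt, Tensor(zb_base), standardize=False)
        lg = generation_loss(Tensor(logits_base) + wt[(np.array([0]), np.array([0]))].sum(), targets, mask)
        total = barlow_twins_loss(c) + lg
        total.backward()

        eps = 1e-6
        for idx in [(0, 0), (1, 1), (2, 0)]:
            w_hi, w_lo = w.copy(), w.copy()
            w_hi[idx] += eps
            w_lo[idx] -= eps
            num = ((l_bt(w_hi) + l_ground(w_hi)) - (l_bt(w_lo) + l_ground(w_lo))) / (2 * eps)
            assert wt.grad[idx] == pytest.approx(num, abs=1e-4)
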