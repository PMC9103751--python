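"""Task losses, the joint objective, and the weighting-strategy laws."""

import numpy as np
import pytest

from jointcws._autodiff import Tensor
from jointcws.losses import (
    WeightState,
    class_loss,
    joint_loss,
    masked_tag_loss,
    update_weights_dwa,
    update_weights_gradnorm,
    update_weights_uncertainty,
)


def _loop_masked_ce(scores, targets, mask):
    total, n = 0.0, 0
    for b in range(scores.shape[0]):
        for t in range(scores.shape[1]):
            if mask[b, t]:
                row = scores[b, t]
                p = np.exp(row - row.max())
                p /= p.sum()
                total += -np.log(p[targets[b, t]])
                n += 1
    return total / n


class TestMaskedTagLoss:
    def test_uniform_scores_give_ln3(self, rng):
        scores = Tensor(np.zeros((4, 6, 3)))
        targets = rng.integers(0, 3, size=(4, 6))
        mask = np.ones((4, 6), dtype=bool)
        assert masked_tag_loss(scores, targets, mask).item() == pytest.approx(np.log(3))

    def test_pad_append_is_bit_identical(self, rng):
        scores = rng.normal(size=(3, 5, 3))
        targets = rng.integers(0, 3, size=(3, 5))
        mask = np.ones((3, 5), dtype=bool)
        base = masked_tag_loss(Tensor(scores), targets, mask).item()
        padded_scores = np.concatenate([scores, rng.normal(size=(3, 2, 3))], axis=1)
        padded_targets = np.concatenate([targets, np.zeros((3, 2), dtype=int)], axis=1)
        padded_mask = np.concatenate([mask, np.zeros((3, 2), dtype=bool)], axis=1)
        padded = masked_tag_loss(Tensor(padded_scores), padded_targets, padded_mask).item()
        assert padded == base  # bit identical, not approx

    def test_matches_per_position_loop_oracle(self, rng):
        for _ in range(50):
            b, t = rng.integers(1, 6), rng.integers(1, 9)
            scores = rng.normal(size=(b, t, 3)) * 3
            targets = rng.integers(0, 3, size=(b, t))
            mask = rng.random((b, t)) < 0.7
            mask[:, 0] = True
            got = masked_tag_loss(Tensor(scores), targets, mask).item()
            assert got == pytest.approx(_loop_masked_ce(scores, targets, mask), abs=1e-6)

    def test_all_false_mask_rejected(self):
        with pytest.raises(ValueError):
            masked_tag_loss(Tensor(np.zeros((1, 2, 3))), np.zeros((1, 2), int),
                            np.zeros((1, 2), bool))

    def test_gradient_matches_finite_differences(self, rng):
        scores = Tensor(rng.normal(size=(2, 3, 3)), requires_grad=True)
        targets = rng.integers(0, 3, size=(2, 3))
        mask = np.array([[True, True, False], [True, False, False]])
        masked_tag_loss(scores, targets, mask).backward()
        eps = 1e-6
        for b, t, k in [(0, 0, 1), (0, 1, 2), (1, 0, 0)]:
            scores.data[b, t, k] += eps
            up = masked_tag_loss(scores, targets, mask).item()
            scores.data[b, t, k] -= 2 * eps
            down = masked_tag_loss(scores, targets, mask).item()
            scores.data[b, t, k] += eps
            assert scores.grad[b, t, k] == pytest.approx((up - down) / (2 * eps), abs=1e-6)
        # masked positions carry zero gradient
        assert np.all(scores.grad[~mask] == 0.0)


class TestClassLoss:
    def test_uniform_scores_give_ln2(self):
        scores = Tensor(np.zeros((5, 2)))
        labels = np.array([0, 1, 1, 0, 1])
        assert class_loss(scores, labels).item() == pytest.approx(np.log(2))

    def test_confident_correct_scores_vanish(self):
        scores = Tensor(np.array([[30.0, -30.0], [-30.0, 30.0]]))
        labels = np.array([0, 1])
        assert class_loss(scores, labels).item() == pytest.approx(0.0, abs=1e-12)

    def test_matches_loop_oracle(self, rng):
        for _ in range(50):
            n = rng.integers(1, 10)
            scores = rng.normal(size=(n, 2)) * 4
            labels = rng.integers(0, 2, size=n)
            expected = np.mean(
                [
                    -np.log(np.exp(s[y] - s.max()) / np.exp(s - s.max()).sum())
                    for s, y in zip(scores, labels)
                ]
            )
            assert class_loss(Tensor(scores), labels).item() == pytest.approx(
                expected, abs=1e-6
            )


class TestJointLoss:
    def test_default_grid_optimum_weights(self):
        state = WeightState.create("fixed")  # grid optimum 0.4/0.4
        assert joint_loss(1.0, 1.0, state).item() == pytest.approx(0.8)

    def test_single_task_degeneration(self):
        state = WeightState.create("fixed", r0=1.0, r1=0.0)
        assert joint_loss(1.7, 9.9, state).item() == pytest.approx(1.7)

    def test_linear_in_each_task_loss(self):
        state = WeightState.create("fixed", r0=0.3, r1=0.9)
        eps = 1e-6
        up = joint_loss(1.0 + eps, 2.0, state).item()
        down = joint_loss(1.0 - eps, 2.0, state).item()
        assert (up - down) / (2 * eps) == pytest.approx(0.3, abs=1e-6)

    def test_uncertainty_form_at_zero_sigma(self):
        state = WeightState.create("uncertainty")
        # exp(0)*L0 + exp(0)*L1 + 0 + 0
        assert joint_loss(1.5, 2.5, state).item() == pytest.approx(4.0)

    def test_uncertainty_sigma_gradient_flows(self):
        state = WeightState.create("uncertainty")
        loss = joint_loss(Tensor(np.float64(2.0)), Tensor(np.float64(1.0)), state)
        loss.backward()
        s0, s1 = state.log_sigma
        # d/ds [exp(-2s) L + s] = -2 exp(-2s) L + 1
        assert s0.grad == pytest.approx(-2 * 2.0 + 1)
        assert s1.grad == pytest.approx(-2 * 1.0 + 1)


class TestGradNorm:
    def test_full_symmetry_leaves_weights_unchanged(self):
        state = WeightState.create("gradnorm")
        update_weights_gradnorm(state, (1.0, 1.0), (0.7, 0.7), step=0)
        assert (state.r0, state.r1) == (1.0, 1.0)

    def test_alpha_zero_targets_ignore_training_rates(self):
        state = WeightState.create("gradnorm", alpha=0.0)
        # unequal training rates but equal weighted gradient norms: no motion
        state.initial_losses = (1.0, 1.0)
        update_weights_gradnorm(state, (0.2, 0.9), (0.5, 0.5), step=1)
        assert (state.r0, state.r1) == (1.0, 1.0)

    def test_inflated_task_weight_decreases_monotonically(self):
        state = WeightState.create("gradnorm")
        history = [state.r0]
        for step in range(20):
            update_weights_gradnorm(state, (1.0, 1.0), (10.0, 1.0), step=step)
            history.append(state.r0)
            assert state.r0 + state.r1 == pytest.approx(2.0)
        diffs = np.diff(history)
        assert np.all(diffs <= 1e-12)
        assert history[-1] < history[0]

    def test_zero_initial_loss_rejected(self):
        state = WeightState.create("gradnorm")
        with pytest.raises(ValueError):
            update_weights_gradnorm(state, (0.0, 1.0), (1.0, 1.0), step=0)


class TestDWA:
    def test_equal_ratios_give_unit_weights(self):
        state = WeightState.create("dwa")
        state.loss_history = [(2.0, 4.0), (1.0, 2.0)]
        update_weights_dwa(state, epoch=2)
        assert state.r0 == pytest.approx(1.0)
        assert state.r1 == pytest.approx(1.0)

    def test_infinite_temperature_limit(self):
        state = WeightState.create("dwa", temperature=1e9)
        state.loss_history = [(5.0, 1.0), (1.0, 5.0)]
        update_weights_dwa(state, epoch=2)
        assert state.r0 == pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_case(self):
        state = WeightState.create("dwa", temperature=2.0)
        # ratios w = (0.5, 1.0)
        state.loss_history = [(2.0, 2.0), (1.0, 2.0)]
        update_weights_dwa(state, epoch=2)
        expected_r0 = 2 * np.exp(0.25) / (np.exp(0.25) + np.exp(0.5))
        assert state.r0 == pytest.approx(expected_r0)
        assert state.r0 + state.r1 == pytest.approx(2.0)

    def test_first_epochs_use_uniform_weights(self):
        state = WeightState.create("dwa")
        state.loss_history = [(1.0, 2.0)]
        update_weights_dwa(state, epoch=1)
        assert (state.r0, state.r1) == (1.0, 1.0)

    def test_zero_denominator_rejected(self):
        state = WeightState.create("dwa")
        state.loss_history = [(0.0, 1.0), (1.0, 1.0)]
        with pytest.raises(ValueError):
            update_weights_dwa(state, epoch=2)


class TestUncertainty:
    def test_zero_log_sigma_weighs_tasks_equally(self):
        state = WeightState.create("uncertainty")
        assert state.effective_weights() == (1.0, 1.0)

    def test_weight_strictly_decreasing_in_log_sigma(self):
        state = WeightState.create("uncertainty")
        weights = []
        for s in (0.0, 0.5, 1.0, 2.0):
            state.log_sigma[0].data = np.float64(s)
            update_weights_uncertainty(state)
            weights.append(state.r0)
        assert all(a > b for a, b in zip(weights, weights[1:]))
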