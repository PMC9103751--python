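"""Task losses and the weighted joint objective.

The joint objective is ``Loss = r0 * L0 + r1 * L1`` where ``L0`` is a
masked cross-entropy over per-character tag scores (padding positions
contribute exactly zero) and ``L1`` is the ordinary cross-entropy over
sentence-class scores.  Four weighting strategies are supported:

``fixed``
    constant (r0, r1); the default (0.4, 0.4) is the grid-search optimum
    on the validation classification accuracy.
``gradnorm``
    gradient normalization: weights are stepped so each task's gradient
    norm on the shared trunk tracks the mean norm scaled by that task's
    relative inverse training rate (asymmetry ``alpha``), then
    renormalized to sum to the task count.
``dwa``
    dynamic weight averaging: a softmax (temperature ``T``) over each
    task's last-two-epoch loss ratio, scaled to sum to the task count;
    tasks whose loss is falling fast get down-weighted.
``uncertainty``
    homoscedastic-uncertainty weighting: per-task log-noise scales
    ``s_i`` are trained with the network; the objective becomes
    ``sum_i exp(-2 s_i) * L_i + s_i``, so a noisier task ends up with a
    larger ``s_i`` and a smaller effective weight, while the ``+ s_i``
    regularizer prevents collapse to zero weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor

__all__ = [
    "masked_tag_loss",
    "class_loss",
    "WeightState",
    "joint_loss",
    "update_weights_gradnorm",
    "update_weights_dwa",
    "update_weights_uncertainty",
]

N_TASKS = 2


def _log_softmax(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=-1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))


def masked_tag_loss(tag_scores: Tensor, tag_targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean NLL of the target tag over real-character positions only."""
    if not mask.any():
        raise ValueError("mask selects no positions; nothing to supervise")
    scores = tag_scores.data
    log_p = _log_softmax(scores)
    n = int(mask.sum())
    picked = np.take_along_axis(log_p, tag_targets[..., None], axis=-1)[..., 0]
    # sum over the selected entries only: appending padded positions must not
    # even change floating-point summation order
    value = -picked[mask].sum() / n

    def backward(g):
        grad = np.exp(log_p)
        one_hot = np.zeros_like(grad)
        np.put_along_axis(one_hot, tag_targets[..., None], 1.0, axis=-1)
        grad = (grad - one_hot) * mask[..., None] / n
        return (g * grad,)

    return Tensor._result(np.float64(value), (tag_scores,), backward)


def class_loss(class_scores: Tensor, labels: np.ndarray) -> Tensor:
    """Mean NLL of the true class."""
    log_p = _log_softmax(class_scores.data)
    n = class_scores.data.shape[0]
    value = -log_p[np.arange(n), labels].sum() / n

    def backward(g):
        grad = np.exp(log_p)
        grad[np.arange(n), labels] -= 1.0
        return (g * grad / n,)

    return Tensor._result(np.float64(value), (class_scores,), backward)


@dataclass
class WeightState:
    """Per-task loss weights plus strategy-specific running state."""

    strategy: str = "fixed"
    r0: float = 1.0
    r1: float = 1.0
    alpha: float = 1.5            # gradnorm asymmetry
    temperature: float = 2.0      # dwa softmax temperature
    weight_lr: float = 0.025      # gradnorm weight step size
    initial_losses: tuple[float, float] | None = None
    loss_history: list[tuple[float, float]] = field(default_factory=list)
    log_sigma: tuple[Tensor, Tensor] | None = None

    VALID = ("fixed", "gradnorm", "dwa", "uncertainty")

    @staticmethod
    def create(strategy: str = "fixed", r0: float | None = None, r1: float | None = None,
               **kwargs) -> "WeightState":
        if strategy not in WeightState.VALID:
            raise ValueError(f"unknown strategy {strategy!r}")
        if strategy == "fixed":
            # grid-search optimum on validation classification accuracy
            r0 = 0.4 if r0 is None else r0
            r1 = 0.4 if r1 is None else r1
        else:
            r0 = 1.0 if r0 is None else r0
            r1 = 1.0 if r1 is None else r1
        state = WeightState(strategy=strategy, r0=float(r0), r1=float(r1), **kwargs)
        if strategy == "uncertainty":
            state.log_sigma = (
                Tensor(np.float64(0.0), requires_grad=True),
                Tensor(np.float64(0.0), requires_grad=True),
            )
        return state

    def trainable_parameters(self) -> list[Tensor]:
        return list(self.log_sigma) if self.log_sigma is not None else []

    def effective_weights(self) -> tuple[float, float]:
        if self.strategy == "uncertainty":
            return (
                float(np.exp(-2.0 * self.log_sigma[0].data)),
                float(np.exp(-2.0 * self.log_sigma[1].data)),
            )
        return (self.r0, self.r1)


def joint_loss(L0, L1, state: WeightState) -> Tensor:
    """Weighted joint objective; returns a scalar graph node."""
    L0 = L0 if isinstance(L0, Tensor) else Tensor(np.float64(L0))
    L1 = L1 if isinstance(L1, Tensor) else Tensor(np.float64(L1))
    if state.strategy == "uncertainty":
        s0, s1 = state.log_sigma
        return (
            (s0 * -2.0).exp() * L0 + (s1 * -2.0).exp() * L1 + s0 + s1
        )
    return Tensor(np.float64(state.r0)) * L0 + Tensor(np.float64(state.r1)) * L1


def update_weights_gradnorm(
    state: WeightState,
    per_task_losses: tuple[float, float],
    shared_grad_norms: tuple[float, float],
    step: int,
) -> WeightState:
    """One gradient-normalization weight step.

    ``shared_grad_norms`` are the norms of each *unweighted* task loss's
    gradient on the shared trunk; the weighted norm is ``G_i = r_i * n_i``.
    Targets are ``mean(G) * rho_i ** alpha`` with ``rho_i`` the relative
    inverse training rate; weights move against ``d|G_i - target_i|/dr_i``
    and are renormalized to sum to the task count.
    """
    if state.initial_losses is None:
        if any(L <= 0.0 for L in per_task_losses):
            raise ValueError("gradnorm requires positive initial losses")
        state.initial_losses = (float(per_task_losses[0]), float(per_task_losses[1]))
    r = np.array([state.r0, state.r1])
    norms = np.asarray(shared_grad_norms, dtype=np.float64)
    G = r * norms
    tilde = np.asarray(per_task_losses) / np.asarray(state.initial_losses)
    rho = tilde / tilde.mean()
    targets = G.mean() * rho**state.alpha
    # damped proportional step: the step length decays as G_i approaches its
    # target, so the weights settle instead of ping-ponging around equilibrium
    grad_r = (G - targets) * norms / (G.mean() + 1e-12)
    r = np.maximum(r - state.weight_lr * grad_r, 1e-4)
    r = r * (N_TASKS / r.sum())
    state.r0, state.r1 = float(r[0]), float(r[1])
    return state


def update_weights_dwa(state: WeightState, epoch: int) -> WeightState:
    """Dynamic-weight-averaging update from the last two epochs' mean losses."""
    if len(state.loss_history) < 2:
        state.r0 = state.r1 = 1.0
        return state
    prev, prev2 = state.loss_history[-1], state.loss_history[-2]
    if prev2[0] == 0.0 or prev2[1] == 0.0:
        raise ValueError("dwa: zero loss in history denominator")
    w = np.array([prev[0] / prev2[0], prev[1] / prev2[1]])
    e = np.exp(w / state.temperature)
    r = N_TASKS * e / e.sum()
    state.r0, state.r1 = float(r[0]), float(r[1])
    return state


def update_weights_uncertainty(state: WeightState, gradients=None) -> WeightState:
    """Sync the logged (r0, r1) from the learned log-sigmas.

    The log-sigmas themselves are ordinary trainable scalars stepped by
    the network optimizer through the ``joint_loss`` graph.
    """
    state.r0, state.r1 = state.effective_weights()
    return state
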