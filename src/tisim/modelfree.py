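"""Model-free value-learning agents: Q-learning and the Value Transfer Model.

Both agents keep one value per item (context is deliberately ignored: a
pair-contextual table could never generalize to novel pairings) and choose
with a softmax policy whose contrast parameter theta multiplies the values
of every presented alternative.

Q-learning updates the chosen item's value toward the obtained consequence
plus a discounted prospective term gamma * max(Q) over the whole
contextless value vector; because the task's trial sequence is
choice-independent, the prospective term acts as task-determined noise
rather than planning.  The Value Transfer Model (VTM) replaces the
prospective term with tau times the value of the other presented item, so
value leaks between items that appear together — the associative mechanism
historically proposed to explain transitive-inference-like behavior.

``update_mode`` selects symmetric updating (both presented items are
updated, the unchosen one with its counterfactual consequence: its reward
magnitude if it was in fact the correct item, else 0) or asymmetric
updating of the chosen item only.  Symmetric steps use pre-update partner
values, so the two item updates commute.
"""

from __future__ import annotations

import math

import numpy as np

from .base import Agent, register_agent
from .task import ListSpec

__all__ = ["softmax_policy", "QAgent", "VTMAgent"]


def softmax_policy(values, theta: float) -> np.ndarray:
    """Softmax choice probabilities with inverse temperature theta.

    p(i) = exp(theta * v_i) / sum_j exp(theta * v_j), computed with
    max-subtraction so large values cannot overflow.  theta = 0 yields
    equiprobable responding.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("softmax requires finite values")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    z = theta * v
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def _check_unit(name: str, value: float, closed_low=False):
    lo_ok = value >= 0 if closed_low else value > 0
    if not (lo_ok and value < 1):
        raise ValueError(f"{name} must lie in the unit interval, got {value}")


class _ValueAgent(Agent):
    """Shared machinery for the per-item value vector and softmax policy."""

    def __init__(self, list_spec: ListSpec, *, delta, theta, update_mode):
        super().__init__(list_spec)
        _check_unit("delta", delta)
        if theta < 0:
            raise ValueError("theta must be non-negative")
        if update_mode not in ("symmetric", "asymmetric"):
            raise ValueError(f"unknown update mode {update_mode!r}")
        self.delta = float(delta)
        self.theta = float(theta)
        self.update_mode = update_mode
        self.q = np.zeros(len(self.items))

    def pair_prob(self, a: str, b: str) -> float:
        qa = self.q[self._index[a]]
        qb = self.q[self._index[b]]
        # two-option softmax = logistic of the scaled value difference
        return 1.0 / (1.0 + math.exp(-self.theta * (qa - qb)))

    def item_score(self, item: str) -> float:
        return float(self.q[self._index[item]])

    def snapshot(self) -> dict:
        return {"q": dict(zip(self.items, self.q.tolist()))}

    @staticmethod
    def _consequences(chosen, unchosen, correct, magnitude):
        c_chosen = magnitude if chosen == correct else 0.0
        c_unchosen = magnitude if unchosen == correct else 0.0
        return c_chosen, c_unchosen


@register_agent("q")
class QAgent(_ValueAgent):
    """Contextless Q-learning with softmax choice."""

    param_names = ("delta", "theta", "gamma")
    param_bounds = {"delta": (1e-3, 0.999), "theta": (0.0, 20.0), "gamma": (0.0, 0.95)}

    def __init__(self, list_spec, *, delta, theta, gamma=0.0, update_mode="symmetric"):
        super().__init__(list_spec, delta=delta, theta=theta, update_mode=update_mode)
        if not 0 <= gamma < 1:
            raise ValueError("gamma must lie in [0, 1)")
        self.gamma = float(gamma)

    def update(self, a, b, chosen, correct, magnitude=1.0, rng=None):
        unchosen = b if chosen == a else a
        c_ch, c_un = self._consequences(chosen, unchosen, correct, magnitude)
        # prospective term: max over the whole contextless value vector,
        # frozen before either update; identical for both items of the trial
        prospect = self.gamma * self.q.max()
        i = self._index[chosen]
        j = self._index[unchosen]
        qi, qj = self.q[i], self.q[j]
        self.q[i] = qi + self.delta * (c_ch + prospect - qi)
        if self.update_mode == "symmetric":
            self.q[j] = qj + self.delta * (c_un + prospect - qj)


@register_agent("vtm")
class VTMAgent(_ValueAgent):
    """Value Transfer Model: Rescorla-Wagner learning with paired transfer."""

    param_names = ("delta", "theta", "tau")
    param_bounds = {"delta": (1e-3, 0.999), "theta": (0.0, 20.0), "tau": (0.0, 0.999)}

    def __init__(self, list_spec, *, delta, theta, tau, update_mode="symmetric"):
        super().__init__(list_spec, delta=delta, theta=theta, update_mode=update_mode)
        _check_unit("tau", tau, closed_low=True)
        self.tau = float(tau)

    def update(self, a, b, chosen, correct, magnitude=1.0, rng=None):
        unchosen = b if chosen == a else a
        c_ch, c_un = self._consequences(chosen, unchosen, correct, magnitude)
        i = self._index[chosen]
        j = self._index[unchosen]
        qi, qj = self.q[i], self.q[j]  # pre-update partner values
        self.q[i] = qi + self.delta * (c_ch + self.tau * qj - qi)
        if self.update_mode == "symmetric":
            self.q[j] = qj + self.delta * (c_un + self.tau * qi - qj)
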