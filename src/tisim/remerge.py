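"""RL-REMERGE: a recurrent similarity network grown online over observed pairs.

The network has three layers.  Feature nodes (one per list item) receive
external input when their item is on screen.  Conjunctive nodes represent
stimulus pairs; a node exists only once its pair has actually been
presented, so the network's inferential reach grows with experience.
Feature and conjunctive layers exchange mutually excitatory activity until
a steady state is reached; excitation entering the conjunctive layer is
"hedged" during renormalization,

    y_p = exp(lam * net_p) / (omega + sum_q exp(lam * net_q)),

so that activity flowing along long chains of nodes washes out as omega
grows.  After settling, each conjunctive node projects to the response
nodes of its two items through weights learned by a delta rule with targets
+1 (correct choice) and -1 (incorrect choice), making wrong links
inhibitory.  Choices apply a softmax over the response activations of the
two presented items.

Settling is deterministic; feature activations are recomputed each sweep
from external input plus conjunctive feedback (no self-decay) and
convergence is declared on the conjunctive activations.
"""

from __future__ import annotations

import math

import numpy as np

from .base import Agent, register_agent
from .task import ListSpec

__all__ = ["RemergeAgent", "Activations"]


class Activations:
    """Settled network state: feature (x), conjunctive (y), response (r)."""

    __slots__ = ("x", "y", "r", "converged", "n_iter")

    def __init__(self, x, y, r, converged, n_iter):
        self.x = x
        self.y = y
        self.r = r
        self.converged = converged
        self.n_iter = n_iter


@register_agent("remerge")
class RemergeAgent(Agent):
    param_names = ("lam", "omega", "theta", "delta")
    param_bounds = {
        "lam": (0.05, 10.0),
        "omega": (0.0, 60.0),
        "theta": (0.0, 20.0),
        "delta": (0.01, 1.0),
    }

    def __init__(
        self,
        list_spec: ListSpec,
        *,
        lam,
        omega,
        theta,
        delta,
        update_mode="symmetric",
        tol: float = 1e-4,
        max_iter: int = 200,
    ):
        super().__init__(list_spec)
        if lam <= 0:
            raise ValueError("lam must be positive")
        if omega < 0:
            raise ValueError("omega must be non-negative")
        if not 0 < delta <= 1:
            raise ValueError("delta must lie in (0, 1]")
        if update_mode not in ("symmetric", "asymmetric"):
            raise ValueError(f"unknown update mode {update_mode!r}")
        self.lam = float(lam)
        self.omega = float(omega)
        self.theta = float(theta)
        self.delta = float(delta)
        self.update_mode = update_mode
        self.tol = float(tol)
        self.max_iter = int(max_iter)
        n = len(self.items)
        # conjunctive nodes, created on first observation of their pair
        self._node_of: dict[frozenset[str], int] = {}
        self._members = np.empty((0, 2), dtype=np.intp)  # item indices per node
        self._weights = np.empty((0, 2))  # link to members' response nodes
        self._n = n
        self.settle_failures = 0

    # -- network growth ----------------------------------------------------
    @property
    def n_conjunctive(self) -> int:
        return len(self._node_of)

    def observe_pair(self, a: str, b: str) -> None:
        """Idempotently add a conjunctive node for the pair {a, b}."""
        key = frozenset((a, b))
        if key in self._node_of:
            return
        self._node_of[key] = len(self._node_of)
        pair_idx = np.array([[self._index[a], self._index[b]]], dtype=np.intp)
        self._members = np.vstack([self._members, pair_idx])
        self._weights = np.vstack([self._weights, np.zeros((1, 2))])

    def begin_trial(self, a: str, b: str) -> None:
        self.observe_pair(a, b)

    # -- settling ----------------------------------------------------------
    def settle(self, stimulated: set[str] | tuple[str, ...]) -> Activations:
        """Iterate feature/conjunctive feedback to a steady state."""
        if not stimulated:
            raise ValueError("at least one item must be stimulated")
        n = self._n
        ext = np.zeros(n)
        for it in stimulated:
            ext[self._index[it]] = 1.0
        m = len(self._node_of)
        if m == 0:
            return Activations(ext.copy(), np.zeros(0), np.zeros(n), True, 0)
        mem = self._members
        y = np.zeros(m)
        converged = False
        it_count = 0
        for it_count in range(1, self.max_iter + 1):
            x = ext.copy()
            np.add.at(x, mem[:, 0], y)
            np.add.at(x, mem[:, 1], y)
            net = x[mem[:, 0]] + x[mem[:, 1]]
            e = np.exp(self.lam * net)
            y_new = e / (self.omega + e.sum())
            if np.abs(y_new - y).max() < self.tol:
                y = y_new
                converged = True
                break
            y = y_new
        if not converged:
            self.settle_failures += 1
        x = ext.copy()
        np.add.at(x, mem[:, 0], y)
        np.add.at(x, mem[:, 1], y)
        r = np.zeros(n)
        np.add.at(r, mem[:, 0], y * self._weights[:, 0])
        np.add.at(r, mem[:, 1], y * self._weights[:, 1])
        return Activations(x, y, r, converged, it_count)

    # -- behavior ----------------------------------------------------------
    def pair_prob(self, a: str, b: str) -> float:
        r = self.settle((a, b)).r
        ra, rb = r[self._index[a]], r[self._index[b]]
        return 1.0 / (1.0 + math.exp(-self.theta * (ra - rb)))

    def greedy(self, a: str, b: str) -> str | None:
        r = self.settle((a, b)).r
        ra, rb = r[self._index[a]], r[self._index[b]]
        if ra == rb:
            return None
        return a if ra > rb else b

    def update(self, a, b, chosen, correct, magnitude=1.0, rng=None):
        key = frozenset((a, b))
        if key not in self._node_of:
            raise ValueError("pair must be observed (begin_trial) before learning")
        node = self._node_of[key]
        unchosen = b if chosen == a else a
        slot = {self.items[i]: k for k, i in enumerate(self._members[node])}
        target_chosen = 1.0 if chosen == correct else -1.0
        w = self._weights[node]
        k = slot[chosen]
        w[k] += self.delta * (target_chosen - w[k])
        if self.update_mode == "symmetric":
            target_un = 1.0 if unchosen == correct else -1.0
            k = slot[unchosen]
            w[k] += self.delta * (target_un - w[k])

    def link_weight(self, a: str, b: str, item: str) -> float:
        node = self._node_of[frozenset((a, b))]
        slot = {self.items[i]: k for k, i in enumerate(self._members[node])}
        return float(self._weights[node][slot[item]])

    def snapshot(self) -> dict:
        return {
            "n_conjunctive": self.n_conjunctive,
            "weights": {
                tuple(sorted(k)): self._weights[v].tolist()
                for k, v in self._node_of.items()
            },
        }
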