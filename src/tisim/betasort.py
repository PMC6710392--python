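"""Betasort: beta-distributed position estimates with implicit updating.

Each item's position on a unit scale is represented by two non-negative
evidence totals U ("upper") and L ("lower"); the working density is
Beta(U + 0.5, L + 0.5), i.e. the evidence combined with a Jeffreys prior,
with summary mean (U + 0.5) / (U + L + 1).  To choose between two items the
agent draws one value from each density and picks the larger, except that
with lapse probability rho it responds uniformly at random, which caps
accuracy at 1 - rho/2.

After every trial, all items are first relaxed: U and L are multiplied by
an effective recall factor f.  While recent performance is at or above
chance, f equals the recall parameter phi (at the reference phi = 0.495
the representation loses roughly half of its evidence per trial); when
performance collapses below chance, f shrinks proportionally, so evidence
that consistently produces errors is discarded even faster.  Leaky
accumulators of recent hits and trials drive this modulation; the exact
rule is a documented choice of this package (see docs/methods.md) and is
selectable via ``recall_mode``.  Then:

* correct choice -> every item is consolidated, U += U/(U+L) and
  L += L/(U+L), sharpening all positions without moving the evidence
  ratio U/(U+L);
* incorrect choice -> direct updating (chosen L += 1, unchosen presented
  item U += 1) followed by implicit updating of the non-presented items
  classified by their pre-trial means: above both pair members U += 1,
  below both L += 1, in between consolidated.

Implicit updating is what lets Betasort preserve relative order through
massed or degenerate training.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import special

from .base import Agent, register_agent
from .task import ListSpec

__all__ = ["BetasortAgent", "beta_exceedance", "position_mean"]


def position_mean(u, l):
    """Jeffreys-posterior mean position (U + 0.5)/(U + L + 1)."""
    u = np.asarray(u, dtype=float)
    l = np.asarray(l, dtype=float)
    return (u + 0.5) / (u + l + 1.0)


@lru_cache(maxsize=8)
def _leggauss(n_nodes: int):
    return np.polynomial.legendre.leggauss(n_nodes)


def beta_exceedance(u1, l1, u2, l2, n_nodes: int = 64):
    """P(X > Y) for X ~ Beta(u1+0.5, l1+0.5), Y ~ Beta(u2+0.5, l2+0.5).

    Evaluated as the one-dimensional integral of pdf_X * cdf_Y after the
    probability-integral substitution q = F_X(x), which turns it into the
    quadrature of the smooth, bounded map q -> F_Y(F_X^{-1}(q)) on (0, 1)
    (the Jeffreys shapes have endpoint singularities in the raw density
    that this removes).  Vectorized over broadcastable parameter arrays.
    """
    a1 = np.asarray(u1, dtype=float) + 0.5
    b1 = np.asarray(l1, dtype=float) + 0.5
    a2 = np.asarray(u2, dtype=float) + 0.5
    b2 = np.asarray(l2, dtype=float) + 0.5
    a1, b1, a2, b2 = np.broadcast_arrays(a1, b1, a2, b2)
    shape = a1.shape
    a1 = a1.reshape(-1, 1)
    b1 = b1.reshape(-1, 1)
    a2 = a2.reshape(-1, 1)
    b2 = b2.reshape(-1, 1)
    nodes, wts = _leggauss(n_nodes)
    q = 0.5 * (nodes[None, :] + 1.0)  # map to (0, 1)
    x = special.betaincinv(a1, b1, q)
    Fy = special.betainc(a2, b2, x)
    out = 0.5 * np.einsum("ij,j->i", Fy, wts)
    out = np.clip(out, 0.0, 1.0)
    return out.reshape(shape) if shape else float(out[0])


@register_agent("betasort")
class BetasortAgent(Agent):
    param_names = ("rho", "phi")
    param_bounds = {"rho": (0.0, 1.0), "phi": (0.01, 0.99)}

    RECALL_MODES = ("performance", "constant")

    def __init__(self, list_spec: ListSpec, *, rho, phi, recall_mode="performance"):
        super().__init__(list_spec)
        if not 0 <= rho <= 1:
            raise ValueError("rho must lie in [0, 1]")
        if not 0 < phi < 1:
            raise ValueError("phi must lie in (0, 1)")
        if recall_mode not in self.RECALL_MODES:
            raise ValueError(f"unknown recall mode {recall_mode!r}")
        self.rho = float(rho)
        self.phi = float(phi)
        self.recall_mode = recall_mode
        n = len(self.items)
        self.u = np.zeros(n)
        self.l = np.zeros(n)
        # leaky accumulators for the performance-modulated recall
        self.recent_correct = 0.0
        self.recent_trials = 0.0

    # -- readouts ----------------------------------------------------------
    def item_score(self, item: str) -> float:
        i = self._index[item]
        return float(position_mean(self.u[i], self.l[i]))

    def means(self) -> np.ndarray:
        return position_mean(self.u, self.l)

    def pair_prob(self, a: str, b: str) -> float:
        """Choice probability of ``a`` via quadrature, with the lapse mixture.

        Used for likelihood evaluation and accuracy curves; simulation
        samples choices by random draws instead (distributionally equal).
        """
        i, j = self._index[a], self._index[b]
        p = beta_exceedance(self.u[i], self.l[i], self.u[j], self.l[j])
        return self.rho / 2.0 + (1.0 - self.rho) * float(p)

    def choose(self, a: str, b: str, rng: np.random.Generator) -> str:
        if rng.random() < self.rho:
            return a if rng.random() < 0.5 else b
        i, j = self._index[a], self._index[b]
        xa = rng.beta(self.u[i] + 0.5, self.l[i] + 0.5)
        xb = rng.beta(self.u[j] + 0.5, self.l[j] + 0.5)
        return a if xa > xb else b

    # -- learning ----------------------------------------------------------
    def _recall_factor(self) -> float:
        """Effective per-trial retention f in [0, phi]."""
        if self.recall_mode == "constant":
            return self.phi
        p_hat = (self.recent_correct + 0.5) / (self.recent_trials + 1.0)
        return self.phi * min(1.0, 2.0 * p_hat)

    def _consolidate(self, mask=None):
        tot = self.u + self.l
        sel = tot > 0 if mask is None else mask & (tot > 0)
        ratio_u = np.where(sel, self.u / np.where(sel, tot, 1.0), 0.0)
        ratio_l = np.where(sel, self.l / np.where(sel, tot, 1.0), 0.0)
        self.u += ratio_u
        self.l += ratio_l

    def update(self, a, b, chosen, correct, magnitude=1.0, rng=None):
        was_correct = chosen == correct
        means_before = self.means()
        # recall modulation tracks performance including the current trial
        self.recent_correct = self.phi * self.recent_correct + float(was_correct)
        self.recent_trials = self.phi * self.recent_trials + 1.0
        f = self._recall_factor()
        self.u *= f
        self.l *= f
        if was_correct:
            self._consolidate()
            return
        # direct updating of the presented pair
        i, j = self._index[chosen], self._index[b if chosen == a else a]
        self.l[i] += 1.0
        self.u[j] += 1.0
        hi = max(means_before[i], means_before[j])
        lo = min(means_before[i], means_before[j])
        hidden = np.ones(len(self.items), dtype=bool)
        hidden[[i, j]] = False
        above = hidden & (means_before > hi)
        below = hidden & (means_before < lo)
        between = hidden & ~above & ~below
        self.u[above] += 1.0
        self.l[below] += 1.0
        self._consolidate(between)

    def snapshot(self) -> dict:
        return {
            "u": dict(zip(self.items, self.u.tolist())),
            "l": dict(zip(self.items, self.l.tolist())),
            "means": dict(zip(self.items, self.means().tolist())),
        }
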