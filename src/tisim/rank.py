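"""Rank-inference agents: RL-Elo ratings and a sequential Monte Carlo filter.

RL-Elo keeps one rating per item.  The probability that the correct item
would be chosen is the logistic of theta times the rating difference (the
two-option softmax), and after feedback the winner's rating rises — and the
loser's falls — by delta * (1 - p_winner), so surprising outcomes move
ratings more.  Updates depend only on the revealed correct item, so the
rating trajectory is independent of the agent's own choices and the total
rating is conserved exactly.

The SMC ("particle filter") agent entertains many hypothetical orderings at
once: each particle is a vector of item positions drawn initially from
Normal(0, sigma0^2).  Choice probability is the weight-averaged logistic
discrimination across particles.  After feedback each particle's weight is
multiplied by the probability it assigned to the revealed correct item
(Bayesian reweighting); when the effective sample size 1/sum(w^2) falls
below a fraction of the particle count, particles are resampled
systematically in proportion to their weights; finally every position
receives Normal(0, sigma^2) jitter.  sigma0 and sigma are standard
deviations.
"""

from __future__ import annotations

import math

import numpy as np

from .base import Agent, register_agent
from .task import ListSpec

__all__ = ["EloAgent", "SMCAgent", "systematic_resample"]


@register_agent("elo")
class EloAgent(Agent):
    param_names = ("delta", "theta")
    param_bounds = {"delta": (1e-3, 0.999), "theta": (1e-3, 20.0)}

    def __init__(self, list_spec: ListSpec, *, delta, theta):
        super().__init__(list_spec)
        if not 0 < delta < 1:
            raise ValueError("delta must lie in (0, 1)")
        if theta <= 0:
            raise ValueError("theta must be positive")
        self.delta = float(delta)
        self.theta = float(theta)
        self.v = np.zeros(len(self.items))

    def pair_prob(self, a: str, b: str) -> float:
        d = self.v[self._index[a]] - self.v[self._index[b]]
        return 1.0 / (1.0 + math.exp(-self.theta * d))

    def update(self, a, b, chosen, correct, magnitude=1.0, rng=None):
        loser = b if correct == a else a
        p_win = self.pair_prob(correct, loser)
        step = self.delta * (1.0 - p_win)
        self.v[self._index[correct]] += step
        self.v[self._index[loser]] -= step

    def item_score(self, item: str) -> float:
        return float(self.v[self._index[item]])

    def snapshot(self) -> dict:
        return {"v": dict(zip(self.items, self.v.tolist()))}


def systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a systematic resample proportional to ``weights``."""
    k = len(weights)
    positions = (rng.random() + np.arange(k)) / k
    return np.searchsorted(np.cumsum(weights), positions)


@register_agent("smc")
class SMCAgent(Agent):
    param_names = ("sigma0", "sigma", "theta")
    param_bounds = {"sigma0": (0.01, 3.0), "sigma": (0.0, 1.0), "theta": (0.0, 20.0)}

    def __init__(
        self,
        list_spec: ListSpec,
        *,
        sigma0,
        sigma,
        theta,
        rng: np.random.Generator,
        n_particles: int = 10_000,
        ess_fraction: float = 0.5,
    ):
        super().__init__(list_spec)
        if sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0 < ess_fraction <= 1:
            raise ValueError("ess_fraction must lie in (0, 1]")
        self.sigma0 = float(sigma0)
        self.sigma = float(sigma)
        self.theta = float(theta)
        self.n_particles = int(n_particles)
        self.ess_fraction = float(ess_fraction)
        self.positions = rng.normal(
            0.0, self.sigma0, size=(self.n_particles, len(self.items))
        )
        self.weights = np.full(self.n_particles, 1.0 / self.n_particles)
        self.n_resamples = 0

    def _particle_probs(self, a: str, b: str) -> np.ndarray:
        d = self.positions[:, self._index[a]] - self.positions[:, self._index[b]]
        # clipped logistic keeps the multiplicative weight update away from 0
        return 1.0 / (1.0 + np.exp(np.clip(-self.theta * d, -700, 700)))

    def pair_prob(self, a: str, b: str) -> float:
        return float(self.weights @ self._particle_probs(a, b))

    def update(self, a, b, chosen, correct, magnitude=1.0, rng=None):
        if rng is None:
            raise ValueError("the particle filter needs an rng for its dynamics")
        loser = b if correct == a else a
        like = self._particle_probs(correct, loser)
        w = self.weights * like
        total = w.sum()
        if not total > 0:
            raise FloatingPointError("particle weights collapsed to zero")
        w /= total
        ess = 1.0 / (w @ w)
        if ess < self.ess_fraction * self.n_particles:
            idx = systematic_resample(w, rng)
            self.positions = self.positions[idx]
            w = np.full(self.n_particles, 1.0 / self.n_particles)
            self.n_resamples += 1
        self.weights = w
        if self.sigma > 0:
            self.positions = self.positions + rng.normal(
                0.0, self.sigma, size=self.positions.shape
            )

    def item_score(self, item: str) -> float:
        """Weighted-mean position of the item across particles."""
        return float(self.weights @ self.positions[:, self._index[item]])

    def snapshot(self) -> dict:
        return {
            "mean_positions": {
                it: self.item_score(it) for it in self.items
            },
            "n_resamples": self.n_resamples,
        }
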