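"""Trialwise likelihoods, maximum-likelihood fitting, BIC model comparison.

A choice dataset is replayed trial by trial: the model's probability of the
*observed* choice is accumulated in log, then the agent is updated with the
observed choice and its outcome, so the likelihood unfolds exactly as the
model's representation would have.  For agents whose updates are driven by
noise (the particle filter), a fixed seed supplies common random numbers
across likelihood evaluations so the objective is a deterministic function
of the parameters.

BIC = k*ln(n) - 2*logL; ensemble weights approximate Bayesian model
averaging via exp(-0.5 * dBIC), normalized.  ``windowed_ensemble`` scores
the globally fitted models locally with a short moving window of trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .base import make_agent
from .io import ChoiceDataset

__all__ = [
    "FitResult",
    "EnsembleResult",
    "trialwise_logliks",
    "trialwise_loglik",
    "fit_mle",
    "model_comparison",
    "windowed_ensemble",
]

_PROB_FLOOR = 1e-12  # softmax/logistic/lapse policies never reach exact zero


@dataclass(frozen=True)
class FitResult:
    agent_kind: str
    params: dict[str, float]
    log_likelihood: float
    k: int
    n: int
    converged: bool = True
    fixed_params: dict[str, float] = field(default_factory=dict)

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n) - 2.0 * self.log_likelihood


@dataclass(frozen=True)
class EnsembleResult:
    agent_kinds: tuple[str, ...]
    bic: np.ndarray
    delta_bic: np.ndarray
    weights: np.ndarray  # exp(-0.5 * delta_bic), un-normalized
    support: np.ndarray  # normalized, sums to 1
    #: optional per-window trajectories, shape (n_windows, n_models)
    window_support: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            kind: {
                "bic": float(b),
                "delta_bic": float(d),
                "support": float(s),
            }
            for kind, b, d, s in zip(
                self.agent_kinds, self.bic, self.delta_bic, self.support
            )
        }


def _replay(agent_kind, params, dataset: ChoiceDataset, seed, extra=None):
    rng = np.random.default_rng(seed)
    p = dict(params)
    if extra:
        p.update(extra)
    agent = make_agent(agent_kind, dataset.list_spec, p, rng=rng)
    lls = np.empty(len(dataset))
    for t, tr in enumerate(dataset.trials):
        agent.begin_trial(tr.left, tr.right)
        p_left = agent.pair_prob(tr.left, tr.right)
        p_obs = p_left if tr.chosen == tr.left else 1.0 - p_left
        lls[t] = math.log(max(p_obs, _PROB_FLOOR))
        agent.update(tr.left, tr.right, tr.chosen, tr.correct, tr.reward, rng=rng)
    return lls


def trialwise_logliks(
    agent_kind: str,
    params: Mapping[str, float],
    dataset: ChoiceDataset,
    seed: int = 0,
    *,
    fixed_params: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Log-probability of each observed choice, in presentation order."""
    return _replay(agent_kind, params, dataset, seed, fixed_params)


def trialwise_loglik(agent_kind, params, dataset, seed: int = 0, **kw) -> float:
    return float(trialwise_logliks(agent_kind, params, dataset, seed, **kw).sum())


def fit_mle(
    agent_kind: str,
    dataset: ChoiceDataset,
    seed: int = 0,
    *,
    n_starts: int = 4,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    fixed_params: Mapping[str, float] | None = None,
    x0: Mapping[str, float] | None = None,
) -> FitResult:
    """Bounded multi-start maximum-likelihood fit of one agent.

    Starting points are drawn from a Latin-hypercube over the bounds (plus
    the caller's ``x0`` if given); each start is polished with L-BFGS-B on
    the negative trialwise log-likelihood.  Stochastic likelihoods reuse
    the same seed on every evaluation (common random numbers).
    """
    from .base import _REGISTRY  # agent classes carry names/bounds

    cls = _REGISTRY[agent_kind]
    names = list(cls.param_names)
    bnds = dict(cls.param_bounds)
    if bounds:
        bnds.update(bounds)
    if fixed_params:
        names = [nm for nm in names if nm not in fixed_params]
    lo = np.array([bnds[nm][0] for nm in names])
    hi = np.array([bnds[nm][1] for nm in names])

    def neg_ll(x):
        params = dict(zip(names, x))
        try:
            return -trialwise_loglik(
                agent_kind, params, dataset, seed, fixed_params=fixed_params
            )
        except (FloatingPointError, OverflowError):
            return 1e12

    sampler = stats.qmc.LatinHypercube(d=len(names), seed=seed)
    starts = [lo + (hi - lo) * row for row in sampler.random(n_starts)]
    if x0 is not None:
        starts.insert(0, np.array([x0[nm] for nm in names]))
    best = None
    any_ok = False
    for s in starts:
        res = optimize.minimize(
            neg_ll, s, method="L-BFGS-B", bounds=list(zip(lo, hi))
        )
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    params = dict(zip(names, best.x.tolist()))
    return FitResult(
        agent_kind=agent_kind,
        params=params,
        log_likelihood=-float(best.fun),
        k=len(names),
        n=len(dataset),
        converged=any_ok,
        fixed_params=dict(fixed_params or {}),
    )


def _ensemble(bics: np.ndarray):
    delta = bics - bics.min()
    w = np.exp(-0.5 * delta)
    return delta, w, w / w.sum()


def model_comparison(fits: Sequence[FitResult]) -> EnsembleResult:
    """Delta-BIC and normalized ensemble supports for fits of one dataset."""
    if len(fits) < 2:
        raise ValueError("model comparison needs at least two fits")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError("fits compare different datasets (trial counts differ)")
    bics = np.array([f.bic for f in fits])
    delta, w, support = _ensemble(bics)
    return EnsembleResult(
        tuple(f.agent_kind for f in fits), bics, delta, w, support
    )


def windowed_ensemble(
    fits: Sequence[FitResult],
    dataset: ChoiceDataset,
    seed: int = 0,
    window: int = 3,
) -> EnsembleResult:
    """Local model support along the dataset with a moving trial window.

    Each model keeps its whole-dataset maximum-likelihood parameters and
    its state evolves from the full dataset prefix; only the scoring is
    local: for every trial t the window of trials centered at t (clipped
    at the edges) yields a BIC with n = the window's size, from which
    delta-BIC and normalized supports are computed per window.
    """
    if window > len(dataset):
        raise ValueError("window exceeds dataset length")
    if window < 1:
        raise ValueError("window must be positive")
    ll = np.stack(
        [
            trialwise_logliks(
                f.agent_kind, f.params, dataset, seed, fixed_params=f.fixed_params
            )
            for f in fits
        ]
    )  # (n_models, n_trials)
    n_models, n_trials = ll.shape
    half = (window - 1) // 2
    ks = np.array([f.k for f in fits])
    supports = np.empty((n_trials, n_models))
    bic_total = np.array([f.bic for f in fits])
    for t in range(n_trials):
        a = max(0, t - half)
        b = min(n_trials, t - half + window)
        n_w = b - a
        bic_w = ks * math.log(n_w) - 2.0 * ll[:, a:b].sum(axis=1)
        supports[t] = _ensemble(bic_w)[2]
    delta, w, support = _ensemble(bic_total)
    return EnsembleResult(
        tuple(f.agent_kind for f in fits),
        bic_total,
        delta,
        w,
        support,
        window_support=supports,
    )
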