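"""Uniform agent contract shared by all learning models.

Every agent exposes the same surface so the simulator and the fitting code
are agent-agnostic:

``begin_trial(a, b)``
    Called when a pair is actually presented (lets configural models grow
    their representation online); evaluation methods never call it.
``pair_prob(a, b)``
    The model's current probability of choosing ``a`` over ``b``.
``choose(a, b, rng)``
    Sample a choice (by default from ``pair_prob``).
``update(a, b, chosen, correct, magnitude, rng)``
    Learn from the trial's feedback.  ``magnitude`` is the reward delivered
    for choosing ``correct``; an incorrect choice earns 0.
``greedy(a, b)``
    The deterministically preferred item, or ``None`` on an exact tie.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from typing import Mapping

import numpy as np

from .task import ListSpec

__all__ = ["Agent", "AGENT_KINDS", "make_agent", "register_agent"]

_REGISTRY: dict[str, type["Agent"]] = {}


def register_agent(kind: str):
    def deco(cls):
        cls.kind = kind
        _REGISTRY[kind] = cls
        return cls

    return deco


class Agent(ABC):
    kind: str = ""
    #: ordered free-parameter names, also the fitting order
    param_names: tuple[str, ...] = ()
    #: fitting bounds per parameter
    param_bounds: dict[str, tuple[float, float]] = {}

    def __init__(self, list_spec: ListSpec, **params):
        self.list_spec = list_spec
        self.items = list_spec.items
        self._index = {it: i for i, it in enumerate(self.items)}

    # -- lifecycle ---------------------------------------------------------
    def begin_trial(self, a: str, b: str) -> None:
        """Hook invoked when the pair (a, b) is presented on a real trial."""

    @abstractmethod
    def pair_prob(self, a: str, b: str) -> float:
        """P(choose a | pair {a, b}) under the current state."""

    def choose(self, a: str, b: str, rng: np.random.Generator) -> str:
        return a if rng.random() < self.pair_prob(a, b) else b

    @abstractmethod
    def update(
        self,
        a: str,
        b: str,
        chosen: str,
        correct: str,
        magnitude: float = 1.0,
        rng: np.random.Generator | None = None,
    ) -> None: ...

    # -- deterministic core ------------------------------------------------
    def item_score(self, item: str) -> float:
        raise NotImplementedError

    def greedy(self, a: str, b: str) -> str | None:
        sa, sb = self.item_score(a), self.item_score(b)
        if sa == sb:
            return None
        return a if sa > sb else b

    def snapshot(self) -> dict:
        """A plain-data view of the internal state (for logging/tests)."""
        return {}

    # -- fitting support ---------------------------------------------------
    @property
    def n_params(self) -> int:
        return len(self.param_names)


AGENT_KINDS = ("q", "vtm", "remerge", "elo", "smc", "betasort")


def make_agent(
    kind: str,
    list_spec: ListSpec,
    params: Mapping[str, float] | str = "hubble",
    rng: np.random.Generator | None = None,
) -> Agent:
    """Instantiate an agent by kind.

    ``params`` may be a mapping of parameter values or the string
    ``"hubble"`` to use the reference parameter sets fitted to the monkey
    dataset (see :mod:`tisim.hubble`).
    """
    # imported here to avoid circularity: agent modules import this base
    from . import betasort, hubble, modelfree, rank, remerge  # noqa: F401

    if kind not in _REGISTRY:
        raise ValueError(f"unknown agent kind {kind!r}; known: {sorted(_REGISTRY)}")
    if isinstance(params, str):
        if params != "hubble":
            raise ValueError(f"unknown parameter preset {params!r}")
        params = hubble.HUBBLE_PARAMETERS[kind]
    cls = _REGISTRY[kind]
    kwargs = dict(params)
    if kind == "smc":
        if rng is None:
            raise ValueError("the particle-filter agent needs an rng at init")
        kwargs["rng"] = rng
    return cls(list_spec, **kwargs)
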