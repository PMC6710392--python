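"""Task construction for two-alternative serial-learning experiments.

A transitive-inference (TI) experiment presents pairs of items drawn from an
ordered list.  One item of every pair is "correct" (the one with lower rank,
i.e. closer to the dominant end of the list) and choosing it yields reward.
Trials are organized in blocks within which every pair appears exactly twice,
once per left/right screen placement, in randomly permuted order; the whole
schedule is fixed before the subject makes any choice, so choices never
influence what is presented next.

Five standard designs are provided:

``classical``
    Adjacent-pair training (11 blocks, 132 trials for a 7-item list) followed
    by all-pairs testing (5 blocks, 210 trials).
``reward_gradient``
    Same schedule, but the reward magnitude for a correct choice equals the
    rank of the correct item (1 unit for the dominant item, 2 for the next,
    and so on), putting reward magnitude in conflict with rank.
``massed``
    Adjacent-pair training, then 132 further trials of the single pair FG,
    then all-pairs testing.
``reversal``
    All 21 pairs trained for 210 trials, then the target ordering is
    reversed and all pairs are presented for another 210 trials.
``list_linking``
    Two 5-item lists trained on adjacent pairs (17 blocks, 272 trials),
    optionally followed by 34 trials of the linking pair EF, then all 45
    pairs of the implied 10-item list for 5 blocks (450 trials).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ListSpec",
    "StimulusPair",
    "Trial",
    "Block",
    "Phase",
    "Schedule",
    "PairClass",
    "enumerate_pairs",
    "classify_pair",
    "build_block",
    "build_design",
    "DESIGN_KINDS",
]


def default_items(n: int) -> tuple[str, ...]:
    """Item identifiers A, B, C, ... for an n-item list."""
    if n > 26:
        raise ValueError("default item labels support at most 26 items")
    return tuple(string.ascii_uppercase[:n])


@dataclass(frozen=True)
class ListSpec:
    """An ordered list of unique items; rank 1 is the dominant end.

    ``reward_magnitudes`` gives the reward delivered when each item is the
    correct choice (default 1 for every item).
    """

    items: tuple[str, ...]
    reward_magnitudes: Mapping[str, float] | None = None

    def __post_init__(self):
        if len(self.items) < 2:
            raise ValueError("a list needs at least 2 items")
        if len(set(self.items)) != len(self.items):
            raise ValueError("list items must be unique")
        if self.reward_magnitudes is not None:
            missing = set(self.items) - set(self.reward_magnitudes)
            if missing:
                raise ValueError(f"missing reward magnitudes for {sorted(missing)}")
            if any(m <= 0 for m in self.reward_magnitudes.values()):
                raise ValueError("reward magnitudes must be positive")

    @classmethod
    def of_size(cls, n: int, reward_magnitudes=None) -> "ListSpec":
        return cls(default_items(n), reward_magnitudes)

    @property
    def n(self) -> int:
        return len(self.items)

    def rank(self, item: str) -> int:
        """1-based rank; rank 1 is the always-dominant item."""
        try:
            return self.items.index(item) + 1
        except ValueError:
            raise KeyError(f"unknown item {item!r}") from None

    def index(self, item: str) -> int:
        return self.rank(item) - 1

    def magnitude(self, item: str) -> float:
        if self.reward_magnitudes is None:
            return 1.0
        return float(self.reward_magnitudes[item])

    def correct_of(self, a: str, b: str) -> str:
        """The dominant (lower-rank) member of the pair under this ordering."""
        return a if self.rank(a) < self.rank(b) else b

    def reversed(self) -> "ListSpec":
        return ListSpec(tuple(reversed(self.items)), self.reward_magnitudes)


@dataclass(frozen=True)
class StimulusPair:
    """One left/right arrangement of two items, with the correct member."""

    left: str
    right: str
    correct: str

    def __post_init__(self):
        if self.left == self.right:
            raise ValueError("pair members must differ")
        if self.correct not in (self.left, self.right):
            raise ValueError("correct item must be a member of the pair")

    @property
    def items(self) -> frozenset[str]:
        return frozenset((self.left, self.right))

    @property
    def incorrect(self) -> str:
        return self.right if self.correct == self.left else self.left


@dataclass(frozen=True)
class Trial:
    pair: StimulusPair
    phase_label: str
    reward_magnitude: float = 1.0

    def __post_init__(self):
        if self.reward_magnitude <= 0:
            raise ValueError("reward magnitude must be positive")


@dataclass(frozen=True)
class Block:
    trials: tuple[Trial, ...]


@dataclass(frozen=True)
class Phase:
    label: str
    ordering: ListSpec
    trials: tuple[Trial, ...]


@dataclass(frozen=True)
class Schedule:
    """A fixed, choice-independent sequence of phases of trials."""

    phases: tuple[Phase, ...]
    list_spec: ListSpec = field(compare=False, default=None)

    @property
    def trials(self) -> tuple[Trial, ...]:
        return tuple(t for ph in self.phases for t in ph.trials)

    @property
    def n_trials(self) -> int:
        return sum(len(ph.trials) for ph in self.phases)

    def phase(self, label: str) -> Phase:
        for ph in self.phases:
            if ph.label == label:
                return ph
        raise KeyError(f"no phase labelled {label!r}")

    def truncated(self, last_label: str) -> "Schedule":
        """The schedule up to and including the phase ``last_label``."""
        kept = []
        for ph in self.phases:
            kept.append(ph)
            if ph.label == last_label:
                return Schedule(tuple(kept), self.list_spec)
        raise KeyError(f"no phase labelled {last_label!r}")


class PairClass(str, Enum):
    ADJACENT = "adjacent"
    TERMINAL = "terminal"
    CRITICAL = "critical"
    OTHER = "other-nonadjacent"


def enumerate_pairs(list_spec: ListSpec) -> set[frozenset[str]]:
    """All n(n-1)/2 unordered item pairs of the list."""
    items = list_spec.items
    return {
        frozenset((items[i], items[j]))
        for i in range(len(items))
        for j in range(i + 1, len(items))
    }


def classify_pair(pair: Iterable[str], list_spec: ListSpec) -> tuple[PairClass, int]:
    """Classify a pair relative to adjacent-pair training on the list.

    Returns ``(class, symbolic distance)`` where distance is the absolute
    rank difference.  Adjacent pairs (distance 1) are the training set;
    pairs containing a terminal item (rank 1 or rank n) have unambiguous
    reward histories; the remaining non-adjacent, non-terminal pairs are the
    "critical" pairs whose above-chance discrimination evidences inference.
    """
    a, b = tuple(pair)
    ra, rb = list_spec.rank(a), list_spec.rank(b)
    distance = abs(ra - rb)
    if distance == 0:
        raise ValueError("pair members must differ")
    if distance == 1:
        cls = PairClass.ADJACENT
    elif 1 in (ra, rb) or list_spec.n in (ra, rb):
        cls = PairClass.TERMINAL
    else:
        cls = PairClass.CRITICAL
    return cls, distance


def critical_pairs(list_spec: ListSpec) -> set[frozenset[str]]:
    return {
        p
        for p in enumerate_pairs(list_spec)
        if classify_pair(p, list_spec)[0] is PairClass.CRITICAL
    }


def adjacent_pairs(list_spec: ListSpec) -> list[frozenset[str]]:
    items = list_spec.items
    return [frozenset((items[i], items[i + 1])) for i in range(len(items) - 1)]


def nonterminal_pairs(list_spec: ListSpec) -> set[frozenset[str]]:
    terminals = {list_spec.items[0], list_spec.items[-1]}
    return {p for p in enumerate_pairs(list_spec) if not (p & terminals)}


def _pair_trials(
    pair: frozenset[str], ordering: ListSpec, label: str
) -> tuple[Trial, Trial]:
    """Both placements of one pair, correct item per the phase ordering."""
    a, b = sorted(pair, key=ordering.rank)
    mag = ordering.magnitude(a)  # a is the correct member
    return (
        Trial(StimulusPair(a, b, a), label, mag),
        Trial(StimulusPair(b, a, a), label, mag),
    )


def build_block(
    pair_set: Iterable[frozenset[str]],
    ordering: ListSpec,
    rng: np.random.Generator,
    label: str = "",
) -> Block:
    """A block presenting each pair twice, once per placement, permuted."""
    pairs = list(pair_set)
    if not pairs:
        raise ValueError("a block needs a nonempty pair set")
    trials = [t for p in pairs for t in _pair_trials(p, ordering, label)]
    order = rng.permutation(len(trials))
    return Block(tuple(trials[i] for i in order))


def _blocks_phase(
    label: str,
    ordering: ListSpec,
    pair_set: Sequence[frozenset[str]],
    n_blocks: int,
    rng: np.random.Generator,
) -> Phase:
    trials = []
    for _ in range(n_blocks):
        trials.extend(build_block(pair_set, ordering, rng, label).trials)
    return Phase(label, ordering, tuple(trials))


DESIGN_KINDS = ("classical", "reward_gradient", "massed", "reversal", "list_linking")


def build_design(
    kind: str,
    rng: np.random.Generator,
    *,
    n_items: int = 7,
    n_train_blocks: int = 11,
    n_test_blocks: int = 5,
    n_massed_trials: int = 132,
    n_link_trials: int = 34,
    n_link_train_blocks: int = 17,
    link: bool = True,
) -> Schedule:
    """Construct the full trial schedule for one of the five designs.

    Defaults reproduce the standard 7-item preparations: classical training
    is 11 twelve-trial blocks (132 trials) and testing 5 blocks of all 21
    pairs (210 trials).  ``link`` selects the Linking vs No-Linking variant
    of ``list_linking``.
    """
    if kind not in DESIGN_KINDS:
        raise ValueError(f"unknown design kind {kind!r}")

    if kind == "list_linking":
        if n_items != 10:
            n_items = 10
        full = ListSpec.of_size(10)
        first = ListSpec(full.items[:5])
        second = ListSpec(full.items[5:])
        train_pairs = adjacent_pairs(first) + adjacent_pairs(second)
        phases = [
            _blocks_phase("train", full, train_pairs, n_link_train_blocks, rng)
        ]
        if link:
            link_pair = frozenset((full.items[4], full.items[5]))  # EF
            phases.append(
                _blocks_phase("link", full, [link_pair], n_link_trials // 2, rng)
            )
        phases.append(
            _blocks_phase("test", full, sorted(enumerate_pairs(full), key=sorted),
                          n_test_blocks, rng)
        )
        return Schedule(tuple(phases), full)

    if kind == "reward_gradient":
        spec = ListSpec.of_size(
            n_items,
            {it: float(i + 1) for i, it in enumerate(default_items(n_items))},
        )
    else:
        spec = ListSpec.of_size(n_items)

    all_pairs = sorted(enumerate_pairs(spec), key=sorted)
    adj = adjacent_pairs(spec)

    if kind in ("classical", "reward_gradient"):
        phases = (
            _blocks_phase("train", spec, adj, n_train_blocks, rng),
            _blocks_phase("test", spec, all_pairs, n_test_blocks, rng),
        )
    elif kind == "massed":
        if n_massed_trials % 2:
            raise ValueError("massed trial count must be even (counterbalanced)")
        massed_pair = frozenset(spec.items[-2:])  # FG for the 7-item list
        phases = (
            _blocks_phase("train", spec, adj, n_train_blocks, rng),
            _blocks_phase("massed", spec, [massed_pair], n_massed_trials // 2, rng),
            _blocks_phase("test", spec, all_pairs, n_test_blocks, rng),
        )
    else:  # reversal
        rev = spec.reversed()
        phases = (
            _blocks_phase("train", spec, all_pairs, n_test_blocks, rng),
            _blocks_phase("reversed", rev, all_pairs, n_test_blocks, rng),
        )
    return Schedule(phases, spec)
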