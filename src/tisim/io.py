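"""Choice-data CSV interchange, configuration, and fixture generation.

Two-alternative serial-learning choice data has no domain-standard file
format, so a fixed CSV dialect is used with header columns

    session, trial, phase, left_item, right_item, chosen_item,
    correct_item, reward

where ``reward`` is the magnitude available for the correct choice on that
trial.  Schedules can be exported in the same layout with the choice
column empty.  ``generate_choices`` simulates an agent over a design and
returns its realized choices as a dataset — the synthetic stand-in for
empirical data (one choice per trial, deterministic correct/incorrect
feedback).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .task import ListSpec, Schedule, build_design

__all__ = [
    "ChoiceTrial",
    "ChoiceDataset",
    "read_choices",
    "write_choices",
    "generate_choices",
    "schedule_to_frame",
    "load_config",
]

COLUMNS = (
    "session",
    "trial",
    "phase",
    "left_item",
    "right_item",
    "chosen_item",
    "correct_item",
    "reward",
)


@dataclass(frozen=True)
class ChoiceTrial:
    left: str
    right: str
    chosen: str
    correct: str
    reward: float = 1.0
    phase: str = ""
    session: int = 1


class ChoiceDataset:
    """An ordered sequence of observed two-alternative choices."""

    def __init__(self, trials: Sequence[ChoiceTrial], items: Sequence[str] | None = None):
        self.trials = tuple(trials)
        for i, tr in enumerate(self.trials):
            if tr.chosen not in (tr.left, tr.right):
                raise ValueError(
                    f"trial {i}: chosen item {tr.chosen!r} not in pair "
                    f"({tr.left!r}, {tr.right!r})"
                )
            if tr.correct not in (tr.left, tr.right):
                raise ValueError(f"trial {i}: correct item not in pair")
        if items is None:
            seen = []
            for tr in self.trials:
                for it in (tr.left, tr.right):
                    if it not in seen:
                        seen.append(it)
            items = sorted(seen)
        self.items = tuple(items)

    def __len__(self) -> int:
        return len(self.trials)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ChoiceDataset)
            and self.trials == other.trials
            and self.items == other.items
        )

    @property
    def list_spec(self) -> ListSpec:
        """Item universe as a ListSpec (ordering is only a label universe:
        agents start symmetric, and feedback comes from the data)."""
        return ListSpec(self.items)

    def subset(self, start: int, stop: int) -> "ChoiceDataset":
        return ChoiceDataset(self.trials[start:stop], self.items)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "session": [t.session for t in self.trials],
                "trial": np.arange(1, len(self.trials) + 1),
                "phase": [t.phase for t in self.trials],
                "left_item": [t.left for t in self.trials],
                "right_item": [t.right for t in self.trials],
                "chosen_item": [t.chosen for t in self.trials],
                "correct_item": [t.correct for t in self.trials],
                "reward": [t.reward for t in self.trials],
            }
        )


def read_choices(path) -> ChoiceDataset:
    """Parse the choice-data CSV; malformed rows are reported by line."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return ChoiceDataset([])
    if df.empty and df.columns.size == 0:
        return ChoiceDataset([])
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    trials = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        left, right = row.left_item, row.right_item
        chosen, correct = row.chosen_item, row.correct_item
        if chosen not in (left, right) or correct not in (left, right):
            raise ValueError(
                f"{path}:{i}: chosen/correct item must be one of the pair "
                f"({left!r}, {right!r})"
            )
        try:
            reward = float(row.reward)
            session = int(row.session)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{i}: malformed numeric field ({exc})") from exc
        trials.append(
            ChoiceTrial(left, right, chosen, correct, reward, str(row.phase), session)
        )
    return ChoiceDataset(trials)


def write_choices(dataset: ChoiceDataset, path, header_comment: str | None = None):
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        dataset.to_frame().to_csv(fh, index=False)


def schedule_to_frame(schedule: Schedule) -> pd.DataFrame:
    """Export a schedule in the choice-data layout with empty choice column."""
    rows = []
    for t, (phase, trial) in enumerate(
        ((ph.label, tr) for ph in schedule.phases for tr in ph.trials), start=1
    ):
        rows.append(
            {
                "session": 1,
                "trial": t,
                "phase": phase,
                "left_item": trial.pair.left,
                "right_item": trial.pair.right,
                "chosen_item": "",
                "correct_item": trial.pair.correct,
                "reward": trial.reward_magnitude,
            }
        )
    return pd.DataFrame(rows, columns=list(COLUMNS))


def generate_choices(
    agent_kind: str,
    params: Mapping[str, float] | str,
    design_kind: str,
    seed: int,
    *,
    design_kwargs: Mapping | None = None,
) -> ChoiceDataset:
    """Simulate one agent run and export its realized choices.

    Emulates the structure of the empirical preparation: a fixed
    counterbalanced schedule, one choice per trial, deterministic feedback.
    Deterministic given (configuration, seed).
    """
    from .base import make_agent  # local import: io is imported by fitting

    rng = np.random.default_rng(seed)
    schedule = build_design(design_kind, rng, **dict(design_kwargs or {}))
    agent = make_agent(agent_kind, schedule.list_spec, params, rng=rng)
    trials = []
    for ph in schedule.phases:
        for trial in ph.trials:
            pair = trial.pair
            agent.begin_trial(pair.left, pair.right)
            chosen = agent.choose(pair.left, pair.right, rng)
            reward = trial.reward_magnitude
            agent.update(pair.left, pair.right, chosen, pair.correct, reward, rng=rng)
            trials.append(
                ChoiceTrial(
                    pair.left, pair.right, chosen, pair.correct, reward, ph.label
                )
            )
    return ChoiceDataset(trials, schedule.list_spec.items)


def load_config(path) -> dict:
    """Flat key-value run configuration (YAML, hence also JSON)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
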