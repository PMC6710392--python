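"""Run agents over schedules and compute behavioral summaries.

Accuracy curves use the model's probability of the correct item at choice
time (which has much lower Monte-Carlo variance than realized 0/1 choices);
realized choices are recorded alongside.  "Transfer" accuracy is evaluated
at trial zero of a phase: the state of knowledge after the last trial of
the previous phase, before any update from the new phase.

The reorder statistic used for the reversal design is the first trial index
(0-based, within the phase) whose post-update greedy preferences agree with
the phase's target ordering on every critical pair and keep agreeing
through the end of the phase; simulations that never reach that absorbing
regime are scored at the phase length (a censored value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .base import Agent, make_agent
from .task import (
    ListSpec,
    PairClass,
    Schedule,
    build_design,
    classify_pair,
    critical_pairs,
    enumerate_pairs,
    nonterminal_pairs,
)

__all__ = [
    "ChoiceRecord",
    "SimulationResult",
    "run_simulation",
    "simulate_many",
    "transfer_accuracy",
    "effect_measures",
    "reorder_trial",
    "mean_reorder_trial",
    "reversal_recovery_trial",
]


@dataclass(frozen=True)
class ChoiceRecord:
    trial_index: int
    phase_label: str
    left: str
    right: str
    chosen: str
    was_correct: bool
    reward: float
    p_correct: float  # model probability of the correct item (nan if not recorded)


@dataclass
class SimulationResult:
    records: list[ChoiceRecord]
    #: pair-probability tables evaluated at the start of each phase (and at
    #: "end"), before any update from that phase: {label: {pair: p_correct}}
    phase_probs: dict[str, dict[frozenset[str], float]] = field(default_factory=dict)
    #: per requested phase, one greedy-preference snapshot per trial
    #: (taken after that trial's update): {label: [{pair: preferred-or-None}]}
    snapshots: dict[str, list[dict[frozenset[str], str | None]]] = field(
        default_factory=dict
    )
    #: per requested phase, post-update deterministic item scores per trial,
    #: shape (n_phase_trials, n_items): {label: ndarray}
    score_traces: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


def _eval_pair_probs(
    agent: Agent, pairs: Iterable[frozenset[str]], ordering: ListSpec
) -> dict[frozenset[str], float]:
    out = {}
    for pair in pairs:
        correct = ordering.correct_of(*pair)
        other = next(iter(pair - {correct}))
        out[pair] = agent.pair_prob(correct, other)
    return out


def run_simulation(
    agent: Agent,
    schedule: Schedule,
    rng: np.random.Generator,
    *,
    record_probs: bool | Sequence[str] = True,
    eval_pairs: Sequence[frozenset[str]] | None = None,
    eval_phase_starts: bool = False,
    snapshot_pairs: Sequence[frozenset[str]] | None = None,
    snapshot_phases: Sequence[str] | None = None,
    score_phases: Sequence[str] | None = None,
) -> SimulationResult:
    """Drive one agent through every trial of a fixed schedule.

    The schedule is never consulted or altered by the agent's choices.
    ``record_probs`` controls recording of the model probability of the
    correct item at choice time (True, False, or a sequence of phase
    labels); ``eval_phase_starts`` evaluates ``eval_pairs`` (default: all
    list pairs) at the start of each phase and after the final trial;
    ``snapshot_pairs`` records per-trial greedy preferences during
    ``snapshot_phases``.
    """
    if any(it not in agent._index for it in schedule.list_spec.items):
        raise ValueError("agent and schedule cover different item sets")
    result = SimulationResult(records=[])
    if eval_pairs is None:
        eval_pairs = sorted(enumerate_pairs(schedule.list_spec), key=sorted)
    t = 0
    for phase in schedule.phases:
        if eval_phase_starts:
            result.phase_probs[phase.label] = _eval_pair_probs(
                agent, eval_pairs, phase.ordering
            )
        snap_here = snapshot_pairs is not None and (
            snapshot_phases is None or phase.label in snapshot_phases
        )
        if snap_here:
            result.snapshots[phase.label] = []
        trace_here = score_phases is not None and phase.label in score_phases
        if trace_here:
            trace = []
        rec_here = (
            record_probs is True
            or (record_probs is not False and phase.label in record_probs)
        )
        for trial in phase.trials:
            pair = trial.pair
            agent.begin_trial(pair.left, pair.right)
            if rec_here:
                p_correct = agent.pair_prob(pair.correct, pair.incorrect)
            else:
                p_correct = float("nan")
            chosen = agent.choose(pair.left, pair.right, rng)
            was_correct = chosen == pair.correct
            reward = trial.reward_magnitude if was_correct else 0.0
            agent.update(
                pair.left,
                pair.right,
                chosen,
                pair.correct,
                trial.reward_magnitude,
                rng=rng,
            )
            result.records.append(
                ChoiceRecord(
                    t, phase.label, pair.left, pair.right, chosen, was_correct,
                    reward, p_correct,
                )
            )
            if snap_here:
                result.snapshots[phase.label].append(
                    {p: agent.greedy(*sorted(p)) for p in snapshot_pairs}
                )
            if trace_here:
                trace.append([agent.item_score(it) for it in schedule.list_spec.items])
            t += 1
        if trace_here:
            result.score_traces[phase.label] = np.asarray(trace)
    if eval_phase_starts:
        last_ordering = schedule.phases[-1].ordering
        result.phase_probs["end"] = _eval_pair_probs(
            agent, eval_pairs, last_ordering
        )
    return result


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_many(
    agent_kind: str,
    params: Mapping[str, float] | str,
    design_kind: str,
    n_sims: int,
    seed: int,
    *,
    design_kwargs: Mapping | None = None,
    agent_kwargs: Mapping | None = None,
    stop_after: str | None = None,
    **run_kwargs,
) -> list[SimulationResult]:
    """Independent seeded simulations, each with its own randomized trial order.

    ``stop_after`` truncates every schedule after the named phase (e.g. to
    evaluate the state at transfer without simulating the test phase).
    """
    design_kwargs = dict(design_kwargs or {})
    results = []
    for rng in _spawn_rngs(seed, n_sims):
        schedule = build_design(design_kind, rng, **design_kwargs)
        if stop_after is not None:
            schedule = schedule.truncated(stop_after)
        p = params if isinstance(params, str) else dict(params)
        if agent_kwargs and not isinstance(p, str):
            p.update(agent_kwargs)
        elif agent_kwargs:
            from .hubble import HUBBLE_PARAMETERS

            p = dict(HUBBLE_PARAMETERS[agent_kind])
            p.update(agent_kwargs)
        agent = make_agent(agent_kind, schedule.list_spec, p, rng=rng)
        results.append(run_simulation(agent, schedule, rng, **run_kwargs))
    return results


def transfer_accuracy(
    results: Sequence[SimulationResult],
    phase_label: str,
    pair_class: PairClass | None = None,
    list_spec: ListSpec | None = None,
) -> pd.Series:
    """Mean model probability of the correct item per pair at a phase start.

    Requires simulations run with ``eval_phase_starts=True``.  When
    ``pair_class`` is given (with its ``list_spec``), only pairs of that
    class are kept.
    """
    tables = [r.phase_probs[phase_label] for r in results]
    pairs = sorted(tables[0], key=sorted)
    if pair_class is not None:
        if list_spec is None:
            raise ValueError("pair_class filtering needs the list_spec")
        pairs = [p for p in pairs if classify_pair(p, list_spec)[0] is pair_class]
    data = {
        "".join(sorted(p)): np.mean([tab[p] for tab in tables]) for p in pairs
    }
    return pd.Series(data, name=phase_label)


def effect_measures(
    pair_accuracy: Mapping[frozenset[str], float], list_spec: ListSpec
) -> dict[str, float]:
    """Distance slope, terminal-item effect and critical-pair mean.

    The symbolic-distance slope is the least-squares slope of accuracy on
    distance over non-terminal pairs; the terminal-item effect is the mean
    accuracy of terminal-containing pairs minus that of non-terminal pairs.
    """
    nonterm = nonterminal_pairs(list_spec)
    xs, ys = [], []
    term_acc, nonterm_acc, crit_acc = [], [], []
    for pair, acc in pair_accuracy.items():
        pair = frozenset(pair)
        cls, dist = classify_pair(pair, list_spec)
        if pair in nonterm:
            xs.append(dist)
            ys.append(acc)
            nonterm_acc.append(acc)
        else:
            term_acc.append(acc)
        if cls is PairClass.CRITICAL:
            crit_acc.append(acc)
    if len(set(xs)) < 2:
        raise ValueError("distance slope needs at least two distance levels")
    slope = float(np.polyfit(xs, ys, 1)[0])
    return {
        "distance_slope": slope,
        "terminal_item_effect": float(np.mean(term_acc) - np.mean(nonterm_acc)),
        "critical_pair_mean": float(np.mean(crit_acc)) if crit_acc else float("nan"),
    }


def reorder_trial(
    snapshots: Sequence[Mapping[frozenset[str], str | None]],
    target_ordering: ListSpec,
    pairs: Iterable[frozenset[str]] | None = None,
) -> int | None:
    """First snapshot index from which greedy preferences stay target-correct.

    ``snapshots[t]`` maps pairs to the greedily preferred item after trial
    ``t`` of the phase.  Returns the first index of the absorbing regime in
    which every pair in ``pairs`` (default: the critical pairs of the
    target ordering) is preferred according to ``target_ordering`` through
    the end of the phase, or None if that never happens.
    """
    if pairs is None:
        pairs = critical_pairs(target_ordering)
    pairs = list(pairs)
    wanted = {p: target_ordering.correct_of(*p) for p in pairs}
    first = None
    for t, snap in enumerate(snapshots):
        ok = all(snap[p] == wanted[p] for p in pairs)
        if ok and first is None:
            first = t
        elif not ok:
            first = None
    return first


def mean_reorder_trial(
    agent_kind: str,
    params: Mapping[str, float] | str,
    n_sims: int,
    seed: int,
    *,
    agent_kwargs: Mapping | None = None,
) -> float:
    """Mean reversal-recovery trial over seeded reversal simulations.

    Runs the reversal design (all 21 pairs for 210 trials, then the
    reversed ordering for 210 trials), records post-update greedy
    preferences on the six critical pairs throughout the reversed phase,
    and averages the reorder statistic; never-recovering runs are censored
    at the phase length.
    """
    probe = build_design("reversal", np.random.default_rng(0))
    crit = sorted(critical_pairs(probe.list_spec), key=sorted)
    rev_ordering = probe.phases[-1].ordering
    phase_len = len(probe.phases[-1].trials)
    results = simulate_many(
        agent_kind,
        params,
        "reversal",
        n_sims,
        seed,
        agent_kwargs=agent_kwargs,
        record_probs=False,
        snapshot_pairs=crit,
        snapshot_phases=["reversed"],
    )
    vals = []
    for res in results:
        t = reorder_trial(res.snapshots["reversed"], rev_ordering, crit)
        vals.append(phase_len if t is None else t)
    return float(np.mean(vals))


def reversal_recovery_trial(
    agent_kind: str,
    params: Mapping[str, float] | str,
    n_sims: int,
    seed: int,
    *,
    agent_kwargs: Mapping | None = None,
) -> int | None:
    """Post-reversal trials until average critical-pair accuracy recovers.

    Runs the reversal design (all 21 pairs for 210 trials, then the
    reversed ordering for another 210) ``n_sims`` times.  At every
    post-reversal trial index, the model probability of the (reversed-)
    correct item is averaged across the simulations whose trial at that
    index presented a critical pair.  The recovery trial is the first
    index at which this averaged critical-pair accuracy exceeds chance and
    stays above chance through the end of the phase; None if it never
    does.  This population-average statistic is the package's summary of
    how many trials an agent needs to reorder the critical pairs after a
    reversal (the per-simulation greedy statistic is :func:`reorder_trial`).
    """
    probe = build_design("reversal", np.random.default_rng(0))
    crit = {
        "".join(sorted(p)) for p in critical_pairs(probe.list_spec)
    }
    results = simulate_many(
        agent_kind,
        params,
        "reversal",
        n_sims,
        seed,
        agent_kwargs=agent_kwargs,
        record_probs=["reversed"],
    )
    phase_len = len(probe.phases[-1].trials)
    acc = np.zeros(phase_len)
    cnt = np.zeros(phase_len)
    for res in results:
        t = 0
        for rec in res.records:
            if rec.phase_label != "reversed":
                continue
            if "".join(sorted((rec.left, rec.right))) in crit:
                acc[t] += rec.p_correct
                cnt[t] += 1
            t += 1
    first = None
    for t in range(phase_len):
        if cnt[t] == 0:
            continue  # no simulation presented a critical pair here
        if acc[t] / cnt[t] > 0.5:
            if first is None:
                first = t
        else:
            first = None
    return first
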