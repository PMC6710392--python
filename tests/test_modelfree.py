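"""Softmax policy, Q-learning and Value Transfer updates."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tisim.modelfree import QAgent, VTMAgent, softmax_policy
from tisim.task import ListSpec, build_design


@pytest.mark.parametrize(
    "theta, expected",
    [(1.0, 0.622), (2.280, 0.758)],
)
def test_softmax_worked_examples(theta, expected):
    p = softmax_policy((1.0, 0.5), theta)[0]
    assert round(p, 3) == expected


def test_softmax_zero_theta_is_chance():
    assert softmax_policy((5.0, -3.0), 0.0) == pytest.approx([0.5, 0.5])


def test_softmax_rejects_bad_inputs():
    with pytest.raises(ValueError):
        softmax_policy((np.inf, 0.0), 1.0)
    with pytest.raises(ValueError):
        softmax_policy((1.0, 0.0), -0.5)


@given(
    v=st.tuples(
        st.floats(-50, 50, allow_nan=False), st.floats(-50, 50, allow_nan=False)
    ),
    theta=st.floats(0, 10),
    bump=st.floats(0.1, 5),
)
def test_softmax_sums_to_one_and_is_monotone(v, theta, bump):
    p = softmax_policy(v, theta)
    assert p.sum() == pytest.approx(1.0)
    p_up = softmax_policy((v[0] + bump, v[1]), theta)
    assert p_up[0] >= p[0] - 1e-12


def test_softmax_overflow_safe():
    p = softmax_policy((1000.0, 0.0), 10.0)
    assert p[0] == pytest.approx(1.0)


# -- Q-learning --------------------------------------------------------------


def test_q_update_direct_substitution(list7):
    ag = QAgent(list7, delta=0.138, theta=1.0, gamma=0.0, update_mode="asymmetric")
    ag.update("A", "B", chosen="A", correct="A", magnitude=1.0)
    assert ag.item_score("A") == pytest.approx(0.138)


def test_q_update_with_prospective_term(list7):
    ag = QAgent(list7, delta=0.1, theta=1.0, gamma=0.5, update_mode="asymmetric")
    ag.q[list7.index("G")] = 0.6  # max of the value vector
    ag.update("A", "B", chosen="A", correct="A", magnitude=1.0)
    # delta * (c + gamma*max(Q) - Q) = 0.1 * (1 + 0.3 - 0)
    assert ag.item_score("A") == pytest.approx(0.13)


def test_q_symmetric_updates_unchosen_counterfactually(list7):
    ag = QAgent(list7, delta=0.2, theta=1.0, gamma=0.0)
    # choosing the wrong item: the unchosen item was correct and earns its
    # reward magnitude counterfactually
    ag.update("A", "B", chosen="B", correct="A", magnitude=2.0)
    assert ag.item_score("B") == pytest.approx(0.0)
    assert ag.item_score("A") == pytest.approx(0.4)


def _rescorla_wagner_oracle(schedule, delta, theta, rng):
    """Independent associative-learning-only reference (no prospective term)."""
    q = {it: 0.0 for it in schedule.list_spec.items}
    trace = []
    for trial in schedule.trials:
        a, b = trial.pair.left, trial.pair.right
        p_a = 1.0 / (1.0 + math.exp(-theta * (q[a] - q[b])))
        _ = a if rng.random() < p_a else b  # choice draw; symmetric updates ignore it
        ca = trial.reward_magnitude if a == trial.pair.correct else 0.0
        cb = trial.reward_magnitude if b == trial.pair.correct else 0.0
        qa, qb = q[a], q[b]
        q[a] = qa + delta * (ca - qa)
        q[b] = qb + delta * (cb - qb)
        trace.append(dict(q))
    return trace


def test_gamma_zero_matches_rescorla_wagner_oracle(rng):
    sched = build_design("classical", np.random.default_rng(0))
    oracle = _rescorla_wagner_oracle(sched, 0.3, 2.0, np.random.default_rng(42))
    ag = QAgent(sched.list_spec, delta=0.3, theta=2.0, gamma=0.0)
    agent_rng = np.random.default_rng(42)
    for t, trial in enumerate(sched.trials):
        a, b = trial.pair.left, trial.pair.right
        chosen = ag.choose(a, b, agent_rng)
        ag.update(a, b, chosen, trial.pair.correct, trial.reward_magnitude)
        for item in sched.list_spec.items:
            assert ag.item_score(item) == pytest.approx(oracle[t][item], abs=1e-12)


def test_vtm_tau_zero_matches_q_gamma_zero(rng):
    sched = build_design("classical", np.random.default_rng(1))
    q = QAgent(sched.list_spec, delta=0.25, theta=1.5, gamma=0.0)
    v = VTMAgent(sched.list_spec, delta=0.25, theta=1.5, tau=0.0)
    rq, rv = np.random.default_rng(7), np.random.default_rng(7)
    for trial in sched.trials:
        a, b = trial.pair.left, trial.pair.right
        cq = q.choose(a, b, rq)
        cv = v.choose(a, b, rv)
        assert cq == cv
        q.update(a, b, cq, trial.pair.correct, trial.reward_magnitude)
        v.update(a, b, cv, trial.pair.correct, trial.reward_magnitude)
    assert np.allclose(q.q, v.q)


def test_vtm_update_worked_example(list7):
    ag = VTMAgent(list7, delta=0.137, theta=1.0, tau=0.406, update_mode="asymmetric")
    ag.q[list7.index("B")] = 0.4
    ag.q[list7.index("C")] = 0.8
    ag.update("B", "C", chosen="B", correct="B", magnitude=1.0)
    # 0.4 + 0.137 * (1 + 0.406*0.8 - 0.4)
    assert ag.item_score("B") == pytest.approx(0.5267, abs=1e-4)


def test_vtm_transfers_value_to_unrewarded_partner(list7):
    """Repeatedly rewarding A in AB raises Q(B) although B never earns."""
    ag = VTMAgent(list7, delta=0.137, theta=2.26, tau=0.406)
    for _ in range(50):
        ag.update("A", "B", chosen="A", correct="A", magnitude=1.0)
    assert ag.item_score("B") > 0.1
    assert ag.item_score("A") > ag.item_score("B")


@pytest.mark.parametrize(
    "cls, kwargs",
    [
        (QAgent, dict(delta=1.5, theta=1.0)),
        (QAgent, dict(delta=0.1, theta=1.0, gamma=1.0)),
        (QAgent, dict(delta=0.1, theta=-1.0)),
        (VTMAgent, dict(delta=0.1, theta=1.0, tau=1.2)),
        (QAgent, dict(delta=0.1, theta=1.0, update_mode="sideways")),
    ],
)
def test_parameter_validation(list7, cls, kwargs):
    with pytest.raises(ValueError):
        cls(list7, **kwargs)


@given(seed=st.integers(0, 2**20), gamma=st.floats(0.0, 0.9))
def test_q_values_stay_bounded(seed, gamma):
    """|Q| <= max reward / (1 - gamma) under arbitrary trial sequences."""
    spec = ListSpec.of_size(4)
    ag = QAgent(spec, delta=0.5, theta=1.0, gamma=gamma)
    rng = np.random.default_rng(seed)
    bound = 1.0 / (1.0 - gamma)
    for _ in range(100):
        i, j = rng.choice(4, size=2, replace=False)
        a, b = spec.items[i], spec.items[j]
        correct = spec.correct_of(a, b)
        chosen = ag.choose(a, b, rng)
        ag.update(a, b, chosen, correct, 1.0)
        assert np.all(np.abs(ag.q) <= bound + 1e-9)


def test_asymmetric_updating_learns_more_slowly():
    """One-sided updates extract less information per trial."""
    from tisim.simulate import simulate_many

    def end_training_accuracy(mode):
        res = simulate_many(
            "q",
            "hubble",
            "classical",
            100,
            99,
            stop_after="train",
            eval_phase_starts=True,
            record_probs=False,
            agent_kwargs={"update_mode": mode},
        )
        vals = [np.mean(list(r.phase_probs["end"].values())) for r in res]
        return float(np.mean(vals))

    assert end_training_accuracy("symmetric") > end_training_accuracy("asymmetric")
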