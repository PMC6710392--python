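"""RL-Elo ratings and the sequential Monte Carlo rank filter."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

from tisim.rank import EloAgent, SMCAgent, systematic_resample
from tisim.task import ListSpec


def _elo(spec, delta=0.079, theta=1.529):
    return EloAgent(spec, delta=delta, theta=theta)


def test_equal_ratings_give_chance(list7):
    assert _elo(list7).pair_prob("A", "B") == pytest.approx(0.5)


def test_logistic_matches_independent_evaluation(list7):
    ag = _elo(list7, theta=1.529)
    ag.v[list7.index("A")] = 1.0
    assert ag.pair_prob("A", "B") == pytest.approx(expit(1.529), abs=1e-12)
    assert ag.pair_prob("A", "B") == pytest.approx(0.822, abs=5e-4)


def test_logistic_equals_two_option_softmax(list7):
    from tisim.modelfree import softmax_policy

    ag = _elo(list7, theta=2.0)
    ag.v[:2] = [0.3, -0.4]
    p = softmax_policy([2.0 * 0.3, 2.0 * -0.4], 1.0)[0]
    assert ag.pair_prob("A", "B") == pytest.approx(p)


def test_first_update_splits_delta_evenly(list7):
    ag = _elo(list7, delta=0.079)
    ag.update("A", "B", chosen="B", correct="A")
    assert ag.item_score("A") == pytest.approx(0.0395)
    assert ag.item_score("B") == pytest.approx(-0.0395)


def test_surprising_outcomes_move_ratings_more(list7):
    expected = _elo(list7)
    expected.v[list7.index("A")] = 1.0  # A already favored; win unsurprising
    surprising = _elo(list7)
    surprising.v[list7.index("B")] = 1.0  # A wins despite being the underdog
    va = expected.item_score("A")
    vb = surprising.item_score("A")
    expected.update("A", "B", chosen="A", correct="A")
    surprising.update("A", "B", chosen="A", correct="A")
    assert (surprising.item_score("A") - vb) > (expected.item_score("A") - va)


@given(seed=st.integers(0, 2**20), n_trials=st.integers(1, 80))
def test_total_rating_is_conserved(seed, n_trials):
    spec = ListSpec.of_size(5)
    ag = _elo(spec, delta=0.3, theta=1.2)
    rng = np.random.default_rng(seed)
    for _ in range(n_trials):
        i, j = rng.choice(5, size=2, replace=False)
        a, b = spec.items[i], spec.items[j]
        ag.update(a, b, chosen=a, correct=spec.correct_of(a, b))
    assert ag.v.sum() == pytest.approx(0.0, abs=1e-12)


def test_elo_updates_are_choice_independent(list7):
    """Rating dynamics depend only on the revealed correct item."""
    a1, a2 = _elo(list7), _elo(list7)
    a1.update("C", "D", chosen="C", correct="C")
    a2.update("C", "D", chosen="D", correct="C")
    assert np.array_equal(a1.v, a2.v)


# -- SMC ---------------------------------------------------------------------


def _smc(spec, rng, n_particles=1000, **kw):
    params = dict(sigma0=0.5, sigma=0.032, theta=1.410)
    params.update(kw)
    return SMCAgent(spec, rng=rng, n_particles=n_particles, **params)


def test_smc_init_distribution(list7, rng):
    ag = _smc(list7, rng, n_particles=20000)
    assert ag.weights.sum() == pytest.approx(1.0)
    assert ag.positions.std() == pytest.approx(0.5, rel=0.02)


def test_smc_init_reproducible(list7):
    a = _smc(list7, np.random.default_rng(5))
    b = _smc(list7, np.random.default_rng(5))
    assert np.array_equal(a.positions, b.positions)


def test_identical_positions_give_chance(list7, rng):
    ag = _smc(list7, rng)
    ag.positions[:] = 0.0
    assert ag.pair_prob("A", "B") == pytest.approx(0.5)


def test_single_particle_reduces_to_logistic(list7, rng):
    ag = _smc(list7, rng, n_particles=4, theta=1.41)
    ag.weights[:] = [1.0, 0.0, 0.0, 0.0]
    d = ag.positions[0, 0] - ag.positions[0, 1]
    assert ag.pair_prob("A", "B") == pytest.approx(float(expit(1.41 * d)))


def test_three_particle_mixture_matches_hand_computation(list7, rng):
    ag = _smc(list7, rng, n_particles=3, theta=2.0)
    ag.positions[:, :2] = [[0.4, 0.1], [-0.2, 0.5], [0.0, 0.0]]
    ag.weights[:] = [0.5, 0.3, 0.2]
    expected = 0.5 * expit(2 * 0.3) + 0.3 * expit(2 * -0.7) + 0.2 * 0.5
    assert ag.pair_prob("A", "B") == pytest.approx(float(expected))


def test_no_jitter_no_resample_leaves_positions_fixed(list7, rng):
    ag = _smc(list7, rng, sigma=0.0, ess_fraction=1e-9)
    before = ag.positions.copy()
    ag.update("A", "B", chosen="A", correct="A", rng=rng)
    assert np.array_equal(ag.positions, before)
    assert ag.weights.sum() == pytest.approx(1.0)


def test_correct_ordering_particles_gain_weight(list7, rng):
    ag = _smc(list7, rng, n_particles=2, sigma=0.0, ess_fraction=1e-9)
    ag.positions[:, :2] = [[1.0, -1.0], [-1.0, 1.0]]  # one correct, one inverted
    ag.weights[:] = 0.5
    ag.update("A", "B", chosen="A", correct="A", rng=rng)
    assert ag.weights[0] > 0.5 > ag.weights[1]
    assert ag.weights.sum() == pytest.approx(1.0)


def test_resampling_preserves_particle_count_and_resets_weights(list7, rng):
    ag = _smc(list7, rng, n_particles=500, ess_fraction=1.0)  # always resample
    ag.update("A", "B", chosen="A", correct="A", rng=rng)
    assert ag.positions.shape == (500, 7)
    assert np.allclose(ag.weights, 1.0 / 500)
    assert ag.n_resamples == 1


def test_systematic_resample_tracks_weights(rng):
    w = np.array([0.7, 0.2, 0.1])
    idx = systematic_resample(w, rng)
    counts = np.bincount(idx, minlength=3) / len(idx)
    assert counts[0] == pytest.approx(0.7, abs=1.0 / 3 + 1e-9)
    assert len(idx) == 3


def test_weights_stay_normalized_over_many_updates(list7, rng):
    ag = _smc(list7, rng, n_particles=300)
    spec = list7
    for _ in range(60):
        i, j = rng.choice(7, size=2, replace=False)
        a, b = spec.items[i], spec.items[j]
        ag.update(a, b, chosen=a, correct=spec.correct_of(a, b), rng=rng)
        assert ag.weights.sum() == pytest.approx(1.0)
    assert ag.positions.shape == (300, 7)


def test_smc_requires_rng(list7, rng):
    ag = _smc(list7, rng)
    with pytest.raises(ValueError):
        ag.update("A", "B", chosen="A", correct="A")
    with pytest.raises(ValueError):
        SMCAgent(list7, sigma0=0.0, sigma=0.1, theta=1.0, rng=rng)


def test_smc_reversal_recovery_is_much_slower_than_betasort():
    """After an order reversal the filter is trapped by its tiny jitter."""
    from tisim.simulate import reversal_recovery_trial

    bs = reversal_recovery_trial("betasort", "hubble", 30, 5)
    smc = reversal_recovery_trial(
        "smc", "hubble", 30, 5, agent_kwargs={"n_particles": 500}
    )
    assert bs is not None and bs < 30
    assert smc is None or smc > 2 * bs
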