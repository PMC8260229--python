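"""Stochastic simulator: redistribution, episodes, invasion, dispersal."""

import math

import numpy as np
import pytest

from patchforage import (
    Environment,
    ForagerStrategy,
    PatchGameConfig,
    dispersal_advantage,
    ess_switch_probability,
    invasion_payoff,
    payoff_remain,
    population_payoff,
    redistribute,
    simulate,
    simulate_episode,
)

TWO_PATCH = Environment(patch_sizes=(1.0, 1.0), initial_counts=(9, 1), switch_cost=0.1)
TWO_PATCH_FREE = Environment(patch_sizes=(1.0, 1.0), initial_counts=(9, 1))


# ---------------------------------------------------------------------------
# independent oracle: exact invasion payoff for two patches by enumeration.
# One focal worm of origin ~ n_i/N plays q, the other N-1 worms play p;
# switcher counts and landings are enumerated with binomial weights, and food
# stranded in an emptied patch is shared N-ways (same rule as the simulator).


def exact_invasion_payoff(n1, n2, food, cost, resident_p, q):
    n_total = n1 + n2

    def binom(n, k, pr):
        return math.comb(n, k) * pr**k * (1 - pr) ** (n - k)

    total = 0.0
    for origin, n_origin in ((0, n1), (1, n2)):
        others = [n1, n2]
        others[origin] -= 1
        expected = 0.0
        for s1 in range(others[0] + 1):
            for s2 in range(others[1] + 1):
                w_s = binom(others[0], s1, resident_p) * binom(others[1], s2, resident_p)
                s = s1 + s2
                for k in range(s + 1):
                    w = w_s * binom(s, k, 0.5)
                    m_others = (others[0] - s1 + k, others[1] - s2 + (s - k))

                    def payoff(patch, paid_cost):
                        m = [m_others[0], m_others[1]]
                        m[patch] += 1
                        stranded = sum(food for mi in m if mi == 0)
                        return (
                            food / m[patch]
                            + stranded / n_total
                            - (cost if paid_cost else 0.0)
                        )

                    remain = payoff(origin, False)
                    switch = 0.5 * payoff(0, True) + 0.5 * payoff(1, True)
                    expected += w * ((1 - q) * remain + q * switch)
        total += (n_origin / n_total) * expected
    return total


# ---------------------------------------------------------------------------
# redistribution


def test_redistribute_identity_at_zero(rng):
    assert np.array_equal(redistribute([9, 1], 0.0, rng), [9, 1])


def test_redistribute_conserves_worms(rng):
    for _ in range(200):
        counts = rng.integers(0, 20, size=rng.integers(2, 6))
        if counts.sum() == 0:
            continue
        p = float(rng.random())
        assert redistribute(counts, p, rng).sum() == counts.sum()


def test_redistribute_mean_matches_closed_form(rng):
    acc = np.zeros(2)
    reps = 10_000
    for _ in range(reps):
        acc += redistribute([9, 1], 1.0, rng)
    # full switching splits the N=10 worms binomially; mean N/2 per patch
    se = math.sqrt(10 * 0.25 / reps)
    assert abs(acc[0] / reps - 5.0) < 3 * se


def test_redistribute_uniform_landing_three_patches(rng):
    acc = np.zeros(3)
    reps = 10_000
    for _ in range(reps):
        acc += redistribute([6, 3, 1], 1.0, rng)
    se = math.sqrt(10 * (1 / 3) * (2 / 3) / reps)
    assert np.all(np.abs(acc / reps - 10 / 3) < 3 * se)


# ---------------------------------------------------------------------------
# episodes


def test_episode_deterministic_without_switching(rng):
    res = simulate_episode(TWO_PATCH_FREE, ForagerStrategy(p_switch=0.0), rng)
    assert res.occupancy_after_switch == (9.0, 1.0)
    intakes = np.sort(res.per_worm_intakes)
    assert np.allclose(intakes[:9], 1 / 9) and intakes[9] == pytest.approx(1.0)


def test_episode_mean_equals_analytic_value_at_p_zero():
    env = Environment(patch_sizes=(1.0, 1.0), initial_counts=(9, 1), switch_cost=0.2)
    res = simulate(env, ForagerStrategy(p_switch=0.0), n_reps=5, seed=0)
    cfg = PatchGameConfig(9, 1, 1.0, 0.2)
    assert res.mean_intake == pytest.approx(payoff_remain(cfg, 0.0))
    assert res.intake_se == 0.0


def test_identical_seeds_are_bit_identical():
    strat = ForagerStrategy(p_switch=0.6)
    a = simulate(TWO_PATCH, strat, n_reps=50, seed=42)
    b = simulate(TWO_PATCH, strat, n_reps=50, seed=42)
    assert a.mean_intake == b.mean_intake
    assert np.array_equal(a.per_worm_intakes, b.per_worm_intakes)
    c = simulate(TWO_PATCH, strat, n_reps=50, seed=43)
    assert not np.array_equal(a.per_worm_intakes, c.per_worm_intakes)


def test_worst_case_intake_bounded_below_by_cost():
    env = Environment(patch_sizes=(1.0, 1.0), initial_counts=(5, 5), switch_cost=0.4)
    res = simulate(env, ForagerStrategy(p_switch=1.0), n_reps=300, seed=3)
    assert res.per_worm_intakes.min() >= -0.4
    assert res.mean_intake >= -0.4


@pytest.mark.parametrize("p", [0.25, 0.5, 0.75])
def test_population_mean_matches_mean_field(p):
    res = simulate(TWO_PATCH, ForagerStrategy(p_switch=p), n_reps=4000, seed=11)
    theory = population_payoff(PatchGameConfig(9, 1, 1.0, 0.1), p)
    assert abs(res.mean_intake - theory) <= 3 * res.intake_se
    # occupancy means track the closed form too
    m1 = 9 * (1 - p) + 5 * p
    assert res.occupancy_after_switch[0] == pytest.approx(m1, abs=0.1)


def test_environment_validation():
    with pytest.raises(ValueError):
        Environment(patch_sizes=(1.0,), initial_counts=(5,))
    with pytest.raises(ValueError):
        Environment(patch_sizes=(1.0, 1.0), initial_counts=(10, 0))
    with pytest.raises(ValueError):
        Environment(patch_sizes=(1.0, 1.0), initial_counts=(9, 1), dispersal_success=1.5)


# ---------------------------------------------------------------------------
# invasion


def test_resident_focal_matches_population_mean():
    pop = simulate(TWO_PATCH, ForagerStrategy(p_switch=0.4), n_reps=4000, seed=5)
    mean, se = invasion_payoff(TWO_PATCH, 0.4, 0.4, n_reps=4000, seed=5)
    assert abs(mean - pop.mean_intake) <= 3 * math.hypot(se, pop.intake_se)


def test_switching_invades_non_switching_residents_when_free():
    stay, se0 = invasion_payoff(TWO_PATCH_FREE, 0.0, 0.0, n_reps=4000, seed=9)
    move, se1 = invasion_payoff(TWO_PATCH_FREE, 0.0, 1.0, n_reps=4000, seed=9)
    assert move - stay > 3 * math.hypot(se0, se1)


@pytest.mark.parametrize("q", [0.0, 0.5, 1.0])
def test_invasion_payoff_matches_exact_enumeration(q):
    p_star = ess_switch_probability(PatchGameConfig(9, 1, 1.0, 0.1)).p_star
    mean, se = invasion_payoff(TWO_PATCH, p_star, q, n_reps=6000, seed=21)
    exact = exact_invasion_payoff(9, 1, 1.0, 0.1, p_star, q)
    assert abs(mean - exact) <= 3 * se


def test_finite_population_favors_less_switching_than_mean_field():
    """At N=10 the continuum p* is not the finite-game optimum: a worm's body
    adds a whole competitor to the patch it joins, so the exact invasion
    payoff strictly decreases in the mutant switching probability."""
    p_star = ess_switch_probability(PatchGameConfig(9, 1, 1.0, 0.1)).p_star
    values = [
        exact_invasion_payoff(9, 1, 1.0, 0.1, p_star, q) for q in (0.0, 0.5, 1.0)
    ]
    assert values[0] > values[1] > values[2]
    # the resident's own payoff still matches the mean-field prediction
    resident = exact_invasion_payoff(9, 1, 1.0, 0.1, p_star, p_star)
    assert resident == pytest.approx(
        payoff_remain(PatchGameConfig(9, 1, 1.0, 0.1), p_star), abs=1e-9
    )


def test_mean_field_ess_uninvadable_in_large_population():
    """Scaling worms and food together leaves per-worm payoffs and p*
    unchanged while shrinking finite-population effects, so in a 200-worm
    world no mutant on the grid beats the mean-field resident."""
    scale = 20
    env = Environment(
        patch_sizes=(1.0 * scale, 1.0 * scale),
        initial_counts=(9 * scale, 1 * scale),
        switch_cost=0.1,
    )
    p_star = ess_switch_probability(PatchGameConfig(9, 1, 1.0, 0.1)).p_star
    resident, _ = invasion_payoff(env, p_star, p_star, n_reps=3000, seed=1)
    for q in np.linspace(0.0, 1.0, 6):
        mean, se = invasion_payoff(env, p_star, float(q), n_reps=3000, seed=1)
        assert mean <= resident + 3 * se


# ---------------------------------------------------------------------------
# dispersal


def test_dispersal_unattractive_while_food_abundant():
    env = Environment(
        patch_sizes=(1.0, 1.0),
        initial_counts=(9, 1),
        unoccupied_food=1.0,
        dispersal_success=0.05,
    )
    assert dispersal_advantage(env, remaining_food_fraction=1.0) < 0


def test_dispersal_pays_once_patches_are_depleted():
    env = Environment(
        patch_sizes=(1.0, 1.0),
        initial_counts=(9, 1),
        unoccupied_food=1.0,
        dispersal_success=0.3,
    )
    assert dispersal_advantage(env, remaining_food_fraction=0.0) > 0
    # advantage grows monotonically as the occupied patches empty
    fracs = np.linspace(1.0, 0.0, 11)
    adv = [dispersal_advantage(env, float(f)) for f in fracs]
    assert np.all(np.diff(adv) > 0)


def test_dispersal_never_pays_without_success_probability():
    env = Environment(
        patch_sizes=(1.0, 1.0), initial_counts=(9, 1), unoccupied_food=5.0
    )
    assert all(
        dispersal_advantage(env, f) <= 0 for f in np.linspace(0.0, 1.0, 11)
    )


def test_successful_dispersers_share_unoccupied_food():
    env = Environment(
        patch_sizes=(1.0, 1.0),
        initial_counts=(9, 1),
        unoccupied_food=2.0,
        dispersal_success=1.0,
    )
    res = simulate(env, ForagerStrategy(p_switch=0.0), n_reps=5, seed=0)
    # everyone disperses successfully: each of the 10 worms adds 2/10 food
    expected = payoff_remain(PatchGameConfig(9, 1, 1.0, 0.0), 0.0) + 0.2
    assert res.mean_intake == pytest.approx(expected)
    off = simulate(
        env, ForagerStrategy(p_switch=0.0, disperse_at_depletion=False), n_reps=5, seed=0
    )
    assert off.mean_intake == pytest.approx(expected - 0.2)
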