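"""Stochastic discrete-worm foraging simulator on K >= 2 occupied patches.

One episode runs the full foraging timeline the mean-field game abstracts:
each worm may switch patch once (landing uniformly over the K occupied
patches, possibly back at its origin, and paying cost c), every patch's food
is then shared evenly among its occupants and eaten to depletion, and
finally all worms disperse towards unoccupied habitat, where a disperser
succeeds with probability s and successful dispersers share the unoccupied
food A_U.  Worms are individuals, so the simulator exposes the
finite-population effects the closed forms average away; it is used to
verify the analytic equilibrium by mutant-invasion experiments.

Randomness discipline: every public entry point takes an integer seed and
replicate ``r`` draws from the independent sub-stream ``(seed, r)``.  The
same seed therefore yields bit-identical results, and sweeps that share a
seed (e.g. a mutant grid) share their noise replicate-by-replicate, giving
paired comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Environment",
    "ForagerStrategy",
    "SimResult",
    "redistribute",
    "simulate_episode",
    "simulate",
    "invasion_payoff",
    "dispersal_advantage",
]


@dataclass(frozen=True)
class Environment:
    """World the episode runs in.

    Parameters
    ----------
    patch_sizes : sequence of float
        Food units ``A_i`` in each occupied patch (K >= 2 entries, > 0).
    initial_counts : sequence of int
        Worms starting in each patch (>= 0; at least two patches total
        worms, total >= 2).
    unoccupied_food : float
        ``A_U``, food available at the unoccupied patch a successful
        disperser reaches (>= 0).
    dispersal_success : float
        Probability s in [0, 1] that a dispersing worm finds the unoccupied
        patch (unoccupied patches carry no pheromone and are hard to find).
    switch_cost : float
        Cost c (food units) paid by each switching worm.
    """

    patch_sizes: tuple[float, ...]
    initial_counts: tuple[int, ...]
    unoccupied_food: float = 0.0
    dispersal_success: float = 0.0
    switch_cost: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "patch_sizes", tuple(float(a) for a in self.patch_sizes))
        object.__setattr__(self, "initial_counts", tuple(int(n) for n in self.initial_counts))
        if len(self.patch_sizes) != len(self.initial_counts):
            raise ValueError("patch_sizes and initial_counts must have equal length")
        if len(self.patch_sizes) < 2:
            raise ValueError("need at least two occupied patches")
        if any(a <= 0 for a in self.patch_sizes):
            raise ValueError("patch sizes must be > 0")
        if any(n < 0 for n in self.initial_counts):
            raise ValueError("worm counts must be >= 0")
        if sum(1 for n in self.initial_counts if n > 0) < 2:
            raise ValueError("at least two patches must start occupied")
        if not 0.0 <= self.dispersal_success <= 1.0:
            raise ValueError("dispersal_success must lie in [0, 1]")
        if self.unoccupied_food < 0 or self.switch_cost < 0:
            raise ValueError("food amounts and costs must be >= 0")

    @property
    def n_patches(self) -> int:
        return len(self.patch_sizes)

    @property
    def n_worms(self) -> int:
        return int(sum(self.initial_counts))


@dataclass(frozen=True)
class ForagerStrategy:
    """A forager's policy for the episode.

    ``p_switch`` is the probability of switching at episode start.
    ``disperse_at_depletion`` applies the standing assumption that worms do
    not disperse until the occupied patches are depleted: when on, every
    worm attempts dispersal after feeding ends; when off, the dispersal
    phase is skipped entirely.
    """

    p_switch: float
    disperse_at_depletion: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_switch <= 1.0:
            raise ValueError("p_switch must lie in [0, 1]")


@dataclass(frozen=True)
class SimResult:
    """Replicate-aggregated simulation outcome."""

    mean_intake: float
    intake_se: float
    occupancy_after_switch: tuple[float, ...]
    per_worm_intakes: np.ndarray = field(repr=False)


def _rng_for(seed: int, replicate: int) -> np.random.Generator:
    # sub-stream (seed, r): independent across replicates, reproducible
    return np.random.default_rng([seed, replicate])


def redistribute(
    counts: Sequence[int], p: float, rng: np.random.Generator
) -> np.ndarray:
    """One switching round on per-patch counts.

    Each worm independently switches with probability p; a switcher lands
    uniformly over all K occupied patches (it may return to its origin).
    Total worm count is conserved; expected counts reduce to the two-patch
    closed form ``m_i = n_i (1-p) + N p / 2`` when K = 2.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size < 2:
        raise ValueError("need at least two patches")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    switchers = rng.binomial(counts, p)
    stayers = counts - switchers
    landed = rng.multinomial(int(switchers.sum()), np.full(counts.size, 1.0 / counts.size))
    return stayers + landed


def _episode_intakes(
    env: Environment, p_by_worm: np.ndarray, disperse: bool, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-worm intakes and post-switch occupancy for one episode.

    Worm w of origin patch i switches with probability ``p_by_worm[w]``
    (worms are ordered patch by patch).  A patch that ends the switching
    round with zero occupants keeps its food only until the other patches
    are depleted: worms forage on between occupied patches once their own
    runs out, so stranded food is eventually found and shared by the whole
    population (an even N-way split, the mean-field limit of that search).
    Total food in occupied patches is therefore fully consumed.
    """
    k = env.n_patches
    origins = np.repeat(np.arange(k), env.initial_counts)
    n = origins.size
    switched = rng.random(n) < p_by_worm
    landings = rng.integers(0, k, size=n)
    dest = np.where(switched, landings, origins)
    occupancy = np.bincount(dest, minlength=k)
    sizes = np.asarray(env.patch_sizes)
    intake = sizes[dest] / occupancy[dest]  # dest patches are occupied by construction
    stranded = float(sizes[occupancy == 0].sum())
    if stranded > 0.0:
        intake = intake + stranded / n
    intake = intake - env.switch_cost * switched
    if disperse:
        found = rng.random(n) < env.dispersal_success
        n_found = int(found.sum())
        if n_found > 0:
            intake = intake + found * (env.unoccupied_food / n_found)
    return intake, occupancy


def simulate_episode(
    env: Environment, strategy: ForagerStrategy, rng: np.random.Generator
) -> SimResult:
    """Run a single replicate; see module docstring for the episode timeline."""
    p = np.full(env.n_worms, strategy.p_switch)
    intakes, occ = _episode_intakes(env, p, strategy.disperse_at_depletion, rng)
    return SimResult(
        mean_intake=float(intakes.mean()),
        intake_se=0.0,
        occupancy_after_switch=tuple(float(x) for x in occ),
        per_worm_intakes=intakes,
    )


def simulate(
    env: Environment, strategy: ForagerStrategy, n_reps: int, seed: int
) -> SimResult:
    """Run ``n_reps`` independent episodes and aggregate.

    ``mean_intake`` averages the per-episode population means; ``intake_se``
    is its Monte-Carlo standard error across replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    means = np.empty(n_reps)
    occ = np.zeros(env.n_patches)
    all_intakes = []
    for r in range(n_reps):
        res = simulate_episode(env, strategy, _rng_for(seed, r))
        means[r] = res.mean_intake
        occ += np.asarray(res.occupancy_after_switch)
        all_intakes.append(res.per_worm_intakes)
    se = float(means.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    return SimResult(
        mean_intake=float(means.mean()),
        intake_se=se,
        occupancy_after_switch=tuple(occ / n_reps),
        per_worm_intakes=np.concatenate(all_intakes),
    )


def invasion_payoff(
    env: Environment,
    resident_p: float,
    mutant_p: float,
    n_reps: int,
    seed: int,
    disperse_at_depletion: bool = True,
) -> tuple[float, float]:
    """Mean intake of a single mutant in a resident population.

    Each replicate, one focal worm (chosen uniformly, so its origin patch
    follows the occupancy prior ``n_i / N``) plays ``mutant_p`` while every
    other worm plays ``resident_p``.  Returns the focal's Monte-Carlo mean
    intake and its standard error.  Replicate r uses sub-stream (seed, r),
    so runs sharing a seed are noise-paired across mutant values.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not 0.0 <= resident_p <= 1.0 or not 0.0 <= mutant_p <= 1.0:
        raise ValueError("switching probabilities must lie in [0, 1]")
    n = env.n_worms
    focal_intakes = np.empty(n_reps)
    for r in range(n_reps):
        rng = _rng_for(seed, r)
        focal = int(rng.integers(n))
        p = np.full(n, resident_p)
        p[focal] = mutant_p
        intakes, _ = _episode_intakes(env, p, disperse_at_depletion, rng)
        focal_intakes[r] = intakes[focal]
    se = float(focal_intakes.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    return float(focal_intakes.mean()), se


def dispersal_advantage(env: Environment, remaining_food_fraction: float) -> float:
    """Expected gain from dispersing now rather than staying put.

    A lone disperser succeeds with probability s and, being the only one,
    eats the unoccupied patch's food ``A_U``; a stayer expects its even
    share of whatever food remains in the occupied patches,
    ``f * sum(A_i) / N`` with f the remaining-food fraction.  The advantage
    ``s * A_U - f * sum(A_i) / N`` is negative while occupied food is
    abundant and grows monotonically as the patches deplete, turning
    positive only near depletion — the patch-residence logic of the
    marginal value theorem.
    """
    if not 0.0 <= remaining_food_fraction <= 1.0:
        raise ValueError("remaining_food_fraction must lie in [0, 1]")
    stay = remaining_food_fraction * sum(env.patch_sizes) / env.n_worms
    return env.dispersal_success * env.unoccupied_food - stay
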