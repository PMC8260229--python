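"""Mean-field two-patch switching game.

Worms distributed over two food patches (``n1 >= n2``, so patch 1 is
overcrowded) may each switch patch with probability ``p``.  A switcher lands
in either patch with probability 1/2 (it may return to its origin), pays a
cost ``c``, and every patch's food ``A_E`` is then shared evenly among its
occupants.  The module provides closed-form occupancies, intakes and
strategy payoffs, the evolutionarily stable switching probability ``p*``
(the mixed strategy at which switching and remaining pay the same), and the
population-average payoff ``H_all = 2 A_E / N - p c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import bisect

__all__ = [
    "PatchGameConfig",
    "MixedStrategy",
    "EquilibriumResult",
    "expected_occupancy",
    "expected_intake",
    "payoff_remain",
    "payoff_switch",
    "payoff_gap",
    "ess_switch_probability",
    "population_payoff",
    "ess_surface",
]

#: default absolute tolerance on p* for the interior bisection root
DEFAULT_TOL = 1e-10
#: iteration cap for the root finder
MAX_ITER = 200


@dataclass(frozen=True)
class PatchGameConfig:
    """Parameters of the two-patch game.

    Worm counts are accepted as positive reals: the mean-field equations are
    continuous in ``n_i`` and the equilibrium surface varies the occupancy
    fraction continuously at fixed total.

    Parameters
    ----------
    n1, n2 : float
        Worms initially in patch 1 and patch 2; convention ``n1 >= n2 >= 1``
        (patch 1 is the overcrowded one).
    food_per_patch : float
        ``A_E``, food units available in each patch (> 0).
    switch_cost : float
        ``c``, food units a switching worm pays (>= 0), same units as
        ``food_per_patch``.
    """

    n1: float
    n2: float
    food_per_patch: float = 1.0
    switch_cost: float = 0.0

    def __post_init__(self) -> None:
        if not (self.n1 >= self.n2 >= 1):
            raise ValueError(
                f"require n1 >= n2 >= 1, got n1={self.n1}, n2={self.n2}"
            )
        if not self.food_per_patch > 0:
            raise ValueError("food_per_patch must be > 0")
        if self.switch_cost < 0:
            raise ValueError("switch_cost must be >= 0")

    @property
    def n_total(self) -> float:
        """Total worm count ``N = n1 + n2``."""
        return self.n1 + self.n2


@dataclass(frozen=True)
class MixedStrategy:
    """A mixed strategy: probability ``p`` of switching patch."""

    p: float

    def __post_init__(self) -> None:
        _check_probability(self.p)


@dataclass(frozen=True)
class EquilibriumResult:
    """Solved equilibrium switching probability.

    Attributes
    ----------
    p_star : float
        Equilibrium switching probability in [0, 1].
    regime : str
        ``"interior"`` (root of the payoff gap in (0, 1)), ``"all_switch"``
        (gap still >= 0 at p=1, includes the costless case), ``"no_switch"``
        (gap <= 0 already at p=0), or ``"neutral"`` (symmetric patches with
        zero cost: every p is an equilibrium; p_star=0 is returned).
    gap_at_p_star : float
        ``H_Switch - H_Remain`` evaluated at ``p_star`` (food units).
    """

    p_star: float
    regime: str
    gap_at_p_star: float


def _check_probability(p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p}")


def expected_occupancy(config: PatchGameConfig, p: float) -> tuple[float, float]:
    """Expected post-switch occupancy ``m_i = n_i (1-p) + N p / 2``.

    The first term is worms that started in patch i and remained; the second
    is switchers from either patch that landed there.  ``m1 + m2 = N``
    exactly for every p.
    """
    _check_probability(p)
    half_pool = (config.n1 + config.n2) * p / 2.0
    return (config.n1 * (1.0 - p) + half_pool, config.n2 * (1.0 - p) + half_pool)


def expected_intake(config: PatchGameConfig, p: float) -> tuple[float, float]:
    """Per-worm intake ``G_i = A_E / m_i`` under even sharing."""
    m1, m2 = expected_occupancy(config, p)
    if m1 <= 0 or m2 <= 0:
        raise ValueError("model assumes both patches occupied (m_i > 0)")
    return (config.food_per_patch / m1, config.food_per_patch / m2)


def payoff_remain(config: PatchGameConfig, p: float) -> float:
    """Expected payoff of remaining.

    A remaining worm sits in patch i with probability ``n_i / N`` (its prior
    over starting patches), so
    ``H_Remain = sum_i (n_i / N) * A_E / m_i(p)``.
    """
    g1, g2 = expected_intake(config, p)
    n = config.n_total
    return (config.n1 / n) * g1 + (config.n2 / n) * g2


def payoff_switch(config: PatchGameConfig, p: float) -> float:
    """Expected payoff of switching.

    A switcher lands in either patch with probability 1/2 and pays the cost:
    ``H_Switch = sum_i (1/2) * A_E / m_i(p) - c``.
    """
    g1, g2 = expected_intake(config, p)
    return 0.5 * (g1 + g2) - config.switch_cost


def payoff_gap(config: PatchGameConfig, p: float) -> float:
    """``H_Switch - H_Remain``; strictly decreasing in p when ``n1 > n2``."""
    g1, g2 = expected_intake(config, p)
    n = config.n_total
    w1 = 0.5 - config.n1 / n
    w2 = 0.5 - config.n2 / n
    return w1 * g1 + w2 * g2 - config.switch_cost


def ess_switch_probability(
    config: PatchGameConfig, tol: float = DEFAULT_TOL
) -> EquilibriumResult:
    """Solve for the evolutionarily stable switching probability.

    The payoff gap is monotone decreasing in p for ``n1 > n2``, so the
    equilibrium is a boundary point or the unique interior root, found by
    bisection.

    Boundary logic: if deviating to switching never pays (gap <= 0 at p=0)
    no worm switches; if switching still pays when everyone switches
    (gap >= 0 at p=1, which always holds at c=0 with unequal patches)
    everyone switches.  Symmetric patches with zero cost make the gap
    identically zero: every p is an equilibrium and the result is flagged
    ``neutral``.
    """
    if config.n1 == config.n2 and config.switch_cost == 0.0:
        return EquilibriumResult(p_star=0.0, regime="neutral", gap_at_p_star=0.0)
    gap0 = payoff_gap(config, 0.0)
    if gap0 <= 0.0:
        return EquilibriumResult(p_star=0.0, regime="no_switch", gap_at_p_star=gap0)
    # closed form at p=1: occupancies equalize (m_i = N/2), so the two
    # payoffs differ by exactly the cost; evaluating the sum numerically
    # leaves ~1e-16 residue that would misclassify the c=0 boundary
    gap1 = -config.switch_cost
    if gap1 >= 0.0:
        return EquilibriumResult(p_star=1.0, regime="all_switch", gap_at_p_star=gap1)
    def gap(p: float) -> float:
        # keep the p=1 endpoint on the same closed form as the boundary test
        return gap1 if p == 1.0 else payoff_gap(config, p)

    root = bisect(gap, 0.0, 1.0, xtol=tol, maxiter=MAX_ITER)
    if not math.isfinite(root):
        raise ArithmeticError("bisection failed to converge")
    return EquilibriumResult(
        p_star=float(root), regime="interior", gap_at_p_star=payoff_gap(config, root)
    )


def population_payoff(config: PatchGameConfig, p: float) -> float:
    """Population-average payoff ``H_all = 2 A_E / N - p c``.

    Total food eaten is fixed at ``2 A_E`` regardless of how worms are
    distributed, so the only population-level effect of switching is the
    cost paid: costless switching is neutral for the population, costly
    switching strictly decreases the average payoff.  The ESS is driven by
    intraspecific competition, not group benefit.
    """
    _check_probability(p)
    return 2.0 * config.food_per_patch / config.n_total - p * config.switch_cost


def ess_surface(
    cost_grid: Sequence[float],
    fraction_grid: Sequence[float],
    n_total: float,
    food_per_patch: float = 1.0,
) -> np.ndarray:
    """Equilibrium p* over a (cost, initial-imbalance) grid.

    Parameters
    ----------
    cost_grid : sequence of float
        Switching costs c >= 0.
    fraction_grid : sequence of float
        Initial fractions ``n1 / N`` in [0.5, 1) (the convention n1 >= n2
        forbids fractions below one half).
    n_total, food_per_patch : float
        Total worm count N and per-patch food A_E, held fixed.

    Returns
    -------
    numpy.ndarray of shape (len(cost_grid), len(fraction_grid))
        Entry [j, k] is p* at (cost_grid[j], fraction_grid[k]).  p* is
        non-increasing along the cost axis and non-decreasing along the
        imbalance axis.
    """
    fracs = np.asarray(fraction_grid, dtype=float)
    costs = np.asarray(cost_grid, dtype=float)
    if np.any((fracs < 0.5) | (fracs >= 1.0)):
        raise ValueError("fractions must lie in [0.5, 1): n1 >= n2 and n2 >= 1")
    out = np.empty((costs.size, fracs.size))
    for j, c in enumerate(costs):
        for k, f in enumerate(fracs):
            n1 = f * n_total
            n2 = n_total - n1
            if n2 < 1.0 <= n2 + 1e-9 * n_total:  # absorb rounding at the n2=1 edge
                n2 = 1.0
            cfg = PatchGameConfig(
                n1=n1,
                n2=n2,
                food_per_patch=food_per_patch,
                switch_cost=float(c),
            )
            out[j, k] = ess_switch_probability(cfg).p_star
    return out
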