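"""Synthetic behavioral count tables with the structure the analysis assumes.

Two generators emulate the two assay designs:

* conditioning assays — each worm either fails to reach a spot (non-chooser)
  or picks the pheromone spot with a scenario-dependent probability q, so
  the population chemotaxis index converges to ``2q - 1``;
* choice-after-food time courses — worms feed on a depleting patch and
  leave with a per-hour hazard that rises as food runs out; a leaver
  immediately commits to the pheromone spot with probability ``q_early``
  during the early hours and ``q_late`` afterwards (azide at the spots
  makes arrivals final), producing the early-attraction / late-repulsion
  CI signature.

Both generators emit frames that conform exactly to the CSV schemas in
:mod:`patchforage.io` and are deterministic given their seed.  The choice
model is intentionally minimal — a binomial choice with a fixed q per
condition — and does not model plate geometry, gradient diffusion, or the
learning process that sets q in real worms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticAssayConfig",
    "SyntheticTimecourseConfig",
    "generate_conditioning_assays",
    "generate_choice_after_food",
    "ci_recovery_study",
]


@dataclass(frozen=True)
class SyntheticAssayConfig:
    """Conditioning-assay generator settings.

    ``scenarios`` maps each scenario label to q, the probability that a
    choosing worm picks the pheromone spot (CI scale: CI = 2q - 1).
    Defaults mirror the source experiments: 10 replicate assays per
    independent experiment with ~50 worms each.  ``nonchooser_rate`` is the
    probability a worm reaches neither spot within the assay; source data
    do not report it, and 0.2 is a plausible placeholder.
    """

    scenarios: Mapping[str, float]
    n_experiments: int = 4
    replicates_per_experiment: int = 10
    worms_per_assay: int = 50
    nonchooser_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValueError("at least one scenario is required")
        for label, q in self.scenarios.items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"choice probability for {label!r} not in [0, 1]")
        if min(self.n_experiments, self.replicates_per_experiment, self.worms_per_assay) < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.nonchooser_rate <= 1.0:
            raise ValueError("nonchooser_rate must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticTimecourseConfig:
    """Choice-after-food generator settings.

    The leaving model is a discrete-hour hazard
    ``baseline_leaving_rate * (1 + depletion_boost * (1 - food_fraction))``
    (capped at 1): leaving is rare while food is abundant and accelerates
    as the patch depletes.  Food drops each hour by ``consumption_rate``
    per worm still in the patch.  Defaults are calibrated so that, of 50
    worms on a patch worth ~2.5 worm-hours of food each, most have left by
    the end of the 5 hr assay.

    ``q_early`` applies to worms leaving in hours 1..``switch_hour``,
    ``q_late`` afterwards, encoding the learned preference inversion.
    """

    n_worms: int = 50
    n_hours: int = 5
    baseline_leaving_rate: float = 0.15
    depletion_boost: float = 5.0
    food_units: float = 120.0
    consumption_rate: float = 1.0
    q_early: float = 0.7
    q_late: float = 0.3
    switch_hour: int = 3
    n_experiments: int = 2
    replicates_per_experiment: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_worms < 1 or self.n_hours < 1:
            raise ValueError("n_worms and n_hours must be >= 1")
        if self.baseline_leaving_rate < 0 or self.depletion_boost < 0:
            raise ValueError("hazard parameters must be >= 0")
        if self.food_units <= 0 or self.consumption_rate < 0:
            raise ValueError("food_units must be > 0 and consumption_rate >= 0")
        for q in (self.q_early, self.q_late):
            if not 0.0 <= q <= 1.0:
                raise ValueError("choice probabilities must lie in [0, 1]")
        if not 1 <= self.switch_hour < self.n_hours:
            raise ValueError("require 1 <= switch_hour < n_hours")
        if min(self.n_experiments, self.replicates_per_experiment) < 1:
            raise ValueError("replication counts must be >= 1")


def generate_conditioning_assays(
    cfg: SyntheticAssayConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate conditioning assays; returns an assay-schema frame.

    Per experiment x replicate x scenario: ``worms_per_assay`` worms each
    independently fail to choose with ``nonchooser_rate``, otherwise pick
    the pheromone spot with the scenario's q.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    rows = []
    for e in range(1, cfg.n_experiments + 1):
        for rep in range(1, cfg.replicates_per_experiment + 1):
            for scenario, q in cfg.scenarios.items():
                choosers = rng.binomial(cfg.worms_per_assay, 1.0 - cfg.nonchooser_rate)
                n_p = rng.binomial(choosers, q)
                rows.append(
                    {
                        "experiment_id": f"exp{e}",
                        "scenario": scenario,
                        "replicate_id": f"rep{rep}",
                        "n_pheromone": int(n_p),
                        "n_control": int(choosers - n_p),
                        "n_total_placed": cfg.worms_per_assay,
                    }
                )
    return pd.DataFrame(rows)


def generate_choice_after_food(
    cfg: SyntheticTimecourseConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate choice-after-food time courses; returns a time-course frame.

    Each replicate starts ``n_worms`` on a patch of ``food_units`` food.
    Hour by hour: the hazard is evaluated on the food fraction at the start
    of the hour, leavers are drawn binomially and commit to a spot at once,
    then the worms still present eat.  Worms never return, so the per-hour
    leaver and arrival counts each sum to at most ``n_worms``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    rows = []
    for e in range(1, cfg.n_experiments + 1):
        for rep in range(1, cfg.replicates_per_experiment + 1):
            remaining = cfg.n_worms
            food = cfg.food_units
            for hour in range(1, cfg.n_hours + 1):
                frac = food / cfg.food_units
                hazard = cfg.baseline_leaving_rate * (
                    1.0 + cfg.depletion_boost * (1.0 - frac)
                )
                leavers = int(rng.binomial(remaining, min(1.0, hazard)))
                q = cfg.q_early if hour <= cfg.switch_hour else cfg.q_late
                to_pher = int(rng.binomial(leavers, q))
                remaining -= leavers
                food = max(0.0, food - cfg.consumption_rate * remaining)
                rows.append(
                    {
                        "experiment_id": f"exp{e}",
                        "replicate_id": f"rep{rep}",
                        "hour": hour,
                        "n_left_patch": leavers,
                        "new_at_pheromone": to_pher,
                        "new_at_control": leavers - to_pher,
                    }
                )
    return pd.DataFrame(rows)


def ci_recovery_study(
    q_grid: list[float],
    sizes: list[int],
    rng: np.random.Generator | None = None,
    n_assays: int = 200,
) -> pd.DataFrame:
    """Bias of the pooled CI estimator over a (q, worm-count) grid.

    For each cell, ``n_assays`` assays of ``n`` choosing worms are drawn
    and the pooled CI (ratio of summed counts) is compared with its target
    ``2q - 1``.  Pooling makes the estimator unbiased in the choice model,
    so the reported bias is Monte-Carlo noise shrinking with n.
    """
    if not q_grid or not sizes:
        raise ValueError("q_grid and sizes must be non-empty")
    rng = np.random.default_rng(0) if rng is None else rng
    rows = []
    for q in q_grid:
        for n in sizes:
            n_p = rng.binomial(n, q, size=n_assays)
            pooled_ci = (2.0 * n_p.sum() - n_assays * n) / (n_assays * n)
            rows.append(
                {
                    "q": q,
                    "n_worms": n,
                    "mean_estimated_ci": pooled_ci,
                    "bias": pooled_ci - (2.0 * q - 1.0),
                }
            )
    return pd.DataFrame(rows)
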