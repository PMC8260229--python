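"""Behavioral-assay statistics from worm count tables.

Two table shapes are consumed (see :mod:`patchforage.io` for the CSV
schemas):

* conditioning assays — per replicate, worms counted within the scoring
  radius of a pheromone spot (``n_pheromone``) and a control-solvent spot
  (``n_control``), under a labelled conditioning scenario;
* choice-after-food time courses — per replicate and hour, worms that
  abandoned the food patch that hour and new arrivals at each spot.

The central statistic is the chemotaxis index
CI = (Np - Nc) / (Np + Nc), in [-1, 1]: +1 is unanimous attraction to the
pheromone spot, -1 unanimous avoidance.  Summaries report mean +/- SEM
across independent experiments, the unit of replication used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UndefinedIndexError",
    "ChemotaxisSummary",
    "chemotaxis_index",
    "hourly_chemotaxis",
    "leaving_histogram",
    "summarize_experiments",
    "summarize_all",
]


class UndefinedIndexError(ValueError):
    """Raised when a chemotaxis index is requested with no choosing worms.

    Zero worms at both spots is "no information", which is distinct from a
    CI of 0 ("no preference"); tabular routines map this case to a missing
    value instead of raising.
    """


@dataclass(frozen=True)
class ChemotaxisSummary:
    """Per-scenario CI summary across independent experiments."""

    scenario: str
    ci_mean: float
    ci_sem: float
    n_experiments: int
    per_experiment_ci: tuple[float, ...]
    #: True when only one experiment contributed, making the SEM degenerate (0)
    single_experiment: bool = False


def chemotaxis_index(n_pheromone: float, n_control: float) -> float:
    """CI = (Np - Nc) / (Np + Nc); antisymmetric under swapping the spots."""
    if n_pheromone < 0 or n_control < 0:
        raise ValueError("counts must be non-negative")
    total = n_pheromone + n_control
    if total == 0:
        raise UndefinedIndexError("no worms at either spot: CI undefined")
    return (n_pheromone - n_control) / total


def _sem(values: np.ndarray) -> float:
    # sample (n-1) standard deviation over sqrt(n); 0 for a single value
    if values.size <= 1:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(values.size))


def _ci_series(num: pd.Series, den: pd.Series) -> pd.Series:
    out = (num - den) / (num + den)
    return out.where((num + den) > 0)  # zero-denominator -> NaN, not 0


def hourly_chemotaxis(tc: pd.DataFrame) -> pd.DataFrame:
    """Per-hour CI of *new* arrivals, mean +/- SEM across replicates.

    The CI at hour h uses only worms that reached a spot during hour h
    (arrival counts are incremental, not cumulative), so it reflects the
    preference of the worms that left the patch around that hour.
    Replicate-hours with no arrivals at either spot contribute a missing
    value and are excluded from that hour's mean and SEM.

    Returns a frame indexed by hour with columns ``ci_mean``, ``ci_sem``
    and ``n_replicates`` (replicates with any arrivals that hour).
    """
    _require_columns(tc, ["hour", "new_at_pheromone", "new_at_control"])
    _check_hours(tc)
    work = tc.copy()
    work["ci"] = _ci_series(
        work["new_at_pheromone"].astype(float), work["new_at_control"].astype(float)
    )
    grouped = work.groupby("hour")["ci"]
    out = pd.DataFrame(
        {
            "ci_mean": grouped.mean(),
            "ci_sem": grouped.apply(lambda s: _sem(s.dropna().to_numpy())),
            "n_replicates": grouped.count(),
        }
    )
    return out


def leaving_histogram(tc: pd.DataFrame) -> pd.DataFrame:
    """Per-hour mean +/- SEM of worms abandoning the food patch.

    Replicates of all experiments are treated as exchangeable.  A single
    replicate yields SEM 0 and ``degenerate=True``.
    """
    _require_columns(tc, ["hour", "n_left_patch"])
    if len(tc) == 0:
        raise ValueError("empty time-course table")
    _check_hours(tc)
    grouped = tc.groupby("hour")["n_left_patch"]
    out = pd.DataFrame(
        {
            "mean_left": grouped.mean(),
            "sem_left": grouped.apply(lambda s: _sem(s.to_numpy(dtype=float))),
            "n_replicates": grouped.count(),
        }
    )
    out["degenerate"] = out["n_replicates"] == 1
    return out


def summarize_experiments(
    counts: pd.DataFrame, scenario: str, aggregation: str = "pooled"
) -> ChemotaxisSummary:
    """Per-scenario CI mean +/- SEM across independent experiments.

    Within each experiment the ~10 replicate assays are combined into one
    per-experiment CI, then the mean and SEM are taken across experiments.

    ``aggregation="pooled"`` (default) sums Np and Nc over an experiment's
    replicates before forming the ratio — with ~50 worms per assay the
    ratio of sums is the less biased choice; ``aggregation="mean"`` instead
    averages the replicate-level CIs.
    """
    _require_columns(
        counts, ["experiment_id", "scenario", "n_pheromone", "n_control"]
    )
    if aggregation not in ("pooled", "mean"):
        raise ValueError("aggregation must be 'pooled' or 'mean'")
    sub = counts[counts["scenario"] == scenario]
    if len(sub) == 0:
        raise KeyError(f"scenario {scenario!r} not present in table")
    per_exp = []
    for _, grp in sub.groupby("experiment_id", sort=True):
        if aggregation == "pooled":
            per_exp.append(
                chemotaxis_index(grp["n_pheromone"].sum(), grp["n_control"].sum())
            )
        else:
            cis = _ci_series(
                grp["n_pheromone"].astype(float), grp["n_control"].astype(float)
            ).dropna()
            if len(cis) == 0:
                raise UndefinedIndexError(
                    "experiment has no replicate with any choosing worm"
                )
            per_exp.append(float(cis.mean()))
    arr = np.asarray(per_exp)
    return ChemotaxisSummary(
        scenario=scenario,
        ci_mean=float(arr.mean()),
        ci_sem=_sem(arr),
        n_experiments=arr.size,
        per_experiment_ci=tuple(per_exp),
        single_experiment=arr.size == 1,
    )


def summarize_all(counts: pd.DataFrame, aggregation: str = "pooled") -> pd.DataFrame:
    """Tabular convenience: one summary row per scenario in the table."""
    rows = []
    for scenario in pd.unique(counts["scenario"]):
        s = summarize_experiments(counts, scenario, aggregation=aggregation)
        rows.append(
            {
                "scenario": s.scenario,
                "ci_mean": s.ci_mean,
                "ci_sem": s.ci_sem,
                "n_experiments": s.n_experiments,
            }
        )
    return pd.DataFrame(rows)


def _require_columns(df: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing required columns: {missing}")


def _check_hours(tc: pd.DataFrame) -> None:
    hours = tc["hour"]
    if len(hours) and (
        not np.issubdtype(hours.dtype, np.integer) or (hours < 1).any()
    ):
        raise ValueError("hour column must contain integers >= 1")
    if {"experiment_id", "replicate_id"}.issubset(tc.columns):
        dup = tc.duplicated(subset=["experiment_id", "replicate_id", "hour"])
        if dup.any():
            raise ValueError(
                f"duplicate hours within a replicate at rows {list(tc.index[dup])}"
            )
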