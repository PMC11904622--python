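"""Replicate-ensemble evaluation and parameter-uncertainty regions.

The simulators are stochastic, so a controller's performance is a
distribution over seeds.  :func:`run_ensemble` summarizes reached states
and loss over a replicate ensemble; :func:`uncertainty_region` extracts the
set of controller parameters whose mean loss is statistically
indistinguishable (within one standard deviation) from the grid-search
optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

from .grid_abm import GridConfig, run
from .objectives import (
    GridSearchResult,
    SteadyStateObjective,
    loss_J1,
    reached_states,
)

__all__ = ["EnsembleSummary", "run_ensemble", "uncertainty_region"]


@dataclass
class EnsembleSummary:
    n: int
    mean_b: float
    sd_b: float
    mean_c: float
    sd_c: float
    mean_loss: float
    sd_loss: float
    table: pd.DataFrame
    seeds: List[int]


def run_ensemble(
    config: GridConfig,
    controller,
    objective: SteadyStateObjective,
    n: int = 50,
    seed0: int = 1000,
) -> EnsembleSummary:
    """Evaluate a rollout controller on ``n`` replicates with seeds
    ``seed0 + i``.  Standard deviations use ddof=1 and are 0 for n=1."""
    if n < 1:
        raise ValueError("need n >= 1 replicates")
    rows = []
    for i in range(n):
        seed = seed0 + i
        traj = run(
            config,
            controller=controller,
            burn_in=objective.burn_in,
            horizon=objective.horizon,
            seed=seed,
        )
        b_bar, c_bar = reached_states(traj, objective.Nt_star)
        rows.append(
            {"seed": seed, "b_bar": b_bar, "c_bar": c_bar,
             "loss": loss_J1((b_bar, c_bar), objective)}
        )
    table = pd.DataFrame(rows)
    sd = lambda col: float(table[col].std(ddof=1)) if n > 1 else 0.0
    return EnsembleSummary(
        n=n,
        mean_b=float(table["b_bar"].mean()),
        sd_b=sd("b_bar"),
        mean_c=float(table["c_bar"].mean()),
        sd_c=sd("c_bar"),
        mean_loss=float(table["loss"].mean()),
        sd_loss=sd("loss"),
        table=table,
        seeds=list(table["seed"]),
    )


def uncertainty_region(
    surface: GridSearchResult, mode: str = "loss"
) -> List[Tuple[float, float]]:
    """Parameter cells statistically indistinguishable from the optimum.

    ``mode="loss"`` (default): cells whose mean loss lies within one
    standard deviation of the optimum's mean loss, i.e.
    ``mean_loss <= mean_loss(opt) + sd_loss(opt)``.  ``mode="reached"``:
    cells whose mean reached states lie within one (per-axis) standard
    deviation of the optimum's reached states.  Both definitions always
    contain the optimum.
    """
    t1_opt, t2_opt = surface.optimum
    at_opt = np.flatnonzero(
        (surface.theta1 == t1_opt) & (surface.theta2 == t2_opt)
    )[0]
    if mode == "loss":
        cutoff = surface.mean_loss[at_opt] + surface.sd_loss[at_opt]
        mask = surface.mean_loss <= cutoff
    elif mode == "reached":
        db = np.abs(surface.mean_b - surface.mean_b[at_opt])
        dc = np.abs(surface.mean_c - surface.mean_c[at_opt])
        mask = (db <= surface.sd_b[at_opt]) & (dc <= surface.sd_c[at_opt])
        mask[at_opt] = True
    else:
        raise ValueError("mode must be 'loss' or 'reached'")
    return [
        (float(t1), float(t2))
        for t1, t2 in zip(surface.theta1[mask], surface.theta2[mask])
    ]
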