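"""Control objectives, reached-state extraction and controller training.

The steady-state and transient population-control tasks share the quadratic
loss J1 = (b_bar - b*)^2 + (c_bar - c*)^2, where b_bar, c_bar are the mean
prey/predator counts over the final averaging window of a rollout.  The
metabolic-pathway task minimizes J2 = sum_k S_k / sum_k (R_k + T_k), the
substrate wasted per unit of end product.

Training on the stochastic simulator uses seed-averaged losses with
derivative-free optimization (Nelder-Mead for the two-parameter controller,
simultaneous-perturbation stochastic approximation for the transient MLP);
the straight-through estimator defines how gradients pass through the
integer rounding wherever a differentiable relaxation of the plant exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from . import nn
from .control import (
    MLPParams,
    SteadyStateParams,
    mlp_controller,
    steady_state_controller,
)
from .grid_abm import GridConfig, Trajectory, run

__all__ = [
    "SteadyStateObjective",
    "TrainReport",
    "GridSearchResult",
    "reached_states",
    "loss_J1",
    "loss_J2",
    "make_targets",
    "evaluate_controller",
    "train_steady_state",
    "train_transient_mlp",
    "grid_search_theta",
]


@dataclass
class SteadyStateObjective:
    """Target reached states and the rollout windows used to measure them."""

    b_target: float
    c_target: float
    Nt_star: int = 100
    burn_in: int = 1000
    horizon: int = 1000

    def __post_init__(self) -> None:
        if not 1 <= self.Nt_star <= self.horizon:
            raise ValueError("need 1 <= Nt_star <= horizon")


@dataclass
class TrainReport:
    best_params: object
    best_loss: float
    loss_history: List[float]
    evaluations: int
    seed_schedule: List[int]
    converged: bool = True
    message: str = ""


def reached_states(traj, Nt_star: int) -> Tuple[float, float]:
    """Mean prey and predator counts over the final ``Nt_star`` periods."""
    if Nt_star < 1 or Nt_star > len(traj.b) - 1:
        raise ValueError("averaging window must fit inside the trajectory")
    return float(np.mean(traj.b[-Nt_star:])), float(np.mean(traj.c[-Nt_star:]))


def loss_J1(reached: Sequence[float], objective: SteadyStateObjective) -> float:
    """Quadratic steady-state loss; zero iff both targets are met exactly."""
    return float(
        (reached[0] - objective.b_target) ** 2 + (reached[1] - objective.c_target) ** 2
    )


def loss_J2(traj) -> float:
    """Substrate wasted per unit product: sum_k S_k / sum_k (R_k + T_k),
    sums over periods 1..Nt (the initial state is excluded)."""
    S = np.asarray(traj.S, dtype=float)[1:]
    R = np.asarray(traj.R, dtype=float)[1:]
    T = np.asarray(traj.T, dtype=float)[1:]
    denom = float(np.sum(R + T))
    if denom <= 0:
        raise ValueError("no end product formed: J2 undefined (product-free run)")
    return float(np.sum(S)) / denom


def make_targets(
    baseline_means: Sequence[float],
    prey_up: float = 0.10,
    pred_down: float = 0.50,
    **objective_kwargs,
) -> SteadyStateObjective:
    """Derive targets from uncontrolled baseline means: raise prey by
    ``prey_up`` and cut predators by ``pred_down`` (rounded to integers)."""
    if prey_up < -1 or pred_down < -1:
        raise ValueError("fractions must be >= -1")
    b, c = baseline_means
    if b < 0 or c < 0:
        raise ValueError("baseline means must be >= 0")
    return SteadyStateObjective(
        b_target=round(b * (1 + prey_up)),
        c_target=round(c * (1 - pred_down)),
        **objective_kwargs,
    )


def evaluate_controller(
    config: GridConfig,
    controller,
    objective: SteadyStateObjective,
    seeds: Sequence[int],
) -> Tuple[float, np.ndarray]:
    """Seed-averaged J1 of a rollout controller plus the per-seed reached
    states (rows: seed; columns: b_bar, c_bar)."""
    reached = np.empty((len(seeds), 2))
    losses = np.empty(len(seeds))
    for i, seed in enumerate(seeds):
        traj = run(
            config,
            controller=controller,
            burn_in=objective.burn_in,
            horizon=objective.horizon,
            seed=int(seed),
        )
        reached[i] = reached_states(traj, objective.Nt_star)
        losses[i] = loss_J1(reached[i], objective)
    return float(losses.mean()), reached


def _default_rollout(config: GridConfig, objective: SteadyStateObjective):
    def rollout(theta: Sequence[float], seed: int) -> Tuple[float, float]:
        controller = steady_state_controller(
            SteadyStateParams(max(theta[0], 0.0), max(theta[1], 0.0))
        )
        traj = run(
            config,
            controller=controller,
            burn_in=objective.burn_in,
            horizon=objective.horizon,
            seed=seed,
        )
        return reached_states(traj, objective.Nt_star)

    return rollout


def train_steady_state(
    config: GridConfig,
    objective: SteadyStateObjective,
    theta0: Sequence[float] = (0.005, 0.005),
    n_seeds: int = 5,
    seed0: int = 0,
    maxiter: int = 60,
    rollout: Optional[Callable[[Sequence[float], int], Tuple[float, float]]] = None,
) -> TrainReport:
    """Fit the two-parameter steady-state controller.

    Minimizes the seed-averaged J1 over (theta1, theta2) >= 0 with
    Nelder-Mead on a fixed seed schedule (the objective is then
    deterministic).  ``rollout`` may replace the lattice simulator by any
    plant mapping (theta, seed) to reached states, e.g. a differentiable toy
    model relaxed through the straight-through estimator.
    """
    seeds = [seed0 + i for i in range(n_seeds)]
    plant = rollout if rollout is not None else _default_rollout(config, objective)
    history: List[float] = []

    def f(theta) -> float:
        loss = float(
            np.mean([loss_J1(plant(np.maximum(theta, 0.0), s), objective) for s in seeds])
        )
        history.append(loss)
        return loss

    t0 = np.asarray(theta0, dtype=float)
    # a wide initial simplex: the floor rounding makes the loss piecewise
    # constant, so tiny default perturbations can start on a flat simplex
    simplex = np.array([t0, t0 * [1.6, 1.0] + [5e-4, 0.0],
                        t0 * [1.0, 1.6] + [0.0, 5e-4]])
    res = optimize.minimize(
        f,
        t0,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-3,
                 "initial_simplex": simplex},
    )
    # the zero controller is part of the search space; never do worse
    candidates = [np.maximum(res.x, 0.0), np.zeros(2)]
    cand_losses = [f(c) for c in candidates]
    best_theta = candidates[int(np.argmin(cand_losses))]
    return TrainReport(
        best_params=SteadyStateParams(float(best_theta[0]), float(best_theta[1])),
        best_loss=float(min(history)),
        loss_history=history,
        evaluations=len(history),
        seed_schedule=seeds,
        converged=bool(res.success),
        message=res.message,
    )


def train_transient_mlp(
    config: GridConfig,
    objective: SteadyStateObjective,
    params0: MLPParams,
    n_seeds: int = 3,
    seed0: int = 0,
    n_iter: int = 80,
    a0: float = 0.05,
    c0: float = 0.05,
    max_step: float = 1.0,
    loss_fn: Optional[Callable[[MLPParams, int], float]] = None,
) -> TrainReport:
    """Train the transient MLP controller with SPSA.

    Each iteration perturbs the flattened weights by a Rademacher direction,
    estimates the gradient of the seed-averaged J1 from two rollout batches
    and takes a decaying step whose norm is capped at ``max_step`` (the
    quadratic loss is on the count scale, so raw SPSA steps can catapult the
    weights into the saturated, zero-gradient region of the u_max clip).  ``loss_fn(params, seed)`` may replace the
    lattice rollout for toy plants.  ``loss_history`` records the
    best-so-far loss, which is non-increasing by construction.
    """
    rng = np.random.default_rng(seed0 + 990_001)
    seeds = [seed0 + i for i in range(n_seeds)]
    sizes = params0.layer_sizes

    def make(theta: np.ndarray) -> MLPParams:
        return MLPParams(
            layers=nn.unflatten(theta, sizes),
            activation=params0.activation,
            b_scale=params0.b_scale,
            c_scale=params0.c_scale,
            u_max=params0.u_max,
        )

    if loss_fn is None:

        def loss_fn(params: MLPParams, seed: int) -> float:  # type: ignore
            controller = mlp_controller(params, objective.burn_in, objective.horizon)
            traj = run(
                config,
                controller=controller,
                burn_in=objective.burn_in,
                horizon=objective.horizon,
                seed=seed,
            )
            return loss_J1(reached_states(traj, objective.Nt_star), objective)

    def batch_loss(theta: np.ndarray) -> float:
        params = make(theta)
        return float(np.mean([loss_fn(params, s) for s in seeds]))

    theta = nn.flatten(params0.layers).copy()
    best_theta = theta.copy()
    best_loss = batch_loss(theta)
    history = [best_loss]
    evals = 1
    for it in range(1, n_iter + 1):
        a_k = a0 / it**0.602
        c_k = c0 / it**0.101
        delta = rng.choice([-1.0, 1.0], size=theta.size)
        lp = batch_loss(theta + c_k * delta)
        lm = batch_loss(theta - c_k * delta)
        evals += 2
        ghat = (lp - lm) / (2 * c_k) * delta
        step = a_k * ghat
        norm = float(np.linalg.norm(step))
        if norm > max_step:
            step *= max_step / norm
        theta = theta - step
        loss = min(lp, lm)
        if loss < best_loss:
            best_loss = loss
            best_theta = (theta + c_k * delta if lp < lm else theta - c_k * delta).copy()
        history.append(best_loss)
    # final evaluation at the last iterate
    final = batch_loss(theta)
    evals += 1
    if final < best_loss:
        best_loss, best_theta = final, theta.copy()
    history.append(best_loss)
    return TrainReport(
        best_params=make(best_theta),
        best_loss=best_loss,
        loss_history=history,
        evaluations=evals,
        seed_schedule=seeds,
    )


@dataclass
class GridSearchResult:
    """Loss surface of the two-parameter controller on a (theta1, theta2)
    grid; row-major over theta1 (outer) and theta2 (inner)."""

    theta1: np.ndarray
    theta2: np.ndarray
    mean_loss: np.ndarray
    sd_loss: np.ndarray
    mean_b: np.ndarray
    sd_b: np.ndarray
    mean_c: np.ndarray
    sd_c: np.ndarray
    optimum: Tuple[float, float]
    replicates: int
    seed0: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "theta1": self.theta1,
                "theta2": self.theta2,
                "mean_loss": self.mean_loss,
                "sd_loss": self.sd_loss,
                "mean_b": self.mean_b,
                "sd_b": self.sd_b,
                "mean_c": self.mean_c,
                "sd_c": self.sd_c,
            }
        )


def grid_search_theta(
    config: GridConfig,
    objective: SteadyStateObjective,
    theta1_grid: Sequence[float],
    theta2_grid: Sequence[float],
    replicates: int = 3,
    seed0: int = 0,
    rollout: Optional[Callable[[Sequence[float], int], Tuple[float, float]]] = None,
) -> GridSearchResult:
    """Exhaustive search over a (theta1, theta2) grid.

    Each cell is evaluated with ``replicates`` rollouts on the common seed
    schedule ``seed0 + i`` (common random numbers across cells).  The
    optimum is the cell with minimal mean loss; ties break toward smaller
    theta1, then theta2.  Standard deviations use ddof=1 (0 for a single
    replicate).
    """
    if len(theta1_grid) == 0 or len(theta2_grid) == 0:
        raise ValueError("grids must be nonempty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    plant = rollout if rollout is not None else _default_rollout(config, objective)
    seeds = [seed0 + i for i in range(replicates)]
    cells = [(t1, t2) for t1 in theta1_grid for t2 in theta2_grid]
    n = len(cells)
    mean_loss = np.empty(n)
    sd_loss = np.empty(n)
    mean_b = np.empty(n)
    sd_b = np.empty(n)
    mean_c = np.empty(n)
    sd_c = np.empty(n)
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    for i, (t1, t2) in enumerate(cells):
        rb, rc, rl = [], [], []
        for s in seeds:
            b_bar, c_bar = plant((t1, t2), s)
            rb.append(b_bar)
            rc.append(c_bar)
            rl.append(loss_J1((b_bar, c_bar), objective))
        mean_loss[i] = np.mean(rl)
        sd_loss[i] = sd(rl)
        mean_b[i] = np.mean(rb)
        sd_b[i] = sd(rb)
        mean_c[i] = np.mean(rc)
        sd_c[i] = sd(rc)
    # ties break toward smaller theta1 then theta2: cells are generated in
    # that (row-major, ascending) order, and argmin returns the first hit
    order = np.lexsort((np.array([c[1] for c in cells]), np.array([c[0] for c in cells])))
    # cells are already sorted if the input grids were; sort defensively
    best = order[np.argmin(mean_loss[order])]
    return GridSearchResult(
        theta1=np.array([c[0] for c in cells]),
        theta2=np.array([c[1] for c in cells]),
        mean_loss=mean_loss,
        sd_loss=sd_loss,
        mean_b=mean_b,
        sd_b=sd_b,
        mean_c=mean_c,
        sd_c=sd_c,
        optimum=(float(cells[best][0]), float(cells[best][1])),
        replicates=replicates,
        seed0=seed0,
    )
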