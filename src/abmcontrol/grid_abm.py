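"""Stochastic resource-prey-predator lattice model.

Three species interact on an ``L x L`` periodic grid: nutrient sites
(species A) regrow ``tau`` periods after being grazed, prey (species B)
perform a biased random walk and forage nutrients, predators (species C)
perform the same walk and consume co-located prey.  Every agent carries an
energy budget: feeding adds ``lambda1`` (prey) or ``lambda2`` (predators),
metabolism costs one unit per period, and agents whose energy drops below
zero die.  Agents reproduce with per-period probability ``alpha/100``; the
offspring appears at a uniformly random cell with a fresh uniform energy
draw that is deducted from the parent.

The model is the classical wolf-sheep-grass lattice system with explicit
energy bookkeeping; it is the plant for the population-control problems in
:mod:`abmcontrol.objectives` and :mod:`abmcontrol.control`.

All updates are vectorized over agents (movement uses the exact
``move_steps``-fold convolution of the single-step kernel, grazing and
predation resolve conflicts with a single sort each), so a 255 x 255 world
with a few thousand agents steps in about a millisecond.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, asdict
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "GridConfig",
    "Observation",
    "Trajectory",
    "WorldState",
    "init_world",
    "step_world",
    "apply_population_control",
    "run",
]


@dataclass
class GridConfig:
    """Parameters of the lattice predator-prey world.

    Defaults reproduce the published study conditions: a 255 x 255 grid,
    2500 prey, 1250 predators, reproduction parameters ``alpha1=4.0`` and
    ``alpha2=5.0`` (percent probability of one offspring per agent per
    period), energy gains ``lambda1=4.0`` per nutrient and ``lambda2=20.0``
    per prey, nutrient regrowth delay ``tau=30`` periods and 50% initially
    nutrient-rich cells.  Walk speed, energy-draw bounds and offspring
    mechanics are the package's calibrated defaults (see docs/methods.md).
    """

    L: int = 255
    b0: int = 2500
    c0: int = 1250
    alpha1: float = 4.0
    alpha2: float = 5.0
    lambda1: float = 4.0
    lambda2: float = 20.0
    tau: int = 30
    nutrient_init_frac: float = 0.5
    #: excess probability of a +x step; each single step goes +x with
    #: probability ``0.25 + bias`` and each other direction ``(0.75 - bias)/3``.
    bias: float = 0.10
    #: lattice steps per period for both species.
    move_steps: int = 2
    #: upper bounds of the uniform integer energy draws used for initial
    #: agents, control-added agents and offspring; ``None`` defaults to
    #: ``round(lambda1 / 2)`` for prey and ``2 * lambda2`` for predators.
    e_init_max_prey: Optional[int] = None
    e_init_max_pred: Optional[int] = None
    #: offspring energy rule: "draw" (fresh uniform draw capped by and
    #: deducted from the parent) or "split" (integer-halved with the parent).
    offspring_energy: str = "draw"
    #: offspring placement: "uniform" (random cell) or "parent" (natal cell).
    offspring_placement: str = "uniform"

    def __post_init__(self) -> None:
        if not isinstance(self.L, (int, np.integer)) or isinstance(self.L, bool):
            raise TypeError(f"L must be an integer, got {self.L!r}")
        if self.L < 3:
            raise ValueError("L must be >= 3")
        if self.b0 < 0 or self.c0 < 0:
            raise ValueError("initial counts must be >= 0")
        if not 0.0 <= self.nutrient_init_frac <= 1.0:
            raise ValueError("nutrient_init_frac must lie in [0, 1]")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1, lambda2 must be >= 0")
        if not -0.25 <= self.bias <= 0.75:
            raise ValueError("bias must keep all move probabilities in [0, 1]")
        if self.move_steps < 0:
            raise ValueError("move_steps must be >= 0")
        if self.offspring_energy not in ("draw", "split"):
            raise ValueError("offspring_energy must be 'draw' or 'split'")
        if self.offspring_placement not in ("uniform", "parent"):
            raise ValueError("offspring_placement must be 'uniform' or 'parent'")
        if self.e_init_max_prey is None:
            self.e_init_max_prey = max(1, int(round(self.lambda1 / 2)))
        if self.e_init_max_pred is None:
            self.e_init_max_pred = max(1, int(round(2 * self.lambda2)))

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class Observation(NamedTuple):
    """Population sizes at one period: nutrient-rich cells, prey, predators."""

    a: int
    b: int
    c: int


@dataclass
class Trajectory:
    """Time-indexed record of one rollout.

    ``a``, ``b``, ``c`` have length ``n_periods + 1`` (the initial state is
    observation 0); ``controls`` holds one integer pair per period.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    controls: np.ndarray  # shape (n_periods, 2)
    config_hash: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int64)
        self.b = np.asarray(self.b, dtype=np.int64)
        self.c = np.asarray(self.c, dtype=np.int64)
        self.controls = np.asarray(self.controls, dtype=np.int64).reshape(-1, 2)
        n = len(self.a)
        if len(self.b) != n or len(self.c) != n:
            raise ValueError("a, b, c must have equal length")
        if len(self.controls) != n - 1:
            raise ValueError("controls must have one entry per period")

    def __len__(self) -> int:
        return len(self.a)

    def observation(self, k: int) -> Observation:
        return Observation(int(self.a[k]), int(self.b[k]), int(self.c[k]))


def _step_kernel(bias: float, steps: int):
    """Displacement distribution of ``steps`` biased von-Neumann steps:
    arrays (dx, dy, cumulative probability)."""
    p_fwd = 0.25 + bias
    p_other = (0.75 - bias) / 3.0
    single = [((1, 0), p_fwd), ((-1, 0), p_other), ((0, 1), p_other), ((0, -1), p_other)]
    dist = {(0, 0): 1.0}
    for _ in range(steps):
        new: dict = {}
        for (dx, dy), p in dist.items():
            for (sx, sy), q in single:
                key = (dx + sx, dy + sy)
                new[key] = new.get(key, 0.0) + p * q
        dist = new
    items = sorted(dist.items())
    dx = np.array([k[0] for k, _ in items], dtype=np.int64)
    dy = np.array([k[1] for k, _ in items], dtype=np.int64)
    cum = np.cumsum([p for _, p in items])
    cum[-1] = 1.0
    return dx, dy, cum


@dataclass
class WorldState:
    """Full mutable state of the lattice world.

    The nutrient field is kept as a boolean ``rich`` array over flattened
    cells plus a regrowth wheel: ``wheel[j]`` lists the cells that turn rich
    again at period ``j`` (mod ``tau + 1``).  Agent positions are separate
    x/y integer arrays.  ``ledger`` records the per-period population
    accounting of the most recent step.
    """

    config: GridConfig
    k: int
    rich: np.ndarray
    wheel: list
    prey_x: np.ndarray
    prey_y: np.ndarray
    prey_energy: np.ndarray
    pred_x: np.ndarray
    pred_y: np.ndarray
    pred_energy: np.ndarray
    rng: np.random.Generator
    n_rich: int = 0
    ledger: dict = field(default_factory=dict)
    _kernel: tuple = None

    def __post_init__(self) -> None:
        if self._kernel is None:
            self._kernel = _step_kernel(self.config.bias, self.config.move_steps)

    @property
    def n_prey(self) -> int:
        return self.prey_x.size

    @property
    def n_predators(self) -> int:
        return self.pred_x.size

    @property
    def prey_pos(self) -> np.ndarray:
        """Flattened prey cell indices."""
        return self.prey_y * self.config.L + self.prey_x

    @property
    def pred_pos(self) -> np.ndarray:
        """Flattened predator cell indices."""
        return self.pred_y * self.config.L + self.pred_x

    @property
    def timer(self) -> np.ndarray:
        """Per-cell periods until regrowth (0 iff nutrient-rich),
        reconstructed from the regrowth wheel."""
        t = np.zeros(self.config.L * self.config.L, dtype=np.int32)
        w = self.config.tau + 1
        for j, cells in enumerate(self.wheel):
            # slot j is released in phase 7 of the next period p >= k
            # with p % w == j
            t[cells] = (j - self.k) % w + 1
        return t

    def observe(self) -> Observation:
        return Observation(self.n_rich, self.n_prey, self.n_predators)

    def copy(self) -> "WorldState":
        import copy as _copy

        return WorldState(
            config=self.config,
            k=self.k,
            rich=self.rich.copy(),
            wheel=[c.copy() for c in self.wheel],
            prey_x=self.prey_x.copy(),
            prey_y=self.prey_y.copy(),
            prey_energy=self.prey_energy.copy(),
            pred_x=self.pred_x.copy(),
            pred_y=self.pred_y.copy(),
            pred_energy=self.pred_energy.copy(),
            rng=_copy.deepcopy(self.rng),
            n_rich=self.n_rich,
            ledger=dict(self.ledger),
            _kernel=self._kernel,
        )


def init_world(config: GridConfig, seed: int) -> WorldState:
    """Build the initial world: ``round(nutrient_init_frac * L^2)`` rich
    cells chosen uniformly without replacement, agents at uniform cells with
    uniform integer energies in ``{1, ..., e_init_max}``.  Poor cells start
    one period from regrowth."""
    rng = np.random.default_rng(seed)
    n_cells = config.L * config.L
    n_rich = int(np.floor(config.nutrient_init_frac * n_cells + 0.5))
    rich = np.zeros(n_cells, dtype=bool)
    rich[rng.choice(n_cells, size=n_rich, replace=False)] = True
    wheel = [np.empty(0, dtype=np.int64) for _ in range(config.tau + 1)]
    # initially poor cells regrow at the end of period 0
    wheel[0] = np.flatnonzero(~rich)
    prey_pos = rng.integers(0, n_cells, size=config.b0)
    pred_pos = rng.integers(0, n_cells, size=config.c0)
    return WorldState(
        config=config,
        k=0,
        rich=rich,
        wheel=wheel,
        prey_x=prey_pos % config.L,
        prey_y=prey_pos // config.L,
        prey_energy=rng.integers(
            1, config.e_init_max_prey + 1, size=config.b0
        ).astype(np.float64),
        pred_x=pred_pos % config.L,
        pred_y=pred_pos // config.L,
        pred_energy=rng.integers(
            1, config.e_init_max_pred + 1, size=config.c0
        ).astype(np.float64),
        rng=rng,
        n_rich=n_rich,
    )


def apply_population_control(world: WorldState, u: Sequence[int]) -> WorldState:
    """Add (u > 0) or remove (u < 0) agents uniformly at random.

    ``u = (u1, u2)`` acts on (prey, predators).  Added agents get fresh
    uniform positions and initial-energy draws; removal requests larger than
    the population are clamped.  Mutates and returns ``world``.
    """
    u1, u2 = int(u[0]), int(u[1])
    cfg = world.config
    rng = world.rng
    n_cells = cfg.L * cfg.L
    added = [0, 0]
    removed = [0, 0]
    if u1 > 0:
        pos = rng.integers(0, n_cells, size=u1)
        en = rng.integers(1, cfg.e_init_max_prey + 1, size=u1).astype(np.float64)
        world.prey_x = np.concatenate([world.prey_x, pos % cfg.L])
        world.prey_y = np.concatenate([world.prey_y, pos // cfg.L])
        world.prey_energy = np.concatenate([world.prey_energy, en])
        added[0] = u1
    elif u1 < 0:
        m = min(-u1, world.n_prey)
        if m > 0:
            keep = np.ones(world.n_prey, dtype=bool)
            keep[rng.choice(world.n_prey, size=m, replace=False)] = False
            world.prey_x = world.prey_x[keep]
            world.prey_y = world.prey_y[keep]
            world.prey_energy = world.prey_energy[keep]
        removed[0] = m
    if u2 > 0:
        pos = rng.integers(0, n_cells, size=u2)
        en = rng.integers(1, cfg.e_init_max_pred + 1, size=u2).astype(np.float64)
        world.pred_x = np.concatenate([world.pred_x, pos % cfg.L])
        world.pred_y = np.concatenate([world.pred_y, pos // cfg.L])
        world.pred_energy = np.concatenate([world.pred_energy, en])
        added[1] = u2
    elif u2 < 0:
        m = min(-u2, world.n_predators)
        if m > 0:
            keep = np.ones(world.n_predators, dtype=bool)
            keep[rng.choice(world.n_predators, size=m, replace=False)] = False
            world.pred_x = world.pred_x[keep]
            world.pred_y = world.pred_y[keep]
            world.pred_energy = world.pred_energy[keep]
        removed[1] = m
    world.ledger["control_added"] = tuple(added)
    world.ledger["control_removed"] = tuple(removed)
    return world


def _move(x, y, L, kernel, rng):
    """Biased random walk: one exact draw from the move_steps-fold kernel."""
    n = x.size
    if n == 0:
        return x, y
    dx, dy, cum = kernel
    cat = np.searchsorted(cum, rng.random(n), side="right")
    return (x + dx[cat]) % L, (y + dy[cat]) % L


def _claim(cells, cand, rnd):
    """Resolve competing claims: among candidates claiming the same cell the
    one with the smallest random tag wins.  Single-sort implementation;
    returns (winner candidate indices, won cells)."""
    key = cells.astype(np.float64) + rnd[cand]
    order = np.argsort(key)
    cc = cells[order]
    first = np.empty(cc.size, dtype=bool)
    first[0] = True
    np.not_equal(cc[1:], cc[:-1], out=first[1:])
    return cand[order[first]], cc[first]


def _feed_prey(world: WorldState, consumed_list: list) -> int:
    """Grazing: every prey tries to consume one nutrient-rich cell, own cell
    first, then the 4-neighbourhood with uniform tie-breaking.  Each cell
    feeds at most one prey; competing claims are resolved by random tags."""
    cfg = world.config
    L = cfg.L
    rng = world.rng
    n = world.prey_x.size
    if n == 0:
        return 0
    rich = world.rich
    pos = world.prey_y * L + world.prey_x
    fed = np.zeros(n, dtype=bool)
    rnd = rng.random(n)  # per-prey priority tags

    def consume(winners, cells):
        rich[cells] = False
        consumed_list.append(cells)
        fed[winners] = True
        world.prey_energy[winners] += cfg.lambda1

    own = np.flatnonzero(rich[pos])
    if own.size:
        consume(*_claim(pos[own], own, rnd))

    nb = None
    for _ in range(4):
        un = np.flatnonzero(~fed)
        if un.size == 0:
            break
        if nb is None:  # neighbour cells, computed once per period
            x = world.prey_x
            y = world.prey_y
            yL = y * L
            nb = np.empty((n, 4), dtype=np.int64)
            nb[:, 0] = yL + (x + 1) % L
            nb[:, 1] = yL + (x - 1) % L
            nb[:, 2] = ((y + 1) % L) * L + x
            nb[:, 3] = ((y - 1) % L) * L + x
        nbu = nb[un]
        nb_rich = rich[nbu]
        cnt = nb_rich.sum(axis=1)
        has = cnt > 0
        if not has.any():
            break
        un = un[has]
        nbu = nbu[has]
        nb_rich = nb_rich[has]
        cnt = cnt[has]
        pick = (rng.random(un.size) * cnt).astype(np.int64)
        col = (nb_rich.cumsum(axis=1) <= pick[:, None]).sum(axis=1)
        cells = nbu[np.arange(un.size), col]
        consume(*_claim(cells, un, rnd))
    return int(fed.sum())


def _runs(sorted_vals: np.ndarray):
    """Unique values and run lengths of a sorted array."""
    first = np.empty(sorted_vals.size, dtype=bool)
    first[0] = True
    np.not_equal(sorted_vals[1:], sorted_vals[:-1], out=first[1:])
    idx = np.flatnonzero(first)
    counts = np.empty(idx.size, dtype=np.int64)
    counts[:-1] = np.diff(idx)
    counts[-1] = sorted_vals.size - idx[-1]
    return sorted_vals[idx], counts


def _predation(world: WorldState) -> int:
    """Each predator sharing a cell with prey removes one uniformly chosen
    co-located prey and gains ``lambda2``; at most one prey per predator and
    each prey is eaten at most once."""
    cfg = world.config
    rng = world.rng
    nb = world.n_prey
    nc = world.n_predators
    if nb == 0 or nc == 0:
        return 0
    pos_b = world.prey_y * cfg.L + world.prey_x
    pos_c = world.pred_y * cfg.L + world.pred_x
    # random within-cell order via a single composite-key sort per species
    order_b = np.argsort(pos_b + rng.random(nb))
    order_c = np.argsort(pos_c + rng.random(nc))
    sb = pos_b[order_b]
    sc = pos_c[order_c]
    ub, count_b = _runs(sb)
    uc, count_c = _runs(sc)
    cells, i_b, i_c = np.intersect1d(ub, uc, assume_unique=True, return_indices=True)
    if cells.size == 0:
        return 0
    n_eat = np.minimum(count_b[i_b], count_c[i_c])
    tot = int(n_eat.sum())
    start_b = np.searchsorted(sb, cells)
    start_c = np.searchsorted(sc, cells)
    offs = np.arange(tot) - np.repeat(np.cumsum(n_eat) - n_eat, n_eat)
    eaten = order_b[np.repeat(start_b, n_eat) + offs]
    eaters = order_c[np.repeat(start_c, n_eat) + offs]
    world.pred_energy[eaters] += cfg.lambda2
    keep = np.ones(nb, dtype=bool)
    keep[eaten] = False
    world.prey_x = world.prey_x[keep]
    world.prey_y = world.prey_y[keep]
    world.prey_energy = world.prey_energy[keep]
    return tot


def _reproduce(x, y, energy, alpha, emax, cfg, rng):
    """Each agent spawns one offspring with probability ``alpha / 100``.
    Offspring energy is either a fresh uniform draw on ``{1, ..., emax}``
    capped by the parent's energy ("draw") or ``floor(parent / 2)``
    ("split"); either way it is deducted from the parent.  Placement is a
    uniformly random cell ("uniform") or the natal cell ("parent")."""
    n = x.size
    if n == 0 or alpha <= 0:
        return x, y, energy, 0
    rep = rng.random(n) < alpha / 100.0
    nrep = int(rep.sum())
    if nrep == 0:
        return x, y, energy, 0
    if cfg.offspring_energy == "draw":
        child_e = np.minimum(
            rng.integers(1, emax + 1, size=nrep).astype(np.float64),
            np.floor(energy[rep]),
        )
    else:
        child_e = np.floor(energy[rep] / 2.0)
    energy[rep] -= child_e
    if cfg.offspring_placement == "uniform":
        cpos = rng.integers(0, cfg.L * cfg.L, size=nrep)
        cx, cy = cpos % cfg.L, cpos // cfg.L
    else:
        cx, cy = x[rep], y[rep]
    return (
        np.concatenate([x, cx]),
        np.concatenate([y, cy]),
        np.concatenate([energy, child_e]),
        nrep,
    )


def step_world(world: WorldState, u: Sequence[int] = (0, 0)) -> WorldState:
    """Advance the world by one period.

    Phase order: control, movement, feeding (grazing then predation),
    metabolic loss, death, reproduction, nutrient regrowth.  A cell grazed
    during period k stays poor for exactly ``tau`` periods and is rich again
    in the observation at period ``k + tau + 1``.  Mutates and returns
    ``world``; per-period accounting lands in ``world.ledger``.
    """
    cfg = world.config
    rng = world.rng
    world.ledger = {}

    b_before = world.n_prey
    c_before = world.n_predators

    # (1) population control
    apply_population_control(world, u)

    # (2) movement
    world.prey_x, world.prey_y = _move(
        world.prey_x, world.prey_y, cfg.L, world._kernel, rng
    )
    world.pred_x, world.pred_y = _move(
        world.pred_x, world.pred_y, cfg.L, world._kernel, rng
    )

    # (3) feeding
    consumed: list = []
    n_fed = _feed_prey(world, consumed)
    n_eaten = _predation(world)

    # (4) metabolism, (5) death strictly below zero energy
    world.prey_energy -= 1.0
    world.pred_energy -= 1.0
    keep_b = world.prey_energy >= 0.0
    keep_c = world.pred_energy >= 0.0
    starved_b = int(b_before + world.ledger["control_added"][0]
                    - world.ledger["control_removed"][0] - n_eaten - int(keep_b.sum()))
    starved_c = int(c_before + world.ledger["control_added"][1]
                    - world.ledger["control_removed"][1] - int(keep_c.sum()))
    world.prey_x = world.prey_x[keep_b]
    world.prey_y = world.prey_y[keep_b]
    world.prey_energy = world.prey_energy[keep_b]
    world.pred_x = world.pred_x[keep_c]
    world.pred_y = world.pred_y[keep_c]
    world.pred_energy = world.pred_energy[keep_c]

    # (6) reproduction
    world.prey_x, world.prey_y, world.prey_energy, born_b = _reproduce(
        world.prey_x, world.prey_y, world.prey_energy,
        cfg.alpha1, cfg.e_init_max_prey, cfg, rng,
    )
    world.pred_x, world.pred_y, world.pred_energy, born_c = _reproduce(
        world.pred_x, world.pred_y, world.pred_energy,
        cfg.alpha2, cfg.e_init_max_pred, cfg, rng,
    )

    # (7) regrowth wheel: cells scheduled for this period turn rich; cells
    # grazed during period k regrow in phase 7 of period k + tau, so they
    # are observed poor for exactly tau periods.
    w = cfg.tau + 1
    slot = world.k % w
    regrown = world.wheel[slot]
    if regrown.size:
        world.rich[regrown] = True
        world.wheel[slot] = np.empty(0, dtype=np.int64)
    write_slot = (world.k + cfg.tau) % w
    if consumed:
        world.wheel[write_slot] = np.concatenate(consumed)
    else:
        world.wheel[write_slot] = np.empty(0, dtype=np.int64)
    world.n_rich += int(regrown.size) - sum(c.size for c in consumed)

    world.k += 1
    world.ledger.update(
        prey_fed=n_fed,
        prey_eaten=n_eaten,
        prey_starved=starved_b,
        pred_starved=starved_c,
        prey_born=born_b,
        pred_born=born_c,
        prey_before=b_before,
        pred_before=c_before,
    )
    return world


Controller = Callable[[Observation, int], Sequence[int]]


def run(
    config: GridConfig,
    controller: Optional[Controller] = None,
    burn_in: int = 1000,
    horizon: int = 1000,
    seed: int = 0,
) -> Trajectory:
    """Roll out the world for ``burn_in + horizon`` periods.

    The controller (a callable ``(observation, k) -> (u1, u2)``) is consulted
    only for ``k >= burn_in``; earlier periods apply no control.  The rollout
    is a deterministic function of ``(config, controller, seed)``.
    """
    if burn_in < 0 or horizon < 0:
        raise ValueError("burn_in and horizon must be >= 0")
    world = init_world(config, seed)
    n_periods = burn_in + horizon
    a = np.empty(n_periods + 1, dtype=np.int64)
    b = np.empty(n_periods + 1, dtype=np.int64)
    c = np.empty(n_periods + 1, dtype=np.int64)
    controls = np.zeros((n_periods, 2), dtype=np.int64)
    obs = world.observe()
    a[0], b[0], c[0] = obs
    for k in range(n_periods):
        if controller is not None and k >= burn_in:
            u = controller(obs, k)
            u1, u2 = u[0], u[1]
            if float(u1) != int(u1) or float(u2) != int(u2):
                raise ValueError(f"controller returned non-integer action {u!r}")
            u = (int(u1), int(u2))
        else:
            u = (0, 0)
        controls[k] = u
        step_world(world, u)
        obs = world.observe()
        a[k + 1], b[k + 1], c[k + 1] = obs
    return Trajectory(
        a=a, b=b, c=c, controls=controls, config_hash=config.hash(), seed=seed
    )
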