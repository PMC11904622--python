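"""Molecule-level ABM of a branched metabolic pathway with end-product
regulation.

Individual molecules diffuse on a periodic lattice: five metabolites
(substrate S, shared precursor P, intermediate Q and the two end products R
and T), four enzymes (A, E, I, O) and the enzyme-metabolite complexes they
form.  The pathway topology is

    S --(A)--> P,   P --(E)--> Q,   Q --(I)--> R,   P --(O)--> T,

and the end product R regulates the branch point: R binds enzyme A and
suppresses its catalysis (feedback inhibition of the first reaction) while
R bound to enzyme O enhances catalysis toward T (activation of the second
branch).  This inhibit-one-branch/boost-the-other motif is typical of
branched amino-acid biosynthesis pathways.

Twelve complex kinds arise: four enzyme-substrate (A.S, E.P, I.Q, O.P),
four enzyme-product (A.P, E.Q, I.R, O.T), two enzyme-regulator (A.R, O.R)
and two ternary regulator-substrate complexes (A.R.S, O.R.P).  Ternary
complexes catalyze with modified rates and release their product directly,
so the state space stays within these twelve kinds.

Substrate inflow is the control input: at each period one new S molecule
appears at a random cell with probability q_k in [0, 1].
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Dict, Optional, Sequence, Union

import numpy as np

from .grid_abm import _step_kernel

__all__ = [
    "METABOLITES",
    "ENZYMES",
    "COMPLEXES",
    "PathwayConfig",
    "ReactionState",
    "MetabolicTrajectory",
    "init_pathway",
    "step_pathway",
    "run_pathway",
    "scaled_config",
]

METABOLITES = ("S", "P", "Q", "R", "T")
ENZYMES = ("A", "E", "I", "O")
COMPLEXES = (
    "A.S", "A.P", "A.R", "A.R.S",
    "E.P", "E.Q",
    "I.Q", "I.R",
    "O.P", "O.T", "O.R", "O.R.P",
)

#: binding rules: (binder kind, free-metabolite partner, complex formed).
#: Binders are free enzymes or the enzyme-regulator complexes A.R / O.R;
#: enzyme-product re-binding is allowed (but never catalyzes backwards).
BINDING_RULES = (
    ("A", "S", "A.S"),
    ("A", "R", "A.R"),
    ("A", "P", "A.P"),
    ("A.R", "S", "A.R.S"),
    ("E", "P", "E.P"),
    ("E", "Q", "E.Q"),
    ("I", "Q", "I.Q"),
    ("I", "R", "I.R"),
    ("O", "P", "O.P"),
    ("O", "R", "O.R"),
    ("O", "T", "O.T"),
    ("O.R", "P", "O.R.P"),
)

#: dissociation: complex -> (residual kind, released metabolite); the most
#: recently bound (or formed) component is released.
DISSOCIATION = {
    "A.S": ("A", "S"), "A.P": ("A", "P"), "A.R": ("A", "R"), "A.R.S": ("A.R", "S"),
    "E.P": ("E", "P"), "E.Q": ("E", "Q"),
    "I.Q": ("I", "Q"), "I.R": ("I", "R"),
    "O.P": ("O", "P"), "O.T": ("O", "T"), "O.R": ("O", "R"), "O.R.P": ("O.R", "P"),
}

#: catalysis: enzyme-substrate complex -> product complex (binary case) or
#: residual complex plus released free product (ternary case).
CATALYSIS_BINARY = {"A.S": "A.P", "E.P": "E.Q", "I.Q": "I.R", "O.P": "O.T"}
CATALYSIS_TERNARY = {"A.R.S": ("A.R", "P"), "O.R.P": ("O.R", "T")}

#: complexes containing each enzyme (for conservation) and each metabolite
#: (for total counts).
ENZYME_MEMBERS = {
    "A": ("A.S", "A.P", "A.R", "A.R.S"),
    "E": ("E.P", "E.Q"),
    "I": ("I.Q", "I.R"),
    "O": ("O.P", "O.T", "O.R", "O.R.P"),
}
METABOLITE_MEMBERS = {
    "S": ("A.S", "A.R.S"),
    "P": ("A.P", "E.P", "O.P", "O.R.P"),
    "Q": ("E.Q", "I.Q"),
    "R": ("A.R", "A.R.S", "I.R", "O.R", "O.R.P"),
    "T": ("O.T",),
}


@dataclass
class PathwayConfig:
    """Parameters of the metabolic-pathway ABM.

    Molecule counts and the horizon follow the published study conditions
    (S, P, Q, R, T start at 80000, 20000, 20000, 10, 10; 200 copies of each
    enzyme; 5e4 periods); kinetic probabilities are the package defaults,
    chosen so a default run shows substrate depletion followed by product
    accumulation.
    """

    L_m: int = 300
    init_S: int = 80000
    init_P: int = 20000
    init_Q: int = 20000
    init_R: int = 10
    init_T: int = 10
    init_enzymes: int = 200
    metabolite_speed: int = 10
    enzyme_speed: int = 1
    p_bind: float = 0.5
    p_diss: float = 0.01
    p_cat: float = 0.1
    #: multiplier on A's catalysis when R is bound (0 = full inhibition)
    inhibition_factor: float = 0.0
    #: multiplier on O's catalysis when R is bound (effective rate capped at 1)
    activation_factor: float = 4.0
    Nt: int = 50_000

    def __post_init__(self) -> None:
        for name in ("p_bind", "p_diss", "p_cat"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.inhibition_factor <= 1.0:
            raise ValueError("inhibition_factor must lie in [0, 1]")
        if self.activation_factor < 1.0:
            raise ValueError("activation_factor must be >= 1")
        counts = [self.init_S, self.init_P, self.init_Q, self.init_R,
                  self.init_T, self.init_enzymes]
        if any(c < 0 for c in counts):
            raise ValueError("molecule counts must be >= 0")
        if self.L_m < 3:
            raise ValueError("L_m must be >= 3")
        if self.metabolite_speed < 0 or self.enzyme_speed < 0:
            raise ValueError("speeds must be >= 0")
        if self.Nt < 0:
            raise ValueError("Nt must be >= 0")

    def init_counts(self) -> Dict[str, int]:
        return {
            "S": self.init_S, "P": self.init_P, "Q": self.init_Q,
            "R": self.init_R, "T": self.init_T,
        }

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def scaled_config(**overrides) -> PathwayConfig:
    """Desk-scale configuration (counts / 100, 60 x 60 lattice, 2000
    periods) preserving all conservation structure; used throughout the
    test suite."""
    defaults = dict(
        L_m=60, init_S=800, init_P=200, init_Q=200, init_R=1, init_T=1,
        init_enzymes=2, Nt=2000,
    )
    defaults.update(overrides)
    return PathwayConfig(**defaults)


@dataclass
class ReactionState:
    """Positions (flattened cell indices) of every molecule, per kind."""

    config: PathwayConfig
    k: int
    agents: Dict[str, np.ndarray]
    rng: np.random.Generator
    _kernels: dict = field(default_factory=dict)

    def count(self, kind: str) -> int:
        return self.agents[kind].size

    def enzyme_total(self, enzyme: str) -> int:
        return self.count(enzyme) + sum(self.count(c) for c in ENZYME_MEMBERS[enzyme])

    def metabolite_total(self, met: str) -> int:
        return self.count(met) + sum(self.count(c) for c in METABOLITE_MEMBERS[met])

    def copy(self) -> "ReactionState":
        import copy as _copy

        return ReactionState(
            config=self.config,
            k=self.k,
            agents={k: v.copy() for k, v in self.agents.items()},
            rng=_copy.deepcopy(self.rng),
            _kernels=self._kernels,
        )


def init_pathway(config: PathwayConfig, seed: int) -> ReactionState:
    """All molecules at uniformly random lattice cells; no complexes."""
    rng = np.random.default_rng(seed)
    n_cells = config.L_m * config.L_m
    agents: Dict[str, np.ndarray] = {}
    for met, count in config.init_counts().items():
        agents[met] = rng.integers(0, n_cells, size=count)
    for enz in ENZYMES:
        agents[enz] = rng.integers(0, n_cells, size=config.init_enzymes)
    for cx in COMPLEXES:
        agents[cx] = np.empty(0, dtype=np.int64)
    return ReactionState(config=config, k=0, agents=agents, rng=rng)


def _kernel_for(state: ReactionState, speed: int):
    if speed not in state._kernels:
        state._kernels[speed] = _step_kernel(0.0, speed)
    return state._kernels[speed]


def _diffuse(pos: np.ndarray, L: int, kernel, rng) -> np.ndarray:
    if pos.size == 0:
        return pos
    dx, dy, cum = kernel
    cat = np.searchsorted(cum, rng.random(pos.size), side="right")
    x = (pos % L + dx[cat]) % L
    y = (pos // L + dy[cat]) % L
    return y * L + x


def _binding(state: ReactionState) -> None:
    """Association phase: binder kinds are processed in fixed order; each
    binder co-located with eligible free metabolites picks one uniformly
    (across all eligible kinds on its cell) and binds with probability
    p_bind.  Conflicting picks of the same molecule are resolved in favour
    of a random claimant; losers stay unbound this period."""
    cfg = state.config
    rng = state.rng
    binder_rules: Dict[str, list] = {}
    for binder, partner, product in BINDING_RULES:
        binder_rules.setdefault(binder, []).append((partner, product))

    for binder, rules in binder_rules.items():
        bpos = state.agents[binder]
        nb = bpos.size
        if nb == 0:
            continue
        partners = [p for p, _ in rules]
        # candidate counts per binder for each partner kind
        cnts = []
        sorted_partner = {}
        for p in partners:
            ppos = state.agents[p]
            if ppos.size == 0:
                cnts.append(np.zeros(nb, dtype=np.int64))
                continue
            order = np.argsort(ppos + rng.random(ppos.size))
            sp = ppos[order]
            sorted_partner[p] = (sp, order)
            left = np.searchsorted(sp, bpos, side="left")
            right = np.searchsorted(sp, bpos, side="right")
            cnts.append(right - left)
        cnt_mat = np.stack(cnts, axis=1)
        total = cnt_mat.sum(axis=1)
        active = np.flatnonzero((total > 0) & (rng.random(nb) < cfg.p_bind))
        if active.size == 0:
            continue
        # choose the partner kind proportionally to co-located counts, then
        # a uniform individual within that kind's cell group
        pick = np.floor(rng.random(active.size) * total[active]).astype(np.int64)
        cum = np.cumsum(cnt_mat[active], axis=1)
        kind_idx = (cum <= pick[:, None]).sum(axis=1)
        within = pick - np.where(kind_idx > 0, np.take_along_axis(
            cum, (kind_idx - 1)[:, None].clip(min=0), axis=1
        ).ravel(), 0)
        taken_per_kind: Dict[str, list] = {p: [] for p in partners}
        binder_of: Dict[str, list] = {p: [] for p in partners}
        for j, p in enumerate(partners):
            sel = kind_idx == j
            if not sel.any():
                continue
            sp, order = sorted_partner[p]
            b_idx = active[sel]
            start = np.searchsorted(sp, bpos[b_idx], side="left")
            taken_per_kind[p] = order[start + within[sel]]
            binder_of[p] = b_idx
        # resolve conflicts (two binders picking the same molecule): first
        # claimant in a random permutation wins
        consumed_binders = []
        for p in partners:
            t = np.asarray(taken_per_kind[p], dtype=np.int64)
            if t.size == 0:
                continue
            b_idx = np.asarray(binder_of[p], dtype=np.int64)
            perm = rng.permutation(t.size)
            uniq, first = np.unique(t[perm], return_index=True)
            winners_b = b_idx[perm[first]]
            product = dict(rules)[p]
            state.agents[product] = np.concatenate(
                [state.agents[product], bpos[winners_b]]
            )
            keep = np.ones(state.agents[p].size, dtype=bool)
            keep[uniq] = False
            state.agents[p] = state.agents[p][keep]
            consumed_binders.append(winners_b)
        if consumed_binders:
            gone = np.concatenate(consumed_binders)
            keep = np.ones(nb, dtype=bool)
            keep[gone] = False
            state.agents[binder] = state.agents[binder][keep]


def _dissociation(state: ReactionState) -> None:
    cfg = state.config
    rng = state.rng
    if cfg.p_diss <= 0:
        return
    for cx, (residual, released) in DISSOCIATION.items():
        pos = state.agents[cx]
        if pos.size == 0:
            continue
        diss = rng.random(pos.size) < cfg.p_diss
        if not diss.any():
            continue
        state.agents[residual] = np.concatenate([state.agents[residual], pos[diss]])
        state.agents[released] = np.concatenate([state.agents[released], pos[diss]])
        state.agents[cx] = pos[~diss]


def _catalysis(state: ReactionState) -> None:
    cfg = state.config
    rng = state.rng
    for cx, product in CATALYSIS_BINARY.items():
        pos = state.agents[cx]
        if pos.size == 0 or cfg.p_cat <= 0:
            continue
        cat = rng.random(pos.size) < cfg.p_cat
        if not cat.any():
            continue
        state.agents[product] = np.concatenate([state.agents[product], pos[cat]])
        state.agents[cx] = pos[~cat]
    rates = {
        "A.R.S": cfg.p_cat * cfg.inhibition_factor,
        "O.R.P": min(cfg.p_cat * cfg.activation_factor, 1.0),
    }
    for cx, (residual, released) in CATALYSIS_TERNARY.items():
        pos = state.agents[cx]
        rate = rates[cx]
        if pos.size == 0 or rate <= 0:
            continue
        cat = rng.random(pos.size) < rate
        if not cat.any():
            continue
        state.agents[residual] = np.concatenate([state.agents[residual], pos[cat]])
        state.agents[released] = np.concatenate([state.agents[released], pos[cat]])
        state.agents[cx] = pos[~cat]


def step_pathway(state: ReactionState, q_k: float = 0.0) -> ReactionState:
    """One period: inflow, movement, association, dissociation, catalysis.

    ``q_k`` is the probability that a single new substrate molecule appears
    at a uniformly random cell this period.  Mutates and returns ``state``.
    """
    if not 0.0 <= q_k <= 1.0:
        raise ValueError("inflow q_k must lie in [0, 1]")
    cfg = state.config
    rng = state.rng
    n_cells = cfg.L_m * cfg.L_m

    # (1) inflow
    if q_k > 0 and rng.random() < q_k:
        state.agents["S"] = np.concatenate(
            [state.agents["S"], rng.integers(0, n_cells, size=1)]
        )

    # (2) movement: metabolites fast, enzymes and complexes slow
    km = _kernel_for(state, cfg.metabolite_speed)
    ke = _kernel_for(state, cfg.enzyme_speed)
    for met in METABOLITES:
        state.agents[met] = _diffuse(state.agents[met], cfg.L_m, km, rng)
    for kind in ENZYMES + COMPLEXES:
        state.agents[kind] = _diffuse(state.agents[kind], cfg.L_m, ke, rng)

    # (3) association, (4) dissociation, (5) catalysis
    _binding(state)
    _dissociation(state)
    _catalysis(state)

    state.k += 1
    return state


@dataclass
class MetabolicTrajectory:
    """Per-period totals (free + complexed) of each metabolite, free-enzyme
    counts and the applied inflow probabilities."""

    S: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    T: np.ndarray
    freeA: np.ndarray
    freeE: np.ndarray
    freeI: np.ndarray
    freeO: np.ndarray
    q: np.ndarray
    config_hash: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.S)
        for name in ("P", "Q", "R", "T", "freeA", "freeE", "freeI", "freeO"):
            if len(getattr(self, name)) != n:
                raise ValueError("all count series must have equal length")
        if len(self.q) != n - 1:
            raise ValueError("q must have one entry per period")
        if any(np.min(getattr(self, nm), initial=0) < 0
               for nm in ("S", "P", "Q", "R", "T")):
            raise ValueError("counts must be >= 0")

    def __len__(self) -> int:
        return len(self.S)

    def states(self) -> np.ndarray:
        """(Nt + 1, 5) array of metabolite totals in S, P, Q, R, T order."""
        return np.stack([self.S, self.P, self.Q, self.R, self.T], axis=1)


InflowFn = Union[float, Callable[[int], float]]


def run_pathway(
    config: PathwayConfig,
    inflow: InflowFn = 0.0,
    seed: int = 0,
    Nt: Optional[int] = None,
) -> MetabolicTrajectory:
    """Roll out the pathway ABM for ``Nt`` periods (default: config.Nt).

    ``inflow`` is either a constant in [0, 1] or a callable period -> q_k;
    values outside [0, 1] are rejected.  Deterministic given (config, seed).
    """
    n_periods = config.Nt if Nt is None else Nt
    q_fn = inflow if callable(inflow) else (lambda k: inflow)
    state = init_pathway(config, seed)
    cols = {m: np.empty(n_periods + 1, dtype=np.int64) for m in METABOLITES}
    free = {e: np.empty(n_periods + 1, dtype=np.int64) for e in ENZYMES}
    qs = np.empty(n_periods, dtype=float)

    def record(i: int) -> None:
        for m in METABOLITES:
            cols[m][i] = state.metabolite_total(m)
        for e in ENZYMES:
            free[e][i] = state.count(e)

    record(0)
    for k in range(n_periods):
        q_k = float(q_fn(k))
        if not 0.0 <= q_k <= 1.0:
            raise ValueError(f"inflow at period {k} is {q_k}, outside [0, 1]")
        qs[k] = q_k
        step_pathway(state, q_k)
        record(k + 1)
    return MetabolicTrajectory(
        S=cols["S"], P=cols["P"], Q=cols["Q"], R=cols["R"], T=cols["T"],
        freeA=free["A"], freeE=free["E"], freeI=free["I"], freeO=free["O"],
        q=qs, config_hash=config.hash(), seed=seed,
    )
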