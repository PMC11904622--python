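"""ODE surrogate models of the agent-based simulators.

Mechanistic, power-law and semi-mechanistic neural right-hand sides share a
single interface (:func:`rhs`, :func:`integrate`) and a common fitting entry
point (:func:`fit_surrogate`) that minimizes the mean squared error between
the integrated surrogate and normalized simulator trajectories.

Pathway surrogates (five states S, P, Q, R, T; inflow q):

* ``mm`` -- Michaelis-Menten kinetics with competitive feedback inhibition
  of the first reaction by R and multiplicative activation of the branch
  reaction: v1 = V1 S / ((K1 + S)(1 + R/K_I)), v2 = V2 P / (K2 + P),
  v3 = V3 Q / (K3 + Q), v4 = V4 P / (K4 + P) (1 + gamma R / (K_A + R)).
* ``gma`` -- generalized mass action: each flux is a power-law monomial,
  with R carrying a negative exponent in v1 and a positive one in v4.
* ``neural`` -- semi-mechanistic neural ODE: the branched-pathway
  stoichiometry is fixed and only nonnegative reaction rates are learned,
  dx/dt = q e_S + N^T softplus(net(x / scale, q)).

All three satisfy d(S+P+Q+R+T)/dt = q identically, because every reaction
row of the stoichiometry conserves mass and inflow enters only through S.

Predator-prey surrogates (three states a, b, c):

* ``lv`` -- logistic-resource Lotka-Volterra chain.
* ``ssystem`` -- S-system (one production and one degradation power-law
  term per state), from biochemical systems theory.

The constant-inflow optimizer and the time-dependent neural inflow
controller evaluate the continuous-time analogue of the substrate-waste
loss J2 with trapezoidal quadrature on the integration grid; controller
training is discretize-then-optimize with exact reverse-mode gradients
through the RK4 unroll.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize

from . import nn
from .control import InflowNetParams

__all__ = [
    "PATHWAY_STOICHIOMETRY",
    "PATHWAY_STATES",
    "SurrogateSpec",
    "FitResult",
    "rhs",
    "integrate",
    "fit_surrogate",
    "loss_curve",
    "optimize_constant_inflow",
    "train_inflow_controller",
    "continuous_J2",
    "mm_default_params",
    "save_fit",
    "load_fit",
]

#: reactions (rows) x species S, P, Q, R, T (columns):
#: v1: S -> P, v2: P -> Q, v3: Q -> R, v4: P -> T.
PATHWAY_STOICHIOMETRY = np.array(
    [
        [-1, 1, 0, 0, 0],
        [0, -1, 1, 0, 0],
        [0, 0, -1, 1, 0],
        [0, -1, 0, 0, 1],
    ],
    dtype=float,
)

PATHWAY_STATES = ("S", "P", "Q", "R", "T")
MM_PARAM_NAMES = ("V1", "V2", "V3", "V4", "K1", "K2", "K3", "K4", "K_I", "K_A", "gamma")
GMA_PARAM_NAMES = ("k1", "k2", "k3", "k4", "f11", "f1R", "f22", "f33", "f42", "f4R")
LV_PARAM_NAMES = ("r", "K", "e1", "c1", "d1", "e2", "c2", "d2")

_EPS = 1e-8


@dataclass
class SurrogateSpec:
    """An ODE right-hand side: kind tag, state names and a flat parameter
    vector; ``meta`` carries structural extras (network sizes, state scale,
    stoichiometry)."""

    kind: str
    state_names: Tuple[str, ...]
    params: np.ndarray
    param_names: Tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        expected = _n_params(self.kind, len(self.state_names), self.meta)
        if expected is not None and self.params.size != expected:
            raise ValueError(
                f"{self.kind} surrogate expects {expected} parameters, "
                f"got {self.params.size}"
            )

    def get(self, name: str) -> float:
        return float(self.params[self.param_names.index(name)])


def _n_params(kind: str, n_states: int, meta: dict) -> Optional[int]:
    if kind == "mm":
        return 11
    if kind == "gma":
        return 10
    if kind == "lv":
        return 8
    if kind == "ssystem":
        return 2 * n_states + 2 * n_states * n_states
    if kind == "neural":
        sizes = meta.get("sizes")
        if sizes is None:
            return None
        return sum((a + 1) * b for a, b in zip(sizes[:-1], sizes[1:]))
    raise ValueError(f"unknown surrogate kind {kind!r}")


def mm_default_params(
    V=(0.8, 1.2, 1.2, 0.6), K=(0.2, 0.5, 0.5, 0.5), K_I=30.0, K_A=1.0, gamma=3.0
) -> SurrogateSpec:
    """A Michaelis-Menten pathway surrogate with hand-picked rate constants
    on the 1e-4-rescaled count scale, used as a synthetic ground truth.

    The first reaction is nearly zeroth-order in S (K1 << S0) with capacity
    ~0.8, so under the canonical initial pools (8, 2, 2, ~0, ~0) and a
    horizon of ~150 time units the substrate-waste loss J2(q) is U-shaped
    in the constant inflow with an interior optimum: low inflow leaves the
    initial substrate cost poorly amortized, inflow beyond the (inhibition-
    reduced) capacity piles up substrate.
    """
    params = np.array([*V, *K, K_I, K_A, gamma])
    return SurrogateSpec("mm", PATHWAY_STATES, params, MM_PARAM_NAMES)


def _mm_fluxes(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    S, P, Q, R, _ = x
    V1, V2, V3, V4, K1, K2, K3, K4, KI, KA, gamma = p
    v1 = V1 * S / ((K1 + S) * (1.0 + R / KI))
    v2 = V2 * P / (K2 + P)
    v3 = V3 * Q / (K3 + Q)
    v4 = V4 * P / (K4 + P) * (1.0 + gamma * R / (KA + R))
    return np.array([v1, v2, v3, v4])


def _mm_jacobian(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the MM right-hand side with respect to x."""
    S, P, Q, R, _ = x
    V1, V2, V3, V4, K1, K2, K3, K4, KI, KA, gamma = p
    inh = 1.0 + R / KI
    act = 1.0 + gamma * R / (KA + R)
    dv = np.zeros((4, 5))
    dv[0, 0] = V1 * K1 / ((K1 + S) ** 2 * inh)
    dv[0, 3] = -V1 * S / ((K1 + S) * inh**2 * KI)
    dv[1, 1] = V2 * K2 / ((K2 + P) ** 2)
    dv[2, 2] = V3 * K3 / ((K3 + Q) ** 2)
    dv[3, 1] = V4 * K4 / ((K4 + P) ** 2) * act
    dv[3, 3] = V4 * P / (K4 + P) * gamma * KA / ((KA + R) ** 2)
    return PATHWAY_STOICHIOMETRY.T @ dv


def _gma_fluxes(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    S, P, Q, R, _ = np.maximum(x, 0.0) + _EPS
    k1, k2, k3, k4, f11, f1R, f22, f33, f42, f4R = p
    v1 = k1 * S**f11 * R**f1R
    v2 = k2 * P**f22
    v3 = k3 * Q**f33
    v4 = k4 * P**f42 * R**f4R
    return np.array([v1, v2, v3, v4])


def _neural_rates(spec: SurrogateSpec, x: np.ndarray, q: float):
    scale = spec.meta["scale"]
    layers = nn.unflatten(spec.params, spec.meta["sizes"])
    z, cache = nn.forward(layers, np.concatenate([x / scale, [q]]))
    return nn.softplus(z), z, cache, layers


def rhs(spec: SurrogateSpec, x: np.ndarray, q: float = 0.0, t: float = 0.0) -> np.ndarray:
    """Evaluate the surrogate right-hand side at state ``x`` and inflow ``q``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-9):
        raise ValueError("surrogate states must be nonnegative")
    if spec.kind == "mm":
        flux = _mm_fluxes(spec.params, x)
        dx = PATHWAY_STOICHIOMETRY.T @ flux
        dx[0] += q
        return dx
    if spec.kind == "gma":
        flux = _gma_fluxes(spec.params, x)
        dx = PATHWAY_STOICHIOMETRY.T @ flux
        dx[0] += q
        return dx
    if spec.kind == "neural":
        rates, _, _, _ = _neural_rates(spec, x, q)
        N = spec.meta.get("stoichiometry", PATHWAY_STOICHIOMETRY)
        dx = np.asarray(N).T @ rates
        dx[0] += q
        return dx
    if spec.kind == "lv":
        r, K, e1, c1, d1, e2, c2, d2 = spec.params
        a, b, c = x
        return np.array(
            [
                r * a * (1.0 - a / K) - e1 * a * b,
                c1 * a * b - d1 * b - e2 * b * c,
                c2 * b * c - d2 * c,
            ]
        )
    if spec.kind == "ssystem":
        n = len(spec.state_names)
        alpha = spec.params[:n]
        beta = spec.params[n : 2 * n]
        g = spec.params[2 * n : 2 * n + n * n].reshape(n, n)
        h = spec.params[2 * n + n * n :].reshape(n, n)
        xs = np.maximum(x, 0.0) + _EPS
        prod = np.exp(g @ np.log(xs))
        deg = np.exp(h @ np.log(xs))
        return alpha * prod - beta * deg
    raise ValueError(f"unknown surrogate kind {spec.kind!r}")


QSchedule = Union[float, Callable[[float], float], np.ndarray]


def _q_fn(q_schedule: QSchedule, t_grid: np.ndarray) -> Callable[[float], float]:
    if callable(q_schedule):
        return q_schedule
    if np.isscalar(q_schedule):
        qv = float(q_schedule)
        return lambda t: qv
    arr = np.asarray(q_schedule, dtype=float)
    if arr.shape != np.asarray(t_grid).shape:
        raise ValueError("array q_schedule must align with t_grid")
    return lambda t: float(np.interp(t, t_grid, arr))


def integrate(
    spec: SurrogateSpec,
    x0: Sequence[float],
    q_schedule: QSchedule,
    t_grid: np.ndarray,
) -> Tuple[np.ndarray, list]:
    """Fixed-step RK4 over ``t_grid``; states are clipped at zero and clip
    events are returned as (step, state-index) pairs.  A NaN state raises
    FloatingPointError naming the offending step."""
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    qf = _q_fn(q_schedule, t_grid)

    def f(x, t):
        return rhs(spec, np.maximum(x, 0.0), qf(t), t)

    return nn.rk4_rollout(f, np.asarray(x0, dtype=float), t_grid)


@dataclass
class FitResult:
    spec: SurrogateSpec
    training_loss: float
    q_values_used: List[float]
    normalization: np.ndarray
    n_starts: int = 1
    start_losses: Tuple[float, ...] = ()
    message: str = ""


def _trajectory_mse(spec, trajectories, normalization) -> float:
    total = 0.0
    count = 0
    for ts, X, q in trajectories:
        sim, _ = integrate(spec, X[0], q, ts)
        total += float(np.sum(((sim - X) / normalization) ** 2))
        count += X.size
    return total / count


def _fit_classical(
    kind: str,
    trajectories,
    normalization: np.ndarray,
    n_starts: int,
    seed: int,
    x_scale_log: float = 1.0,
    max_nfev: int = 200,
    theta0: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, float, list]:
    """Multi-start least squares for mm/gma/lv/ssystem kinds.

    Positive parameters are optimized in log space; GMA/S-system exponents
    stay linear.  Returns (best params, best mse, per-start losses).
    """
    rng = np.random.default_rng(seed)
    n_states = trajectories[0][1].shape[1]
    state_names = PATHWAY_STATES if n_states == 5 else tuple("abc")[:n_states]

    if kind == "mm":
        base = np.log(np.array([4.0, 4.0, 4.0, 4.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 2.0]))
        to_params = lambda th: np.exp(th)
        names = MM_PARAM_NAMES
    elif kind == "gma":
        base = np.concatenate(
            [np.log([1.0, 1.0, 1.0, 1.0]), [1.0, -0.5, 1.0, 1.0, 1.0, 0.5]]
        )
        to_params = lambda th: np.concatenate([np.exp(th[:4]), th[4:]])
        names = GMA_PARAM_NAMES
    elif kind == "lv":
        base = np.log(np.full(8, 0.5))
        to_params = lambda th: np.exp(th)
        names = LV_PARAM_NAMES
    elif kind == "ssystem":
        n = n_states
        base = np.concatenate([np.log(np.full(2 * n, 0.5)), np.zeros(2 * n * n)])
        to_params = lambda th: np.concatenate([np.exp(th[: 2 * n]), th[2 * n :]])
        names = ()
    else:
        raise ValueError(kind)
    if theta0 is not None:
        base = np.asarray(theta0, dtype=float)

    def residuals(th):
        spec = SurrogateSpec(kind, state_names, to_params(th), names)
        res = []
        for ts, X, q in trajectories:
            try:
                sim, _ = integrate(spec, X[0], q, ts)
            except FloatingPointError:
                return np.full(sum(X.size for _, X, _ in trajectories), 1e3)
            res.append(((sim - X) / normalization).ravel())
        return np.concatenate(res)

    best = None
    losses = []
    for start in range(n_starts):
        th0 = base if start == 0 else base + rng.normal(0, x_scale_log, base.shape)
        try:
            sol = optimize.least_squares(residuals, th0, max_nfev=max_nfev)
            mse = float(np.mean(sol.fun**2))
        except (FloatingPointError, ValueError):
            continue
        losses.append(mse)
        if best is None or mse < best[1]:
            best = (to_params(sol.x), mse)
    if best is None:
        raise RuntimeError("all optimization starts diverged")
    return best[0], best[1], losses


def _fit_neural(
    trajectories,
    normalization: np.ndarray,
    seed: int,
    hidden: Sequence[int],
    n_iter: int,
    lr: float,
) -> Tuple[SurrogateSpec, float]:
    rng = np.random.default_rng(seed)
    n_states = trajectories[0][1].shape[1]
    scale = np.maximum(
        np.max([X.max(axis=0) for _, X, _ in trajectories], axis=0), 1e-6
    )
    sizes = [n_states + 1, *hidden, PATHWAY_STOICHIOMETRY.shape[0]]
    layers0 = nn.init_layers(sizes, rng, scale=0.5)
    theta0 = nn.flatten(layers0)
    N = PATHWAY_STOICHIOMETRY
    meta = {"sizes": sizes, "scale": scale, "stoichiometry": N}

    def loss_and_grad(theta):
        spec = SurrogateSpec("neural", PATHWAY_STATES, theta, (), meta)
        total = 0.0
        g = np.zeros_like(theta)
        count = sum(X.size for _, X, _ in trajectories)
        for ts, X, q in trajectories:
            qf = _q_fn(q, ts)

            def f(x, t):
                return rhs(spec, np.maximum(x, 0.0), qf(t), t)

            def f_vjp(x, t, v):
                xc = np.maximum(x, 0.0)
                rates, z, cache, layers = _neural_rates(spec, xc, qf(t))
                gz = (N @ v) * nn.sigmoid(z)
                gin, grads = nn.vjp(layers, cache, gz)
                gx = gin[:n_states] / meta["scale"]
                return gx, nn.flatten(grads)

            sim, _ = nn.rk4_rollout(f, X[0].astype(float), ts)
            err = (sim - X) / normalization
            total += float(np.sum(err**2))
            gxs = 2.0 * err / normalization / count
            g += nn.rk4_rollout_grad(f, f_vjp, X[0], ts, sim, gxs, theta.size)
        return total / count, g

    theta, best_loss, _ = nn.adam(loss_and_grad, theta0, n_iter=n_iter, lr=lr)
    spec = SurrogateSpec("neural", PATHWAY_STATES, theta, (), meta)
    return spec, best_loss


def fit_surrogate(
    kind: str,
    trajectories: Sequence[Tuple[np.ndarray, np.ndarray, QSchedule]],
    normalization: Optional[Sequence[float]] = None,
    n_starts: int = 3,
    seed: int = 0,
    hidden: Sequence[int] = (12,),
    n_iter: int = 150,
    lr: float = 0.05,
    theta0: Optional[np.ndarray] = None,
) -> FitResult:
    """Fit a surrogate to simulator trajectories.

    ``trajectories`` is a sequence of ``(t_grid, states, q)`` triples where
    ``states`` has one row per grid point (already on the rescaled state
    space, e.g. counts x 1e-4 for the pathway) and ``q`` is the inflow
    schedule of that run.  Classical kinds use multi-start least squares in
    log-parameter space; the neural kind uses Adam with exact
    discretize-then-optimize gradients.  Deterministic given ``seed``.
    """
    if len(trajectories) == 0:
        raise ValueError("need at least one trajectory")
    trajectories = [
        (np.asarray(ts, dtype=float), np.asarray(X, dtype=float), q)
        for ts, X, q in trajectories
    ]
    n_states = trajectories[0][1].shape[1]
    if normalization is None:
        normalization = np.maximum(
            np.max([X.max(axis=0) for _, X, _ in trajectories], axis=0), 1e-6
        )
    normalization = np.asarray(normalization, dtype=float)
    q_used = [
        float(q) if np.isscalar(q) else float("nan") for _, _, q in trajectories
    ]
    if kind == "neural":
        spec, loss = _fit_neural(
            trajectories, normalization, seed, hidden, n_iter, lr
        )
        return FitResult(spec, loss, q_used, normalization, n_starts=1)
    params, loss, start_losses = _fit_classical(
        kind, trajectories, normalization, n_starts, seed, theta0=theta0
    )
    state_names = PATHWAY_STATES if n_states == 5 else tuple("abc")[:n_states]
    names = {"mm": MM_PARAM_NAMES, "gma": GMA_PARAM_NAMES, "lv": LV_PARAM_NAMES}.get(
        kind, ()
    )
    spec = SurrogateSpec(kind, state_names, params, names)
    return FitResult(
        spec, loss, q_used, normalization,
        n_starts=n_starts, start_losses=tuple(start_losses),
    )


def continuous_J2(ts: np.ndarray, states: np.ndarray) -> float:
    """Continuous-time substrate-waste loss: trapezoidal
    ``integral S dt / integral (R + T) dt`` on the grid."""
    num = float(np.trapezoid(states[:, 0], ts))
    den = float(np.trapezoid(states[:, 3] + states[:, 4], ts))
    if den <= 0:
        raise ZeroDivisionError("no end product formed under this inflow")
    return num / den


def loss_curve(
    fit: FitResult,
    q_grid: Sequence[float],
    x0: Sequence[float],
    Nt: float,
    n_points: int = 601,
) -> List[Tuple[float, float]]:
    """J2 of the fitted surrogate under each constant inflow in ``q_grid``.
    A run that forms no product yields J2 = inf for that point."""
    ts = np.linspace(0.0, Nt, n_points)
    out = []
    for q in q_grid:
        if not 0.0 <= q <= 1.0:
            raise ValueError("q_grid values must lie in [0, 1]")
        states, _ = integrate(fit.spec, x0, float(q), ts)
        try:
            j2 = continuous_J2(ts, states)
        except ZeroDivisionError:
            j2 = float("inf")
        out.append((float(q), j2))
    return out


def optimize_constant_inflow(
    fit: FitResult, q_grid: Sequence[float], x0: Sequence[float], Nt: float,
    n_points: int = 601,
) -> Tuple[float, float]:
    """Constant inflow minimizing the surrogate J2 over the grid; ties break
    toward smaller q.  Returns (q_opt, J2_opt)."""
    curve = loss_curve(fit, q_grid, x0, Nt, n_points)
    qs = np.array([q for q, _ in curve])
    js = np.array([j for _, j in curve])
    order = np.argsort(qs, kind="stable")
    best = order[np.argmin(js[order])]
    return float(qs[best]), float(js[best])


def train_inflow_controller(
    fit: FitResult,
    params0: InflowNetParams,
    x0: Sequence[float],
    Nt: float,
    n_points: int = 601,
    n_iter: int = 150,
    lr: float = 0.05,
    init_q: Optional[float] = None,
) -> Tuple[InflowNetParams, float, List[float]]:
    """Train the time-dependent inflow network on a differentiable (MM)
    surrogate by gradient descent through the RK4 discretization.

    ``init_q`` sets the output bias so that the initial schedule is the
    constant ``init_q`` (e.g. the best constant inflow), which makes the
    trained controller at least as good as that constant by construction
    (best-so-far iterate is returned).  Returns (params, J2, loss history).
    """
    if fit.spec.kind != "mm":
        raise ValueError(
            "inflow-controller training requires the differentiable "
            "mechanistic (mm) surrogate"
        )
    mm_params = fit.spec.params
    ts = np.linspace(0.0, float(Nt), n_points)
    sizes = params0.layer_sizes
    layers_init = [(w.copy(), b.copy()) for w, b in params0.layers]
    if init_q is not None:
        # start exactly at the constant schedule q = init_q (zero output
        # weights), so the best-so-far iterate can never be worse than the
        # best constant inflow evaluated on the same grid
        qc = np.clip(init_q, 1e-4, 1 - 1e-4)
        w_last, _ = layers_init[-1]
        layers_init[-1] = (
            np.zeros_like(w_last),
            np.full(w_last.shape[0], np.log(qc / (1 - qc))),
        )
    theta0 = nn.flatten(layers_init)
    x0 = np.asarray(x0, dtype=float)

    def q_of(theta_layers, t):
        y, cache = nn.forward(theta_layers, np.array([t / float(Nt)]),
                              params0.activation)
        q = float(nn.sigmoid(y)[0])
        return q, y, cache

    def loss_and_grad(theta):
        layers = nn.unflatten(theta, sizes)

        def f(x, t):
            q, _, _ = q_of(layers, t)
            dx = PATHWAY_STOICHIOMETRY.T @ _mm_fluxes(mm_params, np.maximum(x, 0.0))
            dx[0] += q
            return dx

        def f_vjp(x, t, v):
            xc = np.maximum(x, 0.0)
            gx = _mm_jacobian(mm_params, xc).T @ v
            q, y, cache = q_of(layers, t)
            gy = np.array([v[0] * q * (1.0 - q)])
            _, grads = nn.vjp(layers, cache, gy, params0.activation)
            return gx, nn.flatten(grads)

        states, _ = nn.rk4_rollout(f, x0, ts)
        num = float(np.trapezoid(states[:, 0], ts))
        den = float(np.trapezoid(states[:, 3] + states[:, 4], ts))
        if den <= 0:
            raise ZeroDivisionError("no end product formed during training")
        j2 = num / den
        # d j2 / d states via trapezoid weights and the quotient rule
        wts = np.empty(ts.size)
        wts[0] = (ts[1] - ts[0]) / 2
        wts[-1] = (ts[-1] - ts[-2]) / 2
        wts[1:-1] = (ts[2:] - ts[:-2]) / 2
        gxs = np.zeros_like(states)
        gxs[:, 0] = wts / den
        gxs[:, 3] = -wts * num / den**2
        gxs[:, 4] = gxs[:, 3]
        g = nn.rk4_rollout_grad(f, f_vjp, x0, ts, states, gxs, theta.size)
        return j2, g

    theta, best_loss, history = nn.adam(loss_and_grad, theta0, n_iter=n_iter, lr=lr)
    params = InflowNetParams(
        layers=nn.unflatten(theta, sizes), activation=params0.activation
    )
    return params, best_loss, history


def save_fit(path, fit: FitResult) -> None:
    payload = {
        "kind": fit.spec.kind,
        "state_names": list(fit.spec.state_names),
        "params": fit.spec.params.tolist(),
        "param_names": list(fit.spec.param_names),
        "training_loss": fit.training_loss,
        "q_values_used": fit.q_values_used,
        "normalization": np.asarray(fit.normalization).tolist(),
        "meta": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in fit.spec.meta.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_fit(path) -> FitResult:
    with open(path) as fh:
        payload = json.load(fh)
    meta = {
        k: (np.asarray(v) if k in ("scale", "stoichiometry") else v)
        for k, v in payload["meta"].items()
    }
    spec = SurrogateSpec(
        payload["kind"],
        tuple(payload["state_names"]),
        np.asarray(payload["params"]),
        tuple(payload["param_names"]),
        meta,
    )
    return FitResult(
        spec,
        payload["training_loss"],
        payload["q_values_used"],
        np.asarray(payload["normalization"]),
    )
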