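"""Control functions mapping observations to actions.

Three controller families act on the simulators:

* a two-parameter steady-state controller that removes
  ``floor(theta1 * b_k)`` prey and ``floor(theta2 * c_k)`` predators per
  period,
* a multilayer-perceptron transient controller with integer outputs, and
* a time-dependent substrate-inflow network for the metabolic pathway.

Integer-valued actions are produced by the straight-through floor
:func:`st_floor`: the forward pass takes the floor of the positive part,
while gradient-based training treats the rounding as the identity (slope 1
for positive arguments, 0 otherwise), exposed via :func:`st_floor_grad`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .grid_abm import Observation

__all__ = [
    "st_floor",
    "st_floor_grad",
    "SteadyStateParams",
    "steady_state_control",
    "steady_state_controller",
    "MLPParams",
    "mlp_control",
    "mlp_controller",
    "InflowNetParams",
    "inflow_control",
    "save_controller",
    "load_controller",
]


def st_floor(x):
    """Floor of the positive part: ``[x]+ - {[x]+}`` with ``[x]+ = max(0, x)``.

    Returns an integer (or integer array).  During gradient-based training
    the rounding is transparent: the associated derivative is
    :func:`st_floor_grad` (1 for x > 0, else 0).
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("st_floor requires finite input")
    out = np.floor(np.maximum(arr, 0.0)).astype(np.int64)
    if np.isscalar(x) or arr.ndim == 0:
        return int(out)
    return out


def st_floor_grad(x):
    """Straight-through derivative of :func:`st_floor`: 1 where x > 0, 0
    elsewhere.  Together with the chain rule this makes the training-time
    gradient of ``L(st_floor(g(theta)))`` equal that of ``L(g(theta))``
    wherever ``g > 0``."""
    arr = np.asarray(x, dtype=float)
    out = (arr > 0.0).astype(float)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


@dataclass
class SteadyStateParams:
    """Two nonnegative removal coefficients (prey, predators)."""

    theta1: float = 0.0
    theta2: float = 0.0

    def __post_init__(self) -> None:
        if self.theta1 < 0 or self.theta2 < 0:
            raise ValueError("theta1, theta2 must be >= 0")


def steady_state_control(b: int, c: int, params: SteadyStateParams) -> Tuple[int, int]:
    """Removal-only proportional control:
    ``u1 = -st_floor(b * theta1)``, ``u2 = -st_floor(c * theta2)``."""
    return (-st_floor(b * params.theta1), -st_floor(c * params.theta2))


def steady_state_controller(params: SteadyStateParams):
    """Wrap :func:`steady_state_control` as a rollout controller."""

    def controller(obs: Observation, k: int) -> Tuple[int, int]:
        return steady_state_control(obs.b, obs.c, params)

    return controller


@dataclass
class MLPParams:
    """Transient-controller network.

    Inputs are the normalized observation ``(b / b_scale, c / c_scale)`` and
    normalized time; the two raw outputs are mapped to integers by
    sign-preserving straight-through rounding and clipped at ``u_max``.
    The canonical architecture has three hidden layers with widths between
    16 and 64 (default 3 -> 64 -> 32 -> 16 -> 2, tanh).
    """

    layers: nn.Layers
    activation: str = "tanh"
    b_scale: float = 2500.0
    c_scale: float = 1250.0
    u_max: int = 500

    @property
    def layer_sizes(self) -> List[int]:
        return [self.layers[0][0].shape[1]] + [w.shape[0] for w, _ in self.layers]

    @classmethod
    def create(
        cls,
        hidden: Sequence[int] = (64, 32, 16),
        rng: Optional[np.random.Generator] = None,
        scale: float = 1.0,
        **kwargs,
    ) -> "MLPParams":
        sizes = [3, *hidden, 2]
        if rng is None:
            layers = nn.zero_layers(sizes)
        else:
            layers = nn.init_layers(sizes, rng, scale)
        return cls(layers=layers, **kwargs)

    def validate_transient(self) -> None:
        """Check the canonical transient architecture (three hidden layers,
        widths within [16, 64])."""
        hidden = self.layer_sizes[1:-1]
        if len(hidden) != 3 or any(not 16 <= h <= 64 for h in hidden):
            raise ValueError(
                f"transient controller expects three hidden layers with "
                f"16-64 units, got {hidden}"
            )


def mlp_control(
    obs: Observation, k: int, horizon: int, params: MLPParams
) -> Tuple[int, int]:
    """Evaluate the transient MLP controller at one observation.

    ``k`` is measured from the start of the controlled window and ``horizon``
    is the window length used for time normalization.
    """
    feats = np.array(
        [obs.b / params.b_scale, obs.c / params.c_scale, k / max(horizon, 1)]
    )
    y, _ = nn.forward(params.layers, feats, params.activation)
    u = np.sign(y) * st_floor(np.abs(y))
    u = np.clip(u, -params.u_max, params.u_max)
    return (int(u[0]), int(u[1]))


def mlp_controller(params: MLPParams, burn_in: int, horizon: int):
    """Wrap :func:`mlp_control` as a rollout controller active after
    ``burn_in``; before that the rollout applies no control anyway."""

    def controller(obs: Observation, k: int) -> Tuple[int, int]:
        return mlp_control(obs, max(k - burn_in, 0), horizon, params)

    return controller


@dataclass
class InflowNetParams:
    """Time-dependent inflow network: normalized time ``t / Nt`` is mapped
    through a small MLP and a logistic squashing to ``q`` in [0, 1]."""

    layers: nn.Layers
    activation: str = "tanh"

    @property
    def layer_sizes(self) -> List[int]:
        return [self.layers[0][0].shape[1]] + [w.shape[0] for w, _ in self.layers]

    @classmethod
    def create(
        cls,
        hidden: Sequence[int] = (16, 16),
        rng: Optional[np.random.Generator] = None,
        scale: float = 1.0,
        **kwargs,
    ) -> "InflowNetParams":
        sizes = [1, *hidden, 1]
        if rng is None:
            layers = nn.zero_layers(sizes)
        else:
            layers = nn.init_layers(sizes, rng, scale)
        return cls(layers=layers, **kwargs)

    def lipschitz_bound(self) -> float:
        """Upper bound on |dq/d(t/Nt)|: product of layer spectral norms
        times the logistic slope 1/4 (hidden activations are 1-Lipschitz)."""
        bound = 0.25
        for w, _ in self.layers:
            bound *= np.linalg.norm(w, 2)
        return bound


def inflow_control(k: float, Nt: int, params: InflowNetParams) -> float:
    """Inflow at period ``k``: ``sigmoid(net(k / Nt))`` in [0, 1]."""
    y, _ = nn.forward(params.layers, np.array([k / max(Nt, 1)]), params.activation)
    return float(nn.sigmoid(y)[0])


def save_controller(path, params) -> None:
    """Serialize controller parameters to a flat JSON file."""
    if isinstance(params, SteadyStateParams):
        payload = {"kind": "steady_state", "theta1": params.theta1, "theta2": params.theta2}
    elif isinstance(params, (MLPParams, InflowNetParams)):
        kind = "mlp" if isinstance(params, MLPParams) else "inflow_net"
        payload = {
            "kind": kind,
            "layer_sizes": params.layer_sizes,
            "activation": params.activation,
            "weights": nn.flatten(params.layers).tolist(),
        }
        if isinstance(params, MLPParams):
            payload.update(
                b_scale=params.b_scale, c_scale=params.c_scale, u_max=params.u_max
            )
    else:
        raise TypeError(f"unsupported controller type {type(params)!r}")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_controller(path):
    with open(path) as fh:
        payload = json.load(fh)
    kind = payload.pop("kind")
    if kind == "steady_state":
        return SteadyStateParams(payload["theta1"], payload["theta2"])
    sizes = payload.pop("layer_sizes")
    layers = nn.unflatten(np.asarray(payload.pop("weights")), sizes)
    if kind == "mlp":
        return MLPParams(layers=layers, **payload)
    if kind == "inflow_net":
        return InflowNetParams(layers=layers, **payload)
    raise ValueError(f"unknown controller kind {kind!r}")
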