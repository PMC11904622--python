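"""Minimal dense neural networks with hand-written reverse-mode gradients.

The controllers and the semi-mechanistic neural ODE in this package are
small multilayer perceptrons (tens to a few hundred weights), so a compact
numpy implementation with explicit vector-Jacobian products is both fast
and dependency-free.  The module also provides backpropagation through a
fixed-grid fourth-order Runge-Kutta unroll (discretize-then-optimize) and a
plain Adam optimizer.
"""

from __future__ import annotations

from typing import Callable, List, Sequence, Tuple

import numpy as np

Layers = List[Tuple[np.ndarray, np.ndarray]]

_ACTS = {
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}


def init_layers(
    sizes: Sequence[int], rng: np.random.Generator, scale: float = 1.0
) -> Layers:
    """Glorot-style initialization of ``len(sizes) - 1`` dense layers."""
    layers = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        w = rng.normal(0.0, scale * np.sqrt(2.0 / (n_in + n_out)), (n_out, n_in))
        layers.append((w, np.zeros(n_out)))
    return layers


def zero_layers(sizes: Sequence[int]) -> Layers:
    return [
        (np.zeros((n_out, n_in)), np.zeros(n_out))
        for n_in, n_out in zip(sizes[:-1], sizes[1:])
    ]


def forward(layers: Layers, x: np.ndarray, activation: str = "tanh"):
    """Forward pass.  The last layer is linear; hidden layers use
    ``activation``.  Returns (output, cache-for-vjp)."""
    act, _ = _ACTS[activation]
    h = np.asarray(x, dtype=float)
    pre = []
    posts = [h]
    n = len(layers)
    for i, (w, b) in enumerate(layers):
        z = w @ h + b
        pre.append(z)
        h = act(z) if i < n - 1 else z
        posts.append(h)
    return h, (pre, posts)


def vjp(layers: Layers, cache, gy: np.ndarray, activation: str = "tanh"):
    """Vector-Jacobian product of :func:`forward`: returns the gradient with
    respect to the input and the per-layer weight gradients."""
    _, dact = _ACTS[activation]
    pre, posts = cache
    n = len(layers)
    g = np.asarray(gy, dtype=float)
    grads: List[Tuple[np.ndarray, np.ndarray]] = [None] * n  # type: ignore
    for i in range(n - 1, -1, -1):
        if i < n - 1:
            g = g * dact(pre[i])
        w, _ = layers[i]
        grads[i] = (np.outer(g, posts[i]), g.copy())
        g = w.T @ g
    return g, grads


def flatten(layers: Layers) -> np.ndarray:
    return np.concatenate([np.concatenate([w.ravel(), b]) for w, b in layers])


def unflatten(theta: np.ndarray, sizes: Sequence[int]) -> Layers:
    layers = []
    i = 0
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        w = theta[i : i + n_out * n_in].reshape(n_out, n_in)
        i += n_out * n_in
        b = theta[i : i + n_out]
        i += n_out
        layers.append((w, b))
    if i != theta.size:
        raise ValueError("parameter vector length does not match layer sizes")
    return layers


def softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(np.asarray(z, dtype=float))
    zp = np.asarray(z, dtype=float)
    pos = zp >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-zp[pos]))
    ez = np.exp(zp[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def rk4_rollout(
    f: Callable[[np.ndarray, float], np.ndarray],
    x0: np.ndarray,
    ts: np.ndarray,
    clip_nonnegative: bool = True,
):
    """Fixed-step RK4 over the grid ``ts``.  States are clipped at zero after
    each step when requested; clip events are returned as (step index,
    state index) pairs.  Raises FloatingPointError on non-finite states."""
    ts = np.asarray(ts, dtype=float)
    x = np.asarray(x0, dtype=float).copy()
    out = np.empty((ts.size, x.size))
    out[0] = x
    clips = []
    for n in range(ts.size - 1):
        t = ts[n]
        h = ts[n + 1] - t
        k1 = f(x, t)
        k2 = f(x + 0.5 * h * k1, t + 0.5 * h)
        k3 = f(x + 0.5 * h * k2, t + 0.5 * h)
        k4 = f(x + h * k3, t + h)
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"integration produced non-finite state at step {n} (t={t})"
            )
        if clip_nonnegative:
            neg = x < 0
            if neg.any():
                clips.extend((n, int(j)) for j in np.flatnonzero(neg))
                x = np.maximum(x, 0.0)
        out[n + 1] = x
    return out, clips


def rk4_rollout_grad(
    f: Callable[[np.ndarray, float], np.ndarray],
    f_vjp: Callable[[np.ndarray, float, np.ndarray], Tuple[np.ndarray, np.ndarray]],
    x0: np.ndarray,
    ts: np.ndarray,
    xs: np.ndarray,
    gxs: np.ndarray,
    n_params: int,
) -> np.ndarray:
    """Gradient of ``sum_n gxs[n] . xs[n]`` with respect to the parameters of
    ``f`` by reverse-mode differentiation through the RK4 unroll.

    ``xs`` is the stored forward trajectory from :func:`rk4_rollout` and
    ``f_vjp(x, t, v)`` must return ``(v . df/dx, v . df/dtheta)``.  The
    nonnegativity clip is treated as the identity (straight-through), which
    is exact whenever the forward path never clips.
    """
    ts = np.asarray(ts, dtype=float)
    gtheta = np.zeros(n_params)
    lam = gxs[-1].astype(float).copy()
    for n in range(ts.size - 2, -1, -1):
        t = ts[n]
        h = ts[n + 1] - t
        x = xs[n]
        k1 = f(x, t)
        x2 = x + 0.5 * h * k1
        k2 = f(x2, t + 0.5 * h)
        x3 = x + 0.5 * h * k2
        k3 = f(x3, t + 0.5 * h)
        x4 = x + h * k3
        # adjoint of x_{n+1} = x_n + h/6 (k1 + 2 k2 + 2 k3 + k4)
        gk1 = (h / 6.0) * lam
        gk2 = (h / 3.0) * lam
        gk3 = (h / 3.0) * lam
        gk4 = (h / 6.0) * lam
        gx = lam.copy()
        gx4, gth = f_vjp(x4, t + h, gk4)
        gtheta += gth
        gk3 = gk3 + h * gx4
        gx += gx4
        gx3, gth = f_vjp(x3, t + 0.5 * h, gk3)
        gtheta += gth
        gk2 = gk2 + 0.5 * h * gx3
        gx += gx3
        gx2, gth = f_vjp(x2, t + 0.5 * h, gk2)
        gtheta += gth
        gk1 = gk1 + 0.5 * h * gx2
        gx += gx2
        gx1, gth = f_vjp(x, t, gk1)
        gtheta += gth
        gx += gx1
        lam = gx + gxs[n]
    return gtheta


def adam(
    loss_and_grad: Callable[[np.ndarray], Tuple[float, np.ndarray]],
    theta0: np.ndarray,
    n_iter: int = 200,
    lr: float = 0.01,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
    callback: Callable[[int, float, np.ndarray], None] | None = None,
):
    """Plain Adam; returns (best theta, best loss, loss history)."""
    theta = np.asarray(theta0, dtype=float).copy()
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    best = (np.inf, theta.copy())
    history = []
    for it in range(1, n_iter + 1):
        loss, g = loss_and_grad(theta)
        gnorm = float(np.linalg.norm(g))
        if not np.isfinite(gnorm):
            break
        if gnorm > 1e3:  # norm clip against rare unroll blow-ups
            g = g * (1e3 / gnorm)
        history.append(loss)
        if loss < best[0]:
            best = (loss, theta.copy())
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        mh = m / (1 - beta1**it)
        vh = v / (1 - beta2**it)
        theta = theta - lr * mh / (np.sqrt(vh) + eps)
        if callback is not None:
            callback(it, loss, theta)
    return best[1], best[0], history
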