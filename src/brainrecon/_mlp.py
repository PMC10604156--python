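"""Numpy implementation of the residual MLP decoder network.

The network maps voxel vectors to feature vectors through an input
projection (linear + GELU + dropout), a stack of residual linear blocks
(linear + LayerNorm + GELU + dropout, with an additive skip spanning the
block), and a plain linear head.  Forward, backward and the AdamW update
are written directly in numpy: the model is small enough that explicit
backprop on one CPU is both fast and bit-reproducible.

Parameters live in a flat dict of arrays keyed ``"in.W"``, ``"in.b"``,
``"blk0.W"``, ``"blk0.b"``, ``"blk0.g"``, ``"blk0.beta"``, ...,
``"head.W"``, ``"head.b"``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact GELU: x * Phi(x)."""
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    Phi = 0.5 * (1.0 + erf(x / _SQRT2))
    return Phi + x * phi


def init_params(
    in_dim: int, out_dim: int, n_blocks: int, hidden_dim: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """He-style initialization; LayerNorm gains 1, all biases 0."""
    params: dict[str, np.ndarray] = {}
    params["in.W"] = rng.normal(0.0, np.sqrt(2.0 / in_dim), (in_dim, hidden_dim))
    params["in.b"] = np.zeros(hidden_dim)
    for k in range(n_blocks):
        params[f"blk{k}.W"] = rng.normal(0.0, np.sqrt(2.0 / hidden_dim), (hidden_dim, hidden_dim))
        params[f"blk{k}.b"] = np.zeros(hidden_dim)
        params[f"blk{k}.g"] = np.ones(hidden_dim)
        params[f"blk{k}.beta"] = np.zeros(hidden_dim)
    params["head.W"] = rng.normal(0.0, np.sqrt(1.0 / hidden_dim), (hidden_dim, out_dim))
    params["head.b"] = np.zeros(out_dim)
    return params


def param_count(in_dim: int, out_dim: int, n_blocks: int, hidden_dim: int) -> int:
    n = in_dim * hidden_dim + hidden_dim
    n += n_blocks * (hidden_dim * hidden_dim + hidden_dim + 2 * hidden_dim)
    n += hidden_dim * out_dim + out_dim
    return n


def forward(
    params: dict[str, np.ndarray],
    x: np.ndarray,
    n_blocks: int,
    dropout_rate: float = 0.0,
    layernorm_eps: float = 1e-5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Forward pass.  Dropout is active only when ``rng`` is given (train
    mode); evaluation passes ``rng=None`` and is deterministic."""
    cache: dict = {"x": x, "drop": {}}
    keep = 1.0 - dropout_rate

    def dropout(h: np.ndarray, tag: str) -> np.ndarray:
        if rng is None or dropout_rate <= 0.0:
            return h
        mask = (rng.random(h.shape) < keep) / keep
        cache["drop"][tag] = mask
        return h * mask

    a0 = x @ params["in.W"] + params["in.b"]
    cache["in.a"] = a0
    h = dropout(gelu(a0), "in")
    cache["in.out"] = h

    for k in range(n_blocks):
        cache[f"blk{k}.in"] = h
        a = h @ params[f"blk{k}.W"] + params[f"blk{k}.b"]
        mu = a.mean(axis=1, keepdims=True)
        var = a.var(axis=1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + layernorm_eps)
        xhat = (a - mu) * inv_std
        ln = params[f"blk{k}.g"] * xhat + params[f"blk{k}.beta"]
        act = gelu(ln)
        out = dropout(act, f"blk{k}") + h  # additive skip spans the block
        cache[f"blk{k}.a"] = a
        cache[f"blk{k}.xhat"] = xhat
        cache[f"blk{k}.inv_std"] = inv_std
        cache[f"blk{k}.ln"] = ln
        h = out

    y = h @ params["head.W"] + params["head.b"]
    cache["head.in"] = h
    return y, cache


def backward(
    params: dict[str, np.ndarray],
    cache: dict,
    dy: np.ndarray,
    n_blocks: int,
) -> dict[str, np.ndarray]:
    """Backprop ``dy = dL/dy`` through the network; returns grads per param."""
    grads: dict[str, np.ndarray] = {}
    h_in = cache["head.in"]
    grads["head.W"] = h_in.T @ dy
    grads["head.b"] = dy.sum(axis=0)
    dh = dy @ params["head.W"].T

    for k in reversed(range(n_blocks)):
        # out = dropout(gelu(LN(linear(h)))) + h
        dskip = dh
        dact = dh
        mask = cache["drop"].get(f"blk{k}")
        if mask is not None:
            dact = dact * mask
        dln = dact * gelu_grad(cache[f"blk{k}.ln"])
        xhat = cache[f"blk{k}.xhat"]
        grads[f"blk{k}.g"] = (dln * xhat).sum(axis=0)
        grads[f"blk{k}.beta"] = dln.sum(axis=0)
        dxhat = dln * params[f"blk{k}.g"]
        inv_std = cache[f"blk{k}.inv_std"]
        m = xhat.shape[1]
        da = (
            inv_std
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=1, keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=1, keepdims=True)
            )
        )
        h_prev = cache[f"blk{k}.in"]
        grads[f"blk{k}.W"] = h_prev.T @ da
        grads[f"blk{k}.b"] = da.sum(axis=0)
        dh = da @ params[f"blk{k}.W"].T + dskip

    mask = cache["drop"].get("in")
    if mask is not None:
        dh = dh * mask
    da0 = dh * gelu_grad(cache["in.a"])
    grads["in.W"] = cache["x"].T @ da0
    grads["in.b"] = da0.sum(axis=0)
    return grads


class AdamW:
    """Decoupled-weight-decay Adam, matching the standard formulation."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ) -> None:
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1.0 - b1) * g
            self.v[k] = b2 * self.v[k] + (1.0 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            # decay applies to weights only, not LayerNorm gains or biases
            if k.endswith(".W") and self.weight_decay > 0.0:
                params[k] *= 1.0 - self.lr * self.weight_decay
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_annealed_lr(lr_init: float, epoch: int, total_epochs: int) -> float:
    """Cosine decay from ``lr_init`` at epoch 0 toward 0, no restarts."""
    if total_epochs <= 1:
        return lr_init
    return lr_init * 0.5 * (1.0 + np.cos(np.pi * epoch / total_epochs))
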