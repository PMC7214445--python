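"""Minimal numpy neural-network primitives for the message-passing model.

Forward and backward passes are written out explicitly; no automatic
differentiation framework is used.  All functions operate on 2-D arrays
of shape (n_items, n_features).
"""

from __future__ import annotations

import numpy as np

EPS = 1e-5


def glorot_uniform(rng: np.random.Generator, shape, dtype=np.float32) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def embedding_init(rng: np.random.Generator, n_rows: int, dim: int, dtype=np.float32):
    scale = 1.0 / np.sqrt(dim)
    return rng.uniform(-scale, scale, size=(n_rows, dim)).astype(dtype)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(dout: np.ndarray, pre: np.ndarray) -> np.ndarray:
    return dout * (pre > 0)


def batchnorm_forward(x, gamma, beta, running_mean, running_var,
                      training: bool, momentum: float = 0.99):
    """Feature-wise batch normalization.

    In training mode the batch statistics are used and the running
    statistics are updated in place; in eval mode the running statistics
    are used so single-molecule inference is deterministic.

    Returns (out, cache); cache is None in eval mode.
    """
    if training:
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        inv_std = 1.0 / np.sqrt(var + EPS)
        xhat = (x - mu) * inv_std
        running_mean *= momentum
        running_mean += (1.0 - momentum) * mu
        running_var *= momentum
        running_var += (1.0 - momentum) * var
        cache = (xhat, inv_std, gamma)
    else:
        xhat = (x - running_mean) / np.sqrt(running_var + EPS)
        cache = None
    return gamma * xhat + beta, cache


def batchnorm_backward(dout, cache):
    """Gradient of training-mode batch normalization.

    Returns (dx, dgamma, dbeta).
    """
    xhat, inv_std, gamma = cache
    n = dout.shape[0]
    dgamma = (dout * xhat).sum(axis=0)
    dbeta = dout.sum(axis=0)
    dxhat = dout * gamma
    dx = inv_std / n * (
        n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
    )
    return dx, dgamma, dbeta


class Adam:
    """ADAM optimizer over a dict of parameter arrays, with inverse-time
    learning-rate decay per update step: lr_t = lr / (1 + decay * t)."""

    def __init__(self, params: dict, lr: float = 1e-3, decay: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.decay = decay
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        lr_t = self.lr / (1.0 + self.decay * self.t)
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for key, grad in grads.items():
            m = self.m[key]
            v = self.v[key]
            m *= self.beta1
            m += (1.0 - self.beta1) * grad
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(grad)
            update = lr_t * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            params[key] -= update.astype(params[key].dtype)
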