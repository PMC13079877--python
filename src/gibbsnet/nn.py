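"""Network building blocks: plain and Lipschitz-constrained linear layers.

The gE model's smoothness is controlled by bounding each layer's spectral
norm: raw weights are normalized by an estimate of their largest singular
value (power iteration, two steps per forward call with warm-started
vectors) and rescaled by a learnable per-layer Lipschitz constant
softplus(c*).  The product of the softplus(c*) over all layers is a loose
upper bound on the network's Lipschitz constant and doubles as a
regularization term during training.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

SIGMA_FLOOR = 1e-12


def softplus_inv(y: float) -> float:
    """Inverse of softplus, y > 0."""
    # log(exp(y) - 1), stable for large y
    if y > 30.0:
        return y
    return float(np.log(np.expm1(y)))


def spectral_norm_estimate(weights: np.ndarray, n_iter: int = 2, state=None):
    """Power-iteration estimate of the largest singular value.

    Returns ``(sigma, state)`` where ``state = (u, v)`` are the persistent
    left/right vectors; pass the returned state back in to warm-start the
    next call.  The Rayleigh-quotient estimate approaches sigma_max from
    below and is floored at ``SIGMA_FLOOR`` for the zero matrix.
    """
    w = np.asarray(weights, dtype=np.float64)
    m, n = w.shape
    if state is None or state[0].shape != (m,) or state[1].shape != (n,):
        rng = np.random.default_rng(0)
        u = rng.normal(size=m)
        v = rng.normal(size=n)
    else:
        u, v = state
    for _ in range(max(1, n_iter)):
        v = w.T @ u
        nv = np.linalg.norm(v)
        v = v / nv if nv > 0 else v
        u = w @ v
        nu = np.linalg.norm(u)
        u = u / nu if nu > 0 else u
    sigma = float(u @ w @ v)
    return max(sigma, SIGMA_FLOOR), (u, v)


class Linear:
    """Plain affine layer y = x W^T + b."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(in_features)
        self.weight = Tensor(
            rng.uniform(-k, k, size=(out_features, in_features)), requires_grad=True
        )
        self.bias = Tensor(rng.uniform(-k, k, size=out_features), requires_grad=True)
        self.in_features = in_features
        self.out_features = out_features

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, ad.transpose(self.weight)) + self.bias

    def parameters(self):
        return [self.weight, self.bias]


class LipschitzLinear:
    """Affine layer whose effective weight has spectral norm softplus(c*).

    ``W_scaled = W_raw / sigma_max(W_raw) * softplus(c*)``; sigma_max is
    estimated with two warm-started power iterations per call, with the
    estimate entering the graph as u^T W v so gradients flow through W while
    u, v are treated as constants.  c* is initialized so that softplus(c*)
    equals the raw init's spectral norm, making the scaled weights initially
    identical to the raw initialization.
    """

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(in_features)
        self.weight = Tensor(
            rng.uniform(-k, k, size=(out_features, in_features)), requires_grad=True
        )
        self.bias = Tensor(rng.uniform(-k, k, size=out_features), requires_grad=True)
        U, S, Vt = np.linalg.svd(self.weight.data)
        self.c_star = Tensor(softplus_inv(float(S[0])), requires_grad=True)
        self.n_power_iter = 2
        self.train_mode = False
        self.in_features = in_features
        self.out_features = out_features
        # power-iteration state starts at the exact top singular vectors and
        # tracks weight drift with two iterations per training step
        self._pi_state = (U[:, 0].copy(), Vt[0, :].copy())

    def lipschitz_constant(self) -> Tensor:
        return ad.softplus(self.c_star)

    def scaled_weight(self, n_iter: int | None = None) -> Tensor:
        if self.train_mode or n_iter is not None:
            n = self.n_power_iter if n_iter is None else n_iter
            _, self._pi_state = spectral_norm_estimate(
                self.weight.data, n_iter=n, state=self._pi_state
            )
        u, v = self._pi_state
        sigma = ad.reshape(
            ad.matmul(
                ad.matmul(Tensor(u[None, :]), self.weight), Tensor(v[:, None])
            ),
            (),
        )
        sigma = ad.maximum(sigma, Tensor(SIGMA_FLOOR))
        return self.weight * (ad.softplus(self.c_star) / sigma)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, ad.transpose(self.scaled_weight())) + self.bias

    def parameters(self):
        return [self.weight, self.bias, self.c_star]


def mlp_forward(layers, x: Tensor, activation=ad.silu, final_activation=None) -> Tensor:
    """Apply layers with ``activation`` on all but the last layer."""
    for layer in layers[:-1]:
        x = activation(layer(x))
    x = layers[-1](x)
    if final_activation is not None:
        x = final_activation(x)
    return x
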