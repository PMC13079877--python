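"""Differentiable surrogate solver for binary LLE phase compositions.

Training a gE model directly on liquid-liquid equilibrium data would
require an iterative phase-split solver inside the training loop.  Instead,
a small feed-forward network learns the map from a discretized Delta
g_mix/(RT) curve (101 uniformly spaced compositions) to the two coexisting
phase compositions (x1', x1'') as produced by the convex-envelope method.
The surrogate is differentiable, so gradients flow from measured phase
compositions back through the curve into the gE model's parameters; its
own weights stay frozen during that use.

Permutation equivariance (reversing the curve must map (x1', x1'') to
(1-x1'', 1-x1')) is enforced structurally: the network is evaluated on the
curve and its reverse, and the two passes are cross-paired, x' = (a +
(1-b_r))/2 and x'' = (b + (1-a_r))/2, which satisfies the identity exactly
for arbitrary weights.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Linear
from .optim import Adam, OneCycleLR
from .phase_equilibria import cem_binary, gmix_curve

CURVE_NODES = 101


class SurrogateModel:
    """Three fully connected layers (hidden size 64, ReLU) with sigmoid output."""

    def __init__(self, seed: int = 0, n_nodes: int = CURVE_NODES, hidden: int = 64):
        rng = np.random.default_rng(seed)
        self.n_nodes = n_nodes
        self.layers = [
            Linear(n_nodes, hidden, rng),
            Linear(hidden, hidden, rng),
            Linear(hidden, 2, rng),
        ]

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def _raw(self, curves: Tensor) -> Tensor:
        h = ad.maximum(self.layers[0](curves), Tensor(0.0))
        h = ad.maximum(self.layers[1](h), Tensor(0.0))
        return ad.sigmoid(self.layers[2](h))

    def forward(self, curves) -> Tensor:
        """Phase compositions (B, 2) from curves (B, 101) or (101,).

        Evaluates the network on the curve and its reverse and cross-pairs
        the two outputs, enforcing exact permutation equivariance.
        """
        curves = ad.astensor(curves)
        squeeze = curves.ndim == 1
        if squeeze:
            curves = ad.reshape(curves, (1, curves.shape[0]))
        if curves.shape[1] != self.n_nodes:
            raise ValueError(
                f"surrogate expects curves of length {self.n_nodes}, got {curves.shape[1]}"
            )
        out_fwd = self._raw(curves)
        out_rev = self._raw(curves[:, ::-1])
        a, b = out_fwd[:, 0:1], out_fwd[:, 1:2]
        a_r, b_r = out_rev[:, 0:1], out_rev[:, 1:2]
        xp = (a + (1.0 - b_r)) * 0.5
        xq = (b + (1.0 - a_r)) * 0.5
        out = ad.concat([xp, xq], axis=1)
        return ad.reshape(out, (2,)) if squeeze else out

    __call__ = forward


def make_surrogate_labels(
    provider_for_record, lle_records, return_temperatures: bool = False
):
    """CEM-labeled curves for surrogate training.

    ``provider_for_record(record)`` returns the ground-truth binary gE
    provider for a record; for each LLE record the 101-node curve at the
    record's temperature is labeled with the convex-envelope phase
    compositions.  Records whose curve shows no miscibility gap are
    dropped.  Labels are ordered x1' < x1''.
    """
    curves, labels, temps = [], [], []
    for rec in lle_records:
        provider = provider_for_record(rec)
        curve = gmix_curve(provider, rec.T, n_grid=CURVE_NODES)
        splits = cem_binary(curve)
        if not splits:
            continue
        sp = splits[0]
        curves.append(curve.values)
        labels.append([sp.x1_prime, sp.x1_doubleprime])
        temps.append(rec.T)
    if curves:
        out = np.asarray(curves), np.asarray(labels)
    else:
        out = np.empty((0, CURVE_NODES)), np.empty((0, 2))
    if return_temperatures:
        return (*out, np.asarray(temps))
    return out


def write_label_csv(path, temperatures, curves: np.ndarray, labels: np.ndarray):
    """Labeled curves as CSV: T, curve_0..curve_100, x1_prime, x1_doubleprime."""
    import pandas as pd

    cols = {"T": np.asarray(temperatures)}
    for k in range(curves.shape[1]):
        cols[f"curve_{k}"] = curves[:, k]
    cols["x1_prime"] = labels[:, 0]
    cols["x1_doubleprime"] = labels[:, 1]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_label_csv(path):
    import pandas as pd

    df = pd.read_csv(path)
    n = sum(1 for c in df.columns if c.startswith("curve_"))
    curves = df[[f"curve_{k}" for k in range(n)]].to_numpy()
    labels = df[["x1_prime", "x1_doubleprime"]].to_numpy()
    return df["T"].to_numpy(), curves, labels


def train_surrogate(
    train_curves: np.ndarray,
    train_labels: np.ndarray,
    val_curves: np.ndarray,
    val_labels: np.ndarray,
    epochs: int = 200,
    max_lr: float = 0.01,
    batch_size: int = 256,
    seed: int = 0,
) -> tuple[SurrogateModel, dict]:
    """Train on CEM-labeled curves (MSE, Adam, one-cycle schedule).

    Train/validation sets must be split system-wise upstream.  Returns the
    epoch-best model by validation MSE and the training history.
    """
    if len(train_curves) == 0:
        raise ValueError("empty surrogate training set")
    model = SurrogateModel(seed=seed)
    params = model.parameters()
    n = len(train_curves)
    steps_per_epoch = max(1, int(np.ceil(n / batch_size)))
    opt = Adam(params, lr=max_lr)
    sched = OneCycleLR(opt, max_lr=max_lr, total_steps=epochs * steps_per_epoch)
    rng = np.random.default_rng(seed)

    best = {"val_loss": np.inf, "epoch": -1, "weights": None}
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for s in range(steps_per_epoch):
            idx = order[s * batch_size : (s + 1) * batch_size]
            pred = model.forward(Tensor(train_curves[idx]))
            diff = pred - Tensor(train_labels[idx])
            loss = ad.tsum(diff * diff) * (1.0 / diff.size)
            grads = ad.grad(loss, params)
            opt.step(grads)
            sched.step()
            ep_loss += loss.item() * len(idx)
        history["train_loss"].append(ep_loss / n)
        val_pred = model.forward(Tensor(val_curves)).data
        val_loss = float(np.mean((val_pred - val_labels) ** 2))
        history["val_loss"].append(val_loss)
        if val_loss < best["val_loss"]:
            best = {
                "val_loss": val_loss,
                "epoch": epoch,
                "weights": [p.data.copy() for p in params],
            }
    for p, w in zip(params, best["weights"]):
        p.data = w
    history["best_epoch"] = best["epoch"]
    history["best_val_loss"] = best["val_loss"]
    return model, history
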