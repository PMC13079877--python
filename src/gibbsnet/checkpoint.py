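"""Model archives: JSON checkpoints for gE models, ensembles, surrogates.

A checkpoint is a single JSON document holding every layer's parameters,
the learnable Lipschitz constants, the input scalers, the embedding
dimension, and a format-version tag.  Loaders reject unknown versions.
"""

from __future__ import annotations

import json

import numpy as np

from .embeddings import ScalerParams
from .model import EnsembleModel, GibbsEModel
from .surrogate import SurrogateModel

FORMAT_VERSION = 1


def _layer_payload(layer, lipschitz: bool) -> dict:
    out = {"weight": layer.weight.data.tolist(), "bias": layer.bias.data.tolist()}
    if lipschitz:
        out["c_star"] = float(layer.c_star.data)
    return out


def _restore_layer(layer, payload: dict, lipschitz: bool):
    layer.weight.data = np.asarray(payload["weight"], dtype=np.float64)
    layer.bias.data = np.asarray(payload["bias"], dtype=np.float64)
    if lipschitz:
        layer.c_star.data = np.asarray(payload["c_star"], dtype=np.float64)
        U, _, Vt = np.linalg.svd(layer.weight.data)
        layer._pi_state = (U[:, 0].copy(), Vt[0, :].copy())


def save_ensemble(path, models: list[GibbsEModel] | EnsembleModel, mode: str = "lngamma"):
    if isinstance(models, EnsembleModel):
        mode = models.mode
        models = models.members
    first = models[0]
    payload = {
        "format_version": FORMAT_VERSION,
        "kind": "gibbsnet-ensemble",
        "width": first.width,
        "D": first.D,
        "beta_rbf": first.beta_rbf,
        "ensemble_mode": mode,
        "scalers": {
            "t_mean": first.scalers.t_mean,
            "t_std": first.scalers.t_std,
            "emb_mean": first.scalers.emb_mean.tolist(),
            "emb_std": first.scalers.emb_std.tolist(),
        },
        "members": [
            [_layer_payload(layer, True) for layer in m.lipschitz_layers()]
            for m in models
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_ensemble(path) -> EnsembleModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported checkpoint format version {payload.get('format_version')!r}"
        )
    if payload.get("kind") != "gibbsnet-ensemble":
        raise ValueError(f"not a model checkpoint: kind={payload.get('kind')!r}")
    sc = payload["scalers"]
    scalers = ScalerParams(
        t_mean=sc["t_mean"], t_std=sc["t_std"],
        emb_mean=np.asarray(sc["emb_mean"]), emb_std=np.asarray(sc["emb_std"]),
    )
    members = []
    for layers in payload["members"]:
        m = GibbsEModel(scalers, width=payload["width"], beta_rbf=payload["beta_rbf"])
        for layer, lp in zip(m.lipschitz_layers(), layers):
            _restore_layer(layer, lp, True)
        members.append(m.eval())
    return EnsembleModel(members, mode=payload.get("ensemble_mode", "lngamma"))


def save_surrogate(path, model: SurrogateModel):
    payload = {
        "format_version": FORMAT_VERSION,
        "kind": "gibbsnet-surrogate",
        "n_nodes": model.n_nodes,
        "layers": [_layer_payload(layer, False) for layer in model.layers],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_surrogate(path) -> SurrogateModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported checkpoint format version {payload.get('format_version')!r}"
        )
    if payload.get("kind") != "gibbsnet-surrogate":
        raise ValueError(f"not a surrogate checkpoint: kind={payload.get('kind')!r}")
    model = SurrogateModel(n_nodes=payload["n_nodes"])
    for layer, lp in zip(model.layers, payload["layers"]):
        _restore_layer(layer, lp, False)
    return model
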