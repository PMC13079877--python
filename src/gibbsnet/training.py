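"""Losses, data splitting, and the training loop for the neural gE model.

Five data losses (smooth-L1 with per-type transition points) cover the
record types: activity coefficients from TPXY records, total pressures
from TPX, infinite-dilution activity coefficients, surrogate-predicted LLE
phase compositions (masked by the spinodal condition), and excess
enthalpies.  Two structural terms complete the objective: a Gibbs
stability loss that penalizes the *absence* of negative Gibbs-energy
curvature at states where demixing was observed, and the product of the
learnable per-layer Lipschitz constants.  The total loss is the weighted
sum divided by the batch size.

Data splitting is system-wise (all records of a system stay in one set)
and stratified by the combination of record types a system carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from . import autodiff as ad
from .autodiff import Tensor
from .embeddings import ComponentRecord, fit_scalers
from .model import (
    GAS_CONSTANT,
    GibbsEModel,
    binary_gibbs_graph,
    binary_ln_gamma_graph,
)
from .optim import AdamW, OneCycleLR
from .surrogate import CURVE_NODES, SurrogateModel

SMOOTH_L1_BETA = {"TPXY": 1.0, "TPX": 1.0, "ACI": 2.0, "LLE": 0.35, "HE": 2.0}


def smooth_l1(pred, target, beta: float):
    """Elementwise smooth-L1: 0.5 d^2/beta for |d| < beta, else |d| - beta/2."""
    if beta <= 0:
        raise ValueError("smooth-L1 transition point beta must be positive")
    d = ad.astensor(pred) - ad.astensor(target)
    a = ad.absolute(d)
    return ad.where(a.data < beta, d * d * (0.5 / beta), a - 0.5 * beta)


@dataclass
class LossWeights:
    """Nonnegative weights of the total loss; w_lips = 0 switches to L2."""

    w_tpx: float = 1.0
    w_lle: float = 5.0
    w_he: float = 0.1
    w_gibbs: float = 0.1
    w_lips: float = 1e-6
    l2: float = 1e-6  # fallback when w_lips == 0

    def validate(self):
        for name in ("w_tpx", "w_lle", "w_he", "w_gibbs", "w_lips"):
            if getattr(self, name) < 0:
                raise ValueError(f"loss weight {name} must be nonnegative")


# -- batch assembly -----------------------------------------------------------

@dataclass
class TrainingBatch:
    """Per-type stacked arrays with precomputed targets."""

    tpxy: dict | None = None
    tpx: dict | None = None
    aci: dict | None = None
    lle: dict | None = None
    he: dict | None = None
    n_records: int = 0

    def groups(self):
        return {
            "TPXY": self.tpxy, "TPX": self.tpx, "ACI": self.aci,
            "LLE": self.lle, "HE": self.he,
        }


def prepare_batch(records, comp_map: dict, antoine_map: dict) -> TrainingBatch:
    """Stack records into per-type arrays and derive training targets.

    TPXY targets are ln(gamma) from extended Raoult's law applied to the
    record's (p, y, x) with Antoine vapor pressures; TPX targets are
    ln(p/bar); HE targets are converted to kJ/mol.
    """
    by_type: dict[str, list] = {}
    for r in records:
        by_type.setdefault(r.type, []).append(r)
    out = TrainingBatch(n_records=len(list(records)))

    def emb(recs):
        e1 = np.stack([comp_map[r.component_ids[0]].embedding for r in recs])
        e2 = np.stack([comp_map[r.component_ids[1]].embedding for r in recs])
        return e1, e2

    if "TPXY" in by_type:
        recs = by_type["TPXY"]
        e1, e2 = emb(recs)
        T = np.array([r.T for r in recs])
        x1 = np.array([r.x[0] for r in recs])
        ps1 = np.array([float(antoine_map[r.system_id][0].p_sat(r.T)) for r in recs])
        ps2 = np.array([float(antoine_map[r.system_id][1].p_sat(r.T)) for r in recs])
        p = np.array([r.p for r in recs])
        y1 = np.array([r.y[0] for r in recs])
        out.tpxy = dict(
            e1=e1, e2=e2, x1=x1, T=T,
            lg1=np.log(p * y1 / (ps1 * x1)),
            lg2=np.log(p * (1 - y1) / (ps2 * (1 - x1))),
        )
    if "TPX" in by_type:
        recs = by_type["TPX"]
        e1, e2 = emb(recs)
        out.tpx = dict(
            e1=e1, e2=e2,
            x1=np.array([r.x[0] for r in recs]),
            T=np.array([r.T for r in recs]),
            ln_p=np.log([r.p for r in recs]),
            ps1=np.array([float(antoine_map[r.system_id][0].p_sat(r.T)) for r in recs]),
            ps2=np.array([float(antoine_map[r.system_id][1].p_sat(r.T)) for r in recs]),
        )
    if "ACI" in by_type:
        recs = by_type["ACI"]
        e1, e2 = emb(recs)
        solute = np.array([r.solute_index for r in recs])
        out.aci = dict(
            e1=e1, e2=e2,
            x1=np.where(solute == 0, 0.0, 1.0),
            T=np.array([r.T for r in recs]),
            solute=solute,
            target=np.array([r.ln_gamma_inf for r in recs]),
        )
    if "LLE" in by_type:
        recs = by_type["LLE"]
        e1, e2 = emb(recs)
        xp = np.array([np.nan if r.x1_prime is None else r.x1_prime for r in recs])
        xq = np.array(
            [np.nan if r.x1_doubleprime is None else r.x1_doubleprime for r in recs]
        )
        out.lle = dict(
            e1=e1, e2=e2,
            T=np.array([r.T for r in recs]),
            xp=xp, xq=xq,
            phase_mask=np.stack([~np.isnan(xp), ~np.isnan(xq)], axis=1).astype(float),
        )
    if "HE" in by_type:
        recs = by_type["HE"]
        e1, e2 = emb(recs)
        out.he = dict(
            e1=e1, e2=e2,
            x1=np.array([r.x[0] for r in recs]),
            T=np.array([r.T for r in recs]),
            target_kJ=np.array([r.hE for r in recs]) / 1000.0,
        )
    return out


_FIELD = {"TPXY": "tpxy", "TPX": "tpx", "ACI": "aci", "LLE": "lle", "HE": "he"}


class PreparedDataset:
    """Whole-dataset arrays prepared once; batches are index slices."""

    def __init__(self, records, comp_map: dict, antoine_map: dict):
        self.records = list(records)
        self.full = prepare_batch(self.records, comp_map, antoine_map)
        counters: dict[str, int] = {}
        self.index = []
        for r in self.records:
            pos = counters.get(r.type, 0)
            counters[r.type] = pos + 1
            self.index.append((r.type, pos))

    def __len__(self):
        return len(self.records)

    def batch(self, idx) -> TrainingBatch:
        sel: dict[str, list] = {}
        for i in idx:
            k, pos = self.index[i]
            sel.setdefault(k, []).append(pos)
        out = TrainingBatch(n_records=len(idx))
        for k, positions in sel.items():
            src = getattr(self.full, _FIELD[k])
            pos = np.asarray(positions)
            setattr(out, _FIELD[k], {key: v[pos] for key, v in src.items()})
        return out


# -- loss terms ---------------------------------------------------------------

_GRID = np.linspace(0.0, 1.0, CURVE_NODES)
_IDEAL = xlogy(_GRID, _GRID) + xlogy(1 - _GRID, 1 - _GRID)
_IDEAL_CURV = 1.0 / _GRID[1:-1] + 1.0 / (1.0 - _GRID[1:-1])


def lle_curves_and_stability(model, e1, e2, T):
    """Delta g_mix/(RT) curves (B, 101) and interior curvature S (B, 99).

    Both come from one flattened evaluation of the model over the grid;
    the ideal-mixing part and its curvature are analytic constants.
    """
    B = len(T)
    x_flat = np.tile(_GRID, B)
    e1_flat = np.repeat(e1, CURVE_NODES, axis=0)
    e2_flat = np.repeat(e2, CURVE_NODES, axis=0)
    T_flat = np.repeat(np.asarray(T), CURVE_NODES)
    g, x_leaf, _ = binary_gibbs_graph(model, e1_flat, e2_flat, x_flat, T_flat)
    (d1,) = ad.grad(ad.tsum(g), [x_leaf])
    (d2,) = ad.grad(ad.tsum(d1), [x_leaf])
    curve = ad.reshape(g, (B, CURVE_NODES)) + Tensor(np.tile(_IDEAL, (B, 1)))
    s_interior = ad.reshape(d2, (B, CURVE_NODES))[:, 1:-1] + Tensor(
        np.tile(_IDEAL_CURV, (B, 1))
    )
    return curve, s_interior


def _lle_terms(model, surrogate: SurrogateModel, lle: dict):
    """Shared computation of L_LLE (masked) and L_Gibbs for one batch."""
    curve, s = lle_curves_and_stability(model, lle["e1"], lle["e2"], lle["T"])
    s_min = ad.tmin(s, axis=1)
    mask = (s_min.data < 0).astype(float)  # Eq.-of-stability gate, recomputed each pass

    # Gibbs loss: penalize missing curvature where demixing was observed
    gibbs = ad.tsum(ad.maximum(s_min, Tensor(0.0)))

    # LLE data loss through the frozen surrogate, masked records only
    pred = surrogate.forward(curve)
    targets = np.stack(
        [np.nan_to_num(lle["xp"]), np.nan_to_num(lle["xq"])], axis=1
    )
    pm = lle["phase_mask"]
    err = smooth_l1(pred, Tensor(targets), SMOOTH_L1_BETA["LLE"])
    per_rec = ad.tsum(err * Tensor(pm), axis=1) * Tensor(1.0 / np.maximum(pm.sum(1), 1.0))
    l_lle = ad.tsum(per_rec * Tensor(mask))
    return l_lle, gibbs, mask


def data_losses(model, surrogate: SurrogateModel, batch: TrainingBatch):
    """The five data losses as tensors (sums over the batch's records)."""
    zero = Tensor(0.0)
    L = {"TPXY": zero, "TPX": zero, "ACI": zero, "LLE": zero, "HE": zero}

    if batch.tpxy is not None:
        b = batch.tpxy
        ln1, ln2, _, _ = binary_ln_gamma_graph(model, b["e1"], b["e2"], b["x1"], b["T"])
        beta = SMOOTH_L1_BETA["TPXY"]
        per_rec = (smooth_l1(ln1, b["lg1"], beta) + smooth_l1(ln2, b["lg2"], beta)) * 0.5
        L["TPXY"] = ad.tsum(per_rec)

    if batch.tpx is not None:
        b = batch.tpx
        ln1, ln2, _, _ = binary_ln_gamma_graph(model, b["e1"], b["e2"], b["x1"], b["T"])
        p_pred = Tensor(b["ps1"] * b["x1"]) * ad.exp(ln1) + Tensor(
            b["ps2"] * (1 - b["x1"])
        ) * ad.exp(ln2)
        L["TPX"] = ad.tsum(smooth_l1(ad.log(p_pred), b["ln_p"], SMOOTH_L1_BETA["TPX"]))

    if batch.aci is not None:
        b = batch.aci
        ln1, ln2, _, _ = binary_ln_gamma_graph(model, b["e1"], b["e2"], b["x1"], b["T"])
        ln_inf = ad.where(b["solute"] == 0, ln1, ln2)
        L["ACI"] = 0.5 * ad.tsum(smooth_l1(ln_inf, b["target"], SMOOTH_L1_BETA["ACI"]))

    if batch.lle is not None:
        l_lle, _, _ = _lle_terms(model, surrogate, batch.lle)
        L["LLE"] = l_lle

    if batch.he is not None:
        b = batch.he
        g, _, tstar = binary_gibbs_graph(model, b["e1"], b["e2"], b["x1"], b["T"])
        (dg_dt,) = ad.grad(ad.tsum(g), [tstar])
        hE_kJ = (
            Tensor(-GAS_CONSTANT * b["T"] ** 2 / model.scalers.t_std / 1000.0) * dg_dt
        )
        L["HE"] = ad.tsum(smooth_l1(hE_kJ, b["target_kJ"], SMOOTH_L1_BETA["HE"]))

    return L


def gibbs_loss(model, surrogate: SurrogateModel, lle: dict):
    """L_Gibbs = sum_k max(0, min_d S_k) over a batch of LLE records."""
    _, gibbs, _ = _lle_terms(model, surrogate, lle)
    return gibbs


def lipschitz_loss(model: GibbsEModel):
    """Product of softplus(c*) over all layers of the three networks."""
    out = Tensor(1.0)
    for layer in model.lipschitz_layers():
        out = out * layer.lipschitz_constant()
    return out


def total_loss(losses: dict, weights: LossWeights, n_batch: int, model=None):
    """Weighted sum of all loss terms divided by the batch size.

    ``losses`` maps TPXY/TPX/ACI/LLE/HE/Gibbs (tensors); the Lipschitz term
    (or its L2 fallback when w_lips = 0) is computed from ``model``.
    """
    weights.validate()
    if n_batch <= 0:
        raise ValueError("batch size must be positive")
    total = (
        losses["TPXY"]
        + weights.w_tpx * losses["TPX"]
        + losses["ACI"]
        + weights.w_lle * losses["LLE"]
        + weights.w_he * losses["HE"]
        + weights.w_gibbs * losses.get("Gibbs", Tensor(0.0))
    )
    if model is not None:
        if weights.w_lips > 0:
            total = total + weights.w_lips * lipschitz_loss(model)
        elif weights.l2 > 0:
            reg = Tensor(0.0)
            for p in model.parameters():
                reg = reg + ad.tsum(p * p)
            total = total + weights.l2 * reg
    return total * (1.0 / n_batch)


# -- system-wise splitting ----------------------------------------------------

def split_systems(records, mode: str, seed: int, n_folds: int = 10):
    """System-wise stratified split.

    ``tenfold``: systems are partitioned into ``n_folds`` test folds,
    stratified by the set of record types each system carries; per fold the
    remaining systems are split 90/10 into train/validation.  ``full``:
    95/5 train/validation, no test.  A system's records never straddle
    sets.  Returns a list of dicts of system-key sets (one dict for
    ``full``).
    """
    systems: dict[frozenset, set] = {}
    for r in records:
        systems.setdefault(r.system_key, set()).add(r.type)
    keys = sorted(systems, key=lambda k: "|".join(sorted(k)))
    rng = np.random.default_rng(seed)

    if mode == "full":
        order = list(rng.permutation(len(keys)))
        n_val = max(1, int(round(0.05 * len(keys))))
        val = {keys[i] for i in order[:n_val]}
        return [{"train": set(keys) - val, "val": val, "test": set()}]

    if mode != "tenfold":
        raise ValueError(f"unknown split mode {mode!r}")
    if len(keys) < n_folds:
        raise ValueError(f"need at least {n_folds} systems for {n_folds}-fold splitting")

    strata: dict[tuple, list] = {}
    for k in keys:
        strata.setdefault(tuple(sorted(systems[k])), []).append(k)
    fold_sets: list[set] = [set() for _ in range(n_folds)]
    start = 0
    for stratum in sorted(strata):
        members = strata[stratum]
        members = [members[i] for i in rng.permutation(len(members))]
        for i, k in enumerate(members):
            fold_sets[(start + i) % n_folds].add(k)
        start += len(members)

    folds = []
    for f in range(n_folds):
        test = fold_sets[f]
        rest = [k for k in keys if k not in test]
        rest = [rest[i] for i in rng.permutation(len(rest))]
        n_val = max(1, int(round(0.1 * len(rest))))
        val = set(rest[:n_val])
        folds.append({"train": set(rest[n_val:]), "val": val, "test": test})
    return folds


def filter_records(records, system_keys) -> list:
    return [r for r in records if r.system_key in system_keys]


# -- training loop ------------------------------------------------------------

@dataclass
class TrainConfig:
    width: int = 32
    epochs: int = 100
    batch_size: int = 128
    max_lr: float = 0.01
    min_epoch: int = 50
    n_ensemble: int = 1
    seed: int = 0
    weight_decay: float = 1e-4
    beta_rbf: float = 100.0
    weights: LossWeights = field(default_factory=LossWeights)


def weighted_validation_loss(model, surrogate, batch: TrainingBatch, weights: LossWeights):
    """Weighted sum of the five data losses per record (model selection metric)."""
    losses = data_losses(model, surrogate, batch)
    total = (
        losses["TPXY"].item()
        + weights.w_tpx * losses["TPX"].item()
        + losses["ACI"].item()
        + weights.w_lle * losses["LLE"].item()
        + weights.w_he * losses["HE"].item()
    )
    return total / max(batch.n_records, 1)


def train_hanna(
    train_records,
    val_records,
    components: list[ComponentRecord],
    antoine_map: dict,
    surrogate: SurrogateModel,
    config: TrainConfig,
):
    """Train an ensemble of gE models; returns (models, histories).

    Scalers are fitted on the training records only.  Per epoch, records
    are shuffled and chunked into mixed-type batches; the epoch-best model
    (weighted validation data loss, epochs >= ``min_epoch``) is restored at
    the end.  The surrogate's weights are frozen throughout.
    """
    if not val_records:
        raise ValueError("validation set is empty")
    comp_map = {c.component_id: c for c in components}
    scalers = fit_scalers(train_records, comp_map)
    val_batch = prepare_batch(val_records, comp_map, antoine_map)
    prepared = PreparedDataset(train_records, comp_map, antoine_map)

    models, histories = [], []
    for member in range(config.n_ensemble):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, member]))
        model = GibbsEModel(
            scalers,
            width=config.width,
            beta_rbf=config.beta_rbf,
            seed=int(rng.integers(2**31)),
        )
        params = model.parameters()
        n = len(train_records)
        steps = max(1, int(np.ceil(n / config.batch_size)))
        opt = AdamW(params, lr=config.max_lr, weight_decay=config.weight_decay)
        sched = OneCycleLR(opt, max_lr=config.max_lr, total_steps=config.epochs * steps)

        loss_keys = ("TPXY", "TPX", "ACI", "LLE", "HE", "Gibbs")
        history = {
            "train_loss": [], "val_loss": [], "lr": [],
            **{f"train_{k}": [] for k in loss_keys},
        }
        best = {"val": np.inf, "epoch": -1, "weights": None}
        model.eval()
        history["val_loss_initial"] = weighted_validation_loss(
            model, surrogate, val_batch, config.weights
        )
        for epoch in range(config.epochs):
            model.train()
            order = rng.permutation(n)
            ep_loss = 0.0
            ep_terms = dict.fromkeys(loss_keys, 0.0)
            for s in range(steps):
                idx = order[s * config.batch_size : (s + 1) * config.batch_size]
                batch = prepared.batch(idx)
                losses = data_losses(model, surrogate, batch)
                if batch.lle is not None:
                    _, gibbs, _ = _lle_terms(model, surrogate, batch.lle)
                    losses["Gibbs"] = gibbs
                loss = total_loss(losses, config.weights, len(idx), model=model)
                grads = ad.grad(loss, params)
                opt.step(grads)
                history["lr"].append(sched.step())
                ep_loss += loss.item() * len(idx)
                for k in loss_keys:
                    if k in losses:
                        ep_terms[k] += losses[k].item()
            model.eval()
            val = weighted_validation_loss(model, surrogate, val_batch, config.weights)
            history["train_loss"].append(ep_loss / n)
            for k in loss_keys:
                history[f"train_{k}"].append(ep_terms[k] / n)
            history["val_loss"].append(val)
            if epoch + 1 >= config.min_epoch and val < best["val"]:
                best = {
                    "val": val,
                    "epoch": epoch,
                    "weights": [p.data.copy() for p in params],
                }
        if best["weights"] is not None:
            for p, w in zip(params, best["weights"]):
                p.data = w
        history["best_epoch"] = best["epoch"]
        history["best_val_loss"] = best["val"]
        models.append(model.eval())
        histories.append(history)
    return models, histories
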