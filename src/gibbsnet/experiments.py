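"""Scaled-down end-to-end studies on synthetic data.

These drive the whole pipeline — synthetic systems with embedding-linked
ground truth, curation, system-wise splitting, surrogate pre-training, gE
model training — at desk scale: 60 binary systems (40% with a miscibility
gap), model width 32, 16-dimensional embeddings, 100 epochs at batch size
128.  The study answers a parameter-recovery question: can the model
recover the ground-truth activity-coefficient surfaces from noisy
synthetic measurements well enough to (a) predict ln(gamma) at held-out
state points of the training systems and (b) detect the miscibility gaps
of the demixing systems?
"""

from __future__ import annotations

import numpy as np

from .gemodels import Margules, NRTL, NeuralBinaryProvider
from .model import binary_ln_gamma_graph
from .phase_equilibria import cem_binary, equal_activity_split, gmix_curve, stability_values
from .surrogate import CURVE_NODES, train_surrogate, make_surrogate_labels
from .synthetic_data import curate, generate_dataset, sample_systems
from .training import TrainConfig, filter_records, split_systems, train_hanna
from .evaluation import detection_rate


def _demixing_provider_pool(n: int, seed: int):
    """Seeded Margules/NRTL models that all show a miscibility gap at 300 K."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        if rng.random() < 0.5:
            provider = Margules(a=float(rng.uniform(2.05, 4.0)))
        else:
            t = float(rng.uniform(1.6, 2.6))
            provider = NRTL(
                a12=t + float(rng.uniform(-0.2, 0.2)),
                a21=t + float(rng.uniform(-0.2, 0.2)),
                alpha=0.3,
            )
        if cem_binary(gmix_curve(provider, 300.0)):
            out.append(provider)
    return out


def surrogate_benchmark(seed: int, n_curves: int = 2000, epochs: int = 200) -> dict:
    """Train the surrogate on CEM-labeled classical curves; report accuracy.

    Curves come from seeded Margules (A uniform on [2.05, 4]) and NRTL
    draws that demix; labels are the convex-envelope phase compositions.
    90/10 train/validation split (each curve is its own system).  Returns
    validation mean absolute error in mole fraction and the training
    history.
    """
    providers = _demixing_provider_pool(n_curves, seed)
    curves, labels = [], []
    for p in providers:
        curve = gmix_curve(p, 300.0, n_grid=CURVE_NODES)
        splits = cem_binary(curve)
        if not splits:
            continue
        curves.append(curve.values)
        labels.append([splits[0].x1_prime, splits[0].x1_doubleprime])
    curves = np.asarray(curves)
    labels = np.asarray(labels)
    n_val = max(1, len(curves) // 10)
    model, hist = train_surrogate(
        curves[:-n_val], labels[:-n_val], curves[-n_val:], labels[-n_val:],
        epochs=epochs, seed=seed,
    )
    val_mae = float(np.mean(np.abs(model.forward(curves[-n_val:]).data - labels[-n_val:])))
    return {"model": model, "val_mae_x": val_mae, "history": hist, "n_curves": len(curves)}


def cem_oracle_benchmark(seed: int, n_demixing: int = 50, n_miscible: int = 50) -> dict:
    """Convex-envelope splits against the iterative equal-activity solver."""
    rng = np.random.default_rng(seed)
    providers = _demixing_provider_pool(n_demixing, seed)
    max_dev = 0.0
    for p in providers:
        splits = cem_binary(gmix_curve(p, 300.0))
        oracle = equal_activity_split(p, 300.0)
        assert splits and oracle is not None
        max_dev = max(
            max_dev,
            abs(splits[0].x1_prime - oracle.x1_prime),
            abs(splits[0].x1_doubleprime - oracle.x1_doubleprime),
        )
    false_gaps = 0
    for _ in range(n_miscible):
        if rng.random() < 0.5:
            p = Margules(a=float(rng.uniform(0.0, 1.8)))
        else:
            p = NRTL(
                a12=float(rng.uniform(0.0, 1.0)),
                a21=float(rng.uniform(0.0, 1.0)),
                alpha=0.3,
            )
        if cem_binary(gmix_curve(p, 300.0)):
            false_gaps += 1
    return {"max_endpoint_dev": max_dev, "false_gaps": false_gaps}


def recovery_experiment(
    seed: int,
    n_systems: int = 60,
    miscibility_mix: float = 0.4,
    width: int = 32,
    epochs: int = 100,
    batch_size: int = 128,
    surrogate_epochs: int = 200,
    n_holdout_points: int = 8,
) -> dict:
    """The scaled-down parameter-recovery study; see the module docstring.

    Returns held-out MAE(ln gamma) on the training systems, the LLE
    detection rate at the demixing systems' recorded state points, the
    relative drop of the weighted validation data loss, and the surrogate's
    validation accuracy.
    """
    seed = int(seed) % (2**31)
    systems, components, _ = sample_systems(n_systems, seed, miscibility_mix)
    records = curate(generate_dataset(systems, seed=seed))
    (split,) = split_systems(records, "full", seed=seed)
    train = filter_records(records, split["train"])
    val = filter_records(records, split["val"])
    antoine_map = {s.system_id: s.antoine for s in systems}
    sys_by_id = {s.system_id: s for s in systems}
    comp_map = {c.component_id: c for c in components}

    # surrogate pre-training on ground-truth curves of the LLE training records
    lle_train = [r for r in train if r.type == "LLE"]
    lle_val = [r for r in val if r.type == "LLE"]
    provider_of = lambda r: sys_by_id[r.system_id].provider()  # noqa: E731
    tr_c, tr_l = make_surrogate_labels(provider_of, lle_train)
    va_c, va_l = make_surrogate_labels(provider_of, lle_val)
    if len(va_c) == 0:
        tr_c, va_c = tr_c[:-20], tr_c[-20:]
        tr_l, va_l = tr_l[:-20], tr_l[-20:]
    surrogate, s_hist = train_surrogate(
        tr_c, tr_l, va_c, va_l, epochs=surrogate_epochs, seed=seed
    )
    surrogate_val_mae = float(np.mean(np.abs(surrogate.forward(va_c).data - va_l)))

    # burn-in covers the one-cycle warm-up and peak: epochs become eligible
    # for selection only once the learning rate is annealing
    config = TrainConfig(
        width=width, epochs=epochs, batch_size=batch_size,
        min_epoch=max(1, epochs // 2), seed=seed,
    )
    models, histories = train_hanna(train, val, components, antoine_map, surrogate, config)
    model = models[0]
    hist = histories[0]
    # drop of the selection metric relative to the untrained model
    val_drop = 1.0 - hist["best_val_loss"] / hist["val_loss_initial"]

    # held-out state points of the training systems, noise-free targets
    rng = np.random.default_rng(seed + 1)
    train_sys = sorted({r.system_id for r in train})
    errs = []
    for sid in train_sys:
        s = sys_by_id[sid]
        provider = s.provider()
        T = rng.uniform(273.0, 428.0, n_holdout_points)
        x = rng.uniform(0.02, 0.98, n_holdout_points)
        e1 = np.tile(comp_map[s.component_ids[0]].embedding, (n_holdout_points, 1))
        e2 = np.tile(comp_map[s.component_ids[1]].embedding, (n_holdout_points, 1))
        ln1, ln2, _, _ = binary_ln_gamma_graph(model, e1, e2, x, T)
        for k in range(n_holdout_points):
            lg1, lg2 = provider.ln_gamma(np.array([x[k]]), float(T[k]))
            errs.append(abs(ln1.data[k] - lg1[0]))
            errs.append(abs(ln2.data[k] - lg2[0]))
    mae_ln_gamma = float(np.mean(errs))

    # miscibility-gap detection at the recorded LLE state points
    lle_all = [r for r in records if r.type == "LLE"]
    grid = np.linspace(0.0, 1.0, CURVE_NODES)
    gaps = []
    for r in lle_all:
        provider = NeuralBinaryProvider(
            model, comp_map[r.component_ids[0]], comp_map[r.component_ids[1]]
        )
        gaps.append(bool(np.min(stability_values(provider, r.T, grid)) < 0))
    rate = detection_rate(lle_all, gaps)

    return {
        "models": models,
        "history": hist,
        "mae_ln_gamma": mae_ln_gamma,
        "detection_rate": rate,
        "n_lle_records": len(lle_all),
        "val_loss_initial": hist["val_loss_initial"],
        "val_loss_first": hist["val_loss"][0],
        "val_loss_best": hist["best_val_loss"],
        "val_drop": val_drop,
        "surrogate_val_mae_x": surrogate_val_mae,
        "n_train_records": len(train),
        "n_holdout_points": 2 * n_holdout_points * len(train_sys),
    }
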