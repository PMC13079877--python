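"""Per-record error metrics, system-wise aggregation, and LLE detection.

Errors are absolute deviations on the scale each data type is modeled on:
mean |ln gamma| deviation over components for TPXY, |ln p| for TPX,
|ln gamma_inf| for ACI, mean phase-composition deviation for LLE, and
|hE| in kJ/mol for HE.  System-wise mean absolute errors (MAE_sys) average
over all records of a system so that heavily measured systems do not
dominate summary statistics.

LLE records where the model predicts no miscibility gap cannot produce a
composition error; they enter the detection tally instead (a system counts
as detected if gaps are predicted at the majority of its recorded state
points).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gemodels import BinaryGEProvider, NeuralBinaryProvider


def record_error(record, prediction, antoine=None) -> float:
    """Absolute deviation of one prediction from one record.

    ``prediction`` per type: TPXY -> ln_gamma array; TPX -> p (bar);
    ACI -> ln_gamma_inf; LLE -> (x1_prime, x1_doubleprime); HE -> hE in
    J/mol.  LLE errors average over both components and the reported
    phases.  TPXY needs the system's Antoine coefficient pair to convert
    the record's (p, x, y) into experimental ln gamma via Raoult's law.
    """
    t = record.type
    if t == "TPXY":
        if antoine is None:
            raise ValueError("TPXY errors need the system's Antoine coefficients")
        pred = np.asarray(prediction, dtype=np.float64)
        ps = np.array([float(a.p_sat(record.T)) for a in antoine])
        target = np.log(record.p * np.asarray(record.y) / (ps * np.asarray(record.x)))
        return float(np.mean(np.abs(pred - target)))
    if t == "TPX":
        return float(abs(np.log(float(prediction)) - np.log(record.p)))
    if t == "ACI":
        return float(abs(float(prediction) - record.ln_gamma_inf))
    if t == "LLE":
        xp_pred, xq_pred = prediction
        n = len(record.component_ids)
        terms = []
        if record.x1_prime is not None:
            # |dx| is identical for both components of a binary (x2 = 1 - x1)
            terms.extend([abs(xp_pred - record.x1_prime)] * n)
        if record.x1_doubleprime is not None:
            terms.extend([abs(xq_pred - record.x1_doubleprime)] * n)
        if not terms:
            raise ValueError("LLE record reports no phase composition")
        return float(np.mean(terms))
    if t == "HE":
        return float(abs(float(prediction) - record.hE) / 1000.0)
    raise ValueError(f"unknown record type {t!r}")


def mae_sys(errors: list[tuple]) -> pd.DataFrame:
    """System-wise MAE table from (system_id, type, error) triples.

    Returns one row per (system, type); overall per-type mean/median across
    systems are computed from this table.
    """
    df = pd.DataFrame(errors, columns=["system_id", "type", "error"])
    if df.empty:
        return pd.DataFrame(columns=["system_id", "type", "mae"])
    out = (
        df.groupby(["system_id", "type"])["error"]
        .mean()
        .reset_index()
        .rename(columns={"error": "mae"})
    )
    return out


def summarize_mae(table: pd.DataFrame) -> dict:
    """Per-type mean and median of MAE_sys (systems weighted equally)."""
    summary = {}
    for t, grp in table.groupby("type"):
        summary[t] = {
            "mean": float(grp["mae"].mean()),
            "median": float(grp["mae"].median()),
            "n_systems": int(len(grp)),
        }
    return summary


def detection_rate(lle_records, gap_predicted: list[bool]) -> float:
    """Fraction of LLE systems whose miscibility gap the model finds.

    ``gap_predicted[k]`` says whether a gap was predicted at record k's
    state point.  Each record votes; a system is detected when the
    majority of its records' state points show a predicted gap.
    """
    lle_records = list(lle_records)
    if len(lle_records) != len(gap_predicted):
        raise ValueError("records and predictions differ in length")
    if not lle_records:
        return 0.0
    votes: dict[str, list[bool]] = {}
    for rec, hit in zip(lle_records, gap_predicted):
        votes.setdefault(rec.system_id, []).append(bool(hit))
    detected = sum(1 for v in votes.values() if sum(v) * 2 >= len(v))
    return detected / len(votes)


class MeanBinaryProvider(BinaryGEProvider):
    """Ensemble-mean gE/(RT) surface of a binary system."""

    def __init__(self, models, comp_i, comp_j):
        self.providers = [NeuralBinaryProvider(m, comp_i, comp_j) for m in models]

    def gE_RT(self, x1, T):
        out = self.providers[0].gE_RT(x1, T)
        for p in self.providers[1:]:
            out = out + p.gE_RT(x1, T)
        return out * (1.0 / len(self.providers))


def score_records(models, records, components, antoine_map):
    """Predict every record with an ensemble and score it.

    Returns ``(errors, lle_records, gap_predicted)``: errors are
    (system_id, type, epsilon) triples ready for :func:`mae_sys`; LLE
    records with no predicted gap are excluded from the error pool and
    tallied through ``gap_predicted`` for :func:`detection_rate`.
    """
    from . import autodiff as ad
    from .model import GAS_CONSTANT, binary_gibbs_graph, binary_ln_gamma_graph
    from .phase_equilibria import cem_binary, gmix_curve
    from .training import prepare_batch

    comp_map = components if isinstance(components, dict) else {
        c.component_id: c for c in components
    }
    records = list(records)
    by_type: dict[str, list] = {}
    for r in records:
        by_type.setdefault(r.type, []).append(r)
    errors: list[tuple] = []

    def mean_ln_gamma(b):
        acc1 = acc2 = None
        for m in models:
            ln1, ln2, _, _ = binary_ln_gamma_graph(m, b["e1"], b["e2"], b["x1"], b["T"])
            acc1 = ln1.data if acc1 is None else acc1 + ln1.data
            acc2 = ln2.data if acc2 is None else acc2 + ln2.data
        return acc1 / len(models), acc2 / len(models)

    for t in ("TPXY", "TPX", "ACI"):
        if t not in by_type:
            continue
        recs = by_type[t]
        batch = prepare_batch(recs, comp_map, antoine_map)
        b = getattr(batch, t.lower())
        ln1, ln2 = mean_ln_gamma(b)
        if t == "TPXY":
            eps = 0.5 * (np.abs(ln1 - b["lg1"]) + np.abs(ln2 - b["lg2"]))
        elif t == "TPX":
            p_pred = b["ps1"] * b["x1"] * np.exp(ln1) + b["ps2"] * (1 - b["x1"]) * np.exp(ln2)
            eps = np.abs(np.log(p_pred) - b["ln_p"])
        else:
            ln_inf = np.where(b["solute"] == 0, ln1, ln2)
            eps = np.abs(ln_inf - b["target"])
        errors.extend((r.system_id, t, float(e)) for r, e in zip(recs, eps))

    if "HE" in by_type:
        recs = by_type["HE"]
        batch = prepare_batch(recs, comp_map, antoine_map)
        b = batch.he
        acc = None
        for m in models:
            g, _, tstar = binary_gibbs_graph(m, b["e1"], b["e2"], b["x1"], b["T"])
            (dg_dt,) = ad.grad(ad.tsum(g), [tstar])
            h = -GAS_CONSTANT * b["T"] ** 2 / m.scalers.t_std * dg_dt.data
            acc = h if acc is None else acc + h
        eps = np.abs(acc / len(models) / 1000.0 - b["target_kJ"])
        errors.extend((r.system_id, "HE", float(e)) for r, e in zip(recs, eps))

    lle_records = by_type.get("LLE", [])
    gap_predicted: list[bool] = []
    for r in lle_records:
        provider = MeanBinaryProvider(
            models, comp_map[r.component_ids[0]], comp_map[r.component_ids[1]]
        )
        splits = cem_binary(gmix_curve(provider, r.T))
        gap_predicted.append(bool(splits))
        if splits:
            sp = splits[0]
            errors.append(
                (
                    r.system_id,
                    "LLE",
                    record_error(r, (sp.x1_prime, sp.x1_doubleprime)),
                )
            )
    return errors, lle_records, gap_predicted
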