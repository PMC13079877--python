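"""Synthetic thermodynamic datasets with known classical ground truth.

Experimental mixture databases are proprietary, so training and evaluation
here run on synthetic data generated from classical gE models (two-suffix
Margules and NRTL with a + b/T temperature dependence) plus Antoine vapor
pressures.  Five record types are emitted, mirroring the structure of
typical phase-equilibrium collections:

TPXY  vapor-liquid equilibrium with vapor composition (T, p, x, y),
TPX   vapor-liquid equilibrium without vapor composition (T, p, x),
ACI   activity coefficient at infinite dilution (solute, solvent, ln g_inf),
LLE   liquid-liquid phase compositions (T, x1', x1''; possibly one phase),
HE    molar excess enthalpy (T, x1, hE).

A deliberate design choice makes the learning task solvable: every
ground-truth quantity of a system — the model family and its parameters —
is a *deterministic function of the component embeddings* through fixed
random linear readouts (affine parameter maps with rarely-active range
clipping; a thresholded readout for the family).  A model that reads the
embeddings can therefore generalize across systems, emulating the premise
that mixture behavior is predictable from molecular structure.  Fictitious
components are small random chain molecules; their embeddings come from
the deterministic hash-based backend.

Curation mirrors standard practice: vapor-liquid records above 10 bar and
liquid-liquid records above 50 bar are excluded, and mixed-solvent
infinite-dilution data are kept only when their pure-solvent endpoints
agree with binary references (within +-5 K) to 0.1 in ln gamma_inf.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .embeddings import ComponentRecord, embed_component
from .gemodels import AntoineCoefficients, BinaryGEProvider, Margules, NRTL
from .phase_equilibria import equal_activity_split

T_RANGE = (273.0, 428.0)  # 95% of sampled temperatures fall here
T_TAIL = 15.0
P_MAX_VLE = 10.0  # bar
P_MAX_LLE = 50.0  # bar
ACI_T_WINDOW = 5.0  # K
ACI_DEV_MAX = 0.1


@dataclass
class NoiseParams:
    """Additive/multiplicative noise magnitudes for synthetic records."""

    sigma_ln_gamma: float = 0.02
    sigma_x_lle: float = 0.005
    sigma_hE: float = 10.0  # J/mol
    sigma_ln_p: float = 0.01
    sigma_y: float = 0.005

    @classmethod
    def zero(cls):
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class DataRecord:
    """One observation of any of the five record types."""

    type: str
    system_id: str
    component_ids: tuple
    T: float
    p: float | None = None
    x: tuple | None = None
    y: tuple | None = None
    x1_prime: float | None = None
    x1_doubleprime: float | None = None
    phase_flags: str = ""
    ln_gamma_inf: float | None = None
    solute_index: int | None = None
    hE: float | None = None

    def __post_init__(self):
        if self.type not in ("TPXY", "TPX", "ACI", "LLE", "HE"):
            raise ValueError(f"unknown record type {self.type!r}")

    @property
    def system_key(self) -> frozenset:
        return frozenset(self.component_ids)


@dataclass
class GroundTruthSystem:
    """A fictitious binary system with closed-form gE ground truth."""

    system_id: str
    component_ids: tuple
    model: str
    params: dict
    antoine: tuple

    def provider(self) -> BinaryGEProvider:
        if self.model == "margules":
            return Margules(**self.params)
        if self.model == "nrtl":
            return NRTL(**self.params)
        raise ValueError(f"unknown ground-truth model {self.model!r}")

    def demixes(self, T_lo: float = T_RANGE[0], T_hi: float = T_RANGE[1]) -> bool:
        return demixing_temperatures(self.provider(), T_lo, T_hi).size > 0


def demixing_temperatures(
    provider: BinaryGEProvider, T_lo: float, T_hi: float, n_T: int = 12
) -> np.ndarray:
    """Temperatures on a scan grid at which the system has a spinodal region."""
    from .phase_equilibria import stability_values

    temps = np.linspace(T_lo, T_hi, n_T)
    grid = np.linspace(0.0, 1.0, 101)
    out = []
    for T in temps:
        if np.min(stability_values(provider, float(T), grid)) < 0:
            out.append(T)
    return np.asarray(out)


# -- fictitious components and the embedding -> parameter link ----------------

_CHAIN_ATOMS = "CCCONS"


def _random_smiles(rng: np.random.Generator) -> str:
    length = int(rng.integers(2, 9))
    return "".join(_CHAIN_ATOMS[i] for i in rng.integers(0, len(_CHAIN_ATOMS), length))


def sample_components(n: int, seed: int, dim: int = 16) -> list[ComponentRecord]:
    """Deterministic pool of fictitious chain molecules with embeddings."""
    rng = np.random.default_rng(seed)
    seen, comps = set(), []
    while len(comps) < n:
        try:
            rec = embed_component(
                _random_smiles(rng), backend="synthetic", dim=dim, seed=0
            )
        except ValueError:
            continue
        if rec.smiles in seen:
            continue
        seen.add(rec.smiles)
        comps.append(
            ComponentRecord(
                component_id=f"M{len(comps):03d}",
                smiles=rec.smiles,
                embedding=rec.embedding,
            )
        )
    return comps


class ParameterMap:
    """Fixed random linear maps from embeddings to model parameters.

    Pair parameters use the symmetric feature e_i + e_j, so they are
    invariant under component order; Antoine coefficients use the single
    component's embedding.
    """

    def __init__(self, dim: int, seed: int):
        rng = np.random.default_rng(seed)
        s = 1.0 / np.sqrt(2.0 * dim)
        self.w_margules = rng.normal(scale=s, size=(2, dim))
        self.w_nrtl = rng.normal(scale=s, size=(4, dim))
        self.w_family = rng.normal(scale=s, size=dim)
        self.w_antoine = rng.normal(scale=1.0 / np.sqrt(dim), size=(3, dim))
        self.dim = dim

    def family(self, e_i, e_j, nrtl_fraction: float = 0.5) -> str:
        """Deterministic model-family readout from the pair embedding.

        The family must be a function of the embeddings (like every other
        ground-truth parameter), otherwise the generation process would not
        be learnable from molecular structure.  The linear readout is
        approximately standard normal, so thresholding at its
        (1 - fraction) quantile yields the requested NRTL share.
        """
        from scipy.stats import norm

        u = float(self.w_family @ (np.asarray(e_i) + np.asarray(e_j)))
        if nrtl_fraction <= 0.0:
            return "margules"
        if nrtl_fraction >= 1.0:
            return "nrtl"
        return "nrtl" if u > norm.ppf(1.0 - nrtl_fraction) else "margules"

    def margules_params(self, e_i, e_j) -> dict:
        # affine in the pair feature (std-normal readouts), clipped to the
        # physical range only in the ~5% tails so the map stays essentially
        # linear and hence learnable from a few dozen systems
        f = self.w_margules @ (np.asarray(e_i) + np.asarray(e_j))
        return {
            "a": float(np.clip(0.5 + 0.45 * f[0], -0.4, 1.4)),
            "b": float(np.clip(275.0 + 137.0 * f[1], 0.0, 550.0)),
        }

    def nrtl_params(self, e_i, e_j) -> dict:
        f = self.w_nrtl @ (np.asarray(e_i) + np.asarray(e_j))
        return {
            "a12": float(np.clip(0.3 + 0.25 * f[0], -0.2, 0.8)),
            "a21": float(np.clip(0.3 + 0.25 * f[1], -0.2, 0.8)),
            "b12": float(np.clip(150.0 + 75.0 * f[2], 0.0, 300.0)),
            "b21": float(np.clip(150.0 + 75.0 * f[3], 0.0, 300.0)),
            "alpha": 0.3,
        }

    def antoine(self, e) -> AntoineCoefficients:
        w = np.tanh(self.w_antoine @ np.asarray(e))
        return AntoineCoefficients(
            A=4.05 + 0.25 * w[0],
            B=1250.0 + 150.0 * w[1],
            C=-45.0 + 10.0 * w[2],
            T_min=250.0,
            T_max=450.0,
        )


def sample_systems(
    n_systems: int,
    seed: int,
    miscibility_mix: float = 0.4,
    components: list[ComponentRecord] | None = None,
    nrtl_fraction: float = 0.5,
    max_attempts: int = 200000,
) -> tuple[list[GroundTruthSystem], list[ComponentRecord], ParameterMap]:
    """Draw binary systems with the requested fraction of demixing systems.

    Parameters are pure functions of the embeddings (via the returned
    ParameterMap); the demixing fraction is controlled by *selecting
    component pairs*, never by perturbing the map.
    """
    if n_systems < 1:
        raise ValueError("need at least one system")
    rng = np.random.default_rng(seed)
    auto_pool = components is None
    if auto_pool:
        components = sample_components(max(12, int(1.5 * np.sqrt(2 * n_systems)) + 4), seed)
    else:
        components = list(components)
    pmap = ParameterMap(components[0].embedding.shape[0], seed)

    n_demix = int(round(miscibility_mix * n_systems))
    systems: list[GroundTruthSystem] = []
    tried: set = set()
    attempts = 0
    have_demix = have_misc = 0
    while len(systems) < n_systems and attempts < max_attempts:
        attempts += 1
        n_pairs = len(components) * (len(components) - 1) // 2
        if len(tried) >= n_pairs:
            # pool exhausted before filling the quota: extend it with the
            # deterministic continuation of the same component sequence
            if not auto_pool or len(components) >= 200:
                break
            components = sample_components(len(components) + 8, seed)
        i, j = rng.choice(len(components), size=2, replace=False)
        i, j = sorted((int(i), int(j)))
        ci, cj = components[i], components[j]
        key = (ci.component_id, cj.component_id)
        if key in tried:
            continue
        tried.add(key)
        model = pmap.family(ci.embedding, cj.embedding, nrtl_fraction)
        if model == "margules":
            params = pmap.margules_params(ci.embedding, cj.embedding)
        else:
            params = pmap.nrtl_params(ci.embedding, cj.embedding)
        sys = GroundTruthSystem(
            system_id=f"S{len(systems):03d}",
            component_ids=key,
            model=model,
            params=params,
            antoine=(pmap.antoine(ci.embedding), pmap.antoine(cj.embedding)),
        )
        demix = sys.demixes()
        if demix and have_demix < n_demix:
            have_demix += 1
        elif not demix and have_misc < n_systems - n_demix:
            have_misc += 1
        else:
            continue
        systems.append(sys)
    if len(systems) < n_systems:
        raise RuntimeError(
            f"could not assemble {n_systems} systems with demixing fraction "
            f"{miscibility_mix} from the component pool"
        )
    comp_by_id = {c.component_id: c for c in components}
    systems = [
        GroundTruthSystem(f"S{k:03d}", s.component_ids, s.model, s.params, s.antoine)
        for k, s in enumerate(systems)
    ]
    return systems, [comp_by_id[c] for c in sorted({c for s in systems for c in s.component_ids})], pmap


# -- record generation --------------------------------------------------------

def _sample_T(rng: np.random.Generator) -> float:
    if rng.random() < 0.95:
        return float(rng.uniform(*T_RANGE))
    if rng.random() < 0.5:
        return float(rng.uniform(T_RANGE[0] - T_TAIL, T_RANGE[0]))
    return float(rng.uniform(T_RANGE[1], T_RANGE[1] + T_TAIL))


DEFAULT_COUNTS = {"TPXY": 24, "TPX": 12, "ACI": 6, "LLE": 10, "HE": 12}


def generate_records(
    system: GroundTruthSystem,
    counts: dict | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
    one_phase_fraction: float = 0.75,
) -> list[DataRecord]:
    """Synthetic records of all five types for one binary system.

    Vapor-liquid records are assembled with extended Raoult's law from the
    closed-form activity coefficients and Antoine pressures; LLE endpoints
    come from the iterative equal-activity solver; infinite-dilution and
    excess-enthalpy values are closed-form.  With zero noise every record
    is exactly consistent with the ground truth.
    """
    counts = dict(DEFAULT_COUNTS if counts is None else counts)
    noise = NoiseParams() if noise is None else noise
    rng = np.random.default_rng(seed)
    provider = system.provider()
    ant1, ant2 = system.antoine
    records: list[DataRecord] = []
    base = dict(system_id=system.system_id, component_ids=system.component_ids)

    for _ in range(counts.get("TPXY", 0)):
        T = _sample_T(rng)
        x1 = float(rng.uniform(0.02, 0.98))
        lg1, lg2 = provider.ln_gamma(np.array([x1]), T)
        p1 = float(ant1.p_sat(T)) * x1 * np.exp(lg1[0])
        p2 = float(ant2.p_sat(T)) * (1 - x1) * np.exp(lg2[0])
        p = (p1 + p2) * float(np.exp(rng.normal(0.0, noise.sigma_ln_p)))
        y1 = float(np.clip(p1 / (p1 + p2) + rng.normal(0.0, noise.sigma_y), 1e-6, 1 - 1e-6))
        records.append(
            DataRecord(type="TPXY", T=T, p=float(p), x=(x1, 1 - x1), y=(y1, 1 - y1), **base)
        )

    for _ in range(counts.get("TPX", 0)):
        T = _sample_T(rng)
        x1 = float(rng.uniform(0.02, 0.98))
        lg1, lg2 = provider.ln_gamma(np.array([x1]), T)
        p = float(ant1.p_sat(T)) * x1 * np.exp(lg1[0]) + float(ant2.p_sat(T)) * (
            1 - x1
        ) * np.exp(lg2[0])
        p *= float(np.exp(rng.normal(0.0, noise.sigma_ln_p)))
        records.append(DataRecord(type="TPX", T=T, p=float(p), x=(x1, 1 - x1), **base))

    for _ in range(counts.get("ACI", 0)):
        T = _sample_T(rng)
        solute = int(rng.integers(0, 2))
        lg1, lg2 = provider.ln_gamma(np.array([0.0 if solute == 0 else 1.0]), T)
        lg_inf = float(lg1[0] if solute == 0 else lg2[0])
        lg_inf += float(rng.normal(0.0, noise.sigma_ln_gamma))
        x = (0.0, 1.0) if solute == 0 else (1.0, 0.0)
        records.append(
            DataRecord(
                type="ACI", T=T, x=x, ln_gamma_inf=lg_inf, solute_index=solute, **base
            )
        )

    n_lle = counts.get("LLE", 0)
    if n_lle:
        demix_T = demixing_temperatures(provider, T_RANGE[0], T_RANGE[1], n_T=16)
        if demix_T.size == 0:
            pass  # fully miscible over the range: no LLE records
        else:
            lo, hi = float(demix_T.min()), float(demix_T.max())
            made = 0
            tries = 0
            while made < n_lle and tries < 8 * n_lle:
                tries += 1
                T = float(rng.uniform(lo, hi))
                split = equal_activity_split(provider, T)
                if split is None:
                    continue
                xp = split.x1_prime + float(rng.normal(0.0, noise.sigma_x_lle))
                xq = split.x1_doubleprime + float(rng.normal(0.0, noise.sigma_x_lle))
                xp, xq = float(np.clip(xp, 0.0, 1.0)), float(np.clip(xq, 0.0, 1.0))
                if xp > xq:
                    xp, xq = xq, xp
                flags = "both"
                if rng.random() < one_phase_fraction:
                    flags = "prime" if rng.random() < 0.5 else "doubleprime"
                records.append(
                    DataRecord(
                        type="LLE",
                        T=T,
                        p=1.0,
                        x1_prime=xp if flags in ("both", "prime") else None,
                        x1_doubleprime=xq if flags in ("both", "doubleprime") else None,
                        phase_flags=flags,
                        **base,
                    )
                )
                made += 1

    for _ in range(counts.get("HE", 0)):
        T = _sample_T(rng)
        x1 = float(rng.uniform(0.02, 0.98))
        hE = float(provider.h_excess(np.array([x1]), T)[0] + rng.normal(0.0, noise.sigma_hE))
        records.append(DataRecord(type="HE", T=T, x=(x1, 1 - x1), hE=hE, **base))

    return records


def generate_dataset(
    systems: list[GroundTruthSystem],
    counts: dict | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> list[DataRecord]:
    """Records for all systems, with per-system derived seeds."""
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(systems))
    records = []
    for sys_, cs in zip(systems, child):
        records.extend(
            generate_records(sys_, counts=counts, noise=noise, seed=int(cs.generate_state(1)[0] % (2**31)))
        )
    return records


# -- curation -----------------------------------------------------------------

def curate(records: list[DataRecord]) -> list[DataRecord]:
    """Apply the standard filters; idempotent.

    Drops TPXY/TPX records above 10 bar and LLE records above 50 bar.
    Ternary infinite-dilution data are validated at their pure-solvent
    endpoints against binary references within +-5 K; systems with no
    reference or an absolute ln gamma_inf deviation above 0.1 are dropped
    entirely, and only mixed-solvent points of retained systems are kept.
    """
    kept: list[DataRecord] = []
    binary_aci = [r for r in records if r.type == "ACI" and len(r.component_ids) == 2]

    def binary_reference(solute_id: str, solvent_id: str, T: float):
        vals = [
            r.ln_gamma_inf
            for r in binary_aci
            if abs(r.T - T) <= ACI_T_WINDOW
            and r.component_ids[r.solute_index] == solute_id
            and set(r.component_ids) == {solute_id, solvent_id}
        ]
        return None if not vals else float(np.mean(vals))

    ternary_aci = [r for r in records if r.type == "ACI" and len(r.component_ids) == 3]
    bad_systems = set()
    checked_systems = set()
    for rec in ternary_aci:
        solvent_ids = [
            cid for k, cid in enumerate(rec.component_ids) if k != rec.solute_index
        ]
        solvent_x = [rec.x[k] for k, _ in enumerate(rec.component_ids) if k != rec.solute_index]
        if min(solvent_x) > 0:
            continue  # mixed-solvent point: judged via its system's endpoints
        checked_systems.add(rec.system_key)
        active = solvent_ids[int(np.argmax(solvent_x))]
        ref = binary_reference(rec.component_ids[rec.solute_index], active, rec.T)
        if ref is None or abs(rec.ln_gamma_inf - ref) > ACI_DEV_MAX:
            bad_systems.add(rec.system_key)
    # systems whose endpoints were never checkable lack references entirely
    for rec in ternary_aci:
        if rec.system_key not in checked_systems:
            bad_systems.add(rec.system_key)

    for rec in records:
        if rec.type in ("TPXY", "TPX") and rec.p is not None and rec.p > P_MAX_VLE:
            continue
        if rec.type == "LLE" and rec.p is not None and rec.p > P_MAX_LLE:
            continue
        if rec.type == "ACI" and len(rec.component_ids) == 3:
            if rec.system_key in bad_systems:
                continue
            solvent_x = [
                rec.x[k] for k, _ in enumerate(rec.component_ids) if k != rec.solute_index
            ]
            if min(solvent_x) <= 0:
                continue  # endpoint rows are used for checking only
        kept.append(rec)
    return kept


# -- file I/O -----------------------------------------------------------------

RECORD_COLUMNS = [
    "type", "system_id", "component_ids", "T_K", "p_bar",
    "x1", "x2", "x3", "y1", "y2",
    "x1p", "x1pp", "phase_flags", "ln_gamma_inf", "solute_idx", "hE_J_mol",
]


def records_to_frame(records: list[DataRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        x = list(r.x) + [None] * (3 - len(r.x)) if r.x is not None else [None] * 3
        y = list(r.y) + [None] * (2 - len(r.y)) if r.y is not None else [None] * 2
        rows.append(
            dict(
                type=r.type,
                system_id=r.system_id,
                component_ids="|".join(r.component_ids),
                T_K=r.T,
                p_bar=r.p,
                x1=x[0], x2=x[1], x3=x[2], y1=y[0], y2=y[1],
                x1p=r.x1_prime, x1pp=r.x1_doubleprime,
                phase_flags=r.phase_flags,
                ln_gamma_inf=r.ln_gamma_inf,
                solute_idx=r.solute_index,
                hE_J_mol=r.hE,
            )
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[DataRecord]:
    def opt(v):
        return None if pd.isna(v) else float(v)

    records = []
    for row in df.itertuples(index=False):
        ids = tuple(row.component_ids.split("|"))
        xs = [opt(row.x1), opt(row.x2), opt(row.x3)][: len(ids)]
        x = tuple(xs) if all(v is not None for v in xs) else None
        y = (
            (float(row.y1), float(row.y2))
            if not (pd.isna(row.y1) or pd.isna(row.y2))
            else None
        )
        records.append(
            DataRecord(
                type=row.type,
                system_id=row.system_id,
                component_ids=ids,
                T=float(row.T_K),
                p=opt(row.p_bar),
                x=x,
                y=y,
                x1_prime=opt(row.x1p),
                x1_doubleprime=opt(row.x1pp),
                phase_flags="" if pd.isna(row.phase_flags) else str(row.phase_flags),
                ln_gamma_inf=opt(row.ln_gamma_inf),
                solute_index=None if pd.isna(row.solute_idx) else int(row.solute_idx),
                hE=opt(row.hE_J_mol),
            )
        )
    return records


def write_records_csv(records: list[DataRecord], path):
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path) -> list[DataRecord]:
    return frame_to_records(pd.read_csv(path))


def write_components_csv(components: list[ComponentRecord], path):
    dim = components[0].embedding.shape[0]
    df = pd.DataFrame(
        [
            {
                "component_id": c.component_id,
                "smiles": c.smiles,
                "name": c.name or "",
                **{f"emb_{k}": c.embedding[k] for k in range(dim)},
            }
            for c in components
        ]
    )
    df.to_csv(path, index=False)


def read_components_csv(path) -> list[ComponentRecord]:
    df = pd.read_csv(path)
    emb_cols = sorted(
        [c for c in df.columns if c.startswith("emb_")], key=lambda s: int(s[4:])
    )
    comps = []
    for row in df.itertuples(index=False):
        if emb_cols:
            emb = np.array([getattr(row, c) for c in emb_cols])
        else:
            emb = embed_component(row.smiles, backend="synthetic").embedding
        name = getattr(row, "name", "")
        comps.append(
            ComponentRecord(
                component_id=str(row.component_id),
                smiles=str(row.smiles),
                embedding=emb,
                name=None if pd.isna(name) or name == "" else str(name),
            )
        )
    return comps


def write_systems_json(systems: list[GroundTruthSystem], path):
    payload = [
        {
            "system_id": s.system_id,
            "component_ids": list(s.component_ids),
            "model": s.model,
            "params": s.params,
            "antoine": [asdict(a) for a in s.antoine],
        }
        for s in systems
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_systems_json(path) -> list[GroundTruthSystem]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        GroundTruthSystem(
            system_id=d["system_id"],
            component_ids=tuple(d["component_ids"]),
            model=d["model"],
            params=d["params"],
            antoine=tuple(AntoineCoefficients(**a) for a in d["antoine"]),
        )
        for d in payload
    ]
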