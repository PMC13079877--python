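"""Per-component molecular embeddings and input standardization.

Components enter the gE model as fixed numerical embedding vectors computed
from their SMILES.  Two backends are provided:

``synthetic``
    The default.  SMILES are canonicalized with RDKit, the SHA-256 digest of
    the canonical string seeds a generator, and the embedding is a standard
    normal draw of dimension ``D`` (default 16).  This is fully
    deterministic and needs no downloads: identical molecules map to
    bitwise-identical vectors in every process.

``chemberta``
    A transformer-based embedding (hidden size 384).  It requires the
    optional ``transformers`` dependency and a model download, so it is not
    available in a hermetic installation; requesting it without the
    dependency raises an actionable error pointing at the synthetic
    backend.  If available, the embedding is the mean-pooled final hidden
    state over tokens (mean pooling rather than the CLS token; this choice
    is fixed here and documented).

Temperature and embeddings are standard-scaled with statistics fitted on
the training split only.  The temperature scale ``s_T`` is retained because
the excess-enthalpy chain rule needs it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

SYNTHETIC_DIM = 16
CHEMBERTA_DIM = 384
STD_FLOOR = 1e-8


class SmilesParseError(ValueError):
    pass


def canonical_smiles(smiles: str) -> str:
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES string: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass
class ComponentRecord:
    """Identity and embedding vector of one pure substance."""

    component_id: str
    smiles: str | None
    embedding: np.ndarray
    name: str | None = None

    def __post_init__(self):
        self.embedding = np.asarray(self.embedding, dtype=np.float64)
        if not np.all(np.isfinite(self.embedding)):
            raise ValueError(f"non-finite embedding for {self.component_id}")


def synthetic_embedding(canonical: str, dim: int = SYNTHETIC_DIM, seed: int = 0) -> np.ndarray:
    digest = hashlib.sha256(f"{seed}:{canonical}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    return rng.standard_normal(dim)


def embed_component(
    smiles: str,
    backend: str = "synthetic",
    component_id: str | None = None,
    dim: int | None = None,
    seed: int = 0,
) -> ComponentRecord:
    """Canonicalize ``smiles`` and compute its embedding."""
    canonical = canonical_smiles(smiles)
    if backend == "synthetic":
        d = SYNTHETIC_DIM if dim is None else dim
        emb = synthetic_embedding(canonical, dim=d, seed=seed)
    elif backend == "chemberta":
        try:
            import transformers  # noqa: F401
        except ImportError as err:
            raise RuntimeError(
                "the 'chemberta' embedding backend requires the optional "
                "'transformers' dependency (and a model download); use "
                "backend='synthetic' for a hermetic, deterministic embedding"
            ) from err
        emb = _chemberta_embedding(canonical)
    else:
        raise ValueError(f"unknown embedding backend: {backend!r}")
    return ComponentRecord(
        component_id=component_id or canonical, smiles=canonical, embedding=emb
    )


def _chemberta_embedding(canonical: str) -> np.ndarray:  # pragma: no cover
    import torch  # type: ignore
    from transformers import AutoModel, AutoTokenizer  # type: ignore

    name = "DeepChem/ChemBERTa-77M-MTR"
    tok = AutoTokenizer.from_pretrained(name)
    model = AutoModel.from_pretrained(name)
    with torch.no_grad():
        out = model(**tok(canonical, return_tensors="pt"))
    # mean pooling over tokens of the final hidden state
    return out.last_hidden_state.mean(dim=1).squeeze(0).numpy().astype(np.float64)


@dataclass
class ScalerParams:
    """Standard-scaling statistics for temperature and embeddings."""

    t_mean: float
    t_std: float
    emb_mean: np.ndarray
    emb_std: np.ndarray

    def __post_init__(self):
        self.emb_mean = np.asarray(self.emb_mean, dtype=np.float64)
        self.emb_std = np.maximum(np.asarray(self.emb_std, dtype=np.float64), STD_FLOOR)
        self.t_std = max(float(self.t_std), STD_FLOOR)

    def scale_temperature(self, T):
        return (T - self.t_mean) / self.t_std

    def unscale_temperature(self, t_star):
        return t_star * self.t_std + self.t_mean

    def scale_embedding(self, emb: np.ndarray) -> np.ndarray:
        return (np.asarray(emb) - self.emb_mean) / self.emb_std

    def unscale_embedding(self, e_star: np.ndarray) -> np.ndarray:
        return np.asarray(e_star) * self.emb_std + self.emb_mean

    @property
    def dim(self) -> int:
        return self.emb_mean.shape[0]


def fit_scalers(training_records, components: dict | list) -> ScalerParams:
    """Fit temperature/embedding scalers on the training split.

    Temperature statistics are taken over the training records; embedding
    statistics over the distinct components that appear in them (sample
    standard deviation, ddof=1, floored at 1e-8).
    """
    records = list(training_records)
    if not records:
        raise ValueError("cannot fit scalers on an empty training set")
    if isinstance(components, list):
        components = {c.component_id: c for c in components}

    temps = np.array([r.T for r in records], dtype=np.float64)
    ids = sorted({cid for r in records for cid in r.component_ids})
    embs = np.stack([components[cid].embedding for cid in ids])

    t_std = float(np.std(temps, ddof=1)) if temps.size > 1 else 0.0
    emb_std = (
        np.std(embs, axis=0, ddof=1) if embs.shape[0] > 1 else np.zeros(embs.shape[1])
    )
    return ScalerParams(
        t_mean=float(np.mean(temps)),
        t_std=t_std,
        emb_mean=np.mean(embs, axis=0),
        emb_std=emb_std,
    )
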