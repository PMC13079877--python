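"""The neural excess-Gibbs-energy model and its forward pass.

The model predicts gE/(RT) of an N-component liquid mixture from
per-component embedding vectors, temperature, and composition, and obtains
activity coefficients by *differentiating* that prediction with respect to
the N-1 independent mole fractions.  Because ln(gamma) is derived from a
single scalar generating function, Gibbs-Duhem consistency and the pure
component limits hold by construction, for any parameter values.

Forward pass:

1. scale T and the embeddings e_i with the training-set scalers,
2. reconstruct x_N = 1 - sum(x_1..x_{N-1}),
3. refine embeddings: theta_i = EmbeddingNetwork(e_i*),
4. pair similarity R_ij = exp(-beta ||theta_i - theta_j||^2), beta = 100,
5. lump identical components: x~_i = sum_j x_j R_ij,
6. for every pair i<j: project to the binary subsystem
   (X_i = (1 + x~_i - x~_j)/2), build feature vectors [theta, X, T*],
   alpha = MixtureNetwork(c), phi_ij = PropertyNetwork(alpha_i + alpha_j),
   q_ij = phi_ij (1 - R_ij),
7. gE/(RT) = sum_{i<j} x_i x_j q_ij,
8/9. ln gamma_i = g + dg/dx_i - sum_j x_j dg/dx_j (and the analogous
   expression without the dg/dx_i term for component N).

The deep-set aggregation in step 6 (sum of the two mixture-network outputs)
makes q_ij exactly symmetric, and R_ij = 1 forces q_ij = 0, so duplicated
components reduce exactly to the corresponding smaller mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .embeddings import ComponentRecord, ScalerParams
from .nn import LipschitzLinear, mlp_forward

GAS_CONSTANT = 8.31446  # J/(mol K)
DEFAULT_WIDTH = 96
DEFAULT_BETA_RBF = 100.0


@dataclass
class MixtureState:
    """Components, mole fractions, and temperature of one evaluation point."""

    components: list[ComponentRecord]
    x: np.ndarray
    T: float

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        n = len(self.components)
        if n < 2:
            raise ValueError("a mixture needs at least two components")
        if self.x.shape != (n,):
            raise ValueError(f"expected {n} mole fractions, got shape {self.x.shape}")
        if np.any(self.x < -1e-12) or np.any(self.x > 1 + 1e-12):
            raise ValueError("mole fractions must lie in [0, 1]")
        if abs(self.x.sum() - 1.0) > 1e-9:
            raise ValueError(f"mole fractions must sum to 1, got {self.x.sum()}")
        if not self.T > 0:
            raise ValueError("temperature must be positive (Kelvin)")

    @property
    def n(self) -> int:
        return len(self.components)


@dataclass
class GammaResult:
    """Activity coefficients and the generating gE/(RT) at one state."""

    ln_gamma: np.ndarray
    gE_over_RT: float
    diagnostics: dict = field(default_factory=dict)


class GibbsEModel:
    """Three Lipschitz-constrained networks plus input scalers.

    EmbeddingNetwork: one layer D -> width (SiLU); MixtureNetwork: two
    layers width+2 -> width -> width (SiLU); PropertyNetwork: width -> width
    (SiLU) -> 1 (linear).  The reference configuration uses width 96 (so the
    mixture-network input has 98 nodes); a narrower width is available for
    scaled-down studies.
    """

    def __init__(
        self,
        scalers: ScalerParams,
        width: int = DEFAULT_WIDTH,
        beta_rbf: float = DEFAULT_BETA_RBF,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        D = scalers.dim
        self.width = width
        self.D = D
        self.beta_rbf = float(beta_rbf)
        self.scalers = scalers
        self.embedding_net = LipschitzLinear(D, width, rng)
        self.mixture_net = [
            LipschitzLinear(width + 2, width, rng),
            LipschitzLinear(width, width, rng),
        ]
        self.property_net = [
            LipschitzLinear(width, width, rng),
            LipschitzLinear(width, 1, rng),
        ]

    # -- building blocks ----------------------------------------------------
    def refine(self, e_star: Tensor) -> Tensor:
        """EmbeddingNetwork: refined embeddings theta (rows)."""
        return ad.silu(self.embedding_net(e_star))

    def pair_phi(self, theta_i, theta_j, Xi, Xj, tstar) -> Tensor:
        """Deep-set pair interaction phi_ij (rows of theta; Xi, Xj scalars or columns).

        The two feature vectors run through the mixture network as one
        stacked batch, so both see bitwise-identical effective weights and
        phi_ij is exactly symmetric under i <-> j.
        """
        ci = ad.concat([theta_i, _as_col(Xi), _broadcast_col(tstar, theta_i)], axis=1)
        cj = ad.concat([theta_j, _as_col(Xj), _broadcast_col(tstar, theta_j)], axis=1)
        b = ci.shape[0]
        a = self._mixture_hidden(ad.concat([ci, cj], axis=0))
        phi = mlp_forward(self.property_net, a[:b, :] + a[b:, :], activation=ad.silu)
        return phi

    def _mixture_hidden(self, c: Tensor) -> Tensor:
        h = ad.silu(self.mixture_net[0](c))
        return ad.silu(self.mixture_net[1](h))

    def lipschitz_layers(self) -> list[LipschitzLinear]:
        return [self.embedding_net, *self.mixture_net, *self.property_net]

    def train(self):
        """Enable power-iteration updates (training mode)."""
        for layer in self.lipschitz_layers():
            layer.train_mode = True
        return self

    def eval(self):
        """Freeze power-iteration state for deterministic inference."""
        for layer in self.lipschitz_layers():
            layer.train_mode = False
        return self

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.lipschitz_layers() for p in layer.parameters()]


def _as_col(x) -> Tensor:
    x = ad.astensor(x)
    if x.ndim == 0:
        return ad.reshape(x, (1, 1))
    if x.ndim == 1:
        return ad.reshape(x, (x.shape[0], 1))
    return x


def _broadcast_col(t, like: Tensor) -> Tensor:
    t = _as_col(t)
    if t.shape[0] != like.shape[0]:
        t = ad.broadcast_to(t, (like.shape[0], 1))
    return t


# -- forward-pass operations --------------------------------------------------

def refine_and_similarity(model, components: list[ComponentRecord]):
    """Refined embeddings theta and the pair-similarity matrix R.

    R_ij = exp(-beta ||theta_i - theta_j||^2) with exact ones on the
    diagonal; returned as differentiable tensors.
    """
    E = np.stack([c.embedding for c in components])
    if E.shape[1] != model.scalers.dim:
        raise ValueError(
            f"embedding dimension {E.shape[1]} does not match model input "
            f"dimension {model.scalers.dim}"
        )
    e_star = Tensor(model.scalers.scale_embedding(E))
    theta = model.refine(e_star)
    diff = theta[:, None, :] - theta[None, :, :]
    dist2 = ad.tsum(diff * diff, axis=2)
    R = ad.exp(-model.beta_rbf * dist2)
    return theta, R


def lump_mole_fractions(x: Tensor, R: Tensor) -> Tensor:
    """x~_i = sum_j x_j R_ij (identical components share their amount)."""
    x = ad.astensor(x)
    return ad.tsum(R * ad.reshape(x, (1, x.shape[0])), axis=1)


def muggianu_project(x_tilde: Tensor, i: int, j: int):
    """Symmetric projection onto the i-j binary subsystem; Xi + Xj = 1 exactly."""
    if i == j:
        raise ValueError("projection needs two distinct components")
    # algebraically (1 + xt_i - xt_j)/2, arranged so the binary limit
    # (xt_j = 1 - xt_i) returns xt_i bit-exactly and Xi + Xj = 1 exactly
    Xi = 0.5 + (x_tilde[i] - x_tilde[j]) * 0.5
    Xj = 0.5 + (x_tilde[j] - x_tilde[i]) * 0.5
    return Xi, Xj


def binary_interaction(model, theta_i, theta_j, Xi, Xj, tstar, R_ij) -> Tensor:
    """q_ij = phi_ij (1 - R_ij); exactly symmetric and zero for R_ij = 1."""
    phi = model.pair_phi(theta_i, theta_j, Xi, Xj, tstar)
    return ad.reshape(phi, ()) * (1.0 - R_ij)


def _gibbs_graph(model, components, x: np.ndarray, T: float):
    """Build the gE/(RT) graph with leaf tensors for x_1..x_{N-1} and T*.

    Returns (g, x_free, tstar, diagnostics).
    """
    n = len(components)
    x = np.asarray(x, dtype=np.float64)
    x_free = Tensor(x[: n - 1], requires_grad=True)
    x_n = 1.0 - ad.tsum(x_free)
    x_all = ad.concat([x_free, ad.reshape(x_n, (1,))])
    tstar = Tensor(float(model.scalers.scale_temperature(T)), requires_grad=True)

    theta, R = refine_and_similarity(model, components)
    x_tilde = lump_mole_fractions(x_all, R)

    g = Tensor(0.0)
    diagnostics = {}
    for i in range(n - 1):
        for j in range(i + 1, n):
            Xi, Xj = muggianu_project(x_tilde, i, j)
            q = binary_interaction(
                model,
                theta[i : i + 1, :],
                theta[j : j + 1, :],
                Xi,
                Xj,
                tstar,
                R[i, j],
            )
            g = g + x_all[i] * x_all[j] * q
            diagnostics[(i, j)] = {
                "R": float(R.data[i, j]),
                "Xi": float(Xi.data),
                "Xj": float(Xj.data),
                "q": float(q.data),
                "gE_ij_over_RT": float((x_all[i] * x_all[j] * q).data),
            }
    return g, x_free, tstar, diagnostics


def excess_gibbs(model, state: MixtureState) -> float:
    """gE/(RT) of the mixture (dimensionless)."""
    g, _, _, _ = _gibbs_graph(model, state.components, state.x, state.T)
    return float(g.data)


def activity_coefficients(model, state: MixtureState) -> GammaResult:
    """ln(gamma_i) for all components, Raoult normalization.

    Derived from the exact gradient of the implemented gE/(RT) forward pass
    with respect to the N-1 independent mole fractions; Gibbs-Duhem
    consistent by construction.
    """
    g, x_free, _, diag = _gibbs_graph(model, state.components, state.x, state.T)
    (dg,) = ad.grad(g, [x_free])
    gval = float(g.data)
    dgv = dg.data
    correction = float(np.dot(state.x[: state.n - 1], dgv))
    ln_gamma = np.empty(state.n)
    ln_gamma[: state.n - 1] = gval + dgv - correction
    ln_gamma[state.n - 1] = gval - correction
    return GammaResult(ln_gamma=ln_gamma, gE_over_RT=gval, diagnostics=diag)


def excess_enthalpy(model, state: MixtureState) -> float:
    """Molar excess enthalpy hE in J/mol.

    hE = -R T^2 d(gE/RT)/dT = -(R T^2 / s_T) d(gE/RT)/dT*, the 1/s_T factor
    coming from the chain rule through the temperature scaler.
    """
    g, _, tstar, _ = _gibbs_graph(model, state.components, state.x, state.T)
    (dg_dt,) = ad.grad(g, [tstar])
    return float(-GAS_CONSTANT * state.T**2 / model.scalers.t_std * dg_dt.data)


def ln_gamma_infinite_dilution(
    model, components: list[ComponentRecord], solute_index: int, solvent_x, T: float
) -> float:
    """ln(gamma) of a solute at infinite dilution in the given solvent mix.

    ``solvent_x`` holds the mole fractions of the non-solute components (in
    component order, solute excluded) and must sum to 1.
    """
    n = len(components)
    if not 0 <= solute_index < n:
        raise IndexError(f"solute index {solute_index} out of range for {n} components")
    solvent_x = np.asarray(solvent_x, dtype=np.float64)
    if solvent_x.shape != (n - 1,) or abs(solvent_x.sum() - 1.0) > 1e-9:
        raise ValueError("solvent fractions must cover the non-solute components and sum to 1")
    x = np.empty(n)
    x[solute_index] = 0.0
    x[np.arange(n) != solute_index] = solvent_x
    state = MixtureState(components=components, x=x, T=T)
    return float(activity_coefficients(model, state).ln_gamma[solute_index])


# -- vectorized binary path (training and phase-equilibrium grids) ------------

def binary_gibbs_graph(model, e1: np.ndarray, e2: np.ndarray, x1, T):
    """Batched gE/(RT) for binary mixtures.

    ``e1``, ``e2``: unscaled embeddings, shape (B, D) or (D,); ``x1``: mole
    fractions, shape (B,); ``T``: temperatures, shape (B,) or scalar.
    Returns (g, x1_leaf, tstar_leaf) with g of shape (B,).
    """
    x1 = np.atleast_1d(np.asarray(x1, dtype=np.float64))
    B = x1.shape[0]
    tarr = np.broadcast_to(np.atleast_1d(np.asarray(T, dtype=np.float64)), (B,))
    x1_leaf = Tensor(x1, requires_grad=True)
    tstar = Tensor(model.scalers.scale_temperature(tarr), requires_grad=True)
    g = binary_gibbs_graph_on(model, e1, e2, x1_leaf, None, tstar=tstar)
    return g, x1_leaf, tstar


def binary_gibbs_graph_on(model, e1, e2, x1: Tensor, T, tstar: Tensor | None = None):
    """Batched binary gE/(RT) built directly on the caller's x1 tensor.

    ``T`` may be a scalar/array (converted through the temperature scaler)
    or ``None`` when a pre-scaled ``tstar`` tensor is supplied.
    """
    B = x1.shape[0] if x1.ndim else 1
    xr = ad.reshape(x1, (B,))
    e1 = np.atleast_2d(e1)
    e2 = np.atleast_2d(e2)
    if e1.shape[0] == 1 and B > 1:
        e1 = np.broadcast_to(e1, (B, e1.shape[1]))
        e2 = np.broadcast_to(e2, (B, e2.shape[1]))
    if tstar is None:
        tarr = np.broadcast_to(np.atleast_1d(np.asarray(T, dtype=np.float64)), (B,))
        tstar = Tensor(model.scalers.scale_temperature(tarr))

    th1 = model.refine(Tensor(model.scalers.scale_embedding(e1)))
    th2 = model.refine(Tensor(model.scalers.scale_embedding(e2)))
    diff = th1 - th2
    R = ad.exp(-model.beta_rbf * ad.tsum(diff * diff, axis=1))

    x2 = 1.0 - xr
    xt1 = xr + x2 * R
    xt2 = x2 + xr * R
    X1 = 0.5 + (xt1 - xt2) * 0.5
    X2 = 0.5 + (xt2 - xt1) * 0.5

    phi = model.pair_phi(th1, th2, X1, X2, ad.reshape(tstar, (B, 1)))
    q = ad.reshape(phi, (B,)) * (1.0 - R)
    g = xr * x2 * q
    return ad.reshape(g, x1.shape)


def binary_ln_gamma_graph(model, e1, e2, x1, T):
    """Batched (ln_gamma1, ln_gamma2) tensors for binary mixtures."""
    g, x1_leaf, tstar = binary_gibbs_graph(model, e1, e2, x1, T)
    (dg,) = ad.grad(ad.tsum(g), [x1_leaf])
    ln_g1 = g + (1.0 - x1_leaf) * dg
    ln_g2 = g - x1_leaf * dg
    return ln_g1, ln_g2, g, tstar


class EnsembleModel:
    """Average of independently initialized models.

    Aggregation averages ln(gamma) arithmetically across members (the
    default); averaging gE/(RT) before differentiation is available via
    ``mode='ge'``.
    """

    def __init__(self, members: list[GibbsEModel], mode: str = "lngamma"):
        if not members:
            raise ValueError("empty ensemble")
        if mode not in ("lngamma", "ge"):
            raise ValueError(f"unknown ensemble mode {mode!r}")
        self.members = members
        self.mode = mode

    def activity_coefficients(self, state: MixtureState) -> GammaResult:
        results = [activity_coefficients(m, state) for m in self.members]
        ln_gamma = np.mean([r.ln_gamma for r in results], axis=0)
        ge = float(np.mean([r.gE_over_RT for r in results]))
        return GammaResult(ln_gamma=ln_gamma, gE_over_RT=ge)

    def excess_gibbs(self, state: MixtureState) -> float:
        return float(np.mean([excess_gibbs(m, state) for m in self.members]))

    def excess_enthalpy(self, state: MixtureState) -> float:
        return float(np.mean([excess_enthalpy(m, state) for m in self.members]))
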