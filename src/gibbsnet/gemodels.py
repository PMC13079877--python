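"""Classical binary excess-Gibbs-energy models and vapor pressures.

These serve two roles: as ground truth for synthetic datasets (their
closed-form activity coefficients, excess enthalpies, and phase behavior
are known exactly) and as independent cross-checks for the differentiated
neural model.  All models implement ``gE_RT(x1, T)`` in autodiff-compatible
operations, so the generic machinery (activity coefficients by
differentiation, stability analysis, Gibbs-energy-of-mixing curves) applies
to them exactly as it does to the neural model.

Conventions: temperature in K, pressure in bar, R = 8.31446 J/(mol K).
Temperature dependence is of the classical a + b/T form, which makes the
excess enthalpy nonzero and analytic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

GAS_CONSTANT = 8.31446  # J/(mol K)


class BinaryGEProvider:
    """Base class: a binary gE/(RT) surface over (x1, T).

    Subclasses implement ``gE_RT`` with autodiff ops; activity coefficients
    and excess enthalpy are then available generically by differentiation.
    Closed-form overrides in subclasses provide the independent route for
    cross-checking.
    """

    def gE_RT(self, x1, T):
        raise NotImplementedError

    def gE_RT_np(self, x1, T) -> np.ndarray:
        out = self.gE_RT(ad.astensor(x1), T)
        return out.data if isinstance(out, Tensor) else np.asarray(out)

    def ln_gamma(self, x1, T):
        """(ln gamma_1, ln gamma_2) by exact differentiation of gE/(RT)."""
        x1 = np.atleast_1d(np.asarray(x1, dtype=np.float64))
        leaf = Tensor(x1, requires_grad=True)
        g = self.gE_RT(leaf, T)
        (dg,) = ad.grad(ad.tsum(g), [leaf])
        ln_g1 = g.data + (1.0 - x1) * dg.data
        ln_g2 = g.data - x1 * dg.data
        return ln_g1, ln_g2

    def h_excess(self, x1, T) -> np.ndarray:
        """hE in J/mol by exact temperature differentiation: -R T^2 d(gE/RT)/dT."""
        t_leaf = Tensor(float(T), requires_grad=True)
        g = self.gE_RT(ad.astensor(np.atleast_1d(x1)), t_leaf)
        (dg_dt,) = ad.grad(ad.tsum(g), [t_leaf])
        # dg_dt is the derivative of the *sum*; for a shared scalar T leaf the
        # per-point derivative requires one graph per point, so evaluate pointwise.
        x1 = np.atleast_1d(np.asarray(x1, dtype=np.float64))
        out = np.empty_like(x1)
        for k, xv in enumerate(x1):
            t = Tensor(float(T), requires_grad=True)
            gk = self.gE_RT(ad.astensor(np.array([xv])), t)
            (d,) = ad.grad(ad.tsum(gk), [t])
            out[k] = -GAS_CONSTANT * float(T) ** 2 * float(d.data)
        return out


class IdealMixture(BinaryGEProvider):
    """gE = 0, gamma = 1 everywhere."""

    def gE_RT(self, x1, T):
        x1 = ad.astensor(x1)
        return x1 * 0.0

    def ln_gamma(self, x1, T):
        x1 = np.atleast_1d(np.asarray(x1, dtype=np.float64))
        return np.zeros_like(x1), np.zeros_like(x1)

    def h_excess(self, x1, T):
        return np.zeros_like(np.atleast_1d(np.asarray(x1, dtype=np.float64)))


@dataclass
class Margules(BinaryGEProvider):
    """Two-suffix (one-parameter) Margules model with A(T) = a + b/T.

    gE/(RT) = A(T) x1 x2; ln gamma_1 = A x2^2; hE = R b x1 x2.  Demixing
    occurs exactly when A > 2 (symmetric gap).
    """

    a: float
    b: float = 0.0

    def A(self, T):
        return self.a + self.b / T

    def gE_RT(self, x1, T):
        x1 = ad.astensor(x1)
        A = self.a + self.b / ad.astensor(T)
        return A * x1 * (1.0 - x1)

    def ln_gamma(self, x1, T):
        x1 = np.atleast_1d(np.asarray(x1, dtype=np.float64))
        A = self.A(float(T))
        return A * (1.0 - x1) ** 2, A * x1**2

    def h_excess(self, x1, T):
        x1 = np.atleast_1d(np.asarray(x1, dtype=np.float64))
        return GAS_CONSTANT * self.b * x1 * (1.0 - x1)


@dataclass
class NRTL(BinaryGEProvider):
    """Binary NRTL model with tau_ij(T) = a_ij + b_ij/T and nonrandomness alpha.

    gE/(RT) = x1 x2 [tau21 G21 / (x1 + x2 G21) + tau12 G12 / (x2 + x1 G12)],
    G_ij = exp(-alpha tau_ij).
    """

    a12: float
    a21: float
    b12: float = 0.0
    b21: float = 0.0
    alpha: float = 0.3

    def __post_init__(self):
        if not 0.0 < self.alpha <= 0.5:
            raise ValueError("nonrandomness parameter alpha must be in (0, 0.5]")

    def taus(self, T):
        return self.a12 + self.b12 / T, self.a21 + self.b21 / T

    def gE_RT(self, x1, T):
        x1 = ad.astensor(x1)
        Tt = ad.astensor(T)
        t12 = self.a12 + self.b12 / Tt
        t21 = self.a21 + self.b21 / Tt
        G12 = ad.exp(-self.alpha * t12)
        G21 = ad.exp(-self.alpha * t21)
        x2 = 1.0 - x1
        return x1 * x2 * (t21 * G21 / (x1 + x2 * G21) + t12 * G12 / (x2 + x1 * G12))

    def ln_gamma(self, x1, T):
        x1 = np.atleast_1d(np.asarray(x1, dtype=np.float64))
        x2 = 1.0 - x1
        t12, t21 = self.taus(float(T))
        G12 = np.exp(-self.alpha * t12)
        G21 = np.exp(-self.alpha * t21)
        ln_g1 = x2**2 * (
            t21 * (G21 / (x1 + x2 * G21)) ** 2 + t12 * G12 / (x2 + x1 * G12) ** 2
        )
        ln_g2 = x1**2 * (
            t12 * (G12 / (x2 + x1 * G12)) ** 2 + t21 * G21 / (x1 + x2 * G21) ** 2
        )
        return ln_g1, ln_g2

    def h_excess(self, x1, T):
        x1 = np.atleast_1d(np.asarray(x1, dtype=np.float64))
        x2 = 1.0 - x1
        T = float(T)
        t12, t21 = self.taus(T)
        dt12, dt21 = -self.b12 / T**2, -self.b21 / T**2
        G12, G21 = np.exp(-self.alpha * t12), np.exp(-self.alpha * t21)
        dG12, dG21 = -self.alpha * dt12 * G12, -self.alpha * dt21 * G21

        def term_dT(tau, dtau, G, dG, xa, xb):
            den = xa + xb * G
            return (dtau * G + tau * dG) / den - tau * G * xb * dG / den**2

        dg_dT = x1 * x2 * (
            term_dT(t21, dt21, G21, dG21, x1, x2)
            + term_dT(t12, dt12, G12, dG12, x2, x1)
        )
        return -GAS_CONSTANT * T**2 * dg_dT


@dataclass
class AntoineCoefficients:
    """log10(p_sat / bar) = A - B / (T/K + C)."""

    A: float
    B: float
    C: float
    T_min: float | None = None
    T_max: float | None = None

    def p_sat(self, T) -> np.ndarray:
        T = np.asarray(T, dtype=np.float64)
        if self.T_min is not None and np.any(T < self.T_min) or (
            self.T_max is not None and np.any(T > self.T_max)
        ):
            warnings.warn(
                f"temperature outside Antoine validity range "
                f"[{self.T_min}, {self.T_max}] K",
                stacklevel=2,
            )
        return 10.0 ** (self.A - self.B / (T + self.C))


class NeuralBinaryProvider(BinaryGEProvider):
    """Adapter exposing a trained neural gE model as a binary provider."""

    def __init__(self, model, comp_i, comp_j):
        self.model = model
        self.comp_i = comp_i
        self.comp_j = comp_j

    def gE_RT(self, x1, T):
        from .model import binary_gibbs_graph_on

        return binary_gibbs_graph_on(
            self.model, self.comp_i.embedding, self.comp_j.embedding, ad.astensor(x1), T
        )
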