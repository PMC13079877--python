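"""Shared fixtures: scalers, components, and interaction-stub models.

The stubs replace the neural pair-interaction with known closed forms
(constant q -> two-suffix Margules; q = a + b/T -> analytic excess
enthalpy), so the generic differentiation machinery can be checked against
hand-derived results.
"""

import numpy as np
import pytest

from gibbsnet import autodiff as ad
from gibbsnet.autodiff import Tensor
from gibbsnet.embeddings import ScalerParams, embed_component
from gibbsnet.model import GibbsEModel


class InteractionStub:
    """Model stand-in with identity refinement and a prescribed phi.

    ``phi_fn(tstar_column) -> Tensor`` column of phi values; similarity is
    still the RBF on the (identity-refined) embeddings, so identical
    components lump exactly.
    """

    def __init__(self, phi_fn, scalers, beta_rbf=100.0):
        self.phi_fn = phi_fn
        self.scalers = scalers
        self.beta_rbf = beta_rbf

    def refine(self, e_star):
        return e_star

    def pair_phi(self, theta_i, theta_j, Xi, Xj, tstar):
        rows = theta_i.shape[0]
        t_col = ad.astensor(tstar)
        if t_col.ndim == 0:
            t_col = ad.reshape(t_col, (1, 1))
        if t_col.shape[0] != rows:
            t_col = ad.broadcast_to(t_col, (rows, 1))
        return self.phi_fn(t_col)


@pytest.fixture(scope="session")
def scalers():
    return ScalerParams(
        t_mean=350.0, t_std=40.0, emb_mean=np.zeros(16), emb_std=np.ones(16)
    )


@pytest.fixture(scope="session")
def components():
    return [
        embed_component("CCO", component_id="A"),
        embed_component("CC(C)O", component_id="B"),
        embed_component("c1ccccc1", component_id="C"),
        embed_component("CCCCCC", component_id="D"),
        embed_component("CC(=O)C", component_id="E"),
    ]


@pytest.fixture()
def small_model(scalers):
    return GibbsEModel(scalers, width=32, seed=7)


@pytest.fixture()
def constant_q_stub(scalers):
    """q_ij == A for distinct components (two-suffix Margules)."""

    def make(A):
        return InteractionStub(lambda t: ad.astensor(np.full((t.shape[0], 1), float(A))) + 0.0 * t, scalers)

    return make


@pytest.fixture()
def temperature_q_stub(scalers):
    """q_ij(T) = a + b/T through the scaled-temperature input."""

    def make(a, b):
        def phi(t_col):
            T = t_col * scalers.t_std + scalers.t_mean
            return a + b / T

        return InteractionStub(phi, scalers)

    return make
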