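"""Forward-pass geometry and closed-form oracles for the gE model.

The interaction stubs make the assembled gE/(RT) a known classical model
(constant q -> two-suffix Margules), so activity coefficients and excess
enthalpies obtained by automatic differentiation can be compared with
hand-derived formulas.
"""

import numpy as np
import pytest

from gibbsnet.autodiff import Tensor
from gibbsnet.embeddings import ComponentRecord
from gibbsnet.model import (
    GAS_CONSTANT,
    MixtureState,
    activity_coefficients,
    binary_interaction,
    excess_enthalpy,
    excess_gibbs,
    ln_gamma_infinite_dilution,
    lump_mole_fractions,
    muggianu_project,
    refine_and_similarity,
)
from conftest import InteractionStub


def comps_with_embeddings(rows):
    return [
        ComponentRecord(f"X{k}", None, np.asarray(r, dtype=float))
        for k, r in enumerate(rows)
    ]


class TestSimilarity:
    def test_identical_embeddings_give_unit_similarity(self, constant_q_stub):
        stub = constant_q_stub(1.0)
        comps = comps_with_embeddings([np.ones(16), np.ones(16)])
        _, R = refine_and_similarity(stub, comps)
        assert R.data[0, 1] == 1.0
        assert np.all(np.diag(R.data) == 1.0)

    def test_rbf_hand_value(self, constant_q_stub):
        stub = constant_q_stub(1.0)
        e2 = np.zeros(16)
        e2[0] = 0.1  # squared distance 0.01, beta = 100 -> exp(-1)
        comps = comps_with_embeddings([np.zeros(16), e2])
        _, R = refine_and_similarity(stub, comps)
        assert R.data[0, 1] == pytest.approx(np.exp(-1.0), rel=1e-12)
        assert R.data[0, 1] == R.data[1, 0]

    def test_far_embeddings_underflow_to_zero(self, constant_q_stub):
        stub = constant_q_stub(1.0)
        comps = comps_with_embeddings([np.zeros(16), np.ones(16)])
        _, R = refine_and_similarity(stub, comps)
        assert R.data[0, 1] == 0.0

    def test_dimension_mismatch_rejected(self, small_model):
        comps = comps_with_embeddings([np.zeros(4), np.ones(4)])
        with pytest.raises(ValueError, match="dimension"):
            refine_and_similarity(small_model, comps)


class TestLumpingAndProjection:
    def test_identity_similarity_leaves_fractions(self):
        x = Tensor(np.array([0.2, 0.3, 0.5]))
        out = lump_mole_fractions(x, Tensor(np.eye(3)))
        assert np.allclose(out.data, x.data)

    def test_duplicate_component_lumps(self):
        R = np.eye(3)
        R[1, 2] = R[2, 1] = 1.0  # B and C identical
        out = lump_mole_fractions(Tensor(np.array([0.2, 0.3, 0.5])), Tensor(R))
        assert np.allclose(out.data, [0.2, 0.8, 0.8])

    def test_all_identical_lump_to_one(self):
        out = lump_mole_fractions(Tensor(np.array([0.2, 0.3, 0.5])), Tensor(np.ones((3, 3))))
        assert np.allclose(out.data, [1.0, 1.0, 1.0])

    def test_projection_hand_values(self):
        xt = Tensor(np.array([0.2, 0.3, 0.5]))
        X1, X2 = muggianu_project(xt, 0, 1)
        assert (X1.item(), X2.item()) == (pytest.approx(0.45), pytest.approx(0.55))
        assert muggianu_project(xt, 0, 2)[0].item() == pytest.approx(0.35)
        assert muggianu_project(xt, 1, 2)[1].item() == pytest.approx(0.60)
        assert X1.item() + X2.item() == 1.0

    def test_binary_projection_reduces_to_fractions(self):
        xt = Tensor(np.array([0.37, 0.63]))
        X1, X2 = muggianu_project(xt, 0, 1)
        assert X1.item() == 0.37 and X2.item() == 0.63

    def test_equal_fractions_project_to_half(self):
        xt = Tensor(np.array([0.4, 0.4, 0.2]))
        X1, X2 = muggianu_project(xt, 0, 1)
        assert X1.item() == 0.5 == X2.item()

    def test_same_index_rejected(self):
        with pytest.raises(ValueError):
            muggianu_project(Tensor(np.array([0.5, 0.5])), 1, 1)


class TestBinaryInteraction:
    def test_unit_similarity_forces_zero_q(self, small_model):
        th = Tensor(np.random.default_rng(0).normal(size=(1, 32)))
        q = binary_interaction(
            small_model, th, th, Tensor(0.5), Tensor(0.5), Tensor(0.0), Tensor(1.0)
        )
        assert q.item() == 0.0

    def test_swap_symmetry_bitwise(self, small_model):
        rng = np.random.default_rng(1)
        ti, tj = Tensor(rng.normal(size=(1, 32))), Tensor(rng.normal(size=(1, 32)))
        Xi, Xj = Tensor(0.3), Tensor(0.7)
        q_ij = binary_interaction(small_model, ti, tj, Xi, Xj, Tensor(0.1), Tensor(0.0))
        q_ji = binary_interaction(small_model, tj, ti, Xj, Xi, Tensor(0.1), Tensor(0.0))
        assert q_ij.item() == q_ji.item()

    def test_zero_similarity_returns_phi(self, small_model):
        rng = np.random.default_rng(2)
        ti, tj = Tensor(rng.normal(size=(1, 32))), Tensor(rng.normal(size=(1, 32)))
        q = binary_interaction(small_model, ti, tj, Tensor(0.4), Tensor(0.6), Tensor(0.0), Tensor(0.0))
        phi = small_model.pair_phi(ti, tj, Tensor(0.4), Tensor(0.6), Tensor(0.0))
        assert q.item() == pytest.approx(float(phi.data.ravel()[0]), rel=1e-15)


class TestExcessGibbs:
    def test_pure_component_zero(self, constant_q_stub, components):
        state = MixtureState(components[:2], np.array([1.0, 0.0]), 320.0)
        assert excess_gibbs(constant_q_stub(2.0), state) == 0.0

    def test_constant_q_equimolar_ternary(self, constant_q_stub, components):
        state = MixtureState(components[:3], np.array([1, 1, 1]) / 3.0, 320.0)
        assert excess_gibbs(constant_q_stub(2.0), state) == pytest.approx(2.0 / 3.0, rel=1e-10)

    def test_duplicated_component_reduces_to_binary(self, constant_q_stub, components):
        stub = constant_q_stub(1.7)
        dup = MixtureState(
            [components[0], components[1], components[1]],
            np.array([0.2, 0.3, 0.5]), 320.0,
        )
        binary = MixtureState(components[:2], np.array([0.2, 0.8]), 320.0)
        assert excess_gibbs(stub, dup) == pytest.approx(excess_gibbs(stub, binary), abs=1e-8)


class TestActivityCoefficients:
    def test_margules_closed_form_on_grid(self, constant_q_stub, components):
        A = 2.0
        stub = constant_q_stub(A)
        for x1 in np.linspace(0.0, 1.0, 101):
            state = MixtureState(components[:2], np.array([x1, 1 - x1]), 320.0)
            res = activity_coefficients(stub, state)
            assert res.ln_gamma[0] == pytest.approx(A * (1 - x1) ** 2, abs=1e-10)
            assert res.ln_gamma[1] == pytest.approx(A * x1**2, abs=1e-10)

    def test_pure_component_limit_exact(self, small_model, components):
        state = MixtureState(components[:2], np.array([1.0, 0.0]), 320.0)
        res = activity_coefficients(small_model, state)
        assert abs(res.ln_gamma[0]) < 1e-12

    def test_permutation_equivariance(self, small_model, components):
        x = np.array([0.2, 0.3, 0.5])
        base = activity_coefficients(small_model, MixtureState(components[:3], x, 320.0))
        perm = [2, 0, 1]
        res = activity_coefficients(
            small_model,
            MixtureState([components[i] for i in perm], x[perm], 320.0),
        )
        assert np.max(np.abs(res.ln_gamma - base.ln_gamma[perm])) <= 1e-10


class TestExcessEnthalpy:
    def test_temperature_independent_q_gives_zero(self, constant_q_stub, components):
        state = MixtureState(components[:2], np.array([0.5, 0.5]), 320.0)
        assert excess_enthalpy(constant_q_stub(2.0), state) == pytest.approx(0.0, abs=1e-10)

    def test_one_over_T_interaction_closed_form(self, temperature_q_stub, components):
        stub = temperature_q_stub(0.5, 100.0)
        state = MixtureState(components[:2], np.array([0.5, 0.5]), 320.0)
        # hE = R * b * x1 * x2 for q = a + b/T
        assert excess_enthalpy(stub, state) == pytest.approx(
            GAS_CONSTANT * 100.0 * 0.25, rel=1e-10
        )
        assert excess_enthalpy(stub, state) == pytest.approx(207.86, abs=0.01)

    def test_autodiff_matches_finite_difference(self, small_model, components):
        state = MixtureState(components[:2], np.array([0.35, 0.65]), 330.0)
        h = excess_enthalpy(small_model, state)
        dT = 0.01
        g_hi = excess_gibbs(small_model, MixtureState(components[:2], state.x, 330.0 + dT))
        g_lo = excess_gibbs(small_model, MixtureState(components[:2], state.x, 330.0 - dT))
        fd = -GAS_CONSTANT * 330.0**2 * (g_hi - g_lo) / (2 * dT)
        assert h == pytest.approx(fd, rel=1e-4)


class TestInfiniteDilution:
    def test_margules_limit(self, constant_q_stub, components):
        val = ln_gamma_infinite_dilution(
            constant_q_stub(2.0), components[:2], 0, np.array([1.0]), 320.0
        )
        assert val == pytest.approx(2.0, abs=1e-10)

    def test_solute_identical_to_solvent(self, constant_q_stub, components):
        comps = [components[0], components[0]]
        val = ln_gamma_infinite_dilution(constant_q_stub(2.0), comps, 0, np.array([1.0]), 320.0)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_ternary_solvent_swap(self, constant_q_stub, components):
        stub = constant_q_stub(1.3)
        a = ln_gamma_infinite_dilution(stub, components[:3], 0, np.array([0.5, 0.5]), 320.0)
        swapped = [components[0], components[2], components[1]]
        b = ln_gamma_infinite_dilution(stub, swapped, 0, np.array([0.5, 0.5]), 320.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_solute_index_out_of_range(self, constant_q_stub, components):
        with pytest.raises(IndexError):
            ln_gamma_infinite_dilution(
                constant_q_stub(1.0), components[:2], 5, np.array([1.0]), 320.0
            )
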