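"""Loss terms, Lipschitz machinery, and system-wise splitting."""

import numpy as np
import pytest

from gibbsnet import autodiff as ad
from gibbsnet.autodiff import Tensor
from gibbsnet.nn import LipschitzLinear, spectral_norm_estimate
from gibbsnet.surrogate import SurrogateModel
from gibbsnet.synthetic_data import DataRecord
from gibbsnet.training import (
    LossWeights,
    TrainingBatch,
    _lle_terms,
    data_losses,
    lipschitz_loss,
    smooth_l1,
    split_systems,
    total_loss,
)


class TestSmoothL1:
    @pytest.mark.parametrize(
        "d,beta,expected",
        [
            (0.0, 1.0, 0.0),
            (0.5, 1.0, 0.125),
            (2.0, 1.0, 1.5),
            (0.35, 0.35, 0.175),  # value at the quadratic/linear knee
            (-0.5, 1.0, 0.125),
        ],
    )
    def test_closed_form_values(self, d, beta, expected):
        out = smooth_l1(Tensor(np.array([d])), Tensor(np.array([0.0])), beta)
        assert out.data[0] == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ValueError):
            smooth_l1(Tensor(1.0), Tensor(0.0), 0.0)


class TestDataLosses:
    def _tpxy_batch(self, model, components, errors):
        from gibbsnet.model import binary_ln_gamma_graph

        e1 = components[0].embedding[None, :]
        e2 = components[1].embedding[None, :]
        x1 = np.array([0.4])
        T = np.array([320.0])
        ln1, ln2, _, _ = binary_ln_gamma_graph(model, e1, e2, x1, T)
        batch = TrainingBatch(n_records=1)
        batch.tpxy = dict(
            e1=e1, e2=e2, x1=x1, T=T,
            lg1=ln1.data - errors[0], lg2=ln2.data - errors[1],
        )
        return batch

    def test_perfect_predictions_give_zero(self, small_model, components):
        batch = self._tpxy_batch(small_model, components, (0.0, 0.0))
        losses = data_losses(small_model, SurrogateModel(seed=0), batch)
        assert all(l.item() == 0.0 for l in losses.values())

    def test_tpxy_averages_both_components(self, small_model, components):
        # errors (0.5, 0) at beta=1 -> (0.125 + 0)/2 = 0.0625
        batch = self._tpxy_batch(small_model, components, (0.5, 0.0))
        losses = data_losses(small_model, SurrogateModel(seed=0), batch)
        assert losses["TPXY"].item() == pytest.approx(0.0625, rel=1e-10)

    def test_aci_half_factor(self, small_model, components):
        from gibbsnet.model import binary_ln_gamma_graph

        e1 = components[0].embedding[None, :]
        e2 = components[1].embedding[None, :]
        x1, T = np.array([0.0]), np.array([320.0])
        ln1, _, _, _ = binary_ln_gamma_graph(small_model, e1, e2, x1, T)
        batch = TrainingBatch(n_records=1)
        batch.aci = dict(
            e1=e1, e2=e2, x1=x1, T=T, solute=np.array([0]),
            target=ln1.data - 0.5,
        )
        losses = data_losses(small_model, SurrogateModel(seed=0), batch)
        # 1/2 * smooth_l1(0.5, beta=2) = 1/2 * 0.5*0.25/2 = 0.03125
        assert losses["ACI"].item() == pytest.approx(0.03125, rel=1e-10)


class TestGibbsLoss:
    def _lle_dict(self, components, T=320.0):
        return dict(
            e1=components[0].embedding[None, :],
            e2=components[1].embedding[None, :],
            T=np.array([T]),
            xp=np.array([0.15]), xq=np.array([0.85]),
            phase_mask=np.array([[1.0, 1.0]]),
        )

    def test_ideal_like_model_contributes_four(self, constant_q_stub, components):
        # q == 0: the mixing curve is ideal, min curvature 4 at x = 0.5
        stub = constant_q_stub(0.0)
        l_lle, gibbs, mask = _lle_terms(stub, SurrogateModel(seed=0), self._lle_dict(components))
        assert gibbs.item() == pytest.approx(4.0, rel=1e-10)
        assert mask[0] == 0.0
        assert l_lle.item() == 0.0  # masked out: mutually exclusive with Gibbs

    def test_demixing_model_contributes_zero(self, constant_q_stub, components):
        stub = constant_q_stub(2.5)
        l_lle, gibbs, mask = _lle_terms(stub, SurrogateModel(seed=0), self._lle_dict(components))
        assert gibbs.item() == 0.0
        assert mask[0] == 1.0
        assert l_lle.item() > 0.0

    def test_gibbs_gradient_nonzero_when_positive(self, small_model, components):
        small_model.train()
        _, gibbs, _ = _lle_terms(small_model, SurrogateModel(seed=0), self._lle_dict(components))
        if gibbs.item() > 0:
            grads = ad.grad(gibbs, small_model.parameters())
            assert any(np.any(g.data != 0) for g in grads)

    def test_one_phase_record_uses_reported_phase_only(self, constant_q_stub, components):
        stub = constant_q_stub(2.5)
        d = self._lle_dict(components)
        d["xq"] = np.array([np.nan])
        d["phase_mask"] = np.array([[1.0, 0.0]])
        d2 = self._lle_dict(components)
        sur = SurrogateModel(seed=0)
        l_single, _, _ = _lle_terms(stub, sur, d)
        pred = sur.forward(Tensor(np.zeros((1, 101)))).data  # just shape sanity
        assert np.isfinite(l_single.item())


class TestLipschitz:
    def test_identity_matrix_exact(self):
        sigma, _ = spectral_norm_estimate(np.eye(5), n_iter=2)
        assert sigma == pytest.approx(1.0, rel=1e-12)

    def test_diagonal_converges_to_svd(self):
        w = np.diag([3.0, 1.0])
        state = None
        sigma = 0.0
        for _ in range(10):
            sigma, state = spectral_norm_estimate(w, n_iter=1, state=state)
        assert sigma == pytest.approx(3.0, abs=1e-6)

    def test_estimate_monotone_nondecreasing(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(8, 6))
        state, prev = None, 0.0
        for _ in range(12):
            sigma, state = spectral_norm_estimate(w, n_iter=1, state=state)
            assert sigma >= prev - 1e-12
            prev = sigma
        assert prev <= np.linalg.svd(w, compute_uv=False)[0] + 1e-9

    def test_zero_matrix_floored(self):
        sigma, _ = spectral_norm_estimate(np.zeros((4, 4)))
        assert sigma == 1e-12

    def test_scaled_weight_norm_equals_softplus_cstar(self):
        rng = np.random.default_rng(1)
        layer = LipschitzLinear(20, 16, rng)
        layer.c_star.data = np.asarray(0.7)
        w = layer.scaled_weight(n_iter=10).data
        target = np.logaddexp(0, 0.7)
        assert np.linalg.svd(w, compute_uv=False)[0] == pytest.approx(target, rel=1e-3)

    def test_empirical_lipschitz_bound(self):
        rng = np.random.default_rng(2)
        layers = [LipschitzLinear(8, 16, rng), LipschitzLinear(16, 16, rng), LipschitzLinear(16, 1, rng)]
        bound = np.prod([np.logaddexp(0, float(l.c_star.data)) for l in layers])
        bound *= 1.1**2  # two hidden activations

        def f(x):
            h = x
            for layer in layers[:-1]:
                h = ad.silu(layer(h)).data
                h = Tensor(h)
            return layers[-1](h).data

        x0 = rng.normal(size=(1000, 8))
        x1 = x0 + rng.normal(scale=0.5, size=(1000, 8))
        num = np.linalg.norm(f(Tensor(x1)) - f(Tensor(x0)), axis=1)
        den = np.linalg.norm(x1 - x0, axis=1)
        assert np.max(num / den) <= bound * (1 + 1e-9)

    def test_lipschitz_loss_product(self, scalers):
        from gibbsnet.model import GibbsEModel
        from gibbsnet.nn import softplus_inv

        model = GibbsEModel(scalers, width=8, seed=0)
        for layer in model.lipschitz_layers():
            layer.c_star.data = np.asarray(softplus_inv(2.0))
        assert lipschitz_loss(model).item() == pytest.approx(32.0, rel=1e-9)
        for layer in model.lipschitz_layers():
            layer.c_star.data = np.asarray(softplus_inv(1.0))
        assert lipschitz_loss(model).item() == pytest.approx(1.0, rel=1e-9)
        # strictly decreasing in any single c*
        model.lipschitz_layers()[2].c_star.data -= 0.5
        assert lipschitz_loss(model).item() < 1.0


class TestTotalLoss:
    def _zeros(self):
        return {k: Tensor(0.0) for k in ("TPXY", "TPX", "ACI", "LLE", "HE", "Gibbs")}

    def test_lipschitz_term_scaling(self, scalers):
        from gibbsnet.model import GibbsEModel
        from gibbsnet.nn import softplus_inv

        model = GibbsEModel(scalers, width=8, seed=0)
        for layer in model.lipschitz_layers():
            layer.c_star.data = np.asarray(softplus_inv(1.0))
        w = LossWeights(w_lips=0.1)
        out = total_loss(self._zeros(), w, 10, model=model)
        assert out.item() == pytest.approx(0.01, rel=1e-9)

    def test_unit_losses_sum(self):
        losses = {k: Tensor(1.0) for k in ("TPXY", "TPX", "ACI", "LLE", "HE", "Gibbs")}
        w = LossWeights(w_tpx=1, w_lle=1, w_he=1, w_gibbs=1, w_lips=0, l2=0)
        assert total_loss(losses, w, 1).item() == pytest.approx(6.0)

    def test_doubling_batch_size_halves(self):
        losses = {k: Tensor(2.0) for k in ("TPXY", "TPX", "ACI", "LLE", "HE")}
        w = LossWeights()
        a = total_loss(losses, w, 4).item()
        b = total_loss(losses, w, 8).item()
        assert a == pytest.approx(2 * b, rel=1e-12)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            total_loss(self._zeros(), LossWeights(w_lle=-1.0), 1)

    def test_l2_fallback_when_w_lips_zero(self, scalers):
        from gibbsnet.model import GibbsEModel

        model = GibbsEModel(scalers, width=8, seed=0)
        w = LossWeights(w_lips=0.0, l2=1e-3)
        out = total_loss(self._zeros(), w, 1, model=model)
        expected = 1e-3 * sum(float(np.sum(p.data**2)) for p in model.parameters())
        assert out.item() == pytest.approx(expected, rel=1e-9)


def _rec(t, sysid, ids, **kw):
    base = dict(type=t, system_id=sysid, component_ids=ids, T=300.0)
    if t in ("TPXY", "TPX"):
        base.update(p=1.0, x=(0.5, 0.5))
        if t == "TPXY":
            base.update(y=(0.5, 0.5))
    elif t == "ACI":
        base.update(x=(0.0, 1.0), ln_gamma_inf=1.0, solute_index=0)
    elif t == "LLE":
        base.update(x1_prime=0.1, x1_doubleprime=0.9, phase_flags="both")
    elif t == "HE":
        base.update(x=(0.5, 0.5), hE=100.0)
    base.update(kw)
    return DataRecord(**base)


class TestSplitting:
    def _records(self, n_systems=30, seed=0):
        rng = np.random.default_rng(seed)
        records = []
        for k in range(n_systems):
            ids = (f"A{k}", f"B{k}")
            types = ["TPXY", "HE"] if k % 3 else ["TPXY", "LLE", "HE", "ACI"]
            for t in types:
                for _ in range(rng.integers(1, 4)):
                    records.append(_rec(t, f"S{k}", ids))
        return records

    def test_tenfold_partitions_systems(self):
        records = self._records(40)
        folds = split_systems(records, "tenfold", seed=1)
        all_keys = {r.system_key for r in records}
        test_sets = [f["test"] for f in folds]
        assert set().union(*test_sets) == all_keys
        for a in range(10):
            for b in range(a + 1, 10):
                assert not (test_sets[a] & test_sets[b])

    def test_no_system_straddles_sets(self):
        records = self._records(40)
        for fold in split_systems(records, "tenfold", seed=2):
            assert not (fold["train"] & fold["val"])
            assert not (fold["train"] & fold["test"])
            assert not (fold["val"] & fold["test"])

    def test_same_seed_identical_assignment(self):
        records = self._records(25)
        f1 = split_systems(records, "tenfold", seed=7)
        f2 = split_systems(records, "tenfold", seed=7)
        assert f1 == f2

    def test_full_split_ratio(self):
        records = self._records(40)
        (split,) = split_systems(records, "full", seed=3)
        assert len(split["val"]) == 2  # 5% of 40
        assert not split["test"]

    def test_too_few_systems_rejected(self):
        records = self._records(5)
        with pytest.raises(ValueError):
            split_systems(records, "tenfold", seed=0)
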