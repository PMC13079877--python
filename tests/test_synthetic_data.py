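"""Synthetic ground-truth systems, record generation, and curation."""

import numpy as np
import pytest

from gibbsnet.gemodels import BinaryGEProvider, Margules, NRTL
from gibbsnet.synthetic_data import (
    DataRecord,
    GroundTruthSystem,
    NoiseParams,
    curate,
    demixing_temperatures,
    frame_to_records,
    generate_records,
    records_to_frame,
    sample_systems,
)


@pytest.fixture(scope="module")
def small_world():
    systems, components, pmap = sample_systems(8, seed=21, miscibility_mix=0.5)
    return systems, components


class TestGroundTruth:
    def test_closed_forms_consistent_with_autodiff(self, small_world):
        systems, _ = small_world
        x = np.linspace(0.05, 0.95, 7)
        for s in systems[:4]:
            p = s.provider()
            lg1, lg2 = p.ln_gamma(x, 320.0)
            lg1_ad, lg2_ad = BinaryGEProvider.ln_gamma(p, x, 320.0)
            assert np.allclose(lg1, lg1_ad, atol=1e-10)
            assert np.allclose(lg2, lg2_ad, atol=1e-10)
            he = p.h_excess(x, 320.0)
            he_ad = BinaryGEProvider.h_excess(p, x, 320.0)
            assert np.allclose(he, he_ad, rtol=1e-8, atol=1e-8)

    def test_margules_demixing_threshold(self):
        # A(T) = 625/T crosses the demixing threshold A = 2 at T = 312.5 K
        provider = Margules(a=0.0, b=625.0)
        temps = demixing_temperatures(provider, 273.0, 428.0, n_T=40)
        assert temps.size > 0
        assert temps.max() < 312.5
        assert 312.5 < 428.0 and not np.any(temps > 312.5)

    def test_requested_miscibility_mix(self, small_world):
        systems, _ = small_world
        assert sum(s.demixes() for s in systems) == 4

    def test_zero_mix_gives_no_demixing(self):
        systems, _, _ = sample_systems(5, seed=3, miscibility_mix=0.0)
        assert not any(s.demixes() for s in systems)

    def test_same_seed_identical_parameters(self):
        s1, _, _ = sample_systems(6, seed=9)
        s2, _, _ = sample_systems(6, seed=9)
        assert [s.params for s in s1] == [s.params for s in s2]
        assert [s.component_ids for s in s1] == [s.component_ids for s in s2]

    def test_nrtl_alpha_bounds_enforced(self):
        with pytest.raises(ValueError):
            NRTL(a12=1.0, a21=1.0, alpha=0.7)


class TestRecordGeneration:
    def test_zero_noise_tpxy_round_trip(self, small_world):
        systems, _ = small_world
        s = systems[0]
        provider = s.provider()
        a1, a2 = s.antoine
        for r in generate_records(s, noise=NoiseParams.zero(), seed=5):
            if r.type != "TPXY":
                continue
            g1 = r.p * r.y[0] / (float(a1.p_sat(r.T)) * r.x[0])
            g2 = r.p * r.y[1] / (float(a2.p_sat(r.T)) * r.x[1])
            lg1, lg2 = provider.ln_gamma(np.array([r.x[0]]), r.T)
            assert np.log(g1) == pytest.approx(lg1[0], abs=1e-10)
            assert np.log(g2) == pytest.approx(lg2[0], abs=1e-10)

    def test_zero_noise_aci_and_he_closed_form(self, small_world):
        systems, _ = small_world
        s = systems[0]
        provider = s.provider()
        for r in generate_records(s, noise=NoiseParams.zero(), seed=6):
            if r.type == "ACI":
                lg1, lg2 = provider.ln_gamma(
                    np.array([0.0 if r.solute_index == 0 else 1.0]), r.T
                )
                expected = lg1[0] if r.solute_index == 0 else lg2[0]
                assert r.ln_gamma_inf == pytest.approx(expected, abs=1e-10)
            elif r.type == "HE":
                assert r.hE == pytest.approx(
                    float(provider.h_excess(np.array([r.x[0]]), r.T)[0]), abs=1e-8
                )

    def test_margules_constant_A_lle_endpoints(self):
        s = GroundTruthSystem(
            "S0", ("A", "B"), "margules", {"a": 2.5, "b": 0.0},
            antoine=(None, None),
        )
        recs = [
            r
            for r in generate_records(
                s, counts={"LLE": 5}, noise=NoiseParams.zero(), seed=7
            )
            if r.type == "LLE"
        ]
        assert recs
        for r in recs:
            if r.x1_prime is not None:
                assert r.x1_prime == pytest.approx(0.14479, abs=1e-4)
            if r.x1_doubleprime is not None:
                assert r.x1_doubleprime == pytest.approx(0.85521, abs=1e-4)

    def test_lle_endpoints_satisfy_equal_activity(self, small_world):
        systems, _ = small_world
        demix = next(s for s in systems if s.demixes())
        provider = demix.provider()
        recs = [
            r
            for r in generate_records(demix, noise=NoiseParams.zero(), seed=8)
            if r.type == "LLE" and r.phase_flags == "both"
        ]
        for r in recs:
            lg1p, lg2p = provider.ln_gamma(np.array([r.x1_prime]), r.T)
            lg1q, lg2q = provider.ln_gamma(np.array([r.x1_doubleprime]), r.T)
            assert r.x1_prime * np.exp(lg1p[0]) == pytest.approx(
                r.x1_doubleprime * np.exp(lg1q[0]), abs=1e-8
            )
            assert (1 - r.x1_prime) * np.exp(lg2p[0]) == pytest.approx(
                (1 - r.x1_doubleprime) * np.exp(lg2q[0]), abs=1e-8
            )

    def test_hE_closed_form_value(self):
        # A(T) = b/T with b = 100 K: hE(x=0.5) = R * 100 * 0.25 = 207.86 J/mol
        provider = Margules(a=0.0, b=100.0)
        assert provider.h_excess(np.array([0.5]), 320.0)[0] == pytest.approx(207.86, abs=0.01)

    def test_miscible_system_yields_no_lle_records(self):
        s = GroundTruthSystem(
            "S0", ("A", "B"), "margules", {"a": 1.0, "b": 0.0}, antoine=(None, None)
        )
        recs = generate_records(s, counts={"LLE": 5}, seed=1)
        assert [r for r in recs if r.type == "LLE"] == []

    def test_temperature_range_mostly_in_band(self, small_world):
        systems, _ = small_world
        temps = [
            r.T
            for r in generate_records(systems[1], counts={"HE": 400}, seed=2)
        ]
        frac = np.mean([(273.0 <= t <= 428.0) for t in temps])
        assert 0.9 <= frac <= 1.0


def _aci(sysid, ids, T, solute, x, value):
    return DataRecord(
        type="ACI", system_id=sysid, component_ids=ids, T=T,
        solute_index=solute, x=x, ln_gamma_inf=value,
    )


class TestCuration:
    def test_high_pressure_vle_dropped_lle_kept(self):
        recs = [
            DataRecord(type="TPXY", system_id="S", component_ids=("A", "B"), T=300,
                       p=12.0, x=(0.5, 0.5), y=(0.5, 0.5)),
            DataRecord(type="TPX", system_id="S", component_ids=("A", "B"), T=300,
                       p=9.0, x=(0.5, 0.5)),
            DataRecord(type="LLE", system_id="S", component_ids=("A", "B"), T=300,
                       p=40.0, x1_prime=0.1, x1_doubleprime=0.9, phase_flags="both"),
        ]
        out = curate(recs)
        assert [r.type for r in out] == ["TPX", "LLE"]

    def test_ternary_aci_endpoint_deviation_drops_system(self):
        binary_ref = _aci("B1", ("X", "A"), 300.0, 0, (0.0, 1.0), 1.0)
        good_ep = _aci("T1", ("X", "A", "B"), 300.0, 0, (0.0, 1.0, 0.0), 1.05)
        good_mix = _aci("T1", ("X", "A", "B"), 300.0, 0, (0.0, 0.5, 0.5), 0.8)
        bad_ep = _aci("T2", ("X", "A", "C"), 300.0, 0, (0.0, 1.0, 0.0), 1.2)
        bad_mix = _aci("T2", ("X", "A", "C"), 300.0, 0, (0.0, 0.5, 0.5), 0.7)
        out = curate([binary_ref, good_ep, good_mix, bad_ep, bad_mix])
        kept = {(r.system_id, r.x) for r in out}
        assert ("T1", (0.0, 0.5, 0.5)) in kept  # mixed point of the good system
        assert all(r.system_id != "T2" for r in out)  # deviation 0.2 > 0.1
        assert ("T1", (0.0, 1.0, 0.0)) not in kept  # endpoint rows not retained

    def test_ternary_aci_without_reference_dropped(self):
        orphan_mix = _aci("T3", ("X", "D", "E"), 300.0, 0, (0.0, 0.5, 0.5), 0.8)
        assert curate([orphan_mix]) == []

    def test_curation_idempotent(self, small_world):
        systems, _ = small_world
        recs = []
        for s in systems[:4]:
            recs.extend(generate_records(s, seed=3))
        once = curate(recs)
        assert curate(once) == once


class TestFileRoundTrip:
    def test_records_frame_round_trip(self, small_world):
        systems, _ = small_world
        recs = generate_records(systems[0], seed=4)
        back = frame_to_records(records_to_frame(recs))
        assert back == recs
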