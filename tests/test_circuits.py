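"""Controller-library unit tests: Hill laws, topology builders and
effective transcription rates."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import circuitevo as ce
from circuitevo.circuits import (ConfigurationError, ControllerParams,
                                 GeneSpec, RegulatoryInputs, TOPOLOGIES,
                                 build_circuit, effective_transcription)
from circuitevo.host import CellModel

nonneg = st.floats(min_value=0.0, max_value=1e9, allow_nan=False)
positive = st.floats(min_value=1e-6, max_value=1e9, allow_nan=False)


class TestHillLaws:
    def test_repression_identities(self):
        assert ce.hill_repress(0.0, 5.0) == 1.0
        assert ce.hill_repress(100.0, 100.0) == pytest.approx(0.5)
        assert ce.hill_activate(0.0, 5.0) == 0.0
        assert ce.hill_activate(7.0, 7.0) == pytest.approx(0.5)

    def test_repression_monotone_decreasing(self):
        x = np.linspace(0, 1e4, 200)
        y = ce.hill_repress(x, 50.0, 2.0)
        assert np.all(np.diff(y) < 0)
        assert y[-1] < 1e-4

    @given(x=nonneg, k=positive, h=st.floats(0.5, 6.0))
    def test_complementarity(self, x, k, h):
        r = ce.hill_repress(x, k, h)
        a = ce.hill_activate(x, k, h)
        assert 0.0 <= r <= 1.0 and 0.0 <= a <= 1.0
        assert r + a == pytest.approx(1.0, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ce.hill_repress(1.0, 0.0)
        with pytest.raises(ValueError):
            ce.hill_activate(-1.0, 5.0)


class TestSequestration:
    def test_bilinear_arithmetic(self):
        assert ce.sequestration_flux(100.0, 50.0, 1e-3) == pytest.approx(5.0)
        assert ce.sequestration_flux(100.0, 0.0, 1e-3) == 0.0

    def test_mass_balance_in_cell_odes(self, host):
        # the sequestration flux removes one mRNA and one sRNA per event
        circuit = ce.design("CLpATL", seq_rate=1e-3)
        model = CellModel(host, circuit)
        y = np.full(model.n_species, 10.0)
        rate0 = ce.design("CLpATL", seq_rate=0.0)
        model0 = CellModel(host, rate0)
        dy = model.rhs(y, s_ext=1e12)
        dy0 = model0.rhs(y, s_ext=1e12)
        flux = 1e-3 * 10.0 * 10.0
        im, imB, ir = model.idx["m_A"], model.idx["m_B"], model.idx["r_C"]
        assert dy[im] - dy0[im] == pytest.approx(-flux)
        assert dy[imB] - dy0[imB] == pytest.approx(-flux)
        # r_C serves both co-transcribed target mRNAs: one flux per pair
        assert dy[ir] - dy0[ir] == pytest.approx(-2 * flux)


class TestEffectiveTranscription:
    def test_open_loop_is_unregulated(self):
        spec = ce.design("OL", omega_A=7.0)
        obs = RegulatoryInputs(p={"A": 1e6}, lam=1e-9, P=1e12)
        assert effective_transcription(spec, obs)["A"] == pytest.approx(7.0)

    def test_product_feedback_half_saturation(self):
        spec = ce.design("PHEN_PA", omega_A=10.0, k_A=450.0)
        obs = RegulatoryInputs(p={"A": 450.0})
        assert effective_transcription(spec, obs)["A"] == pytest.approx(5.0)

    def test_dual_input_is_product_of_single_factors(self):
        dual = ce.design("PHEN_DUAL", omega_A=10.0, k_A=300.0, k_lambda=0.02)
        prod = ce.design("PHEN_PA", omega_A=10.0, k_A=300.0)
        growth = ce.design("PHEN_LAMBDA", omega_A=10.0, k_lambda=0.02)
        obs = RegulatoryInputs(p={"A": 120.0}, lam=0.015)
        w_d = effective_transcription(dual, obs)["A"]
        w_p = effective_transcription(prod, obs)["A"]
        w_g = effective_transcription(growth, obs)["A"]
        assert w_d == pytest.approx(w_p * w_g / 10.0)

    def test_shared_promoter_rates_match(self):
        spec = ce.design("CLpATX", omega_A=20.0, k_B=100.0)
        obs = RegulatoryInputs(p={"A": 0.0, "B": 100.0})
        w = effective_transcription(spec, obs)
        assert w["A"] == w["B"] == pytest.approx(10.0)

    def test_mutation_levels_scale_promoters(self):
        spec = ce.design("CLpATL", omega_A=12.0, omega_C=30.0)
        obs = RegulatoryInputs(p={"A": 0.0, "B": 1e9})   # sRNA fully active
        w = effective_transcription(spec, obs,
                                    levels={"AB": 0.33, "C": 0.67})
        assert w["A"] == pytest.approx(12.0 * 0.33)
        assert w["C"] == pytest.approx(30.0 * 0.67, rel=1e-6)


class TestBuildCircuit:
    @pytest.mark.parametrize("topology,n_mutable,n_states", [
        ("OL", 1, 4), ("PHEN_PA", 1, 4), ("CLpATX", 1, 4),
        ("QS_POP", 1, 4), ("CLpATL", 2, 16), ("CLlamTX", 2, 16),
        ("CLlamPF", 2, 16), ("CLpATXlamTX", 2, 16), ("CLpATLlamPF", 2, 16),
        ("CLlamTL", 3, 64), ("CLpATXlamTL", 3, 64), ("CLpATLlamTX", 3, 64),
        ("CLpATLlamTL", 3, 64),
    ])
    def test_mutable_promoter_counts(self, topology, n_mutable, n_states):
        spec = ce.design(topology)
        assert len(spec.mutable_promoters) == n_mutable
        assert spec.n_mutation_states == n_states

    def test_open_loop_species(self):
        spec = build_circuit("OL")
        assert spec.species() == ("m_A", "c_A", "p_A")

    def test_all_topologies_build_and_validate(self):
        for topology in TOPOLOGIES:
            spec = ce.design(topology)
            species = spec.species()
            assert len(set(species)) == len(species)
            # every sequestration pair references declared species
            for m, s in spec.sequestration:
                assert f"m_{m}" in species and f"r_{s}" in species

    def test_unknown_topology_rejected(self):
        with pytest.raises(ConfigurationError):
            ce.design("CLnope")

    def test_missing_constant_named_in_error(self):
        with pytest.raises(ConfigurationError, match="k_B"):
            build_circuit("CLpATX", params=ControllerParams(k_B=None))
        # k_B missing is fine for OL
        build_circuit("OL", params=ControllerParams())

    def test_gene_override_by_name(self):
        spec = build_circuit(
            "CLpATX", genes=[GeneSpec("B", omega=10.0, b=0.2, length_aa=600)])
        assert spec.gene("B").length_aa == 600
        with pytest.raises(ConfigurationError):
            build_circuit("OL", genes=[GeneSpec("Z", omega=1.0)])

    def test_gene_invariants(self):
        with pytest.raises(ConfigurationError):
            GeneSpec("A", omega=-1.0)
        with pytest.raises(ConfigurationError):
            GeneSpec("C", omega=1.0, b=0.5, is_srna=True)
        with pytest.raises(ConfigurationError):
            GeneSpec("A", omega=1.0, length_aa=0)

    def test_weak_repressor_limit_recovers_coexpression(self, host):
        """CLpATX with k_B -> infinity loses its feedback: the steady
        state converges (repression factor -> 1)."""
        states = []
        for kB in (1e8, 1e10):
            model = CellModel(host, ce.design("CLpATX", k_B=kB))
            states.append(model.steady_state())
        np.testing.assert_allclose(states[0], states[1], rtol=1e-3)

    def test_silenced_srna_controller_equals_coexpression(self, host):
        """CLpATL with zero sequestration and a dead sRNA promoter is the
        plain co-expression system (equals the no-feedback CLpATX limit)."""
        silenced = ce.design("CLpATL", seq_rate=1e-30, omega_C=1e-12)
        m1 = CellModel(host, silenced)
        y1 = m1.steady_state()
        open_like = ce.design("CLpATX", k_B=1e12)
        m2 = CellModel(host, open_like)
        y2 = m2.steady_state()
        for name in ("m_A", "c_A", "p_A", "m_B", "c_B", "p_B", "e", "R"):
            assert y1[m1.idx[name]] == pytest.approx(
                y2[m2.idx[name]], rel=1e-4, abs=1e-8)
        assert y1[m1.idx["r_C"]] == pytest.approx(0.0, abs=1e-6)

    def test_with_params_roundtrip(self):
        spec = ce.design("CLlamTL", omega_A=42.0, k_B=77.0, k_lambda=0.004)
        spec2 = spec.with_params(omega_A=84.0)
        assert spec2.promoter_of("A").omega == pytest.approx(84.0)
        assert spec2.params.k_B == pytest.approx(77.0)
        assert spec2.params.k_lambda == pytest.approx(0.004)
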