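"""Population-simulator tests: competition, mutation transfer, batch
protocol, dilution and trace audits."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import circuitevo as ce
from circuitevo.mutation import MutationScheme
from circuitevo.population import (BatchProtocol, ExtinctPopulationError,
                                   PopulationModel, PopulationState, dilute,
                                   population_odes, run_batch_day)


@pytest.fixture(scope="module")
def ol_model(host):
    circuit = ce.design("OL", omega_A=5.0)
    return PopulationModel(host, circuit, MutationScheme(1, base_rate=1e-5))


@pytest.fixture(scope="module")
def ol_pop(ol_model):
    return ol_model.ancestral_population(BatchProtocol())


class TestPopulationOdes:
    def test_two_strain_exponential_ratio(self, host, ol_model, ol_pop):
        """With fixed growth rates 0.02 and 0.01 /min and no mutation,
        N1/N2 after 100 min equals e^1 (closed-form oracle)."""
        circuit = ce.design("OL", omega_A=5.0)
        scheme = MutationScheme(1, base_rate=0.0)
        model = PopulationModel(host, circuit, scheme)
        pop = PopulationState(
            N=np.array([100.0, 100.0, 0.0, 0.0]), s_X=1e18,
            cells=ol_pop.cells.copy())
        lam = np.array([0.02, 0.01, 0.0, 0.0])

        def rhs(t, y):
            return model.derivatives(y, growth_override=lam)

        y0 = model.pack(pop)
        sol = solve_ivp(rhs, (0.0, 100.0), y0, method="BDF",
                        rtol=1e-10, atol=1e-8)
        N = sol.y[1:5, -1]
        assert N[0] / N[1] == pytest.approx(np.e, rel=1e-6)

    def test_mutation_conserves_cells_at_equal_growth(self, host, ol_pop):
        circuit = ce.design("OL", omega_A=5.0)
        scheme = MutationScheme(1, base_rate=1e-3)
        pop = PopulationState(
            N=np.array([400.0, 300.0, 200.0, 100.0]), s_X=1e12,
            cells=ol_pop.cells.copy())
        dN, _, _ = population_odes(pop, host, circuit, scheme,
                                   growth_override=np.zeros(4))
        assert abs(dN.sum()) < 1e-12
        # and with equal nonzero growth, total growth is unaffected
        dN2, _, _ = population_odes(pop, host, circuit, scheme,
                                    growth_override=np.full(4, 0.02))
        assert dN2.sum() == pytest.approx(0.02 * pop.N.sum(), rel=1e-12)

    def test_strain_lattice_mismatch(self, host, ol_pop):
        circuit = ce.design("OL", omega_A=5.0)
        pop = PopulationState(N=np.ones(3), s_X=1e12,
                              cells=ol_pop.cells[:3].copy())
        with pytest.raises(ValueError):
            population_odes(pop, host, circuit, MutationScheme(1))


class TestBatchDay:
    def test_substrate_monotone_consumption(self, ol_model, ol_pop):
        protocol = BatchProtocol(samples_per_day=12)
        sol, end, _ = run_batch_day(ol_pop, ol_model, protocol)
        s = sol.y[0]
        assert end.s_X < ol_pop.s_X
        assert np.all(np.diff(s) <= 1e-6 * s[0])
        assert s.min() >= 0.0

    def test_no_substrate_no_net_growth(self, ol_model, ol_pop):
        """On an empty substrate bolus only the cells' small internal
        reserves remain, so the population barely grows all day."""
        pop = PopulationState(N=ol_pop.N.copy(), s_X=0.0,
                              cells=ol_pop.cells.copy())
        protocol = BatchProtocol(samples_per_day=12)
        _, end, _ = run_batch_day(pop, ol_model, protocol)
        assert end.N.sum() < 1.05 * pop.N.sum()

    def test_population_scales_with_substrate_bolus(self, host):
        """Simulation oracle: the plateau population grows with the
        substrate reset value."""
        circuit = ce.design("OL", omega_A=5.0)
        model = PopulationModel(host, circuit, MutationScheme(1))
        finals = []
        for reset in (5e11, 1e12, 2e12):
            protocol = BatchProtocol(substrate_reset=reset,
                                     samples_per_day=12)
            pop = model.ancestral_population(protocol)
            _, end, _ = run_batch_day(pop, model, protocol)
            finals.append(end.N.sum())
        assert finals[0] < finals[1] < finals[2]


class TestDilution:
    def test_proportional_rescaling(self):
        pop = PopulationState(N=np.array([9000.0, 3000.0]), s_X=1.0,
                              cells=np.ones((2, 3)))
        out = dilute(pop, BatchProtocol(sample_size=1000.0))
        np.testing.assert_allclose(out.N, [750.0, 250.0])
        assert out.s_X == 1e12
        np.testing.assert_array_equal(out.cells, pop.cells)

    def test_protocol_defaults(self):
        pop = PopulationState(N=np.array([5e6]), s_X=0.0,
                              cells=np.ones((1, 3)))
        out = dilute(pop, BatchProtocol())
        assert out.N.sum() == pytest.approx(1000.0)
        assert out.s_X == 1e12

    def test_multinomial_seeded_reproducible(self):
        pop = PopulationState(N=np.array([7000.0, 2000.0, 1000.0]),
                              s_X=0.0, cells=np.ones((3, 2)))
        a = dilute(pop, BatchProtocol(), mode="multinomial",
                   rng=np.random.default_rng(42))
        b = dilute(pop, BatchProtocol(), mode="multinomial",
                   rng=np.random.default_rng(42))
        np.testing.assert_array_equal(a.N, b.N)
        assert a.N.sum() == 1000.0

    def test_extinct_population(self):
        pop = PopulationState(N=np.zeros(2), s_X=0.0, cells=np.ones((2, 2)))
        with pytest.raises(ExtinctPopulationError, match="extinct"):
            dilute(pop, BatchProtocol())


class TestEvolutionTrace:
    def test_zero_mutation_holds_output_constant(self, toy_cfg):
        """The no-mutation control: daily-endpoint P constant to 0.1%."""
        cfg = ce.RunConfig(**{**toy_cfg.to_dict(),
                              "mutation": {"base_rate": 0.0}})
        trace = cfg.run()
        P = trace.day_end_P
        assert np.all(np.abs(P / P[0] - 1.0) < 1e-3)

    def test_trace_internal_audit(self, toy_trace):
        np.testing.assert_array_equal(toy_trace.recomputed_P(), toy_trace.P)
        assert np.all(np.diff(toy_trace.t) > 0)
        assert np.all(toy_trace.s_X >= 0)
        assert np.all(toy_trace.N >= 0)
        assert toy_trace.Q_cum is not None
        assert np.all(np.diff(toy_trace.Q_cum) >= 0)

    def test_day_end_bookkeeping(self, toy_trace, toy_cfg):
        protocol = BatchProtocol(**toy_cfg.protocol)
        expected = protocol.day_minutes * np.arange(
            1, len(toy_trace.day_end_idx) + 1)
        np.testing.assert_allclose(toy_trace.day_end_t, expected)

    def test_monotone_output_decay(self, toy_trace):
        P = toy_trace.day_end_P
        assert np.all(np.diff(P) < 0)

    def test_tidy_frame(self, toy_trace):
        df = toy_trace.to_frame()
        assert set(df.columns) == {"t", "strain", "variable", "value"}
        assert set(df["variable"]) == {"N", "p_A", "lam", "T_L_A", "P", "s_X"}
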