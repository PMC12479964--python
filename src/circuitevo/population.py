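"""Multi-strain population dynamics under repeated batch culture.

A population is a set of strains — one per mutation state of the circuit's
mutable promoters — competing for a single shared external substrate
``s_X``.  Each strain carries a full intracellular state (host + circuit
species) whose growth rate is produced by the host model; selection
emerges from growth-rate differences and mutation moves cells between
strains as a continuous first-order transfer governed by the mutation
scheme's rate matrix:

    dN_i/dt = lam_i N_i + sum_j (N_j M[j,i] - N_i M[i,j])
    ds_X/dt = - sum_i N_i * import_i

The batch protocol mirrors a serial-passage experiment: each day the
population grows for 24 h on a fixed substrate bolus until the supply is
exhausted and growth stalls, then a representative sample of cells is
carried into fresh medium and the substrate is reset.  Per-strain
intracellular states are integrated jointly with the population variables
in one stacked stiff ODE system.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .circuits import CircuitSpec
from .host import CellModel, HostParams
from .mutation import MutationScheme

__all__ = [
    "BatchProtocol",
    "PopulationState",
    "EvolutionTrace",
    "PopulationModel",
    "population_odes",
    "run_batch_day",
    "dilute",
    "run_evolution",
    "ExtinctPopulationError",
]


class ExtinctPopulationError(RuntimeError):
    """Dilution was requested from an empty population."""


@dataclass(frozen=True)
class BatchProtocol:
    """Serial-batch protocol parameters.

    ``day_minutes`` batch length; ``sample_size`` cells carried over at
    each dilution; ``substrate_reset`` molecules of external substrate per
    fresh batch; ``max_days`` simulation horizon; ``stop_fraction`` stop
    once the daily-endpoint output falls below this fraction of the
    initial output; ``samples_per_day`` stored time points per day.
    """

    day_minutes: float = 1440.0
    sample_size: float = 1000.0
    substrate_reset: float = 1e12
    max_days: int = 60
    stop_fraction: float = 0.01
    samples_per_day: int = 48

    def __post_init__(self) -> None:
        if min(self.day_minutes, self.sample_size, self.substrate_reset) <= 0:
            raise ValueError("protocol quantities must be positive")
        if not 0 < self.stop_fraction < 1:
            raise ValueError("stop_fraction must be in (0, 1)")
        if self.max_days < 1 or self.samples_per_day < 2:
            raise ValueError("need max_days >= 1 and samples_per_day >= 2")


@dataclass
class PopulationState:
    """Strain abundances ``N`` (cells), shared substrate ``s_X``
    (molecules) and per-strain intracellular states (S, D)."""

    N: np.ndarray
    s_X: float
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        self.cells = np.atleast_2d(np.asarray(self.cells, dtype=float))
        if self.N.shape[0] != self.cells.shape[0]:
            raise ValueError("strain count mismatch between N and cells")
        if np.any(self.N < 0) or self.s_X < 0:
            raise ValueError("population state must be non-negative")


@dataclass
class EvolutionTrace:
    """Time series of an evolution run.

    ``t`` minutes since day 0; per-strain arrays have shape (T, S).
    ``day_end_idx`` holds the index of the pre-dilution endpoint of each
    completed day, so ``t[day_end_idx]`` / ``P[day_end_idx]`` is the
    daily-endpoint series used by the longevity metrics.
    """

    t: np.ndarray
    N: np.ndarray
    s_X: np.ndarray
    p_A: np.ndarray
    lam: np.ndarray
    T_L_A: np.ndarray
    P: np.ndarray
    day_end_idx: np.ndarray
    states: list[tuple[int, ...]]
    Q_cum: np.ndarray | None = None

    @property
    def day_end_t(self) -> np.ndarray:
        return self.t[self.day_end_idx]

    @property
    def day_end_P(self) -> np.ndarray:
        return self.P[self.day_end_idx]

    def recomputed_P(self) -> np.ndarray:
        """P recomputed from stored N and p_A (audit of the stored P)."""
        return np.einsum("ts,ts->t", self.N, self.p_A)

    def to_frame(self):
        """Tidy (time, strain, variable, value) DataFrame."""
        import pandas as pd
        frames = []
        labels = ["/".join(map(str, s)) for s in self.states]
        for name, arr in (("N", self.N), ("p_A", self.p_A),
                          ("lam", self.lam), ("T_L_A", self.T_L_A)):
            df = pd.DataFrame(arr, columns=labels)
            df.insert(0, "t", self.t)
            df = df.melt(id_vars="t", var_name="strain", value_name="value")
            df.insert(2, "variable", name)
            frames.append(df)
        pop = pd.DataFrame({"t": self.t, "strain": "(all)",
                            "variable": "P", "value": self.P})
        sub = pd.DataFrame({"t": self.t, "strain": "(env)",
                            "variable": "s_X", "value": self.s_X})
        return pd.concat(frames + [pop, sub], ignore_index=True)


class PopulationModel:
    """Stacked ODE system for one circuit design over its mutation lattice."""

    def __init__(self, host: HostParams, circuit: CircuitSpec,
                 scheme: MutationScheme | None = None):
        self.cell_model = CellModel(host, circuit)
        self.circuit = circuit
        n_mut = len(circuit.mutable_promoters)
        if scheme is None:
            scheme = MutationScheme(n_mut)
        if scheme.n_promoters != n_mut:
            raise ValueError(
                f"mutation scheme spans {scheme.n_promoters} promoters but "
                f"topology {circuit.topology} has {n_mut} mutable promoters")
        self.scheme = scheme
        self.S = scheme.n_states
        self.D = self.cell_model.n_species
        self.levels = scheme.levels_fraction()          # (S, n_mut)
        self.M = scheme.matrix                          # (S, S)
        self._outflow = self.M.sum(axis=1)              # (S,)
        self.senses_population = circuit.topology in ("PHEN_POP", "QS_POP")
        self._ipA = self.cell_model.idx["p_A"]
        self._icA = self.cell_model.idx["c_A"]
        self._ie = self.cell_model.idx["e"]
        self._nA = circuit.gene("A").length_aa
        self._sparsity_cache = None

    # -- state packing -----------------------------------------------------
    # stacked vector: [s_X, N (S), cell states (S*D), cumulative production]

    def pack(self, pop: PopulationState, q_cum: float = 0.0) -> np.ndarray:
        return np.concatenate(([pop.s_X], pop.N, pop.cells.ravel(), [q_cum]))

    def unpack(self, y: np.ndarray) -> tuple[PopulationState, float]:
        S, D = self.S, self.D
        pop = PopulationState(N=np.maximum(y[1:1 + S], 0.0),
                              s_X=max(float(y[0]), 0.0),
                              cells=y[1 + S:1 + S + S * D].reshape(S, D).copy())
        return pop, float(y[-1])

    # -- dynamics ----------------------------------------------------------

    def derivatives(self, y: np.ndarray, growth_override=None):
        S, D = self.S, self.D
        s_X = float(y[0])
        N = y[1:1 + S]
        cells = y[1 + S:1 + S + S * D].reshape(S, D)
        P = float(np.dot(np.maximum(N, 0.0), cells[:, self._ipA]))
        dcells = self.cell_model.rhs(cells, s_X, levels=self.levels,
                                     population_output=P)
        if growth_override is None:
            lam = self.cell_model.growth(cells)
        else:
            lam = np.asarray(growth_override, dtype=float)
        dN = lam * N + self.M.T @ N - self._outflow * N
        ds_X = -float(np.dot(N, self.cell_model.import_flux(cells, s_X)))
        # cumulative process-protein production across the whole culture
        T_L_A = (self.cell_model.gamma(cells[:, self._ie])
                 * cells[:, self._icA] / self._nA)
        dq = float(np.dot(np.maximum(N, 0.0), T_L_A))
        dy = np.empty_like(y)
        dy[0] = ds_X
        dy[1:1 + S] = dN
        dy[1 + S:1 + S + S * D] = dcells.ravel()
        dy[-1] = dq
        return dy

    # -- solver plumbing ---------------------------------------------------

    def _atol(self) -> np.ndarray:
        atol = np.full(2 + self.S + self.S * self.D, 1e-8)
        atol[0] = 1e-2          # substrate, absolute scale ~1e12
        atol[1:1 + self.S] = 1e-6
        atol[-1] = 1.0          # cumulative production, scale >= 1e7
        return atol

    def _jac_sparsity(self) -> sparse.csr_matrix:
        if self._sparsity_cache is not None:
            return self._sparsity_cache
        S, D = self.S, self.D
        n = 2 + S + S * D
        J = sparse.lil_matrix((n, n), dtype=np.int8)
        ipt = self.cell_model.idx["p_t"]
        # substrate row: s_X itself, all N, each strain's transporter
        J[0, 0] = 1
        J[0, 1:1 + S] = 1
        for i in range(S):
            J[0, 1 + S + i * D + ipt] = 1
        # N rows: all N (mutation transfer) + own strain block (growth rate)
        for i in range(S):
            J[1 + i, 1:1 + S] = 1
            J[1 + i, 1 + S + i * D:1 + S + (i + 1) * D] = 1
        # cell rows: own block + substrate column
        for i in range(S):
            r0 = 1 + S + i * D
            J[r0:r0 + D, r0:r0 + D] = 1
            J[r0:r0 + D, 0] = 1
        # cumulative-production row: all N, each strain's e and c_A
        J[n - 1, 1:1 + S] = 1
        for i in range(S):
            J[n - 1, 1 + S + i * D + self._ie] = 1
            J[n - 1, 1 + S + i * D + self._icA] = 1
        if self.senses_population:
            # population output P couples every strain to all N and p_A
            ipA = self._ipA
            rows = slice(1 + S, n - 1)
            J[rows, 1:1 + S] = 1
            for j in range(S):
                J[rows, 1 + S + j * D + ipA] = 1
        self._sparsity_cache = J.tocsr()
        return self._sparsity_cache

    def integrate(self, pop: PopulationState, t_span: tuple[float, float],
                  t_eval: np.ndarray, rtol: float = 1e-6,
                  q_cum: float = 0.0):
        sol = solve_ivp(lambda t, y: self.derivatives(y), t_span,
                        self.pack(pop, q_cum), method="BDF", t_eval=t_eval,
                        rtol=rtol, atol=self._atol(),
                        jac_sparsity=self._jac_sparsity())
        if not sol.success:
            raise RuntimeError(
                f"population integration failed at t={sol.t[-1]:.1f} min: "
                f"{sol.message}")
        return sol

    def ancestral_population(self, protocol: BatchProtocol,
                             equilibrate: bool = True) -> PopulationState:
        """Day-0 state: the whole sample in the fully functional strain.

        Intracellular states start from the nutrient-replete steady state
        and, with ``equilibrate``, are then carried through one mutation-free
        batch cycle (grow + dilute) so the population enters day 1 at the
        periodic state of the serial-passage protocol — under zero mutation
        the daily-endpoint output is then constant from day 1.
        """
        y_ss = self.cell_model.steady_state(s_ext=protocol.substrate_reset)
        cells = np.tile(y_ss, (self.S, 1))
        N = np.zeros(self.S)
        N[self.scheme.ancestral_index()] = protocol.sample_size
        pop = PopulationState(N=N, s_X=protocol.substrate_reset, cells=cells)
        if equilibrate:
            burn_model = PopulationModel(
                self.cell_model.host, self.circuit,
                MutationScheme(self.scheme.n_promoters, base_rate=0.0,
                               attenuation=self.scheme.attenuation))
            for _ in range(2):      # the batch-cycle map converges fast
                _, end, _ = run_batch_day(pop, burn_model, protocol)
                pop = dilute(end, protocol)
            # every strain starts from the equilibrated ancestral cell state
            pop.cells = np.tile(pop.cells[self.scheme.ancestral_index()],
                                (self.S, 1))
        return pop


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def population_odes(pop: PopulationState, host: HostParams,
                    circuit: CircuitSpec,
                    scheme: MutationScheme | None = None,
                    growth_override=None):
    """Time derivatives ``(dN, ds_X, dcells)`` of a population state.

    ``growth_override`` replaces the model-derived per-strain growth rates
    in the N-equation (diagnostic use: closed-form competition checks).
    """
    model = PopulationModel(host, circuit, scheme)
    if pop.N.shape[0] != model.S:
        raise ValueError(
            f"population has {pop.N.shape[0]} strains but the mutation "
            f"lattice has {model.S} states")
    dy = model.derivatives(model.pack(pop), growth_override=growth_override)
    S, D = model.S, model.D
    return dy[1:1 + S], float(dy[0]), dy[1 + S:1 + S + S * D].reshape(S, D)


def run_batch_day(pop: PopulationState, model: PopulationModel,
                  protocol: BatchProtocol, rtol: float = 1e-6,
                  q_cum: float = 0.0):
    """Integrate one batch day; returns ``(sol, end_state, q_cum_end)``.

    ``sol.t`` spans [0, day_minutes] on the protocol's sampling grid; the
    population plateaus once the substrate is exhausted (import, hence
    anabolite supply, hence growth, all vanish with s_X).  ``q_cum``
    carries the cumulative-production integral across days.
    """
    t_eval = np.linspace(0.0, protocol.day_minutes, protocol.samples_per_day + 1)
    sol = model.integrate(pop, (0.0, protocol.day_minutes), t_eval, rtol=rtol,
                          q_cum=q_cum)
    # stiff-solver hygiene: excursions beyond -1e-3 mc would indicate a
    # genuine integration failure; smaller ones are roundoff at the atol
    # scale and are clamped in the reported solution
    if sol.y[1:].min() < -1e-3 or sol.y[0].min() < -1.0:
        raise RuntimeError("negative state at end of batch day")
    np.clip(sol.y, 0.0, None, out=sol.y)
    end, q_end = model.unpack(sol.y[:, -1])
    return sol, end, q_end


def dilute(pop: PopulationState, protocol: BatchProtocol,
           mode: str = "deterministic",
           rng: np.random.Generator | None = None) -> PopulationState:
    """Serial-passage dilution: rescale to ``sample_size`` cells and reset
    the substrate; intracellular states are carried over unchanged.

    ``mode='deterministic'`` keeps exact strain proportions (the expected
    composition of a representative sample); ``mode='multinomial'`` draws
    the sample with the given seeded generator.
    """
    total = float(pop.N.sum())
    if total <= 0:
        raise ExtinctPopulationError("population extinct")
    if mode == "deterministic":
        N_new = pop.N * (protocol.sample_size / total)
    elif mode == "multinomial":
        if rng is None:
            raise ValueError("multinomial dilution needs a seeded Generator")
        N_new = rng.multinomial(
            int(round(protocol.sample_size)), pop.N / total).astype(float)
    else:
        raise ValueError(f"unknown dilution mode '{mode}'")
    return PopulationState(N=N_new, s_X=protocol.substrate_reset,
                           cells=pop.cells.copy())


def run_evolution(circuit: CircuitSpec, host: HostParams | None = None,
                  scheme: MutationScheme | None = None,
                  protocol: BatchProtocol | None = None,
                  dilution: str = "deterministic",
                  seed: int | None = None,
                  rtol: float = 1e-6) -> EvolutionTrace:
    """Simulate the repeated-batch evolution of one circuit design.

    Starts from a population of ``sample_size`` fully functional cells at
    the ancestral intracellular steady state, then alternates
    :func:`run_batch_day` and :func:`dilute` until the daily-endpoint
    population output falls below ``stop_fraction`` of its day-1 value or
    ``max_days`` is reached.
    """
    host = host or HostParams()
    protocol = protocol or BatchProtocol()
    model = PopulationModel(host, circuit, scheme)
    rng = np.random.default_rng(seed) if dilution == "multinomial" else None
    pop = model.ancestral_population(protocol)

    ts, Ns, sXs, pAs, lams, TLAs, Qs = [], [], [], [], [], [], []
    day_end_idx = []
    n_stored = 0
    P0 = None
    q = 0.0
    for day in range(protocol.max_days):
        try:
            sol, end, q = run_batch_day(pop, model, protocol, rtol=rtol,
                                        q_cum=q)
        except RuntimeError as err:
            raise RuntimeError(f"day {day + 1}: {err}") from err
        offset = day * protocol.day_minutes
        # drop the duplicated first sample on subsequent days
        take = slice(1 if day > 0 else 0, None)
        S, D = model.S, model.D
        cells_t = sol.y[1 + S:1 + S + S * D, :].T.reshape(-1, S, D)
        N_t = np.maximum(sol.y[1:1 + S, :].T, 0.0)        # (T, S)
        lam_t = np.stack([model.cell_model.growth(c) for c in cells_t])
        tl_t = np.stack([model.cell_model.translation_fluxes(c)["A"]
                         for c in cells_t])
        pA_t = cells_t[:, :, model.cell_model.idx["p_A"]]
        ts.append(sol.t[take] + offset)
        Ns.append(N_t[take])
        sXs.append(np.maximum(sol.y[0, take], 0.0))
        pAs.append(pA_t[take])
        lams.append(lam_t[take])
        TLAs.append(tl_t[take])
        Qs.append(sol.y[-1, take])
        n_stored += len(sol.t[take])
        day_end_idx.append(n_stored - 1)

        P_end = float(np.dot(end.N, end.cells[:, model.cell_model.idx["p_A"]]))
        if P0 is None:
            P0 = P_end
        if P0 > 0 and P_end < protocol.stop_fraction * P0:
            break
        if day < protocol.max_days - 1:
            pop = dilute(end, protocol, mode=dilution, rng=rng)

    N = np.concatenate(Ns)
    pA = np.concatenate(pAs)
    trace = EvolutionTrace(
        t=np.concatenate(ts), N=N, s_X=np.concatenate(sXs),
        p_A=pA, lam=np.concatenate(lams), T_L_A=np.concatenate(TLAs),
        P=np.einsum("ts,ts->t", N, pA),
        day_end_idx=np.asarray(day_end_idx, dtype=int),
        states=model.scheme.states,
        Q_cum=np.concatenate(Qs))
    return trace
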