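"""Mechanistic single-cell model of bacterial gene expression and growth.

The host is described by the coarse-grained resource-allocation model of
bacterial physiology in which a cell expresses four endogenous gene classes
— transporter, metabolic enzyme, ribosomal and housekeeping — that compete
for a shared pool of ribosomes ``R`` and anabolites ``e``.  External
substrate is imported (transporter ``p_t``), catabolised into anabolites
(enzyme ``p_m``), and anabolites power translation.  Translation of each
transcript proceeds through an mRNA–ribosome "translation complex''; the
elongation rate saturates in the anabolite pool,

    gamma(e) = gamma_max * e / (K_gamma + e),

and the growth rate emerges from the total translation flux normalised by
the cell mass,

    lambda = gamma(e) * (sum of all translation complexes) / M.

Every species is diluted at rate ``lambda``.  A synthetic circuit
(:class:`~circuitevo.circuits.CircuitSpec`) adds its own transcripts,
complexes, proteins and sRNAs to the same pools, which couples circuit
expression to growth and produces the burden phenomenon: circuit
expression diverts ribosomes and anabolites, lowering ``lambda``.

Units are molecules/cell (mc) and minutes throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .circuits import CircuitSpec, RegulatoryInputs, sequestration_flux

__all__ = [
    "HostParams",
    "GrowthOutput",
    "CellModel",
    "HOST_SPECIES",
    "cell_odes",
    "growth_rate",
    "initial_cell_state",
    "SteadyStateError",
]


class SteadyStateError(RuntimeError):
    """Steady-state initialisation failed to converge."""


@dataclass(frozen=True)
class HostParams:
    """Host parameterisation (E. coli defaults, fitted literature values).

    Rates are per minute, abundances molecules/cell, lengths amino acids.
    ``v_t``/``K_t`` import, ``v_m``/``K_m``/``n_s`` catabolism (``n_s``
    anabolites per substrate molecule), ``gamma_max``/``K_gamma`` peptide
    elongation, ``M`` total protein mass per cell (aa), ``k_b``/``k_u``
    ribosome (un)binding for host transcripts, ``w_*``/``theta_*``/``K_q``
    transcriptional regulation of the host gene classes, ``n_r``/``n_x``
    protein lengths, ``d_m`` mRNA degradation.

    ``tx_energy``/``tx_cost`` enable the optional transcription-energy
    extension: each transcribed nucleotide additionally drains ``tx_cost``
    anabolites.  With the flag off the coefficient is ignored.
    """

    v_t: float = 726.0
    K_t: float = 1000.0
    v_m: float = 5800.0
    K_m: float = 1000.0
    n_s: float = 0.5
    gamma_max: float = 1260.0
    K_gamma: float = 6.9946
    M: float = 1e8
    k_b: float = 1.0
    k_u: float = 1.0
    w_r: float = 929.9678874564831
    w_e: float = 4.139172187824451
    w_q: float = 948.9349882947897
    theta_r: float = 426.8693338968694
    theta_nr: float = 4.379733394834643
    K_q: float = 152219.0403737490
    h_q: float = 4.0
    n_r: int = 7549
    n_x: int = 300
    d_m: float = 0.1
    tx_energy: bool = False
    tx_cost: float = 0.0

    def __post_init__(self) -> None:
        for name in ("v_t", "v_m", "n_s", "gamma_max", "M", "k_b", "k_u",
                     "w_r", "w_e", "w_q", "d_m", "tx_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"host rate {name} must be >= 0")
        for name in ("K_t", "K_m", "K_gamma", "theta_r", "theta_nr", "K_q"):
            if getattr(self, name) <= 0:
                raise ValueError(f"half-saturation {name} must be > 0")
        if self.n_r < 1 or self.n_x < 1:
            raise ValueError("protein lengths must be >= 1 aa")


@dataclass(frozen=True)
class GrowthOutput:
    """Growth rate ``lam`` (1/min) and per-gene translation fluxes
    (protein completions per cell per minute)."""

    lam: float
    translation_flux: Mapping[str, float]


#: Host state variables, in storage order.  ``s_i`` internal substrate,
#: ``e`` anabolites, ``R`` free ribosomes; per host class x: transcript
#: ``m_x`` and translation complex ``c_x``; proteins ``p_t``, ``p_m``,
#: ``p_q`` (ribosomal protein is the ``R`` pool itself).
HOST_SPECIES: tuple[str, ...] = (
    "s_i", "e", "R",
    "m_r", "c_r", "m_t", "c_t", "m_m", "c_m", "m_q", "c_q",
    "p_t", "p_m", "p_q",
)


class CellModel:
    """Binds a :class:`HostParams` and a :class:`CircuitSpec` into a
    vectorised ODE right-hand side.

    State arrays have shape ``(n_strains, n_species)``; all operations are
    vectorised over strains so that a whole mutation lattice integrates in
    one call.  Species order: the 14 host variables then the circuit
    species in :meth:`CircuitSpec.species` order.
    """

    def __init__(self, host: HostParams, circuit: CircuitSpec | None = None):
        self.host = host
        self.circuit = circuit
        names = list(HOST_SPECIES)
        if circuit is not None:
            names += list(circuit.species())
        self.species: tuple[str, ...] = tuple(names)
        self.idx: dict[str, int] = {n: i for i, n in enumerate(names)}
        self.n_species = len(names)

        # circuit bookkeeping: protein genes (m, c, p) and sRNA genes (r)
        self._protein_genes = []
        self._srna_genes = []
        if circuit is not None:
            for g in circuit.genes:
                if g.is_srna:
                    self._srna_genes.append(
                        (g, self.idx[f"r_{g.name}"]))
                else:
                    self._protein_genes.append(
                        (g, self.idx[f"m_{g.name}"], self.idx[f"c_{g.name}"],
                         self.idx[f"p_{g.name}"]))
            self._seq_pairs = [
                (self.idx[f"m_{m}"], self.idx[f"r_{s}"])
                for m, s in circuit.sequestration]
            self._mut_col = {p: i for i, p in
                            enumerate(circuit.mutable_promoters)}
        else:
            self._seq_pairs = []
            self._mut_col = {}
        self._complex_idx = np.array(
            [self.idx[n] for n in names if n.startswith("c_")], dtype=int)

        # flattened transcript-class arrays (host classes then circuit
        # protein genes) for a vectorised right-hand side
        h = host
        im = [self.idx["m_r"], self.idx["m_t"], self.idx["m_m"], self.idx["m_q"]]
        ic = [self.idx["c_r"], self.idx["c_t"], self.idx["c_m"], self.idx["c_q"]]
        n_aa = [h.n_r, h.n_x, h.n_x, h.n_x]
        kb = [h.k_b] * 4
        deg = [h.d_m] * 4
        # product slot: ribosomal class feeds R (flag -1), others a protein
        prod = [-1, self.idx["p_t"], self.idx["p_m"], self.idx["p_q"]]
        for g, gm, gc, gp in self._protein_genes:
            im.append(gm); ic.append(gc); n_aa.append(g.length_aa)
            kb.append(g.b); deg.append(g.mrna_deg); prod.append(gp)
        self._im = np.array(im); self._ic = np.array(ic)
        self._n_aa = np.array(n_aa, dtype=float)
        self._kb = np.array(kb, dtype=float)
        self._deg = np.array(deg, dtype=float)
        prod = np.array(prod)
        self._prod_mask = prod >= 0
        self._prod_idx = prod[self._prod_mask]

    # -- observables -------------------------------------------------------

    def gamma(self, e):
        h = self.host
        return h.gamma_max * np.maximum(e, 0.0) / (h.K_gamma + np.maximum(e, 0.0))

    def growth(self, Y):
        """Growth rate per strain: lambda = gamma(e) * sum(c) / M."""
        Y = np.atleast_2d(Y)
        gam = self.gamma(Y[:, self.idx["e"]])
        ctot = Y[:, self._complex_idx].sum(axis=1)
        return gam * ctot / self.host.M

    def import_flux(self, Y, s_ext: float):
        """Per-cell substrate import rate (molecules/cell/min)."""
        h = self.host
        Y = np.atleast_2d(Y)
        return Y[:, self.idx["p_t"]] * h.v_t * max(s_ext, 0.0) / (h.K_t + max(s_ext, 0.0))

    def translation_fluxes(self, Y):
        """Per-gene protein completion rates, keyed by gene name (host
        classes 'r', 't', 'm', 'q' and circuit genes)."""
        Y = np.atleast_2d(Y)
        gam = self.gamma(Y[:, self.idx["e"]])
        h = self.host
        out = {
            "r": gam * Y[:, self.idx["c_r"]] / h.n_r,
            "t": gam * Y[:, self.idx["c_t"]] / h.n_x,
            "m": gam * Y[:, self.idx["c_m"]] / h.n_x,
            "q": gam * Y[:, self.idx["c_q"]] / h.n_x,
        }
        for g, im, ic, ip in self._protein_genes:
            out[g.name] = gam * Y[:, ic] / g.length_aa
        return out

    # -- right-hand side ---------------------------------------------------

    def rhs(self, Y, s_ext: float, levels=None, population_output: float = 0.0):
        """Time derivative of the cell state.

        ``Y``: (S, D) or (D,) state; ``levels``: (S, n_mutable) functional
        levels in [0, 1] for the mutable promoters (default fully
        functional); ``population_output``: total population output P fed
        to population-sensing controllers.
        """
        single = np.ndim(Y) == 1
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        S = Y.shape[0]
        h = self.host
        ix = self.idx
        dY = np.zeros_like(Y)

        e = Y[:, ix["e"]]
        R = Y[:, ix["R"]]
        ep = np.maximum(e, 0.0)
        gam = h.gamma_max * ep / (h.K_gamma + ep)
        ctot = Y[:, self._complex_idx].sum(axis=1)
        lam = gam * ctot / h.M

        # -- metabolism
        si = Y[:, ix["s_i"]]
        sip = np.maximum(si, 0.0)
        se = max(s_ext, 0.0)
        v_imp = Y[:, ix["p_t"]] * h.v_t * se / (h.K_t + se)
        v_cat = Y[:, ix["p_m"]] * h.v_m * sip / (h.K_m + sip)
        dY[:, ix["s_i"]] = v_imp - v_cat - lam * si
        # total translation consumes gamma * ctot anabolites per minute
        de = h.n_s * v_cat - gam * ctot - lam * e

        # -- transcription rates per transcript class (S, C)
        f_nr = ep / (h.theta_nr + ep)
        W = np.empty((S, len(self._im)))
        W[:, 0] = h.w_r * ep / (h.theta_r + ep)
        W[:, 1] = h.w_e * f_nr
        W[:, 2] = W[:, 1]
        W[:, 3] = (h.w_q * f_nr
                   / (1.0 + (np.maximum(Y[:, ix["p_q"]], 0.0) / h.K_q) ** h.h_q))
        tx_nt = 3.0 * (h.n_r * W[:, 0] + h.n_x * (W[:, 1] + W[:, 2] + W[:, 3]))

        w_gene: dict[str, np.ndarray] = {}
        if self.circuit is not None:
            # regulation observables clamped at 0: the solver's Jacobian
            # probes may step a hair below zero
            obs = RegulatoryInputs(
                p={g.name: np.maximum(Y[:, ip], 0.0)
                   for g, _, _, ip in self._protein_genes},
                lam=np.maximum(lam, 0.0),
                P=max(population_output, 0.0))
            if levels is None:
                lv = np.ones((S, len(self._mut_col)))
            else:
                lv = np.atleast_2d(np.asarray(levels, dtype=float))
            # circuit transcription saturates in the anabolite pool like the
            # non-ribosomal host genes (starved cells stop transcribing)
            for prom in self.circuit.promoters:
                w = (prom.omega * f_nr
                     * np.asarray(prom.factor(obs), dtype=float))
                if prom.mutable:
                    w = w * lv[:, self._mut_col[prom.name]]
                w = np.broadcast_to(w, (S,))
                for gname in prom.genes:
                    w_gene[gname] = w
                g0 = self.circuit.gene(prom.genes[0])
                nt = (g0.srna_nt if g0.is_srna else 3 * g0.length_aa)
                tx_nt = tx_nt + nt * w * len(prom.genes)
            for k, (g, _, _, _) in enumerate(self._protein_genes):
                W[:, 4 + k] = w_gene[g.name]

        # -- all transcript classes at once: mRNA, complex, product
        m = Y[:, self._im]
        c = Y[:, self._ic]
        bind = self._kb * R[:, None] * m
        unbind = h.k_u * c
        complete = gam[:, None] * c / self._n_aa
        dY[:, self._im] = (W - (lam[:, None] + self._deg) * m
                           - bind + unbind + complete)
        dY[:, self._ic] = bind - unbind - complete - lam[:, None] * c
        # ribosome pool: release from every class + new ribosomes (class 0)
        dR = (unbind + complete - bind).sum(axis=1) + complete[:, 0] - lam * R
        dY[:, self._prod_idx] = (complete[:, self._prod_mask]
                                 - lam[:, None] * Y[:, self._prod_idx])

        if self.circuit is not None:
            for g, ir in self._srna_genes:
                dY[:, ir] = (w_gene[g.name]
                             - (lam + g.mrna_deg) * Y[:, ir])
            for im_i, ir in self._seq_pairs:
                flux = sequestration_flux(
                    np.maximum(Y[:, im_i], 0.0), np.maximum(Y[:, ir], 0.0),
                    self.circuit.params.seq_rate)
                dY[:, im_i] -= flux
                dY[:, ir] -= flux

        if h.tx_energy:
            de = de - h.tx_cost * tx_nt
        dY[:, ix["e"]] = de
        dY[:, ix["R"]] = dR
        return dY[0] if single else dY

    # -- steady state ------------------------------------------------------

    def steady_state(self, s_ext: float = 1e12, population_output: float = 0.0,
                     t_long: float = 1e5, tol: float = 1e-6,
                     y0: np.ndarray | None = None) -> np.ndarray:
        """Nutrient-replete single-cell steady state.

        Integrates the stiff cell ODEs to ``t_long`` minutes from a small
        positive seed, then polishes with a root solve if the residual
        exceeds ``tol`` (max-norm of the scaled derivative).  Raises
        :class:`SteadyStateError` if neither route converges.
        """
        if y0 is None:
            y0 = np.full(self.n_species, 1.0)
            y0[self.idx["s_i"]] = 100.0
            y0[self.idx["e"]] = 100.0
            y0[self.idx["R"]] = 10.0

        def f(t, y):
            return self.rhs(y, s_ext, population_output=population_output)

        sol = solve_ivp(f, (0.0, t_long), y0, method="BDF",
                        rtol=1e-8, atol=1e-10)
        y = sol.y[:, -1]

        def residual(y):
            dy = self.rhs(y, s_ext, population_output=population_output)
            return np.max(np.abs(dy) / np.maximum(1.0, np.abs(y)))

        res = residual(y)
        if res > tol:
            polished = root(lambda z: self.rhs(z, s_ext,
                                               population_output=population_output),
                            y, method="hybr")
            if polished.success and np.all(polished.x > -1e-9):
                cand = np.maximum(polished.x, 0.0)
                if residual(cand) < res:
                    y, res = cand, residual(cand)
        if res > tol:
            raise SteadyStateError(
                f"steady state did not converge: residual {res:.3e} > {tol:.1e}")
        if np.any(y < -1e-9):
            raise SteadyStateError("steady state contains negative species")
        return np.maximum(y, 0.0)


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def cell_odes(state, host: HostParams, circuit: CircuitSpec | None = None,
              s_ext: float = 1e12, levels=None,
              population_output: float = 0.0):
    """Time derivative of a single cell state (see :class:`CellModel.rhs`)."""
    state = np.asarray(state, dtype=float)
    if np.any(~np.isfinite(state)) or np.any(state < 0):
        raise ValueError("cell state must be finite and non-negative")
    return CellModel(host, circuit).rhs(
        state, s_ext, levels=levels, population_output=population_output)


def growth_rate(state, host: HostParams,
                circuit: CircuitSpec | None = None) -> GrowthOutput:
    """Growth rate and per-gene translation fluxes for a cell state."""
    model = CellModel(host, circuit)
    state = np.asarray(state, dtype=float)
    lam = float(model.growth(state)[0])
    tl = {k: float(v[0]) for k, v in model.translation_fluxes(state).items()}
    return GrowthOutput(lam=lam, translation_flux=tl)


def initial_cell_state(host: HostParams, circuit: CircuitSpec | None = None,
                       s_ext: float = 1e12, population_output: float = 0.0,
                       tol: float = 1e-6) -> np.ndarray:
    """Ancestral (day-0, nutrient-replete) steady state of the cell model."""
    return CellModel(host, circuit).steady_state(
        s_ext=s_ext, population_output=population_output, tol=tol)
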