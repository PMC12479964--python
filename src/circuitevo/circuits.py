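"""Circuit and controller topology builders.

A circuit is a small synthetic gene network layered on top of the host cell
model: a "process" gene ``A`` (e.g. a fluorescent reporter or an enzyme)
whose expression we want to keep stable over evolutionary time, plus the
regulator genes of an optional feedback controller.  Each topology declares

* its genes (protein-coding or small RNA),
* its promoters — which genes each promoter transcribes, its maximal
  transcription rate, and a quasi-steady-state Hill regulation law,
* which promoters are *mutable* (they enter the mutation lattice), and
* which sRNA/mRNA pairs undergo bimolecular sequestration.

The host model consumes a :class:`CircuitSpec` and turns these declarations
into ODE fluxes.  Controller names follow the field convention
``CL<input><actuation>``: the input is the per-cell output protein ``pA``
(intra-circuit feedback), the growth rate ``lam`` (burden/stress sensing) or
the population output ``P`` (quorum sensing); actuation is transcriptional
(``TX``, an inhibitory transcription factor), translational (``TL``, an
sRNA that silences the target mRNA) or protein-free (``PF``, the sRNA gene
sits directly on a growth-sensitive promoter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "GeneSpec",
    "ControllerParams",
    "Promoter",
    "CircuitSpec",
    "RegulatoryInputs",
    "hill_repress",
    "hill_activate",
    "sequestration_flux",
    "effective_transcription",
    "build_circuit",
    "design",
    "TOPOLOGIES",
]


class ConfigurationError(ValueError):
    """A circuit/controller description is internally inconsistent."""


# ---------------------------------------------------------------------------
# Hill regulation primitives
# ---------------------------------------------------------------------------

def _check_hill_args(x, k: float, h: float) -> None:
    if k <= 0:
        raise ValueError(f"Hill constant must be positive, got k={k}")
    if h <= 0:
        raise ValueError(f"Hill coefficient must be positive, got h={h}")
    if np.any(np.asarray(x) < 0):
        raise ValueError("regulator abundance must be non-negative")


def hill_repress(x, k: float, h: float = 2.0):
    """Repressive Hill factor ``k^h / (k^h + x^h)`` in [0, 1].

    ``x`` is the regulator abundance (same units as ``k``); the factor is 1
    with no regulator and 1/2 at half-saturation ``x = k``.
    """
    _check_hill_args(x, k, h)
    a = (np.asarray(x, dtype=float) / k) ** h
    out = 1.0 / (1.0 + a)
    return out if out.ndim else float(out)


def hill_activate(x, k: float, h: float = 2.0):
    """Activating Hill factor ``x^h / (k^h + x^h)``; complement of
    :func:`hill_repress` (the two sum to 1)."""
    _check_hill_args(x, k, h)
    a = (np.asarray(x, dtype=float) / k) ** h
    out = a / (1.0 + a)
    return out if out.ndim else float(out)


def sequestration_flux(m, r, rate_constant: float):
    """Bilinear sRNA sequestration flux ``rate * m * r`` (mc/min).

    One mRNA and one sRNA are removed per event (irreversible
    co-degradation), so the flux appears with coefficient -1 in both species'
    derivatives.
    """
    return rate_constant * np.asarray(m, dtype=float) * np.asarray(r, dtype=float)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    """One gene of a circuit.

    Parameters are in molecules/cell (mc) and minutes: maximal transcription
    rate ``omega`` (mc/min), ribosome binding rate ``b`` (per mc per min),
    protein length ``length_aa`` (aa) and mRNA degradation rate ``mrna_deg``
    (1/min).  sRNA genes have no protein product: ``b = 0`` and
    ``length_aa`` is ignored; ``srna_nt`` is the transcript length used only
    by the optional transcription-energy extension.
    """

    name: str
    omega: float
    b: float = 1.0
    length_aa: int = 300
    mrna_deg: float = 0.1
    is_srna: bool = False
    srna_nt: int = 100

    def __post_init__(self) -> None:
        if self.omega < 0 or self.b < 0 or self.mrna_deg < 0:
            raise ConfigurationError(f"gene {self.name}: rates must be >= 0")
        if self.is_srna:
            if self.b != 0:
                raise ConfigurationError(
                    f"sRNA gene {self.name} cannot bind ribosomes (b must be 0)")
        elif self.length_aa < 1:
            raise ConfigurationError(
                f"gene {self.name}: protein length must be >= 1 aa")


@dataclass(frozen=True)
class ControllerParams:
    """Kinetic constants of the feedback laws.

    Only the constants referenced by the active topology are required; the
    rest may stay ``None``.  ``k_A`` (mc), ``k_P`` (molecules) and the
    ``k_B*`` constants (mc) are repression/activation half-saturations;
    ``k_lambda`` (1/min) is the growth-sensing half-saturation; ``hill`` is
    the shared Hill coefficient; ``seq_rate`` (per mc per min) is the
    sRNA-mRNA sequestration rate constant.
    """

    k_A: float | None = None
    k_lambda: float | None = None
    k_P: float | None = None
    k_B: float | None = None
    k_B1: float | None = None
    k_B2: float | None = None
    hill: float = 2.0
    seq_rate: float = 1e-2

    def require(self, topology: str, *names: str) -> None:
        for n in names:
            v = getattr(self, n)
            if v is None:
                raise ConfigurationError(
                    f"topology {topology} requires controller constant '{n}'")
            if v <= 0:
                raise ConfigurationError(
                    f"controller constant '{n}' must be > 0, got {v}")


@dataclass(frozen=True)
class RegulatoryInputs:
    """Snapshot of the quantities a promoter may sense.

    ``p`` maps gene name to per-cell protein abundance (scalars or arrays,
    one entry per strain), ``lam`` is the instantaneous growth rate (1/min)
    and ``P`` the population-wide output (molecules).
    """

    p: Mapping[str, object]
    lam: object = 0.0
    P: float = 0.0


@dataclass(frozen=True)
class Promoter:
    name: str
    genes: tuple[str, ...]
    omega: float
    mutable: bool = False
    regulation: Callable[[RegulatoryInputs], object] | None = None

    def factor(self, obs: RegulatoryInputs):
        return 1.0 if self.regulation is None else self.regulation(obs)


@dataclass(frozen=True)
class CircuitSpec:
    """A validated circuit/controller topology bound to its parameters."""

    topology: str
    genes: tuple[GeneSpec, ...]
    promoters: tuple[Promoter, ...]
    params: ControllerParams
    sequestration: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate gene names")
        declared = set(names)
        promoted = [g for p in self.promoters for g in p.genes]
        if set(promoted) != declared or len(promoted) != len(declared):
            raise ConfigurationError(
                "every gene must be driven by exactly one promoter")
        for m, s in self.sequestration:
            if m not in declared or s not in declared:
                raise ConfigurationError(
                    f"sequestration pair ({m}, {s}) references unknown gene")
            if self.gene(m).is_srna or not self.gene(s).is_srna:
                raise ConfigurationError(
                    f"sequestration pair ({m}, {s}) must be (mRNA, sRNA)")
        n = len(self.mutable_promoters)
        if not 1 <= n <= 3:
            raise ConfigurationError(
                f"topology {self.topology} declares {n} mutable promoters; "
                "expected 1-3")

    def gene(self, name: str) -> GeneSpec:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    @property
    def mutable_promoters(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.promoters if p.mutable)

    @property
    def n_mutation_states(self) -> int:
        return 4 ** len(self.mutable_promoters)

    def species(self) -> tuple[str, ...]:
        """Ordered circuit species names: m_X, c_X, p_X per protein gene,
        r_X per sRNA gene."""
        out: list[str] = []
        for g in self.genes:
            if g.is_srna:
                out.append(f"r_{g.name}")
            else:
                out.extend((f"m_{g.name}", f"c_{g.name}", f"p_{g.name}"))
        return tuple(out)

    def promoter_of(self, gene_name: str) -> Promoter:
        for p in self.promoters:
            if gene_name in p.genes:
                return p
        raise KeyError(gene_name)

    def with_params(self, **changes) -> "CircuitSpec":
        """Rebuild this topology with updated named parameters (see
        :func:`design`)."""
        current = _named_parameters(self)
        current.update(changes)
        return design(self.topology, **current)


def effective_transcription(
    spec: CircuitSpec,
    obs: RegulatoryInputs,
    levels: Mapping[str, float] | None = None,
) -> dict[str, object]:
    """Per-gene effective transcription rates ``w`` (mc/min).

    Applies each promoter's regulation factor and (optionally) its mutation
    functional level (fraction of the designed maximum, 1.0 = intact).
    Genes sharing a promoter share its rate.
    """
    levels = levels or {}
    w: dict[str, object] = {}
    for prom in spec.promoters:
        rate = prom.omega * levels.get(prom.name, 1.0) * prom.factor(obs)
        for g in prom.genes:
            w[g] = rate
    return w


# ---------------------------------------------------------------------------
# Topology registry
# ---------------------------------------------------------------------------

#: Default kinetic parameters.  These are the nominal study conditions used
#: throughout: a moderate process (omega_A = 5 mc/min), bacterial-regulator
#: length controllers (n_B = 300 aa), cheap abundant sRNA (omega_C = 50
#: mc/min) and growth sensing in the high-sensitivity regime.
DEFAULTS = dict(
    omega_A=5.0, omega_B=10.0, omega_C=50.0,
    b_A=1.0, b_B=1.0, b_B2=1.0,
    n_A=300, n_B=300,
    mrna_deg=0.1,
    k_A=500.0, k_lambda=0.01, k_P=1e9,
    k_B=100.0, k_B1=100.0, k_B2=100.0,
    hill=2.0, seq_rate=1e-2,
)


def _params(d: dict) -> ControllerParams:
    return ControllerParams(
        k_A=d["k_A"], k_lambda=d["k_lambda"], k_P=d["k_P"],
        k_B=d["k_B"], k_B1=d["k_B1"], k_B2=d["k_B2"],
        hill=d["hill"], seq_rate=d["seq_rate"])


def _gene_A(d: dict) -> GeneSpec:
    return GeneSpec("A", omega=d["omega_A"], b=d["b_A"], length_aa=d["n_A"],
                    mrna_deg=d["mrna_deg"])


def _gene_B(d: dict, name: str = "B", b_key: str = "b_B") -> GeneSpec:
    return GeneSpec(name, omega=d["omega_B"], b=d[b_key], length_aa=d["n_B"],
                    mrna_deg=d["mrna_deg"])


def _gene_C(d: dict) -> GeneSpec:
    return GeneSpec("C", omega=d["omega_C"], b=0.0, is_srna=True,
                    mrna_deg=d["mrna_deg"])


def _build_topology(name: str, d: dict) -> CircuitSpec:
    h = d["hill"]
    pars = _params(d)
    A, wA = _gene_A(d), d["omega_A"]

    def rep_p(gene: str, k: float):
        return lambda obs: hill_repress(obs.p[gene], k, h)

    def act_p(gene: str, k: float):
        return lambda obs: hill_activate(obs.p[gene], k, h)

    def act_lam(k: float):  # process production inhibited at low growth
        return lambda obs: hill_activate(obs.lam, k, h)

    def rep_lam(k: float):  # stress promoter: active at low growth
        return lambda obs: hill_repress(obs.lam, k, h)

    def rep_P(k: float):
        return lambda obs: hill_repress(obs.P, k, h)

    if name == "OL":
        pars.require(name)
        return CircuitSpec(name, (A,), (Promoter("A", ("A",), wA, True),), pars)

    if name == "PHEN_PA":
        pars.require(name, "k_A")
        reg = rep_p("A", d["k_A"])
        return CircuitSpec(name, (A,), (Promoter("A", ("A",), wA, True, reg),), pars)

    if name == "PHEN_LAMBDA":
        pars.require(name, "k_lambda")
        reg = act_lam(d["k_lambda"])
        return CircuitSpec(name, (A,), (Promoter("A", ("A",), wA, True, reg),), pars)

    if name in ("PHEN_POP", "QS_POP"):
        # QS_POP is the quasi-steady-state reduction of a fast quorum-sensing
        # signal pool: with signal synthesis proportional to the population
        # output and fast turnover, the sensed signal tracks P and the
        # regulation collapses to Theta(P).
        pars.require(name, "k_P")
        reg = rep_P(d["k_P"])
        return CircuitSpec(name, (A,), (Promoter("A", ("A",), wA, True, reg),), pars)

    if name == "PHEN_DUAL":
        pars.require(name, "k_A", "k_lambda")
        rp, rl = rep_p("A", d["k_A"]), act_lam(d["k_lambda"])

        def reg(obs):
            return rp(obs) * rl(obs)
        return CircuitSpec(name, (A,), (Promoter("A", ("A",), wA, True, reg),), pars)

    if name == "CLpATX":
        pars.require(name, "k_B")
        B = _gene_B(d)
        reg = rep_p("B", d["k_B"])
        return CircuitSpec(
            name, (A, B),
            (Promoter("AB", ("A", "B"), wA, True, reg),), pars)

    if name == "CLpATL":
        pars.require(name, "k_B")
        B, C = _gene_B(d), _gene_C(d)
        return CircuitSpec(
            name, (A, B, C),
            (Promoter("AB", ("A", "B"), wA, True),
             Promoter("C", ("C",), d["omega_C"], True, act_p("B", d["k_B"]))),
            pars, sequestration=(("A", "C"), ("B", "C")))

    if name == "CLlamTX":
        pars.require(name, "k_B", "k_lambda")
        B = _gene_B(d)
        return CircuitSpec(
            name, (A, B),
            (Promoter("A", ("A",), wA, True, rep_p("B", d["k_B"])),
             Promoter("B", ("B",), d["omega_B"], True, rep_lam(d["k_lambda"]))),
            pars)

    if name == "CLlamTL":
        pars.require(name, "k_B", "k_lambda")
        B, C = _gene_B(d), _gene_C(d)
        return CircuitSpec(
            name, (A, B, C),
            (Promoter("A", ("A",), wA, True),
             Promoter("B", ("B",), d["omega_B"], True, rep_lam(d["k_lambda"])),
             Promoter("C", ("C",), d["omega_C"], True, act_p("B", d["k_B"]))),
            pars, sequestration=(("A", "C"),))

    if name == "CLlamPF":
        pars.require(name, "k_lambda")
        C = _gene_C(d)
        return CircuitSpec(
            name, (A, C),
            (Promoter("A", ("A",), wA, True),
             Promoter("C", ("C",), d["omega_C"], True, rep_lam(d["k_lambda"]))),
            pars, sequestration=(("A", "C"),))

    if name == "CLpATXlamTL":
        # protein arm inhibits the shared promoter; growth arm drives an
        # sRNA (via regulator B2) that silences the process mRNA.
        pars.require(name, "k_B1", "k_B2", "k_lambda")
        B1 = _gene_B(d, "B1")
        B2 = _gene_B(d, "B2", b_key="b_B2")
        C = _gene_C(d)
        return CircuitSpec(
            name, (A, B1, B2, C),
            (Promoter("AB1", ("A", "B1"), wA, True, rep_p("B1", d["k_B1"])),
             Promoter("B2", ("B2",), d["omega_B"], True, rep_lam(d["k_lambda"])),
             Promoter("C", ("C",), d["omega_C"], True, act_p("B2", d["k_B2"]))),
            pars, sequestration=(("A", "C"),))

    if name == "CLpATLlamTX":
        # protein arm activates the sRNA; growth arm's regulator B2
        # inhibits transcription of the shared promoter.
        pars.require(name, "k_B1", "k_B2", "k_lambda")
        B1 = _gene_B(d, "B1")
        B2 = _gene_B(d, "B2", b_key="b_B2")
        C = _gene_C(d)
        return CircuitSpec(
            name, (A, B1, B2, C),
            (Promoter("AB1", ("A", "B1"), wA, True, rep_p("B2", d["k_B2"])),
             Promoter("B2", ("B2",), d["omega_B"], True, rep_lam(d["k_lambda"])),
             Promoter("C", ("C",), d["omega_C"], True, act_p("B1", d["k_B1"]))),
            pars, sequestration=(("A", "C"), ("B1", "C")))

    if name == "CLpATLlamTL":
        # both arms co-operatively activate the sRNA.
        pars.require(name, "k_B1", "k_B2", "k_lambda")
        B1 = _gene_B(d, "B1")
        B2 = _gene_B(d, "B2", b_key="b_B2")
        C = _gene_C(d)
        a1, a2 = act_p("B1", d["k_B1"]), act_p("B2", d["k_B2"])

        def reg_c(obs):
            return a1(obs) * a2(obs)
        return CircuitSpec(
            name, (A, B1, B2, C),
            (Promoter("AB1", ("A", "B1"), wA, True),
             Promoter("B2", ("B2",), d["omega_B"], True, rep_lam(d["k_lambda"])),
             Promoter("C", ("C",), d["omega_C"], True, reg_c)),
            pars, sequestration=(("A", "C"), ("B1", "C")))

    if name == "CLpATXlamTX":
        # both arms inhibit transcription of the shared promoter.
        pars.require(name, "k_B1", "k_B2", "k_lambda")
        B1 = _gene_B(d, "B1")
        B2 = _gene_B(d, "B2", b_key="b_B2")
        r1, r2 = rep_p("B1", d["k_B1"]), rep_p("B2", d["k_B2"])

        def reg_ab(obs):
            return r1(obs) * r2(obs)
        return CircuitSpec(
            name, (A, B1, B2),
            (Promoter("AB1", ("A", "B1"), wA, True, reg_ab),
             Promoter("B2", ("B2",), d["omega_B"], True, rep_lam(d["k_lambda"]))),
            pars)

    if name == "CLpATLlamPF":
        # protein arm activates the sRNA whose promoter is itself
        # growth-sensitive (no second regulator protein).
        pars.require(name, "k_B1", "k_lambda")
        B1 = _gene_B(d, "B1")
        C = _gene_C(d)
        a1, rl = act_p("B1", d["k_B1"]), rep_lam(d["k_lambda"])

        def reg_c(obs):
            return a1(obs) * rl(obs)
        return CircuitSpec(
            name, (A, B1, C),
            (Promoter("AB1", ("A", "B1"), wA, True),
             Promoter("C", ("C",), d["omega_C"], True, reg_c)),
            pars, sequestration=(("A", "C"), ("B1", "C")))

    raise ConfigurationError(f"unknown topology '{name}'")


TOPOLOGIES: tuple[str, ...] = (
    "OL", "PHEN_PA", "PHEN_LAMBDA", "PHEN_POP", "PHEN_DUAL",
    "CLpATX", "CLpATL", "CLlamTX", "CLlamTL", "CLlamPF", "QS_POP",
    "CLpATXlamTL", "CLpATLlamTX", "CLpATLlamTL", "CLpATXlamTX",
    "CLpATLlamPF",
)


def design(topology: str, **overrides) -> CircuitSpec:
    """Build a topology from named kinetic parameters.

    Any of the keys in :data:`DEFAULTS` may be overridden (e.g.
    ``design("CLpATL", omega_A=50, k_B=20, n_B=600)``); unknown keys raise
    a :class:`ConfigurationError`.
    """
    if topology not in TOPOLOGIES:
        raise ConfigurationError(f"unknown topology '{topology}'")
    bad = set(overrides) - set(DEFAULTS)
    if bad:
        raise ConfigurationError(f"unknown design parameters: {sorted(bad)}")
    d = dict(DEFAULTS)
    d.update(overrides)
    return _build_topology(topology, d)


def _named_parameters(spec: CircuitSpec) -> dict:
    """Recover the named-parameter dict a spec was built from."""
    d = dict(DEFAULTS)
    for g in spec.genes:
        prom = spec.promoter_of(g.name)
        if g.name == "A":
            d.update(omega_A=g.omega, b_A=g.b, n_A=g.length_aa,
                     mrna_deg=g.mrna_deg)
        elif g.name in ("B", "B1"):
            d.update(b_B=g.b, n_B=g.length_aa)
            if prom.genes == (g.name,):  # own promoter, not co-transcribed
                d["omega_B"] = prom.omega
        elif g.name == "B2":
            d.update(b_B2=g.b, omega_B=prom.omega, n_B=g.length_aa)
        elif g.is_srna:
            d["omega_C"] = prom.omega
    p = spec.params
    for k in ("k_A", "k_lambda", "k_P", "k_B", "k_B1", "k_B2"):
        v = getattr(p, k)
        if v is not None:
            d[k] = v
    d["hill"] = p.hill
    d["seq_rate"] = p.seq_rate
    return d


def build_circuit(
    topology: str,
    genes: Sequence[GeneSpec] | None = None,
    params: ControllerParams | None = None,
) -> CircuitSpec:
    """Build a validated :class:`CircuitSpec` for ``topology``.

    ``genes`` may override the default gene kinetics (matched by name);
    ``params`` overrides the default controller constants.  The mutable
    promoter list is fixed by the topology: the open-loop process has one
    mutable promoter, the co-transcribed sRNA controllers two, and the
    growth-sensing three-promoter controllers three.
    """
    d = dict(DEFAULTS)
    if params is not None:
        # an explicit ControllerParams is authoritative: constants left None
        # are treated as absent so required ones are reported by name
        for k in ("k_A", "k_lambda", "k_P", "k_B", "k_B1", "k_B2"):
            d[k] = getattr(params, k)
        d["hill"] = params.hill
        d["seq_rate"] = params.seq_rate
    spec = _build_topology(topology, d)
    if genes:
        known = {g.name for g in spec.genes}
        for g in genes:
            if g.name not in known:
                raise ConfigurationError(
                    f"topology {topology} has no gene '{g.name}' "
                    f"(expected {sorted(known)})")
        merged = tuple(
            next((g for g in genes if g.name == old.name), old)
            for old in spec.genes)
        proms = tuple(
            replace(p, omega=next(
                (g.omega for g in merged if g.name == p.genes[0]), p.omega))
            for p in spec.promoters)
        spec = CircuitSpec(topology, merged, proms, spec.params,
                           spec.sequestration)
    return spec
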