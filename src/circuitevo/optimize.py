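"""Multi-objective controller design: tri-objective NSGA-II and grid sweeps.

Controller design is cast as the simultaneous maximisation of the three
longevity objectives

    maximise_u  (P0, tau_pm10, tau_50)   subject to  L <= u <= U,

where ``u`` is the vector of tunable kinetic parameters of a topology
(transcription rates, ribosome binding rates, regulation constants).  The
solver is NSGA-II — fast non-dominated sorting with crowding-distance
selection, simulated binary crossover and polynomial mutation — with
rate-like decision variables searched in log space because their feasible
ranges span decades.  Evaluations (full evolution simulations) are cached
by parameter vector, failures receive worst fitness instead of aborting
the run, and everything is deterministic given a seed.

``tau`` objectives that are not reached within the simulation horizon
enter the optimiser capped at the horizon and are flagged in the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .circuits import design
from .host import HostParams
from .metrics import DesignMetrics, design_metrics
from .mutation import MutationScheme
from .population import BatchProtocol, run_evolution

__all__ = [
    "GASettings",
    "OptimizationProblem",
    "ParetoFront",
    "default_problem",
    "nsga2_maximize",
    "pareto_optimize",
    "sweep_designs",
    "evaluate_design",
]


# ---------------------------------------------------------------------------
# Problem definition
# ---------------------------------------------------------------------------

#: Decision variables per topology: the kinetic parameters that dominate
#: the three objectives (process transcription, controller strength,
#: controller expression), with biologically feasible decade-spanning
#: bounds.  All are searched in log space.
_DECISION_VARS: dict[str, tuple[str, ...]] = {
    "OL": ("omega_A",),
    "PHEN_PA": ("omega_A", "k_A"),
    "PHEN_LAMBDA": ("omega_A", "k_lambda"),
    "PHEN_POP": ("omega_A", "k_P"),
    "QS_POP": ("omega_A", "k_P"),
    "PHEN_DUAL": ("omega_A", "k_A", "k_lambda"),
    "CLpATX": ("omega_A", "k_B", "b_B"),
    "CLpATL": ("omega_A", "k_B", "b_B", "omega_C"),
    "CLlamTX": ("omega_A", "omega_B", "b_B", "k_B", "k_lambda"),
    "CLlamTL": ("omega_A", "omega_B", "omega_C", "b_B", "k_B", "k_lambda"),
    "CLlamPF": ("omega_A", "omega_C", "k_lambda"),
    "CLpATXlamTL": ("omega_A", "omega_B", "omega_C", "b_B", "b_B2",
                    "k_B1", "k_B2", "k_lambda"),
    "CLpATLlamTX": ("omega_A", "omega_B", "omega_C", "b_B", "b_B2",
                    "k_B1", "k_B2", "k_lambda"),
    "CLpATLlamTL": ("omega_A", "omega_B", "omega_C", "b_B", "b_B2",
                    "k_B1", "k_B2", "k_lambda"),
    "CLpATXlamTX": ("omega_A", "omega_B", "b_B", "b_B2",
                    "k_B1", "k_B2", "k_lambda"),
    "CLpATLlamPF": ("omega_A", "omega_C", "b_B", "k_B1", "k_lambda"),
}

_BOUNDS: dict[str, tuple[float, float]] = {
    "omega_A": (0.1, 1000.0),
    "omega_B": (0.1, 1000.0),
    "omega_C": (0.1, 1000.0),
    "b_B": (0.01, 10.0),
    "b_B2": (0.01, 10.0),
    "k_A": (1.0, 1e5),
    "k_B": (1.0, 1e4),
    "k_B1": (1.0, 1e4),
    "k_B2": (1.0, 1e4),
    "k_P": (1e5, 1e11),
    "k_lambda": (1e-3, 0.1),
}


@dataclass(frozen=True)
class GASettings:
    """NSGA-II settings.  The full preset mirrors the reference study
    (population 250, Pareto fraction 0.4, tolerance 1e-4); the scaled-down
    preset (population 40, 30 generations) is for desk-scale runs."""

    pop_size: int = 250
    n_gen: int = 100
    pareto_fraction: float = 0.4
    tol: float = 1e-4
    crossover_prob: float = 0.9
    crossover_eta: float = 15.0
    mutation_eta: float = 20.0

    @classmethod
    def scaled_down(cls, pop_size: int = 40, n_gen: int = 30) -> "GASettings":
        return cls(pop_size=pop_size, n_gen=n_gen)


@dataclass(frozen=True)
class OptimizationProblem:
    """Decision vector, bounds and fixed context for one topology."""

    topology: str
    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    n_B: int = 300
    fixed: dict = field(default_factory=dict)
    host: HostParams | None = None
    scheme_base_rate: float = 1e-5
    scheme_attenuation: float = 0.1
    protocol: BatchProtocol | None = None

    def __post_init__(self) -> None:
        L = np.asarray(self.lower, dtype=float)
        U = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", L)
        object.__setattr__(self, "upper", U)
        if L.shape != U.shape or L.shape != (len(self.names),):
            raise ValueError("bounds must match the decision-variable list")
        if np.any(L > U) or np.any(L <= 0):
            raise ValueError("need 0 < L <= U elementwise")

    def build(self, u: Sequence[float]):
        kw = dict(self.fixed)
        kw.update({n: float(v) for n, v in zip(self.names, u)})
        if "n_B" not in kw:
            kw["n_B"] = self.n_B
        return design(self.topology, **kw)

    def evaluate(self, u: Sequence[float]) -> DesignMetrics:
        return evaluate_design(
            self.build(u), host=self.host,
            base_rate=self.scheme_base_rate,
            attenuation=self.scheme_attenuation,
            protocol=self.protocol)


def default_problem(topology: str, n_B: int = 300, **kwargs) -> OptimizationProblem:
    """The standard decision-variable list and bounds for ``topology``."""
    if topology not in _DECISION_VARS:
        raise ValueError(f"no default decision variables for '{topology}'")
    names = _DECISION_VARS[topology]
    L = np.array([_BOUNDS[n][0] for n in names])
    U = np.array([_BOUNDS[n][1] for n in names])
    return OptimizationProblem(topology=topology, names=names,
                               lower=L, upper=U, n_B=n_B, **kwargs)


def evaluate_design(circuit, host: HostParams | None = None,
                    base_rate: float = 1e-5, attenuation: float = 0.1,
                    protocol: BatchProtocol | None = None) -> DesignMetrics:
    """Run one evolution simulation and score it."""
    scheme = MutationScheme(len(circuit.mutable_promoters),
                            base_rate=base_rate, attenuation=attenuation)
    trace = run_evolution(circuit, host=host, scheme=scheme,
                          protocol=protocol)
    return design_metrics(trace)


# ---------------------------------------------------------------------------
# NSGA-II core (generic over the objective function)
# ---------------------------------------------------------------------------

def _fast_non_dominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Fronts (lists of row indices) for maximisation of objective rows."""
    n = F.shape[0]
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if np.all(F[i] >= F[j]) and np.any(F[i] > F[j]):
                dominated_by[i].append(j)
                dom_count[j] += 1
            elif np.all(F[j] >= F[i]) and np.any(F[j] > F[i]):
                dominated_by[j].append(i)
                dom_count[i] += 1
    fronts = []
    current = np.flatnonzero(dom_count == 0)
    while current.size:
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        current = np.array(sorted(nxt), dtype=int)
    return fronts

def _crowding_distance(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for k in range(m):
        order = np.argsort(F[:, k], kind="stable")
        fmin, fmax = F[order[0], k], F[order[-1], k]
        d[order[0]] = d[order[-1]] = np.inf
        if fmax > fmin:
            span = fmax - fmin
            d[order[1:-1]] += (F[order[2:], k] - F[order[:-2], k]) / span
    return d


def _sbx(p1, p2, low, high, eta, rng):
    u = rng.random(p1.shape)
    beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta + 1)),
                    (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
    c1 = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
    c2 = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    return (np.clip(c1, low, high), np.clip(c2, low, high))


def _poly_mutation(x, low, high, eta, prob, rng):
    y = x.copy()
    span = high - low
    do = rng.random(x.shape) < prob
    u = rng.random(x.shape)
    delta = np.where(u < 0.5,
                     (2 * u) ** (1 / (eta + 1)) - 1,
                     1 - (2 * (1 - u)) ** (1 / (eta + 1)))
    y[do] = np.clip(x[do] + delta[do] * span[do], low[do], high[do])
    return y


@dataclass
class ParetoFront:
    """Non-dominated set returned by :func:`nsga2_maximize`.

    ``members`` is a list of dicts with keys ``u`` (decision vector in the
    original parameter space), ``objectives`` and optionally ``metrics``
    (the full :class:`DesignMetrics`).  No member dominates another.
    """

    members: list[dict]
    settings: GASettings
    seed: int | None
    names: tuple[str, ...] = ()
    n_evaluations: int = 0

    def objectives_array(self) -> np.ndarray:
        return np.array([m["objectives"] for m in self.members])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.members:
            row = {f"u_{n}": v for n, v in zip(
                self.names or [str(i) for i in range(len(m["u"]))], m["u"])}
            row.update({f"obj_{k}": v for k, v in zip(
                ("P0", "tau_pm10", "tau_50"), m["objectives"])})
            met = m.get("metrics")
            if met is not None:
                row.update(met.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)


def nsga2_maximize(f: Callable[[np.ndarray], Sequence[float]],
                   lower, upper, settings: GASettings | None = None,
                   seed: int | None = None,
                   log_scale: Sequence[bool] | bool = True,
                   names: Sequence[str] = (),
                   keep: Callable[[np.ndarray], dict] | None = None,
                   ) -> ParetoFront:
    """Maximise a vector objective ``f(u)`` over box bounds with NSGA-II.

    ``log_scale`` searches (all or selected) coordinates in log10 space.
    ``f`` may raise or return non-finite values; such individuals receive
    worst fitness.  Results are cached by parameter vector, so the final
    front re-uses stored evaluations.
    """
    settings = settings or GASettings()
    rng = np.random.default_rng(seed)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    d = lower.size
    logm = np.broadcast_to(np.asarray(log_scale, dtype=bool), (d,))
    lo = np.where(logm, np.log10(lower), lower)
    hi = np.where(logm, np.log10(upper), upper)

    def decode(z):
        return np.where(logm, 10.0 ** z, z)

    cache: dict[tuple, tuple] = {}
    extras: dict[tuple, dict] = {}
    n_eval = 0
    n_obj = [3]

    def evaluate(z):
        nonlocal n_eval
        key = tuple(np.round(z, 12))
        if key in cache:
            return cache[key]
        u = decode(z)
        try:
            obj = tuple(float(v) for v in f(u))
            if any(math.isnan(v) for v in obj):
                raise FloatingPointError("NaN objective")
            n_obj[0] = len(obj)
            n_eval += 1
            if keep is not None:
                extras[key] = keep(u)
        except Exception:
            obj = tuple([-math.inf] * n_obj[0])
        cache[key] = obj
        return obj

    Z = rng.uniform(lo, hi, size=(settings.pop_size, d))
    F = np.array([evaluate(z) for z in Z])

    for _ in range(settings.n_gen):
        # binary tournament on (rank, crowding)
        fronts = _fast_non_dominated_sort(F)
        rank = np.empty(len(Z), dtype=int)
        crowd = np.empty(len(Z))
        for r, idxs in enumerate(fronts):
            rank[idxs] = r
            crowd[idxs] = _crowding_distance(F[idxs])

        def better(i, j):
            if rank[i] != rank[j]:
                return i if rank[i] < rank[j] else j
            return i if crowd[i] >= crowd[j] else j

        children = []
        while len(children) < settings.pop_size:
            i1 = better(*rng.integers(0, len(Z), 2))
            i2 = better(*rng.integers(0, len(Z), 2))
            if rng.random() < settings.crossover_prob:
                c1, c2 = _sbx(Z[i1], Z[i2], lo, hi,
                              settings.crossover_eta, rng)
            else:
                c1, c2 = Z[i1].copy(), Z[i2].copy()
            for c in (c1, c2):
                children.append(_poly_mutation(
                    c, lo, hi, settings.mutation_eta, 1.0 / d, rng))
        Zc = np.array(children[:settings.pop_size])
        Fc = np.array([evaluate(z) for z in Zc])

        # environmental selection from the combined population
        Zall = np.vstack([Z, Zc])
        Fall = np.vstack([F, Fc])
        fronts = _fast_non_dominated_sort(Fall)
        sel: list[int] = []
        for idxs in fronts:
            if len(sel) + len(idxs) <= settings.pop_size:
                sel.extend(idxs.tolist())
            else:
                cd = _crowding_distance(Fall[idxs])
                order = np.argsort(-cd, kind="stable")
                sel.extend(idxs[order][:settings.pop_size - len(sel)].tolist())
                break
        Z, F = Zall[sel], Fall[sel]

    # final non-dominated set, truncated by the Pareto fraction
    finite = np.all(np.isfinite(F), axis=1)
    Zf, Ff = Z[finite], F[finite]
    # deduplicate identical decision vectors
    _, uniq = np.unique(np.round(Zf, 12), axis=0, return_index=True)
    Zf, Ff = Zf[uniq], Ff[uniq]
    front_idx = _fast_non_dominated_sort(Ff)[0] if len(Ff) else np.array([], int)
    max_keep = max(1, int(round(settings.pop_size * settings.pareto_fraction)))
    if len(front_idx) > max_keep:
        cd = _crowding_distance(Ff[front_idx])
        front_idx = front_idx[np.argsort(-cd, kind="stable")[:max_keep]]
    members = []
    for i in front_idx:
        entry = {"u": decode(Zf[i]), "objectives": tuple(Ff[i])}
        extra = extras.get(tuple(np.round(Zf[i], 12)))
        if extra:
            entry.update(extra)
        members.append(entry)
    return ParetoFront(members=members, settings=settings, seed=seed,
                       names=tuple(names), n_evaluations=n_eval)


def pareto_optimize(problem: OptimizationProblem,
                    settings: GASettings | None = None,
                    seed: int | None = None) -> ParetoFront:
    """NSGA-II front for a controller design problem.

    Objectives are (P0, tau_pm10, tau_50), the tau values capped at the
    simulation horizon when not reached; the full metric set of each front
    member is attached to the returned front.
    """
    protocol = problem.protocol or BatchProtocol()
    horizon = protocol.max_days * protocol.day_minutes
    metric_store: dict = {}

    def f(u):
        met = problem.evaluate(u)
        metric_store["last"] = met
        return (met.P0, min(met.tau_pm10, horizon), min(met.tau_50, horizon))

    def keep(u):
        return {"metrics": metric_store.get("last")}

    return nsga2_maximize(f, problem.lower, problem.upper,
                          settings=settings, seed=seed,
                          names=problem.names, keep=keep)


# ---------------------------------------------------------------------------
# Grid sweeps
# ---------------------------------------------------------------------------

def sweep_designs(topology: str, grid: dict[str, Sequence[float]],
                  n_B: int = 300, fixed: dict | None = None,
                  host: HostParams | None = None,
                  base_rate: float = 1e-5, attenuation: float = 0.1,
                  protocol: BatchProtocol | None = None) -> pd.DataFrame:
    """Full-factorial evaluation of a parameter grid.

    Returns one row per grid point with the swept parameters and the full
    metric set; rows whose evaluation failed are flagged (``ok=False``)
    with NaN metrics.  Evaluation order does not affect the result.
    """
    names = list(grid)
    meshes = np.meshgrid(*[np.asarray(grid[n], dtype=float) for n in names],
                         indexing="ij")
    points = np.stack([m.ravel() for m in meshes], axis=-1)
    rows = []
    for pt in points:
        kw = dict(fixed or {})
        kw.update({n: float(v) for n, v in zip(names, pt)})
        kw.setdefault("n_B", n_B)
        row = {n: float(v) for n, v in zip(names, pt)}
        try:
            met = evaluate_design(design(topology, **kw), host=host,
                                  base_rate=base_rate,
                                  attenuation=attenuation,
                                  protocol=protocol)
            row.update(met.as_dict())
            row["ok"] = True
        except Exception as err:      # noqa: BLE001 - flagged, not fatal
            row.update({k: math.nan for k in
                        ("P0", "tau_pm10", "tau_90", "tau_50", "P_max", "Q")})
            row["ok"] = False
            row["error"] = str(err)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.insert(0, "topology", topology)
    return df
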