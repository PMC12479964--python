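"""Configuration, fixtures, serialisation and command-line interface.

A run is fully described by a :class:`RunConfig` (YAML/JSON): host
parameterisation, controller topology and kinetics, mutation scheme,
batch protocol, dilution mode, seed and solver tolerance.  Every command
writes a JSON manifest carrying the canonical config and its hash, so a
run can be re-executed exactly from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .circuits import ConfigurationError, DEFAULTS, TOPOLOGIES, design
from .host import HostParams
from .metrics import (build_openloop_reference, design_metrics,
                      percent_change_vs_openloop)
from .mutation import MutationScheme
from .optimize import (GASettings, default_problem, pareto_optimize,
                       sweep_designs)
from .population import BatchProtocol, EvolutionTrace, run_evolution
from .robustness import robustness_summary

__all__ = [
    "RunConfig",
    "fixture_toy_system",
    "save_trace",
    "load_trace",
    "write_manifest",
    "cli",
]

_MUTATION_KEYS = {"base_rate", "attenuation"}
_HOST_KEYS = {f.name for f in dataclasses.fields(HostParams)}
_PROTOCOL_KEYS = {f.name for f in dataclasses.fields(BatchProtocol)}


@dataclass
class RunConfig:
    """Declarative description of one evolution run."""

    topology: str = "OL"
    design: dict = field(default_factory=dict)
    host: dict = field(default_factory=dict)
    mutation: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    dilution: str = "deterministic"
    seed: int | None = None
    rtol: float = 1e-6

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ConfigurationError(f"unknown topology '{self.topology}'")
        for block, allowed in (("design", set(DEFAULTS)),
                               ("host", _HOST_KEYS),
                               ("mutation", _MUTATION_KEYS),
                               ("protocol", _PROTOCOL_KEYS)):
            bad = set(getattr(self, block)) - allowed
            if bad:
                raise ConfigurationError(
                    f"unknown keys in '{block}' block: {sorted(bad)}")
        if self.dilution not in ("deterministic", "multinomial"):
            raise ConfigurationError(
                f"unknown dilution mode '{self.dilution}'")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True,
                           separators=(",", ":"), default=float)
        return hashlib.sha256(canon.encode()).hexdigest()

    # -- materialisation ---------------------------------------------------

    def build(self):
        circuit = design(self.topology, **self.design)
        host = HostParams(**self.host)
        scheme = MutationScheme(len(circuit.mutable_promoters),
                                **self.mutation)
        protocol = BatchProtocol(**self.protocol)
        return circuit, host, scheme, protocol

    def run(self) -> EvolutionTrace:
        circuit, host, scheme, protocol = self.build()
        return run_evolution(circuit, host=host, scheme=scheme,
                             protocol=protocol, dilution=self.dilution,
                             seed=self.seed, rtol=self.rtol)


def fixture_toy_system() -> RunConfig:
    """Miniature open-loop configuration used across the test suite.

    Fast mutation (base rate 2e-4/min) and a 3-day horizon give a full
    evolution run in a few seconds while preserving every qualitative
    feature: batch growth to substrate exhaustion, mutant takeover and
    monotone day-endpoint output decay.
    """
    return RunConfig(
        topology="OL",
        design={"omega_A": 5.0},
        mutation={"base_rate": 2e-4, "attenuation": 0.1},
        protocol={"max_days": 3, "samples_per_day": 12},
    )


# ---------------------------------------------------------------------------
# Trace / manifest serialisation
# ---------------------------------------------------------------------------

def save_trace(trace: EvolutionTrace, path) -> None:
    """Wide CSV: one row per stored time, per-strain columns, with a
    day_end marker column."""
    labels = ["/".join(map(str, s)) for s in trace.states]
    data = {"t": trace.t, "s_X": trace.s_X, "P": trace.P}
    for name, arr in (("N", trace.N), ("p_A", trace.p_A),
                      ("lam", trace.lam), ("T_L_A", trace.T_L_A)):
        for j, lab in enumerate(labels):
            data[f"{name}[{lab}]"] = arr[:, j]
    if trace.Q_cum is not None:
        data["Q_cum"] = trace.Q_cum
    day_end = np.zeros(len(trace.t), dtype=int)
    day_end[trace.day_end_idx] = 1
    data["day_end"] = day_end
    pd.DataFrame(data).to_csv(path, index=False)


def load_trace(path) -> EvolutionTrace:
    df = pd.read_csv(path)
    labels = [c[2:-1] for c in df.columns if c.startswith("N[")]
    states = [tuple(int(x) for x in lab.split("/")) for lab in labels]

    def block(prefix):
        return df[[f"{prefix}[{lab}]" for lab in labels]].to_numpy()

    return EvolutionTrace(
        t=df["t"].to_numpy(), N=block("N"), s_X=df["s_X"].to_numpy(),
        p_A=block("p_A"), lam=block("lam"), T_L_A=block("T_L_A"),
        P=df["P"].to_numpy(),
        day_end_idx=np.flatnonzero(df["day_end"].to_numpy() == 1),
        states=states,
        Q_cum=df["Q_cum"].to_numpy() if "Q_cum" in df else None)


def write_manifest(path, config: RunConfig, wall_time: float,
                   extra: dict | None = None) -> None:
    manifest = {
        "package": "circuitevo",
        "version": _version,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "solver": {"method": "BDF", "rtol": config.rtol,
                   "atol_cell": 1e-8},
        "wall_time_s": wall_time,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _fail(err: Exception) -> None:
    kind = (2 if isinstance(err, (ConfigurationError, ValueError, KeyError))
            else 4 if isinstance(err, OSError) else 3)
    click.echo(f"error: {err}", err=True)
    sys.exit(kind)


@click.group()
def cli() -> None:
    """Host-aware simulation and design of evolutionarily long-lived
    gene circuits."""


@cli.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path())
def simulate(config_path, out_dir):
    """Run one evolution simulation; write trace, metrics and manifest."""
    try:
        cfg = RunConfig.from_yaml(config_path)
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        t0 = time.perf_counter()
        trace = cfg.run()
        wall = time.perf_counter() - t0
        save_trace(trace, out / "trace.csv")
        _, _, scheme, _ = cfg.build()
        scheme.to_frame().to_csv(out / "mutation_matrix.csv")
        met = design_metrics(trace)
        (out / "metrics.json").write_text(
            json.dumps(met.as_dict(), indent=2, default=float))
        write_manifest(out / "manifest.json", cfg, wall,
                       extra={"days_simulated": int(len(trace.day_end_idx))})
    except Exception as err:    # noqa: BLE001
        _fail(err)
    click.echo(f"simulated {len(trace.day_end_idx)} days -> {out_dir}")


@cli.command()
@click.option("--trace", "trace_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option("--compare", "ref_path", default=None, type=click.Path(exists=True),
              help="open-loop reference CSV for %-change columns")
def metrics(trace_path, out_path, ref_path):
    """Compute the longevity/production metric set from a stored trace."""
    try:
        trace = load_trace(trace_path)
        met = design_metrics(trace)
        payload = met.as_dict()
        if ref_path:
            ref_df = pd.read_csv(ref_path)
            ref = build_openloop_reference(
                ref_df["P0"], ref_df["tau_pm10"], ref_df["tau_50"],
                Q=ref_df["Q"] if "Q" in ref_df else None)
            payload["percent_change_vs_openloop"] = \
                percent_change_vs_openloop(met, ref)
        Path(out_path).write_text(json.dumps(payload, indent=2, default=float))
    except Exception as err:    # noqa: BLE001
        _fail(err)
    click.echo(f"metrics -> {out_path}")


@cli.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--count", default=30, show_default=True)
@click.option("--omega-min", default=0.1, show_default=True)
@click.option("--omega-max", default=1000.0, show_default=True)
@click.option("--out", "out_dir", required=True, type=click.Path())
def reference(config_path, count, omega_min, omega_max, out_dir):
    """Open-loop sweep over the process transcription rate; writes the
    equal-output comparison reference (overburdened branch removed)."""
    try:
        cfg = RunConfig.from_yaml(config_path)
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        grid = np.geomspace(omega_min, omega_max, count)
        t0 = time.perf_counter()
        table = sweep_designs(
            "OL", {"omega_A": grid},
            fixed={k: v for k, v in cfg.design.items() if k != "omega_A"},
            host=HostParams(**cfg.host),
            protocol=BatchProtocol(**cfg.protocol),
            **cfg.mutation)
        table.to_csv(out / "openloop_sweep.csv", index=False)
        ok = table[table["ok"]]
        ref = build_openloop_reference(ok["P0"], ok["tau_pm10"],
                                       ok["tau_50"], Q=ok["Q"])
        pd.DataFrame({"P0": ref.P0, "tau_pm10": ref.tau_pm10,
                      "tau_50": ref.tau_50, "Q": ref.Q}).to_csv(
            out / "reference.csv", index=False)
        write_manifest(out / "manifest.json", cfg,
                       time.perf_counter() - t0,
                       extra={"sweep_count": int(count)})
    except Exception as err:    # noqa: BLE001
        _fail(err)
    click.echo(f"reference ({count} designs) -> {out_dir}")


@cli.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--param", "params", multiple=True, required=True,
              help="grid axis as name=v1,v2,... (repeatable)")
@click.option("--out", "out_path", required=True, type=click.Path())
def sweep(config_path, params, out_path):
    """Full-factorial design sweep; writes the metrics table CSV."""
    try:
        cfg = RunConfig.from_yaml(config_path)
        grid = {}
        for spec_str in params:
            name, _, vals = spec_str.partition("=")
            grid[name] = [float(v) for v in vals.split(",")]
        table = sweep_designs(
            cfg.topology, grid,
            fixed={k: v for k, v in cfg.design.items() if k not in grid},
            host=HostParams(**cfg.host),
            protocol=BatchProtocol(**cfg.protocol),
            **cfg.mutation)
        table.to_csv(out_path, index=False)
    except Exception as err:    # noqa: BLE001
        _fail(err)
    click.echo(f"sweep ({len(table)} designs) -> {out_path}")


@cli.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--pop-size", default=40, show_default=True)
@click.option("--generations", default=30, show_default=True)
@click.option("--n-b", default=300, show_default=True)
@click.option("--out", "out_dir", required=True, type=click.Path())
def optimize(config_path, pop_size, generations, n_b, out_dir):
    """NSGA-II tri-objective controller optimisation (P0, tau_pm10,
    tau_50); writes the Pareto front CSV and a manifest."""
    try:
        cfg = RunConfig.from_yaml(config_path)
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        problem = default_problem(
            cfg.topology, n_B=n_b, host=HostParams(**cfg.host),
            protocol=BatchProtocol(**cfg.protocol),
            scheme_base_rate=cfg.mutation.get("base_rate", 1e-5),
            scheme_attenuation=cfg.mutation.get("attenuation", 0.1))
        t0 = time.perf_counter()
        front = pareto_optimize(
            problem, GASettings.scaled_down(pop_size, generations),
            seed=cfg.seed)
        front.to_frame().to_csv(out / "front.csv", index=False)
        write_manifest(out / "manifest.json", cfg,
                       time.perf_counter() - t0,
                       extra={"n_evaluations": front.n_evaluations,
                              "front_size": len(front.members)})
    except Exception as err:    # noqa: BLE001
        _fail(err)
    click.echo(f"front of {len(front.members)} designs -> {out_dir}")


@cli.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--front", "front_path", required=True, type=click.Path(exists=True))
@click.option("--x", "x_levels", multiple=True, type=float,
              default=(10.0, 25.0), show_default=True)
@click.option("--replicates", default=100, show_default=True)
@click.option("--out", "out_dir", required=True, type=click.Path())
def robustness(config_path, front_path, x_levels, replicates, out_dir):
    """Perturbation robustness analysis of a stored Pareto front."""
    try:
        cfg = RunConfig.from_yaml(config_path)
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        problem = default_problem(
            cfg.topology, host=HostParams(**cfg.host),
            protocol=BatchProtocol(**cfg.protocol),
            scheme_base_rate=cfg.mutation.get("base_rate", 1e-5),
            scheme_attenuation=cfg.mutation.get("attenuation", 0.1))
        front_df = pd.read_csv(front_path)
        ucols = [f"u_{n}" for n in problem.names]
        front = [(row[ucols].to_numpy(dtype=float),
                  {k: row[k] for k in
                   ("P0", "tau_50", "tau_pm10", "tau_90", "P_max")})
                 for _, row in front_df.iterrows()]
        report = robustness_summary(
            front, lambda u: problem.evaluate(u),
            bounds=(problem.lower, problem.upper),
            X_levels=x_levels, n=replicates, seed=cfg.seed)
        report.per_design.to_csv(out / "robustness.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(report.summary(), indent=2, default=float))
    except Exception as err:    # noqa: BLE001
        _fail(err)
    click.echo(f"robustness report -> {out_dir}")
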