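"""Parametric robustness analysis of optimised controller designs.

A design that only performs when its kinetic constants are tuned exactly
is hard to build in vivo, so optimal designs are stress-tested by random
parameter perturbation: each decision variable is drawn uniformly within
±X% of its optimised value (X = 10 and 25 by default), clipped to the
optimisation bounds, and each perturbed design is re-simulated.  Reported
per design and across the front are the mean and standard deviation of
the percentage change — versus the stored baseline metrics — of five
metrics (P0, tau_50, tau_pm10, tau_90, P_max), together with the fraction
of perturbed designs whose output develops an early rise (tau_pm10 no
longer equal to tau_90: a qualitative failure mode, not a gradual drift).

Designs whose *baseline* already has tau_pm10 != tau_90 are excluded from
the analysed set; perturbed replicates with a metric "not reached" are
excluded from that metric's statistics and counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .metrics import DesignMetrics

__all__ = [
    "ROBUSTNESS_METRICS",
    "RobustnessReport",
    "perturb_parameters",
    "robustness_summary",
]

#: The five metrics tracked by the robustness analysis.
ROBUSTNESS_METRICS: tuple[str, ...] = (
    "P0", "tau_50", "tau_pm10", "tau_90", "P_max")


def perturb_parameters(u, X: float, bounds=None, n: int = 100,
                       seed: int | None = None) -> np.ndarray:
    """``n`` uniform perturbations of ``u`` within ±X%, clipped to bounds.

    Each parameter is drawn independently from
    ``[u_i (1 - X/100), u_i (1 + X/100)]``; draws outside the optimisation
    bounds ``(L, U)`` are set to exactly the boundary value so that no
    replicate explores design space that was unavailable to the optimiser.
    """
    u = np.asarray(u, dtype=float)
    if X < 0:
        raise ValueError("perturbation level X must be >= 0")
    rng = np.random.default_rng(seed)
    lo = u * (1.0 - X / 100.0)
    hi = u * (1.0 + X / 100.0)
    samples = rng.uniform(lo, hi, size=(n, u.size))
    if bounds is not None:
        L, U = (np.asarray(b, dtype=float) for b in bounds)
        samples = np.clip(samples, L, U)
    return samples


def _metric_row(met) -> dict:
    if isinstance(met, DesignMetrics):
        return {k: getattr(met, k) for k in ROBUSTNESS_METRICS}
    return {k: float(met[k]) for k in ROBUSTNESS_METRICS}


def _tau_split(met) -> bool:
    row = _metric_row(met)
    return row["tau_pm10"] != row["tau_90"]


@dataclass
class RobustnessReport:
    """Per-design and front-wide perturbation statistics.

    ``per_design`` has one row per (design, X level) with the mean and
    standard deviation of the %-change of each metric, the count of
    replicates excluded per metric ("not reached"), and the fraction of
    replicates that lost ``tau_pm10 == tau_90``.  ``front_std`` and
    ``fail_fraction`` aggregate over all analysed designs per X level.
    """

    per_design: pd.DataFrame
    front_std: dict[float, dict[str, float]]
    front_mean: dict[float, dict[str, float]]
    fail_fraction: dict[float, float]
    n_replicates: int
    X_levels: tuple[float, ...]
    n_designs: int
    n_excluded_baseline: int

    def summary(self) -> dict:
        """JSON-ready front-wide numbers."""
        return {
            "X_levels": list(self.X_levels),
            "n_designs": self.n_designs,
            "n_excluded_baseline": self.n_excluded_baseline,
            "n_replicates": self.n_replicates,
            "front_std_percent": {
                str(X): self.front_std[X] for X in self.X_levels},
            "front_mean_percent": {
                str(X): self.front_mean[X] for X in self.X_levels},
            "tau_split_fail_fraction": {
                str(X): self.fail_fraction[X] for X in self.X_levels},
        }


def robustness_summary(front: Sequence[tuple[Sequence[float], object]],
                       evaluator: Callable[[np.ndarray], object],
                       bounds=None,
                       X_levels: Sequence[float] = (10.0, 25.0),
                       n: int = 100,
                       seed: int | None = None) -> RobustnessReport:
    """Perturbation analysis of a Pareto front.

    ``front`` is a sequence of ``(u, baseline_metrics)`` pairs (metrics as
    :class:`DesignMetrics` or a mapping with the five metric keys);
    ``evaluator(u)`` re-simulates a perturbed parameter vector and returns
    metrics in the same form.  %-changes are computed against the *stored*
    baselines.  Fully deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    analysed = 0
    excluded = 0
    collected: dict[float, dict[str, list[float]]] = {
        float(X): {k: [] for k in ROBUSTNESS_METRICS} for X in X_levels}
    split_counts: dict[float, list[int]] = {float(X): [0, 0] for X in X_levels}

    for d_idx, (u, baseline) in enumerate(front):
        if _tau_split(baseline):
            excluded += 1
            continue
        analysed += 1
        base = _metric_row(baseline)
        for X in X_levels:
            X = float(X)
            reps = perturb_parameters(
                u, X, bounds=bounds, n=n,
                seed=int(rng.integers(0, 2**31 - 1)))
            changes: dict[str, list[float]] = {k: [] for k in ROBUSTNESS_METRICS}
            skipped: dict[str, int] = {k: 0 for k in ROBUSTNESS_METRICS}
            failed_eval = 0
            for rep in reps:
                try:
                    met = _metric_row(evaluator(rep))
                except Exception:     # noqa: BLE001 - recorded, not fatal
                    failed_eval += 1
                    continue
                split_counts[X][1] += 1
                if met["tau_pm10"] != met["tau_90"]:
                    split_counts[X][0] += 1
                for k in ROBUSTNESS_METRICS:
                    if not (math.isfinite(met[k]) and math.isfinite(base[k])
                            and base[k] != 0):
                        skipped[k] += 1
                        continue
                    pc = 100.0 * (met[k] - base[k]) / base[k]
                    changes[k].append(pc)
                    collected[X][k].append(pc)
            row = {"design": d_idx, "X": X, "n_failed_eval": failed_eval}
            for k in ROBUSTNESS_METRICS:
                vals = np.asarray(changes[k])
                row[f"{k}_mean"] = float(vals.mean()) if vals.size else math.nan
                row[f"{k}_std"] = (float(vals.std(ddof=0))
                                   if vals.size else math.nan)
                row[f"{k}_n_excluded"] = skipped[k]
            rows.append(row)

    if analysed == 0:
        raise ValueError(
            "no designs to analyse: every baseline has tau_pm10 != tau_90")

    front_std = {}
    front_mean = {}
    fail_fraction = {}
    for X in X_levels:
        X = float(X)
        front_std[X] = {
            k: (float(np.std(collected[X][k], ddof=0))
                if collected[X][k] else math.nan)
            for k in ROBUSTNESS_METRICS}
        front_mean[X] = {
            k: (float(np.mean(collected[X][k]))
                if collected[X][k] else math.nan)
            for k in ROBUSTNESS_METRICS}
        split, total = split_counts[X]
        fail_fraction[X] = split / total if total else math.nan

    return RobustnessReport(
        per_design=pd.DataFrame(rows),
        front_std=front_std, front_mean=front_mean,
        fail_fraction=fail_fraction, n_replicates=n,
        X_levels=tuple(float(X) for X in X_levels),
        n_designs=analysed, n_excluded_baseline=excluded)
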