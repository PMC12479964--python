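"""Evolutionary-longevity and bioproduction metrics.

The population output ``P(t)`` of an evolution run is a daily sawtooth
(dilution resets the census), so longevity is scored on the daily-endpoint
series, with linear interpolation between endpoints for sub-day crossing
resolution:

* ``P0``   — initial output: the endpoint of the first (ancestral) day.
* ``tau_pm10`` — first time P leaves the band [0.9 P0, 1.1 P0].
* ``tau_90``   — first time P falls below 0.9 P0.
* ``tau_50``   — functional half-life: first time P falls below P0/2.
* ``P_max``    — maximum endpoint output over the run.
* ``Q``    — cumulative production: sum over strains of the integral of
  (per-cell translation flux of the process protein) x (strain census),
  up to the time the output falls below 1% of P0.

Controllers are scored against an *open-loop system of equal initial
output*: a sweep of uncontrolled designs over the process transcription
rate gives the open-loop output/longevity frontier; the overburdened
branch (past the output maximum, where more transcription reduces both
output and longevity) is removed and the remainder interpolated in P0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NOT_REACHED",
    "CrossingTimes",
    "DesignMetrics",
    "OpenLoopReference",
    "total_output",
    "crossing_times",
    "cumulative_output",
    "design_metrics",
    "build_openloop_reference",
    "percent_change_vs_openloop",
]

#: Sentinel for a threshold the trace never crosses.
NOT_REACHED = math.inf


def total_output(N, p_A) -> float:
    """Population-wide output ``P = sum_i N_i * p_A_i`` (molecules)."""
    N = np.asarray(N, dtype=float)
    p_A = np.asarray(p_A, dtype=float)
    if N.shape != p_A.shape:
        raise ValueError("N and p_A must have matching shapes")
    return float(np.dot(N, p_A))


def _first_crossing(t: np.ndarray, P: np.ndarray, threshold: float,
                    direction: str) -> float:
    """First linearly interpolated time P crosses ``threshold``
    (``direction`` 'below' or 'above'); inf if never."""
    if direction == "below":
        hit = P < threshold
    else:
        hit = P > threshold
    if not hit.any():
        return NOT_REACHED
    i = int(np.argmax(hit))
    if i == 0:
        return float(t[0])
    p0, p1 = P[i - 1], P[i]
    if p1 == p0:
        return float(t[i])
    frac = (threshold - p0) / (p1 - p0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


@dataclass(frozen=True)
class CrossingTimes:
    """Longevity crossing times (same time units as the input trace)."""

    tau_pm10: float
    tau_90: float
    tau_50: float
    P_max: float
    upper_exit: bool    # tau_pm10 was reached through the +10% boundary

    @property
    def tau_split(self) -> bool:
        """True when tau_pm10 != tau_90 (early output *rise*)."""
        return self.tau_pm10 != self.tau_90


def crossing_times(t, P, P0: float | None = None) -> CrossingTimes:
    """Crossing-time metrics of an output trace ``P(t)``.

    ``P0`` defaults to ``P[0]``.  Crossings are linearly interpolated
    between samples; thresholds never reached yield ``inf``.
    """
    t = np.asarray(t, dtype=float)
    P = np.asarray(P, dtype=float)
    if t.shape != P.shape or t.ndim != 1:
        raise ValueError("t and P must be congruent 1-d arrays")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time axis must be strictly increasing")
    if P0 is None:
        P0 = float(P[0])
    if P0 <= 0:
        raise ValueError("P0 must be positive")
    tau_90 = _first_crossing(t, P, 0.9 * P0, "below")
    tau_50 = _first_crossing(t, P, 0.5 * P0, "below")
    tau_up = _first_crossing(t, P, 1.1 * P0, "above")
    tau_pm10 = min(tau_90, tau_up)
    return CrossingTimes(
        tau_pm10=tau_pm10, tau_90=tau_90, tau_50=tau_50,
        P_max=float(P.max()), upper_exit=tau_up < tau_90)


def cumulative_output(trace, stop_fraction: float = 0.01) -> float:
    """Cumulative production ``Q`` (molecules) of the process protein.

    The integral ``sum_i int T_L_A_i(t) N_i(t) dt`` is read from the
    solver-integrated cumulative channel when the trace carries one
    (sampling-independent); otherwise it falls back to trapezoidal
    quadrature on the stored trace grid.  Production is counted up to the
    (interpolated) time the daily-endpoint output falls below
    ``stop_fraction`` of P0 — or the end of the trace if it never does.
    """
    if trace.T_L_A is None or trace.N is None:
        raise ValueError("trace lacks translation-flux or census channels")
    t = trace.t
    t_d, P_d = trace.day_end_t, trace.day_end_P
    P0 = float(P_d[0])
    t_end = _first_crossing(t_d, P_d, stop_fraction * P0, "below") \
        if P0 > 0 else NOT_REACHED
    q_cum = getattr(trace, "Q_cum", None)
    if q_cum is not None:
        if not math.isfinite(t_end) or t_end >= t[-1]:
            return float(q_cum[-1])
        return float(np.interp(t_end, t, q_cum))
    rate = np.einsum("ts,ts->t", trace.T_L_A, trace.N)
    if not math.isfinite(t_end) or t_end >= t[-1]:
        return float(np.trapezoid(rate, t))
    k = int(np.searchsorted(t, t_end))
    Q = float(np.trapezoid(rate[:k], t[:k]))
    if 0 < k < len(t):      # partial last interval
        r_end = np.interp(t_end, t, rate)
        Q += 0.5 * (rate[k - 1] + r_end) * (t_end - t[k - 1])
    return Q


@dataclass(frozen=True)
class DesignMetrics:
    """Full metric set for one evaluated design (times in minutes)."""

    P0: float
    tau_pm10: float
    tau_90: float
    tau_50: float
    P_max: float
    Q: float
    upper_exit: bool

    @property
    def tau_split(self) -> bool:
        return self.tau_pm10 != self.tau_90

    def reached(self, name: str) -> bool:
        return math.isfinite(getattr(self, name))

    def as_dict(self) -> dict:
        return {
            "P0": self.P0, "tau_pm10": self.tau_pm10, "tau_90": self.tau_90,
            "tau_50": self.tau_50, "P_max": self.P_max, "Q": self.Q,
            "tau_split": self.tau_split, "upper_exit": self.upper_exit,
        }


def design_metrics(trace, stop_fraction: float = 0.01) -> DesignMetrics:
    """Score an :class:`~circuitevo.population.EvolutionTrace`.

    Longevity metrics use the daily-endpoint output series; ``Q`` uses the
    full continuous trace.
    """
    t_d, P_d = trace.day_end_t, trace.day_end_P
    ct = crossing_times(t_d, P_d)
    return DesignMetrics(
        P0=float(P_d[0]), tau_pm10=ct.tau_pm10, tau_90=ct.tau_90,
        tau_50=ct.tau_50, P_max=ct.P_max,
        Q=cumulative_output(trace, stop_fraction=stop_fraction),
        upper_exit=ct.upper_exit)


@dataclass(frozen=True)
class OpenLoopReference:
    """Single-valued open-loop output -> longevity/production mappings.

    Built from a sweep of open-loop designs ordered by the process
    transcription rate; the overburdened branch is removed so each P0 maps
    to one (tau_pm10, tau_50, Q) triple.  Queries outside the retained P0
    range raise (no extrapolation).
    """

    P0: np.ndarray
    tau_pm10: np.ndarray
    tau_50: np.ndarray
    Q: np.ndarray | None = None

    def _interp(self, x: float, y: np.ndarray) -> float:
        lo, hi = float(self.P0[0]), float(self.P0[-1])
        if not lo <= x <= hi:
            raise ValueError(
                f"P0={x:.4g} outside open-loop reference range "
                f"[{lo:.4g}, {hi:.4g}]")
        return float(np.interp(x, self.P0, y))

    def tau_pm10_at(self, P0: float) -> float:
        return self._interp(P0, self.tau_pm10)

    def tau_50_at(self, P0: float) -> float:
        return self._interp(P0, self.tau_50)

    def Q_at(self, P0: float) -> float:
        if self.Q is None:
            raise ValueError("reference was built without Q values")
        return self._interp(P0, self.Q)


def build_openloop_reference(P0, tau_pm10, tau_50, Q=None) -> OpenLoopReference:
    """Build the equal-output comparison reference from an open-loop sweep.

    Inputs are parallel arrays ordered by increasing process transcription
    rate.  The retained branch is the prefix up to (and including) the P0
    maximum; beyond it designs are overburdened (output and longevity both
    fall) and are discarded.
    """
    P0 = np.asarray(P0, dtype=float)
    tau_pm10 = np.asarray(tau_pm10, dtype=float)
    tau_50 = np.asarray(tau_50, dtype=float)
    if not (len(P0) == len(tau_pm10) == len(tau_50)):
        raise ValueError("sweep arrays must be congruent")
    if len(P0) < 2:
        raise ValueError("need at least two sweep points")
    cut = int(np.argmax(P0)) + 1
    sl = slice(0, cut)
    order = np.argsort(P0[sl], kind="stable")
    Qa = None
    if Q is not None:
        Qa = np.asarray(Q, dtype=float)[sl][order]
    return OpenLoopReference(
        P0=P0[sl][order], tau_pm10=tau_pm10[sl][order],
        tau_50=tau_50[sl][order], Q=Qa)


def percent_change_vs_openloop(metrics: DesignMetrics,
                               ref: OpenLoopReference) -> dict:
    """%-change of a controller's longevity/production metrics versus the
    open-loop design of equal initial output."""
    out = {}
    pairs = [("tau_pm10", ref.tau_pm10_at), ("tau_50", ref.tau_50_at)]
    if ref.Q is not None:
        pairs.append(("Q", ref.Q_at))
    for name, lookup in pairs:
        base = lookup(metrics.P0)
        val = getattr(metrics, name)
        if base <= 0 or not math.isfinite(base):
            out[name] = math.nan
        elif not math.isfinite(val):
            out[name] = math.inf
        else:
            out[name] = 100.0 * (val - base) / base
    return out
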