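"""Shared helpers for the test suite."""

import numpy as np

from circuitevo.population import EvolutionTrace


def synthetic_trace(t, N, T_L_A, P=None):
    """Single-strain EvolutionTrace stub for metric unit tests."""
    t = np.asarray(t, dtype=float)
    N = np.broadcast_to(np.asarray(N, dtype=float), t.shape).reshape(-1, 1)
    TL = np.broadcast_to(np.asarray(T_L_A, dtype=float),
                         t.shape).reshape(-1, 1)
    if P is None:
        P = np.full_like(t, 100.0)
    return EvolutionTrace(
        t=t, N=N.copy(), s_X=np.zeros_like(t), p_A=np.ones_like(N),
        lam=np.zeros_like(N), T_L_A=TL.copy(), P=np.asarray(P, dtype=float),
        day_end_idx=np.arange(len(t)), states=[(100,)])


def constant_flux_trace(T_L_A, N, t_end, n=11):
    return synthetic_trace(np.linspace(0.0, t_end, n), N=N, T_L_A=T_L_A)
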