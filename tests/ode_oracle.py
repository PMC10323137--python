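"""Independent numeric oracle: ODE integration of the compartmental models.

Used only in tests, never in the production path. Integrates the mass-balance
system with infusion forcing at tight tolerances so closed-form solutions can
be checked to sub-0.1% accuracy.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from vancomipd import DoseEvent, PKParameters


def ode_concentrations(params: PKParameters, events: list[DoseEvent], times) -> np.ndarray:
    """Central-compartment concentration via numeric ODE integration."""
    times = np.sort(np.asarray(times, dtype=float))

    def infusion_rate(t: float) -> float:
        return sum(
            e.amount / e.infusion_duration
            for e in events
            if e.start_time <= t < e.start_time + e.infusion_duration
        )

    two_cpt = params.Q is not None

    def rhs(t, y):
        rate = infusion_rate(t)
        if two_cpt:
            a1, a2 = y
            k10, k12, k21 = params.CL / params.V1, params.Q / params.V1, params.Q / params.V2
            return [rate - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]
        return [rate - params.ke * y[0]]

    t_end = float(max(times.max(), max((e.start_time + e.infusion_duration for e in events), default=0.0)))
    # break integration at infusion edges so the discontinuous forcing is resolved
    edges = sorted({0.0, t_end} | {e.start_time for e in events} | {e.start_time + e.infusion_duration for e in events})
    edges = [t for t in edges if 0.0 <= t <= t_end]
    y0 = [0.0, 0.0] if two_cpt else [0.0]
    out = np.zeros_like(times)
    for lo, hi in zip(edges, edges[1:]):
        mask = (times > lo) & (times <= hi)
        t_eval = np.unique(np.concatenate([times[mask], [hi]]))
        sol = solve_ivp(rhs, (lo, hi), y0, t_eval=t_eval, rtol=1e-10, atol=1e-12, method="LSODA")
        if mask.any():
            idx = np.searchsorted(sol.t, times[mask])
            out[mask] = sol.y[0][idx]
        y0 = sol.y[:, -1]
    return out / params.V1
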