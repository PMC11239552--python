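"""Voltage lookup tables for the tissue reaction kernel.

The tissue kernel evaluates the TNNP06 rate formulas millions of times per
simulated millisecond.  All voltage-only quantities are therefore tabulated
on a fine voltage grid (0.01 mV spacing) and linearly interpolated; the
tables are built by evaluating the exact same jitted rate functions the
single-cell integrator uses, so the two paths share one set of formulas.

For each of the 11 voltage-dependent gates the table holds the steady state,
the time constant, and precomputed Rush-Larsen decay factors
``exp(-dt/tau)`` for the two substeps the adaptive rule actually takes
(0.001 ms in fast phases and the full diffusion step otherwise); odd-sized
remainders fall back to the tabulated time constant.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .tnnp2006 import gate_inf_tau, voltage_current_factors, xk1_inf

__all__ = ["RateTables", "build_rate_tables"]

V_MIN = -120.0
V_MAX = 100.0
DV = 0.01

UK_MIN = -60.0  # range of u = V - E_K for the inward-rectifier table
UK_MAX = 220.0

N_GATES = 11
# column layout: gate g -> [4g]=inf, [4g+1]=tau, [4g+2]=exp(-dt_fast/tau),
# [4g+3]=exp(-dt_slow/tau); then the voltage factors of ICaL/INaCa/INaK/IpK.
COL_ICAL_A = 4 * N_GATES
COL_ICAL_B = COL_ICAL_A + 1
COL_NACA_F = COL_ICAL_A + 2
COL_NACA_R = COL_ICAL_A + 3
COL_REC_NAK = COL_ICAL_A + 4
COL_REC_PK = COL_ICAL_A + 5
N_COLS = COL_ICAL_A + 6


@njit(cache=True)
def _fill_tables(v_grid, dt_fast, dt_slow, table):
    for i in range(v_grid.shape[0]):
        v = v_grid[i]
        rates = gate_inf_tau(v)
        for g in range(N_GATES):
            inf = rates[2 * g]
            tau = rates[2 * g + 1]
            table[i, 4 * g] = inf
            table[i, 4 * g + 1] = tau
            table[i, 4 * g + 2] = np.exp(-dt_fast / tau)
            table[i, 4 * g + 3] = np.exp(-dt_slow / tau)
        ical_a, ical_b, naca_f, naca_r, rec_nak, rec_pk = voltage_current_factors(v)
        table[i, COL_ICAL_A] = ical_a
        table[i, COL_ICAL_B] = ical_b
        table[i, COL_NACA_F] = naca_f
        table[i, COL_NACA_R] = naca_r
        table[i, COL_REC_NAK] = rec_nak
        table[i, COL_REC_PK] = rec_pk


@njit(cache=True)
def _fill_k1(u_grid, out):
    for i in range(u_grid.shape[0]):
        out[i] = xk1_inf(u_grid[i])


class RateTables:
    """Tabulated voltage dependencies for a given pair of substep sizes."""

    def __init__(self, dt_fast: float, dt_slow: float):
        self.dt_fast = float(dt_fast)
        self.dt_slow = float(dt_slow)
        self.v_min = V_MIN
        self.inv_dv = 1.0 / DV
        v_grid = np.arange(V_MIN, V_MAX + DV / 2, DV)
        self.table = np.empty((v_grid.shape[0], N_COLS))
        _fill_tables(v_grid, self.dt_fast, self.dt_slow, self.table)
        self.uk_min = UK_MIN
        self.inv_duk = 1.0 / DV
        u_grid = np.arange(UK_MIN, UK_MAX + DV / 2, DV)
        self.k1_table = np.empty(u_grid.shape[0])
        _fill_k1(u_grid, self.k1_table)


_CACHE: dict[tuple[float, float], RateTables] = {}


def build_rate_tables(dt_fast: float, dt_slow: float) -> RateTables:
    key = (round(dt_fast, 9), round(dt_slow, 9))
    if key not in _CACHE:
        _CACHE[key] = RateTables(dt_fast, dt_slow)
    return _CACHE[key]
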