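"""Jitted reaction kernel for tissue simulations.

Advances the TNNP06 membrane model at every excitable node over one diffusion
step (operator splitting: all reaction substeps first, then one explicit
diffusion step).  Voltage-dependent rates come from the lookup tables in
:mod:`fibrosim.cell.tables`; the adaptive substep rule is the same as the
single-cell integrator: 0.001 ms whenever |dV/dt| > 1 mV/ms, otherwise up to
0.1 ms, always subdividing the diffusion step exactly.

Reversal potentials are evaluated once per node per diffusion step; the
ionic concentrations they depend on drift by far less than the table
resolution within 0.05 ms.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .tnnp2006 import (
    BUFC, BUFSR, BUFSS, CAO, CAPACITANCE, DT_REACTION_MIN, DVDT_FAST_THRESHOLD,
    EC_SR, G_BCA, G_BNA, G_CAL, G_K1, G_KR, G_KS, G_NA, G_PCA, G_PK, G_TO,
    GAMMA, INV_VC_F, INV_VC_F2, INV_VSS_F2, K1_PRIME, K2_PRIME, K3, K4, KBUFC,
    KBUFSR, KBUFSS, KM_CA, KM_K, KM_NA, KM_NAI, KO, K_NACA, K_NAK, K_PCA,
    K_SAT, KUP, MAX_SR, MIN_SR, NAO, PK_NA, RTONF, V_C, V_SR, V_SS, VLEAK,
    VMAXUP, VREL, VXFER, fcass_inf_tau, initial_state,
)

__all__ = ["reaction_step", "make_states"]

_SQRT_KO = np.sqrt(KO / 5.4)


@njit(cache=True, fastmath=True)
def reaction_step(
    v_flat,
    states,
    node_ids,
    istim_flat,
    dt_outer,
    dt_rmax,
    table,
    v_min,
    inv_dv,
    k1_table,
    uk_min,
    inv_duk,
    tab_dt_fast,
    tab_dt_slow,
):
    """Advance all listed nodes by ``dt_outer``; returns -1 or a bad node id.

    ``states`` has one row per listed node holding the 18 non-voltage state
    variables (same order as the single-cell vector without V); voltage lives
    in ``v_flat`` indexed by ``node_ids``.
    """
    n_v = table.shape[0]
    n_u = k1_table.shape[0]
    for k in range(node_ids.shape[0]):
        node = node_ids[k]
        v = v_flat[node]
        i_stim = istim_flat[node]
        y = states[k]
        m = y[0]; h = y[1]; j = y[2]
        xr1 = y[3]; xr2 = y[4]; xs = y[5]
        r = y[6]; s = y[7]
        d = y[8]; f = y[9]; f2 = y[10]; fcass = y[11]
        rbar = y[12]
        cai = y[13]; casr = y[14]; cass = y[15]
        nai = y[16]; ki = y[17]

        # reversal potentials, frozen over this diffusion step
        ek = RTONF * np.log(KO / ki)
        ena = RTONF * np.log(NAO / nai)
        eks = RTONF * np.log((KO + PK_NA * NAO) / (ki + PK_NA * nai))
        eca = 0.5 * RTONF * np.log(CAO / cai)

        remaining = dt_outer
        while remaining > 1e-12:
            # table row interpolation at current voltage
            fx = (v - v_min) * inv_dv
            i0 = int(fx)
            if i0 < 0:
                i0 = 0
            elif i0 > n_v - 2:
                i0 = n_v - 2
            w = fx - i0
            r0 = table[i0]
            r1 = table[i0 + 1]

            ical_a = r0[44] + w * (r1[44] - r0[44])
            ical_b = r0[45] + w * (r1[45] - r0[45])
            naca_f = r0[46] + w * (r1[46] - r0[46])
            naca_r = r0[47] + w * (r1[47] - r0[47])
            rec_nak = r0[48] + w * (r1[48] - r0[48])
            rec_pk = r0[49] + w * (r1[49] - r0[49])

            fu = (v - ek - uk_min) * inv_duk
            iu = int(fu)
            if iu < 0:
                iu = 0
            elif iu > n_u - 2:
                iu = n_u - 2
            wu = fu - iu
            xk1 = k1_table[iu] + wu * (k1_table[iu + 1] - k1_table[iu])

            ina = G_NA * m * m * m * h * j * (v - ena)
            ical = G_CAL * d * f * f2 * fcass * ical_a * (0.25 * cass * ical_b - CAO)
            ito = G_TO * r * s * (v - ek)
            ikr = G_KR * _SQRT_KO * xr1 * xr2 * (v - ek)
            iks = G_KS * xs * xs * (v - eks)
            ik1 = G_K1 * xk1 * (v - ek)
            inaca = (
                K_NACA
                * (1.0 / (KM_NAI**3 + NAO**3))
                * (1.0 / (KM_CA + CAO))
                * (1.0 / (1.0 + K_SAT * naca_r))
                * (naca_f * nai**3 * CAO - naca_r * NAO**3 * cai * 2.5)
            )
            inak = K_NAK * (KO / (KO + KM_K)) * (nai / (nai + KM_NA)) * rec_nak
            ipca = G_PCA * cai / (K_PCA + cai)
            ipk = G_PK * rec_pk * (v - ek)
            ibna = G_BNA * (v - ena)
            ibca = G_BCA * (v - eca)

            i_ion = (
                ina + ical + ito + ikr + iks + ik1
                + inaca + inak + ipca + ipk + ibna + ibca
            )
            dvdt = -(i_ion + i_stim)

            if abs(dvdt) > DVDT_FAST_THRESHOLD:
                dt = DT_REACTION_MIN if DT_REACTION_MIN < remaining else remaining
            else:
                dt = dt_rmax if dt_rmax < remaining else remaining
            if dt == tab_dt_fast:
                col = 2
            elif dt == tab_dt_slow:
                col = 3
            else:
                col = -1

            # Rush-Larsen gate updates from tabulated inf / decay factors
            for g in range(11):
                base = 4 * g
                inf = r0[base] + w * (r1[base] - r0[base])
                if col > 0:
                    e = r0[base + col] + w * (r1[base + col] - r0[base + col])
                else:
                    tau = r0[base + 1] + w * (r1[base + 1] - r0[base + 1])
                    e = np.exp(-dt / tau)
                y[g] = inf + (y[g] - inf) * e
            m = y[0]; h = y[1]; j = y[2]
            xr1 = y[3]; xr2 = y[4]; xs = y[5]
            r = y[6]; s = y[7]
            d = y[8]; f = y[9]; f2 = y[10]
            fc_inf, tau_fc = fcass_inf_tau(cass)
            fcass = fc_inf + (fcass - fc_inf) * np.exp(-dt / tau_fc)
            y[11] = fcass

            # calcium subsystem and concentration updates (forward Euler with
            # algebraic buffering, as in the single-cell path)
            kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_SR / casr) ** 2)
            k1r = K1_PRIME / kcasr
            k2r = K2_PRIME * kcasr
            rbar = rbar + dt * (K4 * (1.0 - rbar) - k2r * cass * rbar)
            y[12] = rbar
            o_rel = k1r * cass * cass * rbar / (K3 + k1r * cass * cass)
            irel = VREL * o_rel * (casr - cass)
            ileak = VLEAK * (casr - cai)
            iup = VMAXUP / (1.0 + (KUP / cai) ** 2)
            ixfer = VXFER * (cass - cai)

            ca_csqn = BUFSR * casr / (casr + KBUFSR)
            d_casr = dt * (iup - irel - ileak)
            bjsr = BUFSR - ca_csqn - d_casr - casr + KBUFSR
            cjsr = KBUFSR * (ca_csqn + d_casr + casr)
            casr = (np.sqrt(bjsr * bjsr + 4.0 * cjsr) - bjsr) / 2.0
            y[14] = casr

            ca_ssbuf = BUFSS * cass / (cass + KBUFSS)
            d_cass = dt * (
                -ixfer * (V_C / V_SS)
                + irel * (V_SR / V_SS)
                - ical * INV_VSS_F2 * CAPACITANCE
            )
            bcss = BUFSS - ca_ssbuf - d_cass - cass + KBUFSS
            ccss = KBUFSS * (ca_ssbuf + d_cass + cass)
            cass = (np.sqrt(bcss * bcss + 4.0 * ccss) - bcss) / 2.0
            y[15] = cass

            ca_buf = BUFC * cai / (cai + KBUFC)
            d_cai = dt * (
                -(ibca + ipca - 2.0 * inaca) * INV_VC_F2 * CAPACITANCE
                - (iup - ileak) * (V_SR / V_C)
                + ixfer
            )
            bc = BUFC - ca_buf - d_cai - cai + KBUFC
            cc = KBUFC * (ca_buf + d_cai + cai)
            cai = (np.sqrt(bc * bc + 4.0 * cc) - bc) / 2.0
            y[13] = cai

            nai = nai - dt * (ina + ibna + 3.0 * inak + 3.0 * inaca) * INV_VC_F * CAPACITANCE
            y[16] = nai
            ki = ki - dt * (
                i_stim + ik1 + ito + ikr + iks - 2.0 * inak + ipk
            ) * INV_VC_F * CAPACITANCE
            y[17] = ki

            v = v + dt * dvdt
            remaining -= dt

        if not np.isfinite(v) or abs(v) > 200.0:
            return node
        v_flat[node] = v
    return -1


def make_states(n_nodes: int, rest: np.ndarray | None = None) -> np.ndarray:
    """Allocate per-node state rows (without V) from the quiescent state."""
    y = rest if rest is not None else initial_state()
    return np.tile(y[1:], (n_nodes, 1))
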