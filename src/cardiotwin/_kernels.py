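"""Optional numba kernel for the table-driven ionic update.

The per-node arithmetic of ``IonicTables.step`` is a long chain of scalar
operations; on meshes of a few thousand nodes the numpy version is
dominated by temporaries.  This kernel fuses the whole update into one
loop.  If numba is unavailable the caller falls back to the numpy path —
results agree to floating-point roundoff."""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba present in supported envs
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco

# constants duplicated as plain floats for nopython mode
from cardiotwin import ttp_constants as c

_RTF = c.RTF
_F = c.FARADAY
_CM = c.CM
_VC = c.V_C
_VSR = c.V_SR
_VSS = c.V_SS
_KO = c.K_O
_NAO = c.NA_O
_CAO = c.CA_O
_PKNA = c.P_KNA
_GPCA = c.G_PCA
_KPCA = c.K_PCA
_GBNA = c.G_BNA
_GBCA = c.G_BCA
_KMNA = c.K_MNA
_MAXSR = c.MAX_SR
_MINSR = c.MIN_SR
_ECSR = c.EC_SR
_K1P = c.K1_PRIME
_K2P = c.K2_PRIME
_K3 = c.K3_RYR
_K4 = c.K4_RYR
_VREL = c.V_REL
_VMAXUP = c.VMAX_UP
_KUP = c.K_UP
_VLEAK = c.V_LEAK
_VXFER = c.V_XFER
_BUFC = c.BUF_C
_KBUFC = c.K_BUF_C
_BUFSR = c.BUF_SR
_KBUFSR = c.K_BUF_SR
_BUFSS = c.BUF_SS
_KBUFSS = c.K_BUF_SS


@njit(cache=True, fastmath=True)
def ionic_step(V, w, z, g_to, g_ks, endo, g_CaL, g_Na, g_Kr, I_app, dt,
               v_min, inv_dv, n_grid, w_inf, rl, s_inf_endo, s_rl_endo,
               cal_a, cal_b, naca_a, naca_b, nak_f, pk_f,
               uk_min, n_uk, k1_f):
    n = V.shape[0]
    sqrt_ko = np.sqrt(_KO / 5.4)
    for i in range(n):
        v = V[i]
        gi = int((v - v_min) * inv_dv + 0.5)
        if gi < 0:
            gi = 0
        elif gi >= n_grid:
            gi = n_grid - 1

        ca_i = z[i, 0]
        ca_sr = z[i, 1]
        ca_ss = z[i, 2]
        na_i = z[i, 3]
        k_i = z[i, 4]
        rbar = z[i, 5]

        e_na = _RTF * np.log(_NAO / na_i)
        e_k = _RTF * np.log(_KO / k_i)
        e_ks = _RTF * np.log((_KO + _PKNA * _NAO) / (k_i + _PKNA * na_i))
        e_ca = 0.5 * _RTF * np.log(_CAO / ca_i)

        m = w[i, 0]
        h = w[i, 1]
        jj = w[i, 2]
        xr1 = w[i, 3]
        xr2 = w[i, 4]
        xs = w[i, 5]
        r = w[i, 6]
        s = w[i, 7]
        d = w[i, 8]
        f = w[i, 9]
        f2 = w[i, 10]
        fcass = w[i, 11]

        i_na = g_Na * m * m * m * h * jj * (v - e_na)
        i_cal = g_CaL * d * f * f2 * fcass * (cal_a[gi] * ca_ss + cal_b[gi])
        i_to = g_to[i] * r * s * (v - e_k)
        i_kr = g_Kr * sqrt_ko * xr1 * xr2 * (v - e_k)
        i_ks = g_ks[i] * xs * xs * (v - e_ks)
        ui = int((v - e_k - uk_min) * inv_dv + 0.5)
        if ui < 0:
            ui = 0
        elif ui >= n_uk:
            ui = n_uk - 1
        i_k1 = k1_f[ui]
        i_naca = naca_a[gi] * na_i * na_i * na_i - naca_b[gi] * ca_i
        i_nak = nak_f[gi] * na_i / (na_i + _KMNA)
        i_pca = _GPCA * ca_i / (_KPCA + ca_i)
        i_pk = pk_f[gi] * (v - e_k)
        i_bna = _GBNA * (v - e_na)
        i_bca = _GBCA * (v - e_ca)

        i_ion = (
            i_na + i_cal + i_to + i_kr + i_ks + i_k1
            + i_naca + i_nak + i_pca + i_pk + i_bna + i_bca
        )

        # gates: Rush-Larsen with tabulated targets/factors
        for g in range(11):
            wi = w_inf[gi, g]
            w[i, g] = wi + (w[i, g] - wi) * rl[gi, g]
        if endo[i]:
            si = s_inf_endo[gi]
            w[i, 7] = si + (s - si) * s_rl_endo[gi]
        ca_ratio = (ca_ss / 0.05) ** 2
        fc_inf = 0.6 / (1.0 + ca_ratio) + 0.4
        fc_tau = 80.0 / (1.0 + ca_ratio) + 2.0
        w[i, 11] = fc_inf + (fcass - fc_inf) * np.exp(-dt / fc_tau)
        for g in range(12):
            if w[i, g] < 0.0:
                w[i, g] = 0.0
            elif w[i, g] > 1.0:
                w[i, g] = 1.0

        # calcium subsystem
        kcasr = _MAXSR - (_MAXSR - _MINSR) / (1.0 + (_ECSR / ca_sr) ** 2)
        k1 = _K1P / kcasr
        k2 = _K2P * kcasr
        O = k1 * ca_ss * ca_ss * rbar / (_K3 + k1 * ca_ss * ca_ss)
        d_rbar = -k2 * ca_ss * rbar + _K4 * (1.0 - rbar)
        i_rel = _VREL * O * (ca_sr - ca_ss)
        i_up = _VMAXUP / (1.0 + (_KUP / ca_i) ** 2)
        i_leak = _VLEAK * (ca_sr - ca_i)
        i_xfer = _VXFER * (ca_ss - ca_i)

        buf_c = 1.0 / (1.0 + _BUFC * _KBUFC / ((ca_i + _KBUFC) ** 2))
        buf_sr = 1.0 / (1.0 + _BUFSR * _KBUFSR / ((ca_sr + _KBUFSR) ** 2))
        buf_ss = 1.0 / (1.0 + _BUFSS * _KBUFSS / ((ca_ss + _KBUFSS) ** 2))

        d_ca_i = buf_c * (
            (i_leak - i_up) * _VSR / _VC
            + i_xfer
            - (i_bca + i_pca - 2.0 * i_naca) * _CM / (2.0 * _VC * _F)
        )
        d_ca_sr = buf_sr * (i_up - i_rel - i_leak)
        d_ca_ss = buf_ss * (
            -i_cal * _CM / (2.0 * _VSS * _F)
            + i_rel * _VSR / _VSS
            - i_xfer * _VC / _VSS
        )
        d_na_i = -(i_na + i_bna + 3.0 * i_nak + 3.0 * i_naca) * _CM / (_VC * _F)
        d_k_i = -(
            i_k1 + i_to + i_kr + i_ks - 2.0 * i_nak + i_pk - I_app[i]
        ) * _CM / (_VC * _F)

        z[i, 0] = max(ca_i + dt * d_ca_i, 0.0)
        z[i, 1] = max(ca_sr + dt * d_ca_sr, 0.0)
        z[i, 2] = max(ca_ss + dt * d_ca_ss, 0.0)
        z[i, 3] = max(na_i + dt * d_na_i, 0.0)
        z[i, 4] = max(k_i + dt * d_k_i, 0.0)
        z[i, 5] = max(rbar + dt * d_rbar, 0.0)

        V[i] = v + dt * (-i_ion + I_app[i])
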