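"""ten Tusscher-Panfilov (2006) human ventricular ionic model.

State layout: transmembrane potential V (mV), 12 ion-channel gating
variables w in [0,1], and 6 concentration-like variables z (intracellular,
SR and dyadic-subspace Ca2+, Na+, K+, and the ryanodine-receptor recovery
variable Rbar).  Epicardial, mid-myocardial and endocardial variants differ
in the transient-outward and slow-delayed-rectifier conductances and in the
s-gate kinetics.

The module works both per-cell (0D, the public operations below) and
vectorized over mesh nodes (the private ``advance`` entry point used by the
tissue solver).  Gating is advanced with the Rush-Larsen exponential rule,
concentrations and the potential with explicit Euler, ionic variables
before the potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from cardiotwin import ttp_constants as c


class CellType(Enum):
    EPI = "EPI"
    MCELL = "MCELL"
    ENDO = "ENDO"


# integer codes used by the vectorized tissue path
CELLTYPE_CODE = {CellType.EPI: 0, CellType.MCELL: 1, CellType.ENDO: 2}


@dataclass(frozen=True)
class IonicConductances:
    """The three calibratable maximal conductances; defaults are the
    reference model's values (mid-points of the calibration ranges)."""

    g_CaL: float = c.G_CAL_DEFAULT  # cm ms^-1 uF^-1
    g_Na: float = c.G_NA_DEFAULT   # nS/pF
    g_Kr: float = c.G_KR_DEFAULT   # nS/pF

    def __post_init__(self):
        if not (self.g_CaL > 0 and self.g_Na > 0 and self.g_Kr > 0):
            raise ValueError("all conductances must be positive")


@dataclass
class CellState:
    """State of one cell (or a vector of cells).

    ``w`` has shape (..., 12) in the order of ``ttp_constants.GATE_NAMES``;
    ``z`` has shape (..., 6) in the order of ``ttp_constants.CONC_NAMES``.
    """

    V: np.ndarray
    w: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.w.shape[-1] != 12:
            raise ValueError("w must have 12 gating components")
        if self.z.shape[-1] != 6:
            raise ValueError("z must have 6 concentration components")
        if np.any(self.w < -1e-12) or np.any(self.w > 1 + 1e-12):
            raise ValueError("gating variables must lie in [0, 1]")
        if np.any(self.z < 0):
            raise ValueError("concentration variables must be nonnegative")

    def copy(self) -> "CellState":
        return CellState(self.V.copy(), self.w.copy(), self.z.copy())


def celltype_arrays(codes: np.ndarray):
    """Per-node (g_to, g_Ks, endo_mask) lookups from integer type codes."""
    codes = np.asarray(codes, dtype=int)
    g_to = np.choose(codes, [c.G_TO["EPI"], c.G_TO["MCELL"], c.G_TO["ENDO"]])
    g_ks = np.choose(codes, [c.G_KS["EPI"], c.G_KS["MCELL"], c.G_KS["ENDO"]])
    endo = codes == CELLTYPE_CODE[CellType.ENDO]
    return np.asarray(g_to, float), np.asarray(g_ks, float), endo


def _safe_exp(x):
    return np.exp(np.clip(x, -500.0, 500.0))


def gates_inf_tau(V, Ca_ss, endo_mask):
    """Voltage (and Ca_ss) dependent steady states and time constants for
    the 12 gates, shape (n, 12)."""
    V = np.asarray(V, float)
    n = V.shape
    inf = np.empty(n + (12,))
    tau = np.empty(n + (12,))

    # fast sodium: m, h, j
    inf[..., 0] = 1.0 / (1.0 + _safe_exp((-56.86 - V) / 9.03)) ** 2
    a_m = 1.0 / (1.0 + _safe_exp((-60.0 - V) / 5.0))
    b_m = 0.1 / (1.0 + _safe_exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + _safe_exp((V - 50.0) / 200.0))
    tau[..., 0] = a_m * b_m

    inf[..., 1] = 1.0 / (1.0 + _safe_exp((V + 71.55) / 7.43)) ** 2
    lo = V < -40.0
    a_h = np.where(lo, 0.057 * _safe_exp(-(V + 80.0) / 6.8), 0.0)
    b_h = np.where(
        lo,
        2.7 * _safe_exp(0.079 * V) + 3.1e5 * _safe_exp(0.3485 * V),
        0.77 / (0.13 * (1.0 + _safe_exp(-(V + 10.66) / 11.1))),
    )
    tau[..., 1] = 1.0 / (a_h + b_h)

    inf[..., 2] = inf[..., 1]
    a_j = np.where(
        lo,
        (-2.5428e4 * _safe_exp(0.2444 * V) - 6.948e-6 * _safe_exp(-0.04391 * V))
        * (V + 37.78)
        / (1.0 + _safe_exp(0.311 * (V + 79.23))),
        0.0,
    )
    b_j = np.where(
        lo,
        0.02424 * _safe_exp(-0.01052 * V) / (1.0 + _safe_exp(-0.1378 * (V + 40.14))),
        0.6 * _safe_exp(0.057 * V) / (1.0 + _safe_exp(-0.1 * (V + 32.0))),
    )
    tau[..., 2] = 1.0 / (a_j + b_j)

    # rapid delayed rectifier: xr1, xr2
    inf[..., 3] = 1.0 / (1.0 + _safe_exp((-26.0 - V) / 7.0))
    a = 450.0 / (1.0 + _safe_exp((-45.0 - V) / 10.0))
    b = 6.0 / (1.0 + _safe_exp((V + 30.0) / 11.5))
    tau[..., 3] = a * b

    inf[..., 4] = 1.0 / (1.0 + _safe_exp((V + 88.0) / 24.0))
    a = 3.0 / (1.0 + _safe_exp((-60.0 - V) / 20.0))
    b = 1.12 / (1.0 + _safe_exp((V - 60.0) / 20.0))
    tau[..., 4] = a * b

    # slow delayed rectifier: xs
    inf[..., 5] = 1.0 / (1.0 + _safe_exp((-5.0 - V) / 14.0))
    a = 1400.0 / np.sqrt(1.0 + _safe_exp((5.0 - V) / 6.0))
    b = 1.0 / (1.0 + _safe_exp((V - 35.0) / 15.0))
    tau[..., 5] = a * b + 80.0

    # transient outward: r, s (s kinetics differ endocardially)
    inf[..., 6] = 1.0 / (1.0 + _safe_exp((20.0 - V) / 6.0))
    tau[..., 6] = 9.5 * _safe_exp(-((V + 40.0) ** 2) / 1800.0) + 0.8

    s_inf_epi = 1.0 / (1.0 + _safe_exp((V + 20.0) / 5.0))
    s_tau_epi = 85.0 * _safe_exp(-((V + 45.0) ** 2) / 320.0) + 5.0 / (1.0 + _safe_exp((V - 20.0) / 5.0)) + 3.0
    s_inf_endo = 1.0 / (1.0 + _safe_exp((V + 28.0) / 5.0))
    s_tau_endo = 1000.0 * _safe_exp(-((V + 67.0) ** 2) / 1000.0) + 8.0
    endo_mask = np.broadcast_to(np.asarray(endo_mask, bool), V.shape)
    inf[..., 7] = np.where(endo_mask, s_inf_endo, s_inf_epi)
    tau[..., 7] = np.where(endo_mask, s_tau_endo, s_tau_epi)

    # L-type calcium: d, f, f2, fCass
    inf[..., 8] = 1.0 / (1.0 + _safe_exp((-8.0 - V) / 7.5))
    a = 1.4 / (1.0 + _safe_exp((-35.0 - V) / 13.0)) + 0.25
    b = 1.4 / (1.0 + _safe_exp((V + 5.0) / 5.0))
    g = 1.0 / (1.0 + _safe_exp((50.0 - V) / 20.0))
    tau[..., 8] = a * b + g

    inf[..., 9] = 1.0 / (1.0 + _safe_exp((V + 20.0) / 7.0))
    tau[..., 9] = (
        1102.5 * _safe_exp(-((V + 27.0) ** 2) / 225.0)
        + 200.0 / (1.0 + _safe_exp((13.0 - V) / 10.0))
        + 180.0 / (1.0 + _safe_exp((V + 30.0) / 10.0))
        + 20.0
    )

    inf[..., 10] = 0.67 / (1.0 + _safe_exp((V + 35.0) / 7.0)) + 0.33
    tau[..., 10] = (
        562.0 * _safe_exp(-((V + 27.0) ** 2) / 240.0)
        + 31.0 / (1.0 + _safe_exp((25.0 - V) / 10.0))
        + 80.0 / (1.0 + _safe_exp((V + 30.0) / 10.0))
    )

    ca_ratio = (np.asarray(Ca_ss, float) / 0.05) ** 2
    inf[..., 11] = 0.6 / (1.0 + ca_ratio) + 0.4
    tau[..., 11] = 80.0 / (1.0 + ca_ratio) + 2.0

    return inf, tau


def currents(V, w, z, g_to, g_ks, g_CaL, g_Na, g_Kr):
    """All 12 membrane currents (pA/pF); returns (I_ion, dict of terms)."""
    m, h, j, xr1, xr2, xs, r, s, d, f, f2, fcass = (w[..., i] for i in range(12))
    Ca_i, Ca_sr, Ca_ss, Na_i, K_i, _ = (z[..., i] for i in range(6))

    E_Na = c.RTF * np.log(c.NA_O / Na_i)
    E_K = c.RTF * np.log(c.K_O / K_i)
    E_Ks = c.RTF * np.log((c.K_O + c.P_KNA * c.NA_O) / (K_i + c.P_KNA * Na_i))
    E_Ca = 0.5 * c.RTF * np.log(c.CA_O / Ca_i)

    I_Na = g_Na * m**3 * h * j * (V - E_Na)

    u = 2.0 * (V - 15.0) / c.RTF
    ueu = np.where(np.abs(u) < 1e-8, 1.0 + 0.5 * u, u / np.expm1(np.clip(u, -500, 500)))
    I_CaL = g_CaL * d * f * f2 * fcass * 2.0 * c.FARADAY * ueu * (
        0.25 * Ca_ss * _safe_exp(u) - c.CA_O
    )

    I_to = g_to * r * s * (V - E_K)
    I_Kr = g_Kr * np.sqrt(c.K_O / 5.4) * xr1 * xr2 * (V - E_K)
    I_Ks = g_ks * xs**2 * (V - E_Ks)

    a_k1 = 0.1 / (1.0 + _safe_exp(0.06 * (V - E_K - 200.0)))
    b_k1 = (
        3.0 * _safe_exp(0.0002 * (V - E_K + 100.0)) + _safe_exp(0.1 * (V - E_K - 10.0))
    ) / (1.0 + _safe_exp(-0.5 * (V - E_K)))
    I_K1 = c.G_K1 * np.sqrt(c.K_O / 5.4) * a_k1 / (a_k1 + b_k1) * (V - E_K)

    e_g = _safe_exp(c.GAMMA_NACA * V / c.RTF)
    e_g1 = _safe_exp((c.GAMMA_NACA - 1.0) * V / c.RTF)
    I_NaCa = (
        c.K_NACA
        * (e_g * Na_i**3 * c.CA_O - e_g1 * c.NA_O**3 * Ca_i * c.ALPHA_NACA)
        / (
            (c.K_M_NAI**3 + c.NA_O**3)
            * (c.K_M_CA + c.CA_O)
            * (1.0 + c.K_SAT * e_g1)
        )
    )

    I_NaK = (
        c.P_NAK
        * c.K_O
        * Na_i
        / (
            (c.K_O + c.K_MK)
            * (Na_i + c.K_MNA)
            * (1.0 + 0.1245 * _safe_exp(-0.1 * V / c.RTF) + 0.0353 * _safe_exp(-V / c.RTF))
        )
    )

    I_pCa = c.G_PCA * Ca_i / (c.K_PCA + Ca_i)
    I_pK = c.G_PK * (V - E_K) / (1.0 + _safe_exp((25.0 - V) / 5.98))
    I_bNa = c.G_BNA * (V - E_Na)
    I_bCa = c.G_BCA * (V - E_Ca)

    terms = dict(
        I_Na=I_Na, I_CaL=I_CaL, I_to=I_to, I_Kr=I_Kr, I_Ks=I_Ks, I_K1=I_K1,
        I_NaCa=I_NaCa, I_NaK=I_NaK, I_pCa=I_pCa, I_pK=I_pK, I_bNa=I_bNa, I_bCa=I_bCa,
    )
    I_ion = sum(terms.values())
    return I_ion, terms


def conc_rates(V, w, z, terms, I_app=0.0):
    """Time derivatives of the 6 concentration-like variables (mM/ms)."""
    Ca_i, Ca_sr, Ca_ss, Na_i, K_i, Rbar = (z[..., i] for i in range(6))

    kcasr = c.MAX_SR - (c.MAX_SR - c.MIN_SR) / (1.0 + (c.EC_SR / Ca_sr) ** 2)
    k1 = c.K1_PRIME / kcasr
    k2 = c.K2_PRIME * kcasr
    O = k1 * Ca_ss**2 * Rbar / (c.K3_RYR + k1 * Ca_ss**2)
    dRbar = -k2 * Ca_ss * Rbar + c.K4_RYR * (1.0 - Rbar)

    I_rel = c.V_REL * O * (Ca_sr - Ca_ss)
    I_up = c.VMAX_UP / (1.0 + (c.K_UP / Ca_i) ** 2)
    I_leak = c.V_LEAK * (Ca_sr - Ca_i)
    I_xfer = c.V_XFER * (Ca_ss - Ca_i)

    buf_c = 1.0 / (1.0 + c.BUF_C * c.K_BUF_C / (Ca_i + c.K_BUF_C) ** 2)
    buf_sr = 1.0 / (1.0 + c.BUF_SR * c.K_BUF_SR / (Ca_sr + c.K_BUF_SR) ** 2)
    buf_ss = 1.0 / (1.0 + c.BUF_SS * c.K_BUF_SS / (Ca_ss + c.K_BUF_SS) ** 2)

    dCa_i = buf_c * (
        (I_leak - I_up) * c.V_SR / c.V_C
        + I_xfer
        - (terms["I_bCa"] + terms["I_pCa"] - 2.0 * terms["I_NaCa"]) * c.CM / (2.0 * c.V_C * c.FARADAY)
    )
    dCa_sr = buf_sr * (I_up - I_rel - I_leak)
    dCa_ss = buf_ss * (
        -terms["I_CaL"] * c.CM / (2.0 * c.V_SS * c.FARADAY)
        + I_rel * c.V_SR / c.V_SS
        - I_xfer * c.V_C / c.V_SS
    )
    dNa_i = -(terms["I_Na"] + terms["I_bNa"] + 3.0 * terms["I_NaK"] + 3.0 * terms["I_NaCa"]) * c.CM / (c.V_C * c.FARADAY)
    # the applied (depolarizing) current enters the K+ balance with the
    # opposite sign of the membrane currents
    dK_i = -(
        terms["I_K1"] + terms["I_to"] + terms["I_Kr"] + terms["I_Ks"]
        - 2.0 * terms["I_NaK"] + terms["I_pK"] - I_app
    ) * c.CM / (c.V_C * c.FARADAY)

    return np.stack([dCa_i, dCa_sr, dCa_ss, dNa_i, dK_i, dRbar], axis=-1)


def advance(V, w, z, dt, g_to, g_ks, endo_mask, g_CaL, g_Na, g_Kr, I_app=0.0):
    """One operator-split step (vectorized over nodes).

    Gates: Rush-Larsen; concentrations: explicit Euler; potential:
    explicit Euler with the ionic current evaluated at the old state.
    Returns (V', w', z', I_ion).
    """
    inf, tau = gates_inf_tau(V, z[..., 2], endo_mask)
    I_ion, terms = currents(V, w, z, g_to, g_ks, g_CaL, g_Na, g_Kr)
    dz = conc_rates(V, w, z, terms, I_app=I_app)
    if dt == 0.0:
        return V.copy(), w.copy(), z.copy(), I_ion
    w_new = inf + (w - inf) * np.exp(-dt / tau)
    np.clip(w_new, 0.0, 1.0, out=w_new)
    z_new = z + dt * dz
    np.maximum(z_new, 0.0, out=z_new)
    V_new = V + dt * (-I_ion + I_app)
    return V_new, w_new, z_new, I_ion


class IonicTables:
    """Table-driven fast path for tissue simulations.

    All purely voltage-dependent quantities — gate steady states, the
    Rush-Larsen factors exp(-dt/tau) for a fixed dt, and the voltage
    coefficients of I_CaL, I_NaCa, I_NaK and I_pK — are precomputed on a
    fine V grid and looked up by nearest neighbour (grid step 0.02 mV, an
    error far below the time-discretization error).  The inward-rectifier
    gate depends on V - E_K and gets its own table.  Only the fCass gate
    (Ca_ss-dependent) and the concentration balances are evaluated
    directly.  Semantics match ``advance`` to lookup accuracy.
    """

    def __init__(self, dt: float, v_min: float = -150.0, v_max: float = 100.0, dv: float = 0.02):
        self.dt = dt
        self.v_min = v_min
        self.inv_dv = 1.0 / dv
        V = np.arange(v_min, v_max + dv, dv)
        self.n_grid = len(V)

        inf_epi, tau_epi = gates_inf_tau(V, np.full_like(V, 1e-4), np.zeros(len(V), bool))
        inf_endo, tau_endo = gates_inf_tau(V, np.full_like(V, 1e-4), np.ones(len(V), bool))
        self.w_inf = inf_epi[:, :11]            # fCass (col 11) handled directly
        self.rl = np.exp(-dt / tau_epi[:, :11])
        self.s_inf_endo = inf_endo[:, 7]
        self.s_rl_endo = np.exp(-dt / tau_endo[:, 7])

        u = 2.0 * (V - 15.0) / c.RTF
        ueu = np.where(np.abs(u) < 1e-8, 1.0 + 0.5 * u, u / np.expm1(np.clip(u, -500, 500)))
        self.cal_a = 2.0 * c.FARADAY * ueu * 0.25 * _safe_exp(u)   # multiplies Ca_ss
        self.cal_b = -2.0 * c.FARADAY * ueu * c.CA_O
        e_g1 = _safe_exp((c.GAMMA_NACA - 1.0) * V / c.RTF)
        denom = (c.K_M_NAI**3 + c.NA_O**3) * (c.K_M_CA + c.CA_O) * (1.0 + c.K_SAT * e_g1)
        self.naca_a = c.K_NACA * _safe_exp(c.GAMMA_NACA * V / c.RTF) * c.CA_O / denom     # * Na_i^3
        self.naca_b = c.K_NACA * e_g1 * c.NA_O**3 * c.ALPHA_NACA / denom                  # * Ca_i
        self.nak_f = c.P_NAK * c.K_O / (
            (c.K_O + c.K_MK) * (1.0 + 0.1245 * _safe_exp(-0.1 * V / c.RTF) + 0.0353 * _safe_exp(-V / c.RTF))
        )  # * Na_i/(Na_i+K_mNa)
        self.pk_f = c.G_PK / (1.0 + _safe_exp((25.0 - V) / 5.98))  # * (V-E_K)

        # inward rectifier on u = V - E_K
        uk = np.arange(-150.0, 250.0 + dv, dv)
        self.uk_min = uk[0]
        a_k1 = 0.1 / (1.0 + _safe_exp(0.06 * (uk - 200.0)))
        b_k1 = (3.0 * _safe_exp(0.0002 * (uk + 100.0)) + _safe_exp(0.1 * (uk - 10.0))) / (
            1.0 + _safe_exp(-0.5 * uk)
        )
        self.k1_f = c.G_K1 * np.sqrt(c.K_O / 5.4) * a_k1 / (a_k1 + b_k1) * uk
        self.n_uk = len(uk)

    def _vidx(self, V):
        return np.clip(((V - self.v_min) * self.inv_dv + 0.5).astype(np.int64), 0, self.n_grid - 1)

    def step(self, V, w, z, g_to, g_ks, endo_mask, g_CaL, g_Na, g_Kr, I_app=0.0):
        """One operator-split reaction step (same splitting as ``advance``)."""
        dt = self.dt
        i = self._vidx(V)
        w_inf = self.w_inf[i]
        rl = self.rl[i]
        w_new = np.empty_like(w)
        w_new[:, :11] = w_inf + (w[:, :11] - w_inf) * rl
        if endo_mask is not False and np.any(endo_mask):
            s_inf = self.s_inf_endo[i[endo_mask]]
            w_new[endo_mask, 7] = s_inf + (w[endo_mask, 7] - s_inf) * self.s_rl_endo[i[endo_mask]]
        Ca_ss = z[:, 2]
        ca_ratio = (Ca_ss / 0.05) ** 2
        fc_inf = 0.6 / (1.0 + ca_ratio) + 0.4
        fc_tau = 80.0 / (1.0 + ca_ratio) + 2.0
        w_new[:, 11] = fc_inf + (w[:, 11] - fc_inf) * np.exp(-dt / fc_tau)
        np.clip(w_new, 0.0, 1.0, out=w_new)

        m, h, j, xr1, xr2, xs, r, s, d, f, f2, fcass = (w[:, k] for k in range(12))
        Ca_i, Ca_sr, _, Na_i, K_i, _ = (z[:, k] for k in range(6))

        E_Na = c.RTF * np.log(c.NA_O / Na_i)
        E_K = c.RTF * np.log(c.K_O / K_i)
        E_Ks = c.RTF * np.log((c.K_O + c.P_KNA * c.NA_O) / (K_i + c.P_KNA * Na_i))
        E_Ca = 0.5 * c.RTF * np.log(c.CA_O / Ca_i)

        I_Na = g_Na * m**3 * h * j * (V - E_Na)
        I_CaL = g_CaL * d * f * f2 * fcass * (self.cal_a[i] * Ca_ss + self.cal_b[i])
        I_to = g_to * r * s * (V - E_K)
        I_Kr = g_Kr * np.sqrt(c.K_O / 5.4) * xr1 * xr2 * (V - E_K)
        I_Ks = g_ks * xs**2 * (V - E_Ks)
        iu = np.clip(((V - E_K - self.uk_min) * self.inv_dv + 0.5).astype(np.int64), 0, self.n_uk - 1)
        I_K1 = self.k1_f[iu]
        I_NaCa = self.naca_a[i] * Na_i**3 - self.naca_b[i] * Ca_i
        I_NaK = self.nak_f[i] * Na_i / (Na_i + c.K_MNA)
        I_pCa = c.G_PCA * Ca_i / (c.K_PCA + Ca_i)
        I_pK = self.pk_f[i] * (V - E_K)
        I_bNa = c.G_BNA * (V - E_Na)
        I_bCa = c.G_BCA * (V - E_Ca)

        terms = dict(
            I_Na=I_Na, I_CaL=I_CaL, I_to=I_to, I_Kr=I_Kr, I_Ks=I_Ks, I_K1=I_K1,
            I_NaCa=I_NaCa, I_NaK=I_NaK, I_pCa=I_pCa, I_pK=I_pK, I_bNa=I_bNa, I_bCa=I_bCa,
        )
        I_ion = (
            I_Na + I_CaL + I_to + I_Kr + I_Ks + I_K1
            + I_NaCa + I_NaK + I_pCa + I_pK + I_bNa + I_bCa
        )
        dz = conc_rates(V, w, z, terms, I_app=I_app)
        z_new = z + dt * dz
        np.maximum(z_new, 0.0, out=z_new)
        V_new = V + dt * (-I_ion + I_app)
        return V_new, w_new, z_new, I_ion

    def step_inplace(self, V, w, z, g_to, g_ks, endo_mask, g_CaL, g_Na, g_Kr, I_app):
        """In-place update, dispatching to the fused numba kernel when
        available (numpy fallback otherwise)."""
        from cardiotwin import _kernels

        if _kernels.HAVE_NUMBA:
            _kernels.ionic_step(
                V, w, z, g_to, g_ks, endo_mask,
                float(g_CaL), float(g_Na), float(g_Kr), I_app, self.dt,
                self.v_min, self.inv_dv, self.n_grid,
                self.w_inf, self.rl, self.s_inf_endo, self.s_rl_endo,
                self.cal_a, self.cal_b, self.naca_a, self.naca_b,
                self.nak_f, self.pk_f, self.uk_min, self.n_uk, self.k1_f,
            )
            return V, w, z
        Vn, wn, zn, _ = self.step(V, w, z, g_to, g_ks, endo_mask, g_CaL, g_Na, g_Kr, I_app=I_app)
        V[:], w[:], z[:] = Vn, wn, zn
        return V, w, z


# --------------------------------------------------------------------------
# public 0D operations
# --------------------------------------------------------------------------

def initial_state(cell_type: CellType, n: int | None = None) -> CellState:
    """Published resting state of the reference model (all cell types start
    from the same steady state; the variants diverge under pacing)."""
    s = c.INITIAL_STATE
    w = np.array([s[g] for g in c.GATE_NAMES])
    z = np.array([s[k] for k in c.CONC_NAMES])
    V = np.array(s["V"])
    if n is not None:
        V = np.full(n, s["V"])
        w = np.tile(w, (n, 1))
        z = np.tile(z, (n, 1))
    return CellState(V, w, z)


def _type_params(cell_type: CellType):
    g_to = c.G_TO[cell_type.value]
    g_ks = c.G_KS[cell_type.value]
    endo = cell_type is CellType.ENDO
    return g_to, g_ks, endo


def ionic_rates(state: CellState, cell_type: CellType, cond: IonicConductances):
    """Total ionic current (mV/ms scale) and state derivatives (dw, dz)."""
    if not (np.all(np.isfinite(state.V)) and np.all(np.isfinite(state.w)) and np.all(np.isfinite(state.z))):
        raise FloatingPointError("non-finite cell state (numerical blow-up)")
    g_to, g_ks, endo = _type_params(cell_type)
    inf, tau = gates_inf_tau(state.V, state.z[..., 2], endo)
    I_ion, terms = currents(state.V, state.w, state.z, g_to, g_ks, cond.g_CaL, cond.g_Na, cond.g_Kr)
    dw = (inf - state.w) / tau
    dz = conc_rates(state.V, state.w, state.z, terms)
    return I_ion, dw, dz


def step_cell(state: CellState, dt: float, cell_type: CellType, cond: IonicConductances, I_app: float = 0.0) -> CellState:
    """Advance one cell by dt (ms)."""
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    g_to, g_ks, endo = _type_params(cell_type)
    V, w, z, _ = advance(state.V, state.w, state.z, dt, g_to, g_ks, endo,
                         cond.g_CaL, cond.g_Na, cond.g_Kr, I_app=I_app)
    if not np.all(np.isfinite(V)):
        raise FloatingPointError("transmembrane potential diverged; reduce dt")
    return CellState(V, w, z)


@dataclass
class PacingProtocol:
    """Square stimulus pulses: onset times (ms), amplitude (per-ms potential
    units, positive = depolarizing), duration (ms)."""

    times: tuple = (10.0,)
    amplitude: float = 52.0
    duration: float = 1.0

    def current(self, t: float) -> float:
        for t0 in self.times:
            if t0 <= t < t0 + self.duration:
                return self.amplitude
        return 0.0


@dataclass
class ApTrace:
    t: np.ndarray
    V: np.ndarray
    w: np.ndarray
    z: np.ndarray

    def to_csv(self, path):
        import pandas as pd

        cols = {"t_ms": self.t, "V_mV": self.V}
        for i, g in enumerate(c.GATE_NAMES):
            cols[g] = self.w[:, i]
        for i, k in enumerate(c.CONC_NAMES):
            cols[k] = self.z[:, i]
        pd.DataFrame(cols).to_csv(path, index=False)


def simulate_ap(
    cell_type: CellType,
    cond: IonicConductances = IonicConductances(),
    pacing: PacingProtocol | None = None,
    duration: float = 600.0,
    dt: float = 0.02,
    sample_every: float = 1.0,
    fast: bool = False,
) -> ApTrace:
    """Run the 0D cell for ``duration`` ms and return a sampled trace.

    ``fast=True`` uses the table-driven kernel (lookup error far below the
    time-discretization error); the default evaluates every rate exactly."""
    if pacing is None:
        pacing = PacingProtocol()
    state = initial_state(cell_type, n=1)
    n_steps = int(round(duration / dt))
    stride = max(1, int(round(sample_every / dt)))
    ts, Vs, ws, zs = [], [], [], []
    g_to, g_ks, endo = _type_params(cell_type)
    V, w, z = state.V, state.w, state.z
    if fast:
        tables = IonicTables(dt)
        g_to_a = np.full(1, g_to)
        g_ks_a = np.full(1, g_ks)
        endo_a = np.full(1, endo, dtype=bool)
        I_app = np.zeros(1)
    for k in range(n_steps + 1):
        t = k * dt
        if k % stride == 0:
            ts.append(t)
            Vs.append(float(V[0]))
            ws.append(w[0].copy())
            zs.append(z[0].copy())
        if k == n_steps:
            break
        if fast:
            I_app[0] = pacing.current(t)
            V, w, z = tables.step_inplace(V, w, z, g_to_a, g_ks_a, endo_a,
                                          cond.g_CaL, cond.g_Na, cond.g_Kr, I_app)
        else:
            V, w, z, _ = advance(V, w, z, dt, g_to, g_ks, endo,
                                 cond.g_CaL, cond.g_Na, cond.g_Kr,
                                 I_app=pacing.current(t))
        if not np.all(np.isfinite(V)):
            raise FloatingPointError(f"potential diverged at t={t:.2f} ms")
    return ApTrace(np.array(ts), np.array(Vs), np.array(ws), np.array(zs))


def apd90(trace: ApTrace) -> float:
    """Action-potential duration at 90% repolarization, from the upstroke
    to the downward crossing of V_rest + 0.1 * amplitude."""
    V = trace.V
    t = trace.t
    v_rest = V[0]
    i_peak = int(np.argmax(V))
    v_peak = V[i_peak]
    if v_peak - v_rest < 10.0:
        raise ValueError("no action potential in trace")
    v90 = v_rest + 0.1 * (v_peak - v_rest)
    upstroke = np.nonzero(V[: i_peak + 1] > v_rest + 0.5 * (v_peak - v_rest))[0]
    t_up = t[upstroke[0]]
    below = np.nonzero(V[i_peak:] < v90)[0]
    if len(below) == 0:
        raise ValueError("trace does not repolarize to 90%")
    i0 = i_peak + below[0]
    # linear interpolation of the crossing
    t_down = np.interp(v90, [V[i0], V[i0 - 1]], [t[i0], t[i0 - 1]])
    return float(t_down - t_up)
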