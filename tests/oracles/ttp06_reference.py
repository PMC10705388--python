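"""Independent reference transcription of the ten Tusscher-Panfilov 2006
human ventricular model, used only as a test oracle.

Written separately from the package implementation (different state
layout, per-current functions, generic ODE integration with
scipy.solve_ivp) so that transcription errors in either copy show up as
disagreement.  Equations and constants follow ten Tusscher & Panfilov,
Am J Physiol Heart Circ Physiol 291 (2006) H1088-H1100.
"""

import numpy as np
from scipy.integrate import solve_ivp

R = 8314.472
T = 310.0
F = 96485.3415
RTONF = R * T / F

Ko = 5.4
Nao = 140.0
Cao = 2.0

Gna = 14.838
GcaL = 3.98e-5
Gkr = 0.153
Gk1 = 5.405
Gpk = 0.0146
GpCa = 0.1238
KpCa = 0.0005
Gbna = 0.00029
Gbca = 0.000592
pKNa = 0.03

knaca = 1000.0
KmNai = 87.5
KmCa = 1.38
ksat = 0.1
n_gamma = 0.35
alpha_naca = 2.5

knak = 2.724
KmK = 1.0
KmNa = 40.0

CAPACITANCE = 0.185
Vc = 0.016404
Vsr = 0.001094
Vss = 0.00005468

Vmaxup = 0.006375
Kup = 0.00025
Vrel = 0.102
k1_ = 0.15
k2_ = 0.045
k3 = 0.060
k4 = 0.005
EC = 1.5
maxsr = 2.5
minsr = 1.0
Vleak = 0.00036
Vxfer = 0.0038

Bufc = 0.2
Kbufc = 0.001
Bufsr = 10.0
Kbufsr = 0.3
Bufss = 0.4
Kbufss = 0.00025

# state ordering of this transcription
STATE = ("V", "m", "h", "j", "d", "f", "f2", "fcass", "r", "s",
         "xr1", "xr2", "xs", "Nai", "Ki", "Cai", "Casr", "Cass", "Rq")

Y0 = dict(V=-85.23, m=0.00172, h=0.7444, j=0.7045, d=3.373e-5, f=0.7888,
          f2=0.9755, fcass=0.9953, r=2.42e-8, s=0.999998, xr1=0.00621,
          xr2=0.4712, xs=0.0095, Nai=8.604, Ki=136.89, Cai=0.000126,
          Casr=3.64, Cass=0.00036, Rq=0.9073)


def gate_m(V):
    minf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    return minf, am * bm


def gate_h(V):
    hinf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V < -40.0:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
    else:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    return hinf, 1.0 / (ah + bh)


def gate_j(V):
    jinf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V < -40.0:
        aj = ((-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
              * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))))
        bj = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    else:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    return jinf, 1.0 / (aj + bj)


def gate_d(V):
    dinf = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    return dinf, ad * bd + gd


def gate_f(V):
    finf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tf = (1102.5 * np.exp(-((V + 27.0) ** 2) / 225.0)
          + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
          + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0)) + 20.0)
    return finf, tf


def gate_f2(V):
    f2inf = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    tf2 = (562.0 * np.exp(-((V + 27.0) ** 2) / 240.0)
           + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
           + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0)))
    return f2inf, tf2


def gate_fcass(Cass):
    fcinf = 0.6 / (1.0 + (Cass / 0.05) ** 2) + 0.4
    tfc = 80.0 / (1.0 + (Cass / 0.05) ** 2) + 2.0
    return fcinf, tfc


def gate_r(V):
    rinf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    return rinf, 9.5 * np.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8


def gate_s(V, epicardial):
    if epicardial:
        sinf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
        ts = 85.0 * np.exp(-((V + 45.0) ** 2) / 320.0) + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0
    else:
        sinf = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
        ts = 1000.0 * np.exp(-((V + 67.0) ** 2) / 1000.0) + 8.0
    return sinf, ts


def gate_xr1(V):
    xinf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    a = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    b = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    return xinf, a * b


def gate_xr2(V):
    xinf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    a = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    b = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    return xinf, a * b


def gate_xs(V):
    xinf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    a = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
    b = 1.0 / (1.0 + np.exp((V - 35.0) / 15.0))
    return xinf, a * b + 80.0


def rhs(t, y, cell="epi", gna=Gna, gcal=GcaL, gkr=Gkr, stim=None):
    s = dict(zip(STATE, y))
    V = s["V"]

    gto = 0.073 if cell == "endo" else 0.294
    gks = 0.098 if cell == "mcell" else 0.392

    Ena = RTONF * np.log(Nao / s["Nai"])
    Ek = RTONF * np.log(Ko / s["Ki"])
    Eks = RTONF * np.log((Ko + pKNa * Nao) / (s["Ki"] + pKNa * s["Nai"]))
    Eca = 0.5 * RTONF * np.log(Cao / s["Cai"])

    INa = gna * s["m"] ** 3 * s["h"] * s["j"] * (V - Ena)

    expv = np.exp(2.0 * (V - 15.0) / RTONF)
    if abs(V - 15.0) < 1e-6:
        ICaL = gcal * s["d"] * s["f"] * s["f2"] * s["fcass"] * 2.0 * F * (0.25 * s["Cass"] - Cao)
    else:
        ICaL = (gcal * s["d"] * s["f"] * s["f2"] * s["fcass"]
                * 4.0 * (V - 15.0) * F / RTONF
                * (0.25 * s["Cass"] * expv - Cao) / (expv - 1.0))

    Ito = gto * s["r"] * s["s"] * (V - Ek)
    IKr = gkr * np.sqrt(Ko / 5.4) * s["xr1"] * s["xr2"] * (V - Ek)
    IKs = gks * s["xs"] ** 2 * (V - Eks)

    ak1 = 0.1 / (1.0 + np.exp(0.06 * (V - Ek - 200.0)))
    bk1 = ((3.0 * np.exp(0.0002 * (V - Ek + 100.0)) + np.exp(0.1 * (V - Ek - 10.0)))
           / (1.0 + np.exp(-0.5 * (V - Ek))))
    IK1 = Gk1 * np.sqrt(Ko / 5.4) * ak1 / (ak1 + bk1) * (V - Ek)

    INaCa = (knaca
             * (np.exp(n_gamma * V / RTONF) * s["Nai"] ** 3 * Cao
                - np.exp((n_gamma - 1.0) * V / RTONF) * Nao**3 * s["Cai"] * alpha_naca)
             / ((KmNai**3 + Nao**3) * (KmCa + Cao)
                * (1.0 + ksat * np.exp((n_gamma - 1.0) * V / RTONF))))

    INaK = (knak * Ko * s["Nai"]
            / ((Ko + KmK) * (s["Nai"] + KmNa)
               * (1.0 + 0.1245 * np.exp(-0.1 * V / RTONF) + 0.0353 * np.exp(-V / RTONF))))

    IpCa = GpCa * s["Cai"] / (KpCa + s["Cai"])
    IpK = Gpk * (V - Ek) / (1.0 + np.exp((25.0 - V) / 5.98))
    IbNa = Gbna * (V - Ena)
    IbCa = Gbca * (V - Eca)

    Istim = stim(t) if stim is not None else 0.0

    Iion = INa + ICaL + Ito + IKr + IKs + IK1 + INaCa + INaK + IpCa + IpK + IbNa + IbCa

    dy = {}
    dy["V"] = -Iion + Istim

    for name, (inf, tau) in (
        ("m", gate_m(V)), ("h", gate_h(V)), ("j", gate_j(V)),
        ("d", gate_d(V)), ("f", gate_f(V)), ("f2", gate_f2(V)),
        ("fcass", gate_fcass(s["Cass"])), ("r", gate_r(V)),
        ("s", gate_s(V, cell != "endo")),
        ("xr1", gate_xr1(V)), ("xr2", gate_xr2(V)), ("xs", gate_xs(V)),
    ):
        dy[name] = (inf - s[name]) / tau

    kcasr = maxsr - (maxsr - minsr) / (1.0 + (EC / s["Casr"]) ** 2)
    k1 = k1_ / kcasr
    k2 = k2_ * kcasr
    O = k1 * s["Cass"] ** 2 * s["Rq"] / (k3 + k1 * s["Cass"] ** 2)
    dy["Rq"] = -k2 * s["Cass"] * s["Rq"] + k4 * (1.0 - s["Rq"])

    Irel = Vrel * O * (s["Casr"] - s["Cass"])
    Iup = Vmaxup / (1.0 + (Kup / s["Cai"]) ** 2)
    Ileak = Vleak * (s["Casr"] - s["Cai"])
    Ixfer = Vxfer * (s["Cass"] - s["Cai"])

    bc = 1.0 / (1.0 + Bufc * Kbufc / (s["Cai"] + Kbufc) ** 2)
    bsr = 1.0 / (1.0 + Bufsr * Kbufsr / (s["Casr"] + Kbufsr) ** 2)
    bss = 1.0 / (1.0 + Bufss * Kbufss / (s["Cass"] + Kbufss) ** 2)

    dy["Cai"] = bc * ((Ileak - Iup) * Vsr / Vc + Ixfer
                      - (IbCa + IpCa - 2.0 * INaCa) * CAPACITANCE / (2.0 * Vc * F))
    dy["Casr"] = bsr * (Iup - Irel - Ileak)
    dy["Cass"] = bss * (-ICaL * CAPACITANCE / (2.0 * Vss * F)
                        + Irel * Vsr / Vss - Ixfer * Vc / Vss)
    dy["Nai"] = -(INa + IbNa + 3.0 * INaK + 3.0 * INaCa) * CAPACITANCE / (Vc * F)
    dy["Ki"] = -(IK1 + Ito + IKr + IKs - 2.0 * INaK + IpK - Istim) * CAPACITANCE / (Vc * F)

    return [dy[k] for k in STATE]


GATES = ("m", "h", "j", "d", "f", "f2", "fcass", "r", "s", "xr1", "xr2", "xs")


def run_ap_rush_larsen(cell="epi", duration=500.0, dt=0.02, stim_time=10.0,
                       stim_amp=52.0, stim_dur=1.0, sample_every=1.0):
    """Fixed-step operator-split integration of this transcription (gates
    Rush-Larsen, everything else explicit Euler), mirroring the scheme of
    the implementation under test but using only this module's equations.
    Isolates transcription errors from integrator differences."""
    y = dict(Y0)
    n = int(round(duration / dt))
    stride = max(1, int(round(sample_every / dt)))
    ts, Vs = [], []
    for k in range(n + 1):
        t = k * dt
        if k % stride == 0:
            ts.append(t)
            Vs.append(y["V"])
        if k == n:
            break
        stim = stim_amp if stim_time <= t < stim_time + stim_dur else 0.0
        dy = dict(zip(STATE, rhs(t, [y[s] for s in STATE],
                                 cell=cell, stim=lambda _t: stim)))
        V = y["V"]
        gate_tab = dict(m=gate_m(V), h=gate_h(V), j=gate_j(V), d=gate_d(V),
                        f=gate_f(V), f2=gate_f2(V), fcass=gate_fcass(y["Cass"]),
                        r=gate_r(V), s=gate_s(V, cell != "endo"),
                        xr1=gate_xr1(V), xr2=gate_xr2(V), xs=gate_xs(V))
        new = dict(y)
        for g in GATES:
            inf, tau = gate_tab[g]
            new[g] = min(1.0, max(0.0, inf + (y[g] - inf) * np.exp(-dt / tau)))
        for c in ("Nai", "Ki", "Cai", "Casr", "Cass", "Rq"):
            new[c] = max(0.0, y[c] + dt * dy[c])
        new["V"] = y["V"] + dt * dy["V"]
        y = new
    return np.array(ts), np.array(Vs)


def run_ap(cell="epi", duration=500.0, stim_time=10.0, stim_amp=52.0,
           stim_dur=1.0, gna=Gna, gcal=GcaL, gkr=Gkr, t_eval=None):
    """Integrate one paced beat with LSODA; returns (t, V)."""

    def stim(t):
        return stim_amp if stim_time <= t < stim_time + stim_dur else 0.0

    y0 = [Y0[k] for k in STATE]
    if t_eval is None:
        t_eval = np.arange(0.0, duration + 0.5, 1.0)
    # integrate in segments so the discontinuous stimulus is resolved
    edges = [0.0, stim_time, stim_time + stim_dur, duration]
    ts, Vs = [], []
    y = y0
    for a, b in zip(edges[:-1], edges[1:]):
        if b <= a:
            continue
        seg_eval = t_eval[(t_eval >= a) & (t_eval <= b)]
        sol = solve_ivp(rhs, (a, b), y, method="LSODA",
                        t_eval=seg_eval if len(seg_eval) else None,
                        args=(cell, gna, gcal, gkr, stim),
                        rtol=1e-8, atol=1e-10, max_step=1.0)
        y = sol.y[:, -1]
        if len(seg_eval):
            ts.append(sol.t)
            Vs.append(sol.y[0])
    t = np.concatenate(ts)
    V = np.concatenate(Vs)
    keep = np.concatenate([[True], np.diff(t) > 0])
    return t[keep], V[keep]
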