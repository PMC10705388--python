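"""Constants of the ten Tusscher-Panfilov (2006) human ventricular model.

Transcribed from ten Tusscher & Panfilov, "Alternans and spiral breakup in
a human ventricular tissue model", Am J Physiol Heart Circ Physiol 291
(2006) H1088-H1100 (parameter table and model equations).  Units follow
that publication: potentials in mV, time in ms, concentrations in mM,
conductances in nS/pF except g_CaL in cm ms^-1 uF^-1 (equivalently
cm^3 uF^-1 s^-1 / 1000).

Only g_CaL, g_Na and g_Kr are exposed for calibration; everything else is
pinned here.
"""

# physical constants
R_GAS = 8314.472  # J K^-1 kmol^-1
TEMP = 310.0      # K
FARADAY = 96485.3415  # C mmol^-1
RTF = R_GAS * TEMP / FARADAY  # mV

# geometry / capacitance
CM = 0.185        # membrane capacitance used in concentration balances, uF
V_C = 0.016404    # cytoplasmic volume, um^3 (scaled)
V_SR = 0.001094   # sarcoplasmic-reticulum volume
V_SS = 0.00005468  # dyadic subspace volume

# extracellular concentrations (mM)
K_O = 5.4
NA_O = 140.0
CA_O = 2.0

# default maximal conductances (nS/pF unless noted)
G_NA_DEFAULT = 14.838
G_CAL_DEFAULT = 3.98e-5  # cm ms^-1 uF^-1
G_KR_DEFAULT = 0.153
G_K1 = 5.405
G_PK = 0.0146
G_PCA = 0.1238
G_BNA = 0.00029
G_BCA = 0.000592

# transmural variation: transient outward and slow delayed rectifier
G_TO = {"EPI": 0.294, "MCELL": 0.294, "ENDO": 0.073}
G_KS = {"EPI": 0.392, "MCELL": 0.098, "ENDO": 0.392}

P_KNA = 0.03

# Na/Ca exchanger
K_NACA = 1000.0
GAMMA_NACA = 0.35
K_M_CA = 1.38
K_M_NAI = 87.5
K_SAT = 0.1
ALPHA_NACA = 2.5

# Na/K pump
P_NAK = 2.724
K_MK = 1.0
K_MNA = 40.0

# sarcolemmal Ca pump
K_PCA = 0.0005

# SR release (ryanodine receptor)
V_REL = 0.102
K1_PRIME = 0.15
K2_PRIME = 0.045
K3_RYR = 0.060
K4_RYR = 0.005
EC_SR = 1.5
MAX_SR = 2.5
MIN_SR = 1.0

# SR uptake / leak / transfer
VMAX_UP = 0.006375
K_UP = 0.00025
V_LEAK = 0.00036
V_XFER = 0.0038

# calcium buffering
BUF_C = 0.2
K_BUF_C = 0.001
BUF_SR = 10.0
K_BUF_SR = 0.3
BUF_SS = 0.4
K_BUF_SS = 0.00025

# published resting initial conditions (epicardial steady state at 1 Hz)
INITIAL_STATE = {
    "V": -85.23,
    "m": 0.00172,
    "h": 0.7444,
    "j": 0.7045,
    "xr1": 0.00621,
    "xr2": 0.4712,
    "xs": 0.0095,
    "r": 2.42e-8,
    "s": 0.999998,
    "d": 3.373e-5,
    "f": 0.7888,
    "f2": 0.9755,
    "fcass": 0.9953,
    "Ca_i": 0.000126,
    "Ca_sr": 3.64,
    "Ca_ss": 0.00036,
    "Na_i": 8.604,
    "K_i": 136.89,
    "Rbar": 0.9073,
}

GATE_NAMES = ("m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2", "fcass")
CONC_NAMES = ("Ca_i", "Ca_sr", "Ca_ss", "Na_i", "K_i", "Rbar")
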