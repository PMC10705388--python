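"""Monodomain tissue solver on the coupled Purkinje/myocardium domain.

The reaction-diffusion system

    dPhi/dt + I_ion(Phi, w, z) - div(D_M grad Phi) = I_app,   (D_M grad Phi).n = 0

is discretized with P1 finite elements in space (tensor conductivity
D_M = D_iso I + D_ani f0 (x) f0 in the myocardium, D_purk I on the 1D
network) and an implicit-explicit scheme in time: per step the ionic model
is advanced first at every node (Rush-Larsen gates, explicit Euler
concentrations), then the potential with implicit diffusion and the nodal
ionic current treated explicitly (ionic current interpolation).

Coupling is one-way: the Purkinje network is advanced first; when a
Purkinje-myocardial junction's network potential crosses the activation
threshold, a 2 ms suprathreshold point stimulus is delivered to its mapped
myocardial vertex.  The right bundle root fires at t = 0, the left at
t_LV_stim, mirroring interventricular activation dyssynchrony.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from cardiotwin import ttp_ionic as ion
from cardiotwin.anatomy import Anatomy, PurkinjeNetwork, consistent_mass, stiffness_matrix
from cardiotwin.ecg import LeadTraces, lead_field_matrix

V_ACT_DEFAULT = 0.0     # mV, upward crossing marks activation
V_REP_DEFAULT = -70.0   # mV, last downward crossing marks repolarization


@dataclass(frozen=True)
class ConductivityParams:
    """Tissue and network conductivities, mm^2/ms."""

    D_ani: float = 0.020745
    D_iso: float = 0.006915
    D_purk: float = 2.25

    def __post_init__(self):
        if min(self.D_ani, self.D_iso, self.D_purk) <= 0:
            raise ValueError("conductivities must be positive")


@dataclass(frozen=True)
class StimulusProtocol:
    """Root stimulation: right bundle at t = 0, left bundle at t_LV_stim
    within [0, 100] ms; single 600 ms beat."""

    amplitude: float = 52.0
    duration: float = 2.0
    t_RV_stim: float = 0.0
    t_LV_stim: float = 0.0
    T_HB: float = 600.0

    def __post_init__(self):
        if not (0.0 <= self.t_LV_stim <= 100.0):
            raise ValueError("t_LV_stim must lie in [0, 100] ms")


@dataclass
class SimulationResult:
    t_snap: np.ndarray            # (T,) ms
    V_snap: np.ndarray            # (T, n_myo) mV
    V_purk_snap: np.ndarray       # (T, n_purk)
    activation: np.ndarray        # (n_myo,) ms, NaN if never activated
    repolarization: np.ndarray    # (n_myo,) ms, NaN if undefined
    lead_traces: LeadTraces | None
    log: dict


def assemble_operators(mesh, fibers, purkinje: PurkinjeNetwork, cond: ConductivityParams):
    """Discrete diffusion operators: (A_myo, M_myo, A_purk, M_purk).

    A are P1 stiffness matrices (symmetric positive semidefinite), M are
    consistent mass matrices (myocardium) / 1D consistent mass (network).
    The myocardial tensor is D_iso I + D_ani f0 (x) f0 per tet."""
    f0 = fibers.f0
    eye = np.broadcast_to(np.eye(3), (len(f0), 3, 3))
    tensor = cond.D_iso * eye + cond.D_ani * np.einsum("mi,mj->mij", f0, f0)
    A_myo = stiffness_matrix(mesh, tensor)
    M_myo = consistent_mass(mesh)

    n_p = len(purkinje.nodes)
    le = purkinje.edge_lengths()
    if np.any(le <= 0):
        raise ValueError("zero-length Purkinje edge")
    rows, cols, kvals, mvals = [], [], [], []
    for (a, b), l in zip(purkinje.edges, le):
        k = cond.D_purk / l
        rows += [a, a, b, b]
        cols += [a, b, a, b]
        kvals += [k, -k, -k, k]
        mvals += [l / 3.0, l / 6.0, l / 6.0, l / 3.0]
    A_purk = sp.coo_matrix((kvals, (rows, cols)), shape=(n_p, n_p)).tocsr()
    M_purk = sp.coo_matrix((mvals, (rows, cols)), shape=(n_p, n_p)).tolil()
    # isolated nodes (none expected) get unit mass to keep M invertible
    iso = np.asarray(M_purk.sum(axis=1)).ravel() == 0
    for i in np.nonzero(iso)[0]:
        M_purk[i, i] = 1.0
    return A_myo, M_myo, A_purk, M_purk.tocsr()


def bundle_branch_block(purkinje: PurkinjeNetwork, side: str) -> PurkinjeNetwork:
    """Copy of the network with the chosen bundle inhibited (its edges and
    junctions removed, so its root never fires)."""
    side = side.upper()
    if side not in ("LEFT", "RIGHT"):
        raise ValueError(f"unknown bundle side {side!r}")
    keep_edges = purkinje.edge_bundle != side
    edges = purkinje.edges[keep_edges]
    bundles = purkinje.edge_bundle[keep_edges]
    kept_nodes = np.unique(edges) if len(edges) else np.array([], dtype=int)
    other = "RIGHT" if side == "LEFT" else "LEFT"
    roots = {}
    if other in purkinje.roots:
        root_other = purkinje.roots[other]
        if root_other not in kept_nodes:
            kept_nodes = np.unique(np.append(kept_nodes, root_other))
        roots[other] = root_other
    remap = -np.ones(len(purkinje.nodes), dtype=int)
    remap[kept_nodes] = np.arange(len(kept_nodes))
    pmj_keep = np.isin(purkinje.pmj_nodes, kept_nodes)
    return PurkinjeNetwork(
        nodes=purkinje.nodes[kept_nodes],
        edges=remap[edges],
        edge_bundle=bundles,
        roots={k: int(remap[v]) for k, v in roots.items()},
        av_point=purkinje.av_point.copy(),
        pmj_nodes=remap[purkinje.pmj_nodes[pmj_keep]],
        pmj_vertices=purkinje.pmj_vertices[pmj_keep],
    )


def run_simulation(
    anatomy: Anatomy,
    cond: ConductivityParams = ConductivityParams(),
    ionic: ion.IonicConductances = ion.IonicConductances(),
    stimulus: StimulusProtocol = StimulusProtocol(),
    dt: float = 0.05,
    output_stride: float = 1.0,
    duration: float | None = None,
    compute_ecg: bool = True,
    compute_maps: bool = True,
    pmj_stim_duration: float = 2.0,
    pmj_stim_radius: float = 1.5,
    v_act: float = V_ACT_DEFAULT,
    v_rep: float = V_REP_DEFAULT,
) -> SimulationResult:
    """Run one beat (default T_HB = 600 ms) on the given anatomy."""
    mesh = anatomy.mesh
    purk = anatomy.purkinje
    duration = stimulus.T_HB if duration is None else duration

    A_myo, M_myo, A_purk, M_purk = assemble_operators(mesh, anatomy.fibers, purk, cond)
    lu_myo = spla.splu((M_myo + dt * A_myo).tocsc())
    lu_purk = spla.splu((M_purk + dt * A_purk).tocsc())

    n_m = mesh.n_vertices
    n_p = len(purk.nodes)
    n = n_m + n_p

    # combined ionic state: myocardial nodes first, Purkinje nodes appended
    # (network cells use the endocardial variant)
    codes = np.concatenate([anatomy.cell_types, np.full(n_p, 2, dtype=int)])
    g_to, g_ks, endo_mask = ion.celltype_arrays(codes)
    st = ion.initial_state(ion.CellType.EPI, n=n)
    V, w, z = st.V, st.w, st.z
    tables = ion.IonicTables(dt)

    L = lead_field_matrix(mesh, anatomy.electrodes) if compute_ecg else None

    stride = max(1, int(round(output_stride / dt)))
    n_steps = int(round(duration / dt))
    n_out = n_steps // stride + 1
    t_snap = np.empty(n_out)
    V_snap = np.empty((n_out, n_m))
    P_snap = np.empty((n_out, n_p))
    ecg = np.empty((9, n_out)) if compute_ecg else None

    # the root stimulus covers the root and its one-ring: a single network
    # node cannot capture against the strong 1D Purkinje diffusion
    root_schedule = []
    for bundle, t0 in (("RIGHT", stimulus.t_RV_stim), ("LEFT", stimulus.t_LV_stim)):
        if bundle in purk.roots:
            rid = purk.roots[bundle]
            ring = purk.edges[(purk.edges == rid).any(axis=1)].ravel()
            root_schedule.append((t0, np.unique(np.append(ring, rid))))

    pmj_fired = np.zeros(len(purk.pmj_nodes), dtype=bool)
    pmj_until = np.full(len(purk.pmj_nodes), -1.0)  # myo stimulus end time
    prev_purk_V = V[n_m:].copy()

    # each junction stimulates a small ball of myocardial vertices: a
    # single coarse-mesh vertex cannot capture the tissue
    from scipy.spatial import cKDTree

    vert_tree = cKDTree(mesh.vertices)
    pmj_balls = [
        np.asarray(vert_tree.query_ball_point(mesh.vertices[vid], pmj_stim_radius), dtype=int)
        for vid in purk.pmj_vertices
    ]

    I_app = np.zeros(n)
    out = 0
    for k in range(n_steps + 1):
        t = k * dt
        if k % stride == 0:
            t_snap[out] = t
            V_snap[out] = V[:n_m]
            P_snap[out] = V[n_m:]
            if compute_ecg:
                ecg[:, out] = L @ V[:n_m]
            out += 1
        if k == n_steps:
            break

        I_app[:] = 0.0
        for t0, nodes in root_schedule:
            if t0 <= t < t0 + stimulus.duration:
                I_app[n_m + nodes] = stimulus.amplitude
        for i in np.nonzero(pmj_until > t)[0]:
            I_app[pmj_balls[i]] = stimulus.amplitude

        V, w, z = tables.step_inplace(
            V, w, z, g_to, g_ks, endo_mask,
            ionic.g_CaL, ionic.g_Na, ionic.g_Kr, I_app,
        )
        # implicit diffusion (one-way coupling: network first, no feedback)
        V_p = lu_purk.solve(M_purk @ V[n_m:])
        V_m = lu_myo.solve(M_myo @ V[:n_m])
        V = np.concatenate([V_m, V_p])
        if not np.all(np.isfinite(V)):
            raise FloatingPointError(f"potential diverged at step {k} (t={t + dt:.2f} ms)")

        # PMJ transmission: upward threshold crossing on the network
        cur = V[n_m + purk.pmj_nodes] if len(purk.pmj_nodes) else np.empty(0)
        prev = prev_purk_V[purk.pmj_nodes] if len(purk.pmj_nodes) else np.empty(0)
        newly = (~pmj_fired) & (prev < v_act) & (cur >= v_act)
        if newly.any():
            pmj_fired |= newly
            pmj_until[newly] = t + dt + pmj_stim_duration
        prev_purk_V = V[n_m:].copy()

    if compute_maps:
        act, rep = activation_repolarization_maps(t_snap, V_snap, v_act=v_act, v_rep=v_rep)
    else:
        act = rep = np.full(n_m, np.nan)
    traces = LeadTraces(t_snap, ecg) if compute_ecg else None
    log = dict(
        dt=dt, duration=duration, n_steps=n_steps,
        n_myo=n_m, n_purk=n_p,
        pmj_fired=int(pmj_fired.sum()), pmj_total=len(pmj_fired),
    )
    return SimulationResult(t_snap, V_snap, P_snap, act, rep, traces, log)


def activation_repolarization_maps(
    t_snap: np.ndarray,
    V_snap: np.ndarray,
    v_act: float = V_ACT_DEFAULT,
    v_rep: float = V_REP_DEFAULT,
):
    """Per-vertex activation time (first upward crossing of v_act) and
    repolarization time (last downward crossing of v_rep), linearly
    interpolated between snapshots; NaN marks vertices that never cross.
    Requires a snapshot stride <= 2 ms for meaningful interpolation."""
    t_snap = np.asarray(t_snap, float)
    if len(t_snap) > 1 and np.max(np.diff(t_snap)) > 2.0 + 1e-9:
        raise ValueError("snapshot stride must be <= 2 ms for crossing maps")
    V = np.asarray(V_snap, float)
    T, n = V.shape
    act = np.full(n, np.nan)
    rep = np.full(n, np.nan)

    up = (V[:-1] < v_act) & (V[1:] >= v_act)
    down = (V[:-1] >= v_rep) & (V[1:] < v_rep)
    dt_snap = np.diff(t_snap)

    for j in range(n):
        iu = np.nonzero(up[:, j])[0]
        if len(iu):
            i = iu[0]
            frac = (v_act - V[i, j]) / (V[i + 1, j] - V[i, j])
            act[j] = t_snap[i] + frac * dt_snap[i]
        idn = np.nonzero(down[:, j])[0]
        if len(idn):
            i = idn[-1]
            frac = (V[i, j] - v_rep) / (V[i, j] - V[i + 1, j])
            rep[j] = t_snap[i] + frac * dt_snap[i]

    both = np.isfinite(act) & np.isfinite(rep)
    bad = both & (rep < act)
    rep[bad] = np.nan  # repolarization before activation is meaningless
    return act, rep


def maps_to_csv(path, activation, repolarization):
    import pandas as pd

    pd.DataFrame(
        {
            "vertex_id": np.arange(len(activation)),
            "activation_ms": activation,
            "repolarization_ms": repolarization,
        }
    ).to_csv(path, index=False)
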