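"""Small shared helpers for the test suite (not fixtures)."""

import numpy as np

from cardiotwin.blnm import BLNMConfig, BLNMModel, EcgDataset, init_weights
from cardiotwin.ecg import Normalizer


def measure_planar_cv(D_ani, D_iso, fiber_dir, length=20.0, width=2.0, h=0.5,
                      duration=300.0, dt=0.05):
    """Planar-wave conduction velocity on a bar: stimulate the x = 0 face,
    fit activation time against x in the settled interior (the first few
    mm carry the face-stimulus transient).  Returns (cv mm/ms, activated
    fraction); cv is None if the wave fails to cross."""
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    from cardiotwin import ttp_ionic as ion
    from cardiotwin.anatomy import build_slab_mesh, consistent_mass, stiffness_matrix
    from cardiotwin.monodomain import activation_repolarization_maps

    mesh = build_slab_mesh(length, width, width, h)
    f0 = np.tile(np.asarray(fiber_dir, float), (len(mesh.tets), 1))
    eye = np.broadcast_to(np.eye(3), (len(f0), 3, 3))
    tensor = D_iso * eye + D_ani * np.einsum("mi,mj->mij", f0, f0)
    A = stiffness_matrix(mesh, tensor)
    M = consistent_mass(mesh)
    lu = spla.splu((M + dt * A).tocsc())
    n = mesh.n_vertices
    g_to, g_ks, endo = ion.celltype_arrays(np.zeros(n, int))
    st = ion.initial_state(ion.CellType.EPI, n=n)
    V, w, z = st.V, st.w, st.z
    stim = mesh.vertices[:, 0] <= 0.5 + 1e-9  # fixed-depth stimulated slab
    tables = ion.IonicTables(dt)
    I_app = np.zeros(n)
    snaps, ts = [], []
    for k in range(int(duration / dt)):
        t = k * dt
        I_app[:] = np.where(stim & (t < 2.0), 52.0, 0.0)
        V, w, z = tables.step_inplace(V, w, z, g_to, g_ks, endo,
                                      3.98e-5, 14.838, 0.153, I_app)
        V = lu.solve(M @ V)
        if k % 20 == 0:
            snaps.append(V.copy())
            ts.append(t)
    act, _ = activation_repolarization_maps(np.asarray(ts), np.asarray(snaps))
    x = mesh.vertices[:, 0]
    frac = float(np.mean(np.isfinite(act)))
    if frac < 0.95:
        return None, frac
    sel = np.isfinite(act) & (x > 0.4 * length) & (x < length - 2.0)
    slope = np.polyfit(x[sel], act[sel], 1)[0]
    return 1.0 / slope, frac


def tiny_surrogate(seed=0, T=31, cfg=None):
    """A small random-weight BLNM plus a dataset shell on a coarse grid:
    a cheap, smooth, deterministic map for optimizer/sampler tests."""
    cfg = cfg or BLNMConfig(3, 12, 9, 1)
    model = BLNMModel(cfg, init_weights(cfg, seed) * 1.5)
    t = np.linspace(0.0, 600.0, T)
    norm = Normalizer(lo=-np.ones(9), hi=np.ones(9))
    ds = EcgDataset(
        t=t, params=np.zeros((1, 7)), params_norm=np.zeros((1, 7)),
        leads=np.zeros((1, 9, T)), train_idx=np.array([0]),
        test_idx=np.array([], dtype=int), normalizer=norm,
    )
    return model, ds
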