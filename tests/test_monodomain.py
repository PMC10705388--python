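"""Tissue-solver tests: operator assembly, resting-state preservation,
activation/repolarization maps and bundle-branch-block semantics.

Wave-propagation physics (conduction velocity and anisotropy) lives in
the acceptance suite; here the runs are short or structural."""

import numpy as np
import pytest

from cardiotwin import anatomy as anat
from cardiotwin import monodomain as mono
from cardiotwin import ttp_ionic as ion


@pytest.fixture(scope="module")
def slab_anatomy():
    # h = 0.5 mm: the coarsest spacing at which the depolarization wave
    # conducts at default conductivities
    return anat.slab_preset(lx=6.0, ly=6.0, lz=2.5, h=0.5, branch_len=2.0)


class TestOperators:
    def test_constant_field_in_stiffness_kernel(self, slab_anatomy):
        A, M, Ap, Mp = mono.assemble_operators(
            slab_anatomy.mesh, slab_anatomy.fibers, slab_anatomy.purkinje,
            mono.ConductivityParams(),
        )
        u = np.ones(slab_anatomy.mesh.n_vertices)
        assert np.abs(A @ u).max() < 1e-10
        up = np.ones(len(slab_anatomy.purkinje.nodes))
        assert np.abs(Ap @ up).max() < 1e-10

    def test_isotropic_part_scales_linearly(self, slab_anatomy):
        a = slab_anatomy
        A1, _, _, _ = mono.assemble_operators(a.mesh, a.fibers, a.purkinje,
                                              mono.ConductivityParams(D_ani=1e-12, D_iso=0.01))
        A2, _, _, _ = mono.assemble_operators(a.mesh, a.fibers, a.purkinje,
                                              mono.ConductivityParams(D_ani=1e-12, D_iso=0.02))
        assert np.abs(A2.toarray() - 2.0 * A1.toarray()).max() < 1e-10

    def test_operators_symmetric_psd(self, slab_anatomy):
        a = slab_anatomy
        A, _, _, _ = mono.assemble_operators(a.mesh, a.fibers, a.purkinje, mono.ConductivityParams())
        D = A.toarray()
        assert np.abs(D - D.T).max() < 1e-12
        ev = np.linalg.eigvalsh(D)
        assert ev.min() > -1e-10

    def test_mass_total_equals_volume(self, slab_anatomy):
        a = slab_anatomy
        _, M, _, _ = mono.assemble_operators(a.mesh, a.fibers, a.purkinje, mono.ConductivityParams())
        vol = a.mesh.tet_volumes().sum()
        assert M.sum() == pytest.approx(vol, rel=1e-9)


class TestRunSimulation:
    def test_resting_state_preserved_without_stimulus(self, slab_anatomy):
        # suppress both root stimuli by zero amplitude
        res = mono.run_simulation(
            slab_anatomy, stimulus=mono.StimulusProtocol(amplitude=0.0),
            duration=100.0, compute_ecg=True,
        )
        v_rest = res.V_snap[0, 0]
        assert np.abs(res.V_snap - v_rest).max() < 1.0
        assert np.abs(res.lead_traces.traces).max() < 0.05

    def test_activation_reaches_tissue_and_maps_consistent(self, slab_anatomy):
        res = mono.run_simulation(slab_anatomy, duration=600.0)
        frac = np.mean(np.isfinite(res.activation))
        assert frac > 0.95
        both = np.isfinite(res.activation) & np.isfinite(res.repolarization)
        assert np.all(res.repolarization[both] >= res.activation[both])

    def test_repolarization_minus_activation_tracks_cell_apd(self, slab_anatomy):
        res = mono.run_simulation(slab_anatomy, duration=600.0)
        tr = ion.simulate_ap(ion.CellType.EPI, duration=500.0, dt=0.05, fast=True)
        apd_cell = ion.apd90(tr)
        both = np.isfinite(res.activation) & np.isfinite(res.repolarization)
        apd_tissue = np.median((res.repolarization - res.activation)[both])
        # electrotonic coupling to the long-APD mid-wall layer prolongs
        # the tissue APD relative to the isolated epicardial cell
        assert abs(apd_tissue - apd_cell) < 40.0

    def test_one_way_coupling(self, slab_anatomy):
        """Changing myocardial conductivity must not change Purkinje
        activation times."""
        r1 = mono.run_simulation(slab_anatomy, cond=mono.ConductivityParams(D_iso=0.004),
                                 duration=60.0, compute_ecg=False, compute_maps=False)
        r2 = mono.run_simulation(slab_anatomy, cond=mono.ConductivityParams(D_iso=0.011),
                                 duration=60.0, compute_ecg=False, compute_maps=False)
        assert np.allclose(r1.V_purk_snap, r2.V_purk_snap, atol=1e-9)

    def test_invalid_lv_delay_rejected(self):
        with pytest.raises(ValueError):
            mono.StimulusProtocol(t_LV_stim=150.0)


class TestMaps:
    def test_uniform_stimulus_constant_map(self):
        t = np.arange(0.0, 21.0, 1.0)
        V = np.full((len(t), 5), -85.0)
        V[10:] = 20.0  # simultaneous step everywhere
        act, rep = mono.activation_repolarization_maps(t, V)
        assert np.allclose(act, act[0])

    def test_never_crossing_vertex_flagged(self):
        t = np.arange(0.0, 11.0, 1.0)
        V = np.full((len(t), 3), -85.0)
        V[5:, 0] = 30.0
        act, rep = mono.activation_repolarization_maps(t, V)
        assert np.isfinite(act[0])
        assert np.isnan(act[1]) and np.isnan(act[2])

    def test_linear_interpolation_of_crossing(self):
        t = np.array([0.0, 2.0, 4.0])
        V = np.array([[-85.0], [-10.0], [30.0]])
        act, _ = mono.activation_repolarization_maps(t, V)
        # crossing of 0 mV between t=2 (-10) and t=4 (30): t = 2 + 2*10/40
        assert act[0] == pytest.approx(2.5)

    def test_coarse_stride_rejected(self):
        t = np.array([0.0, 5.0, 10.0])
        with pytest.raises(ValueError):
            mono.activation_repolarization_maps(t, np.zeros((3, 2)))


class TestBundleBranchBlock:
    def test_left_block_removes_left_pmjs(self, slab_anatomy):
        pk = slab_anatomy.purkinje
        blocked = mono.bundle_branch_block(pk, "LEFT")
        assert np.all(blocked.edge_bundle == "RIGHT")
        assert "LEFT" not in blocked.roots
        # remaining junction count equals the right bundle's original count
        n_right = np.sum(np.isin(pk.pmj_nodes, pk.bundle_nodes("RIGHT")))
        assert len(blocked.pmj_nodes) == n_right

    def test_double_block_never_activates(self, slab_anatomy):
        both = mono.bundle_branch_block(
            mono.bundle_branch_block(slab_anatomy.purkinje, "LEFT"), "RIGHT")
        assert len(both.pmj_nodes) == 0
        a = anat.Anatomy(slab_anatomy.mesh, slab_anatomy.phi, slab_anatomy.fibers,
                         both, slab_anatomy.electrodes, slab_anatomy.cell_types)
        res = mono.run_simulation(a, duration=100.0, compute_ecg=False, compute_maps=False)
        assert np.abs(res.V_snap - res.V_snap[0, 0]).max() < 1.0

    def test_right_block_delays_right_side_activation(self, slab_anatomy):
        base = mono.run_simulation(slab_anatomy, duration=600.0, compute_ecg=False)
        blocked = mono.bundle_branch_block(slab_anatomy.purkinje, "RIGHT")
        a = anat.Anatomy(slab_anatomy.mesh, slab_anatomy.phi, slab_anatomy.fibers,
                         blocked, slab_anatomy.electrodes, slab_anatomy.cell_types)
        res = mono.run_simulation(a, duration=600.0, compute_ecg=False)
        # the right half of the endocardial side activates later without
        # its bundle
        rv_side = slab_anatomy.mesh.vertices[:, 0] >= 3.0
        ok = np.isfinite(base.activation) & np.isfinite(res.activation) & rv_side
        assert np.nanmean(res.activation[ok]) > np.nanmean(base.activation[ok])

    def test_unknown_side_rejected(self, slab_anatomy):
        with pytest.raises(ValueError):
            mono.bundle_branch_block(slab_anatomy.purkinje, "SEPTAL")
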