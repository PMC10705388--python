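"""Synthetic anatomy tests: meshes, transmural coordinate, fibers,
Purkinje trees and electrode placement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiotwin import anatomy as anat


class TestSlabMesh:
    def test_structured_counts(self):
        m = anat.build_slab_mesh(10, 10, 4, 2)
        assert len(m.tets) == 6 * 5 * 5 * 2 == 300
        assert m.n_vertices == 6 * 6 * 3 == 108
        m2 = anat.build_slab_mesh(20, 20, 6, 1)
        assert len(m2.tets) == 14_400

    @given(
        nx=st.integers(2, 6), ny=st.integers(2, 6), nz=st.integers(1, 4),
        h=st.sampled_from([0.5, 1.0, 2.0]),
    )
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_volume_partition(self, nx, ny, nz, h):
        lx, ly, lz = nx * h, ny * h, nz * h
        m = anat.build_slab_mesh(lx, ly, lz, h)
        assert m.tet_volumes().sum() == pytest.approx(lx * ly * lz, rel=1e-9)
        assert np.all(m.tet_volumes() > 0)

    def test_boundary_tags_cover_facets(self):
        m = anat.build_slab_mesh(8, 8, 4, 2)
        tags = set(m.boundary_tags)
        assert tags == {"ENDO_LV", "ENDO_RV", "EPI", "BASE"}
        # endo + epi facet areas each equal the slab footprint
        assert m.surface_area("EPI") == pytest.approx(64.0, rel=1e-9)
        assert m.surface_area("ENDO_LV") + m.surface_area("ENDO_RV") == pytest.approx(64.0, rel=1e-9)

    def test_h_larger_than_domain_rejected(self):
        with pytest.raises(ValueError):
            anat.build_slab_mesh(10, 10, 4, 5)


@pytest.fixture(scope="module")
def bv():
    return anat.build_biventricular_mesh()


class TestBiventricularMesh:

    def test_hypoplastic_left_cavity(self, bv):
        assert bv.surface_area("ENDO_LV") < 0.3 * bv.surface_area("ENDO_RV")

    def test_single_connected_component(self, bv):
        assert anat._count_components(bv.n_vertices, bv.tets) == 1

    def test_refinement_growth_factor(self, bv):
        fine = anat.build_biventricular_mesh(h=1.25)
        ratio = len(fine.tets) / len(bv.tets)
        assert 6.0 <= ratio <= 10.0

    def test_positive_volumes_and_watertight(self, bv):
        assert np.all(bv.tet_volumes() > 0)
        # every boundary facet tagged exactly once: counts match
        assert len(bv.boundary_faces) == len(bv.boundary_tags)


class TestTransmuralCoordinate:
    def test_exact_linear_solution_on_slab(self, small_slab):
        phi = anat.transmural_coordinate(small_slab)
        exact = small_slab.vertices[:, 2] / small_slab.vertices[:, 2].max()
        assert np.abs(phi - exact).max() < 1e-6

    def test_discrete_maximum_principle(self):
        bv = anat.build_biventricular_mesh(h=2.5)
        phi = anat.transmural_coordinate(bv)
        assert phi.min() >= -1e-9 and phi.max() <= 1 + 1e-9

    def test_missing_tags_rejected(self, small_slab):
        import dataclasses

        broken = anat.Mesh(
            small_slab.vertices, small_slab.tets, small_slab.boundary_faces,
            np.full(len(small_slab.boundary_tags), "BASE", dtype="U8"), small_slab.h,
        )
        with pytest.raises(ValueError):
            anat.transmural_coordinate(broken)


class TestFibers:
    def test_helix_angle_interpolation_on_slab(self, small_slab):
        phi = anat.transmural_coordinate(small_slab)
        f = anat.rule_based_fibers(small_slab, phi, beta_endo=0.0, beta_epi=0.0)
        phi_bar = phi[small_slab.tets].mean(axis=1)
        alpha = np.deg2rad(60.0 * (1 - phi_bar) - 60.0 * phi_bar)
        expected = np.column_stack([np.cos(alpha), np.sin(alpha), np.zeros_like(alpha)])
        assert np.abs(f.f0 - expected).max() < np.deg2rad(0.5)

    def test_midwall_fiber_is_circumferential(self, small_slab):
        phi = anat.transmural_coordinate(small_slab)
        f = anat.rule_based_fibers(small_slab, phi, beta_endo=0.0, beta_epi=0.0)
        phi_bar = phi[small_slab.tets].mean(axis=1)
        mid = np.argmin(np.abs(phi_bar - 0.5))
        if abs(phi_bar[mid] - 0.5) < 1e-9:
            angle = np.degrees(np.arctan2(f.f0[mid, 1], f.f0[mid, 0]))
            assert abs(angle) < 0.5

    def test_unit_norm_everywhere(self):
        bv = anat.build_biventricular_mesh(h=2.5)
        phi = anat.transmural_coordinate(bv)
        f = anat.rule_based_fibers(bv, phi)
        assert np.abs(np.linalg.norm(f.f0, axis=1) - 1.0).max() < 1e-9

    def test_invariant_under_vertex_permutation(self, small_slab):
        phi = anat.transmural_coordinate(small_slab)
        f1 = anat.rule_based_fibers(small_slab, phi)
        rng = np.random.default_rng(0)
        perm = rng.permutation(small_slab.n_vertices)
        inv = np.argsort(perm)
        m2 = anat.Mesh(small_slab.vertices[perm], inv[small_slab.tets],
                       inv[small_slab.boundary_faces], small_slab.boundary_tags, small_slab.h)
        f2 = anat.rule_based_fibers(m2, phi[perm])
        assert np.abs(f1.f0 - f2.f0).max() < 1e-12


class TestPurkinje:
    def test_terminal_count_bound(self, small_slab):
        pk = anat.generate_purkinje(small_slab, seed=1, n_generations=5, branch_len=2.0)
        for bundle in ("LEFT", "RIGHT"):
            n_term = np.sum(np.isin(pk.pmj_nodes, pk.bundle_nodes(bundle)))
            assert n_term <= 2**5

    def test_seed_determinism(self, small_slab):
        a = anat.generate_purkinje(small_slab, seed=3, n_generations=4, branch_len=3.0)
        b = anat.generate_purkinje(small_slab, seed=3, n_generations=4, branch_len=3.0)
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.edges, b.edges)
        c = anat.generate_purkinje(small_slab, seed=4, n_generations=4, branch_len=3.0)
        assert not np.array_equal(a.nodes, c.nodes)

    def test_forest_of_two_trees(self, small_slab):
        pk = anat.generate_purkinje(small_slab, seed=1, n_generations=4, branch_len=3.0)
        # a forest: every non-root node has exactly one parent edge
        children = pk.edges[:, 1]
        assert len(children) == len(set(children))
        assert set(pk.roots) == {"LEFT", "RIGHT"}
        assert np.all(pk.edge_lengths() > 0)

    def test_pmjs_stay_near_surface(self, small_slab):
        pk = anat.generate_purkinje(small_slab, seed=2, n_generations=4, branch_len=3.0)
        # endocardial surface is z = 0 on the slab
        assert np.abs(pk.nodes[pk.pmj_nodes][:, 2]).max() < small_slab.h


class TestElectrodes:
    def test_nine_unique_labels_and_clearance(self, small_slab):
        es = anat.place_electrodes(small_slab)
        assert set(es.positions) == set(anat.ElectrodeSet.LABELS)
        from scipy.spatial import cKDTree

        tree = cKDTree(small_slab.vertices)
        for p in es.positions.values():
            assert tree.query(p)[0] >= 10.0

    def test_translation_equivariance(self, small_slab):
        es1 = anat.place_electrodes(small_slab)
        shift = np.array([5.0, -3.0, 2.0])
        m2 = anat.Mesh(small_slab.vertices + shift, small_slab.tets,
                       small_slab.boundary_faces, small_slab.boundary_tags, small_slab.h)
        es2 = anat.place_electrodes(m2)
        for k in es1.positions:
            assert np.allclose(es2.positions[k], es1.positions[k] + shift)

    def test_too_small_torso_rejected(self, small_slab):
        with pytest.raises(ValueError):
            anat.place_electrodes(small_slab, torso_scale=0.8)
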