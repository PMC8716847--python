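import numpy as np
import pytest
from scipy import integrate

from cardioem.geometry import (LVGeometry, build_cable, build_lv_ellipsoid,
                               build_mapping, build_sheet, place_electrodes,
                               assign_layers, assign_streeter_fibers,
                               surface_closed_defect, surface_volume)


class TestLVEllipsoid:
    def test_cavity_volume_matches_analytic_integral(self, lv_geometry,
                                                     lv_meshes):
        ep, mech = lv_meshes
        ai, bi, ci = lv_geometry.inner
        # independent solid-of-revolution integral of the inner shell
        val, _ = integrate.quad(
            lambda z: np.pi * ai * bi * (1 - z**2 / ci**2),
            -ci, lv_geometry.z_base)
        analytic = val / 1000.0
        assert analytic == pytest.approx(
            lv_geometry.analytic_cavity_volume(), rel=1e-10)
        for mesh in (ep, mech):
            assert mesh.cavity_volume() == pytest.approx(analytic, rel=0.05)

    def test_degenerate_wall_rejected(self):
        with pytest.raises(ValueError):
            LVGeometry(wall=0.0)
        with pytest.raises(ValueError):
            LVGeometry(wall=40.0)  # wall exceeds a semi-axis

    def test_refinement_scaling(self, lv_geometry):
        ep1, _ = build_lv_ellipsoid(lv_geometry, ep_edge=4.0, mech_edge=13.0)
        ep2, _ = build_lv_ellipsoid(lv_geometry, ep_edge=2.0, mech_edge=13.0)
        assert ep2.n_elems >= 4 * ep1.n_elems

    def test_positive_volumes_and_coordinate_ranges(self, lv_meshes):
        for mesh in lv_meshes:
            assert (mesh.element_volumes() > 0).all()
            for f in (mesh.transmural, mesh.apicobasal):
                assert f.min() >= 0.0 and f.max() <= 1.0
            e = mesh.transmural
            assert (e[mesh.node_sets["endocardium"]] < 0.05).all()
            assert (e[mesh.node_sets["epicardium"]] > 0.95).all()

    def test_cavity_surface_closed_and_orientation_stable(self, lv_meshes):
        ep, _ = lv_meshes
        faces = ep.face_sets["cavity"]
        assert surface_closed_defect(ep.nodes, faces) < 1e-8
        v = surface_volume(ep.nodes, faces)
        # reordering the face list must not change the signed volume
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(faces))
        assert surface_volume(ep.nodes, faces[perm]) == pytest.approx(v)

    def test_ep_edge_must_not_exceed_mech_edge(self, lv_geometry):
        with pytest.raises(ValueError):
            build_lv_ellipsoid(lv_geometry, ep_edge=9.0, mech_edge=3.0)


class TestFibers:
    def test_helix_angle_endpoints_and_midpoint(self, lv_meshes):
        ep, _ = lv_meshes
        e = ep.element_transmural()
        # recompute the helix angle from the assigned frame
        c = ep.element_centroids()
        zhat = np.array([0.0, 0.0, 1.0])
        radial = c / np.linalg.norm(c, axis=1, keepdims=True)
        circ = np.cross(zhat, radial)
        ok = np.linalg.norm(circ, axis=1) > 1e-6
        circ = circ[ok] / np.linalg.norm(circ[ok], axis=1, keepdims=True)
        longi = np.cross(radial[ok], circ)
        longi /= np.linalg.norm(longi, axis=1, keepdims=True)
        f = ep.fiber_f[ok]
        alpha = np.degrees(np.arctan2((f * longi).sum(1), (f * circ).sum(1)))
        expected = 60.0 + e[ok] * (-120.0)
        # the sheet-orthogonalization perturbs the frame only slightly
        near_endo = e[ok] < 0.02
        near_epi = e[ok] > 0.98
        mid = np.abs(e[ok] - 0.5) < 0.02
        if near_endo.any():
            assert np.allclose(alpha[near_endo], 60.0, atol=6.0)
        if near_epi.any():
            assert np.allclose(alpha[near_epi], -60.0, atol=6.0)
        if mid.any():
            assert np.allclose(alpha[mid], 0.0, atol=6.0)
        assert np.abs(alpha - expected[...]).max() < 8.0

    def test_frame_orthonormality(self, lv_meshes):
        for mesh in lv_meshes:
            for v in (mesh.fiber_f, mesh.fiber_s, mesh.fiber_sn):
                assert np.abs(np.linalg.norm(v, axis=1) - 1).max() < 1e-9
            for a, b in [(mesh.fiber_f, mesh.fiber_s),
                         (mesh.fiber_f, mesh.fiber_sn),
                         (mesh.fiber_s, mesh.fiber_sn)]:
                assert np.abs((a * b).sum(1)).max() < 1e-9

    def test_missing_transmural_raises(self, lv_meshes):
        ep, _ = lv_meshes
        import dataclasses
        bare = dataclasses.replace(ep, transmural=None)
        with pytest.raises(ValueError):
            assign_streeter_fibers(bare)


class TestLayers:
    @pytest.mark.parametrize("frac,expect", [
        (0.0, "all_epi"), (1.0, "all_endo")])
    def test_degenerate_fractions(self, lv_meshes, frac, expect):
        ep, _ = lv_meshes
        assign_layers(ep, frac)
        if expect == "all_epi":
            assert (ep.layer == 1).all()
        else:
            assert (ep.layer == 0).all()
        assign_layers(ep, 0.2)  # restore default

    def test_default_20_percent_layer(self, lv_meshes):
        ep, _ = lv_meshes
        assign_layers(ep, 0.2)
        e = ep.element_transmural()
        assert (ep.layer[e < 0.2] == 0).all()
        assert (ep.layer[e >= 0.2] == 1).all()

    def test_invalid_fraction(self, lv_meshes):
        with pytest.raises(ValueError):
            assign_layers(lv_meshes[0], 1.5)


class TestElectrodes:
    def test_standard_set_40mm_outside_epicardium(self, lv_geometry):
        el = place_electrodes()
        assert len(el.names) == 9
        g = lv_geometry
        th = np.linspace(-np.pi / 2, np.arcsin(g.z_base / g.cz), 120)
        ph = np.linspace(0, 2 * np.pi, 240)
        T, P = np.meshgrid(th, ph)
        surf = np.stack([g.ax * np.cos(T) * np.cos(P),
                         g.by * np.cos(T) * np.sin(P),
                         g.cz * np.sin(T)], -1).reshape(-1, 3)
        for p in el.positions:
            assert np.linalg.norm(surf - p, axis=1).min() >= 40.0

    def test_similarity_scaling(self):
        e1 = place_electrodes(scale=1.0)
        e2 = place_electrodes(scale=2.0)
        assert np.allclose(e2.positions, 2.0 * e1.positions)

    def test_duplicate_names_rejected(self):
        from cardioem.geometry import TorsoElectrodes
        with pytest.raises(ValueError):
            TorsoElectrodes(names=["RA", "RA"], positions=np.zeros((2, 3)))


class TestFixtures:
    def test_cable_node_count_convention(self):
        cable = build_cable(20.0, 0.7)
        assert cable.n_nodes == int(np.floor(20.0 / 0.7)) + 1 == 29

    def test_sheet_fiber_transverse_axes(self):
        sheet = build_sheet(10.0, 20.0, 0.7)
        assert np.allclose(sheet.fiber_f, [1, 0, 0])
        assert np.allclose(sheet.fiber_s, [0, 1, 0])

    @pytest.mark.parametrize("dx", [0.0, -1.0])
    def test_invalid_spacing(self, dx):
        with pytest.raises(ValueError):
            build_cable(20.0, dx)
        with pytest.raises(ValueError):
            build_sheet(10.0, 20.0, dx)


@pytest.fixture(scope="module")
def mapping(lv_meshes):
    return build_mapping(*lv_meshes)


class TestMapping:
    def test_partition_of_unity(self, lv_meshes, mapping):
        ep, mech = lv_meshes
        assert np.abs(mapping.mech_to_ep @ np.ones(mech.n_nodes)
                      - 1).max() < 1e-10
        assert np.abs(mapping.ep_to_mech_q @ np.ones(ep.n_nodes)
                      - 1).max() < 1e-10

    def test_linear_field_reproduced_exactly(self, lv_meshes, mapping):
        ep, mech = lv_meshes
        coef = np.array([1.3, -0.7, 0.2])
        err = np.abs(mapping.mech_to_ep @ (mech.nodes @ coef)
                     - ep.nodes @ coef)
        assert err.max() / np.abs(ep.nodes @ coef).max() < 1e-8

    def test_linear_weights_non_negative(self, mapping):
        assert mapping.ep_to_mech_q.data.min() > -1e-6

    def test_mapping_constant_under_deformation(self, lv_meshes, mapping):
        # the operators are built from the reference configuration only;
        # rebuilding after moving the mech mesh must be a caller error,
        # not something the mapping does implicitly
        ep, mech = lv_meshes
        before = mapping.mech_to_ep.copy()
        mech_nodes_backup = mech.nodes.copy()
        try:
            mech.nodes = mech.nodes + 1.7  # rigid translation
            assert (mapping.mech_to_ep != before).nnz == 0
        finally:
            mech.nodes = mech_nodes_backup
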