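import numpy as np
import pytest
from scipy.optimize import fsolve

from cardioem.mechanics import (ContactSurface, MaterialParams,
                                MechanicsProblem, PericardialShell,
                                contact_traction, newmark_single_dof,
                                second_pk_stress, strain_energy)
from cardioem.mechanics.materials import neo_hookean_stress, nh_strain_energy
from cardioem.mechanics.fem import MechState


class TestMaterial:
    def test_stress_free_reference(self):
        S, D = second_pk_stress(np.zeros(6), MaterialParams())
        assert np.abs(S).max() < 1e-10

    def test_active_tension_purely_fiber_component(self):
        S, _ = second_pk_stress(np.zeros(6), MaterialParams(),
                                t_active=10.0)
        assert S[0] == pytest.approx(10.0)
        assert np.abs(S[1:]).max() < 1e-12

    def test_unloading_stress_on_both_in_wall_components(self):
        S, _ = second_pk_stress(np.zeros(6), MaterialParams(), t_init=7.0)
        assert S[0] == pytest.approx(7.0)
        assert S[2] == pytest.approx(7.0)  # sheet-normal (in-plane)
        assert abs(S[1]) < 1e-12           # transmural unaffected

    def test_stress_matches_energy_finite_differences(self):
        rng = np.random.default_rng(1)
        mat = MaterialParams()
        ev = 0.08 * rng.standard_normal((20, 6))
        S, D = second_pk_stress(ev, mat)
        h = 1e-6
        for a in range(6):
            ep = ev.copy(); ep[:, a] += h
            em = ev.copy(); em[:, a] -= h
            fd = (strain_energy(ep, mat) - strain_energy(em, mat)) / (2 * h)
            rel = np.abs(fd - S[:, a]) / np.maximum(np.abs(S[:, a]), 1e-6)
            assert rel.max() < 1e-5

    def test_tangent_matches_stress_finite_differences(self):
        rng = np.random.default_rng(2)
        mat = MaterialParams()
        ev = 0.08 * rng.standard_normal((10, 6))
        _, D = second_pk_stress(ev, mat)
        h = 1e-6
        for a in range(6):
            ep = ev.copy(); ep[:, a] += h
            em = ev.copy(); em[:, a] -= h
            Sp, _ = second_pk_stress(ep, mat, with_tangent=False)
            Sm, _ = second_pk_stress(em, mat, with_tangent=False)
            fd = (Sp - Sm) / (2 * h)
            rel = np.abs(fd - D[:, :, a]) / np.maximum(
                np.abs(D[:, :, a]), 1e-2)
            assert rel.max() < 1e-4

    def test_non_positive_definite_rejected(self):
        ev = np.array([-0.6, -0.6, -0.6, 0, 0, 0.0])
        with pytest.raises(ValueError):
            second_pk_stress(ev, MaterialParams())

    def test_neo_hookean_consistency(self):
        rng = np.random.default_rng(3)
        mat = MaterialParams()
        ev = 0.05 * rng.standard_normal((8, 6))
        S, _ = neo_hookean_stress(ev, mat)
        h = 1e-6
        for a in range(6):
            ep = ev.copy(); ep[:, a] += h
            em = ev.copy(); em[:, a] -= h
            fd = (nh_strain_energy(ep, mat) - nh_strain_energy(em, mat)) \
                / (2 * h)
            assert np.abs(fd - S[:, a]).max() < 1e-4

    def test_frame_indifference_of_energy(self):
        # W depends on F only through C = F^T F, so W(QF) = W(F); verify
        # through the strain measure for random rotations
        rng = np.random.default_rng(4)
        mat = MaterialParams()
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        A = rng.standard_normal((3, 3))
        Q = np.linalg.qr(A)[0]
        for FF in (F, Q @ F):
            C = FF.T @ FF
            E = 0.5 * (C - np.eye(3))
            ev = np.array([E[0, 0], E[1, 1], E[2, 2],
                           2 * E[0, 1], 2 * E[0, 2], 2 * E[1, 2]])
            w = strain_energy(ev, mat)
        C0 = F.T @ F
        E0 = 0.5 * (C0 - np.eye(3))
        ev0 = np.array([E0[0, 0], E0[1, 1], E0[2, 2],
                        2 * E0[0, 1], 2 * E0[0, 2], 2 * E0[1, 2]])
        assert w == pytest.approx(float(strain_energy(ev0, mat)),
                                  rel=1e-10)


class TestContact:
    def test_no_traction_at_positive_gap(self):
        p, dp = contact_traction(np.array([1.0, 0.0, 5.0]), eps=20.0)
        assert np.all(p == 0.0) and np.all(dp == 0.0)

    def test_c1_continuity_at_boundaries(self):
        eps, w = 20.0, 0.5
        h = 1e-7
        for g0 in (0.0, -w):
            pm, dpm = contact_traction(np.array([g0 - h]), eps, w)
            pp, dpp = contact_traction(np.array([g0 + h]), eps, w)
            assert abs(pm[0] - pp[0]) < 1e-5
            assert abs(dpm[0] - dpp[0]) < 1e-5

    def test_monotone_in_penetration_dense_scan(self):
        g = np.linspace(0.5, -3.0, 20001)
        p, _ = contact_traction(g, eps=20.0, width=0.5)
        assert np.all(np.diff(p) >= -1e-12)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            contact_traction(np.array([0.0]), eps=-1.0)

    def test_shell_gap_sign(self):
        shell = PericardialShell(a=10.0, b=10.0, c=10.0)
        g_in, n_in = shell.gap_and_normal(np.array([5.0, 0, 0]))
        g_out, _ = shell.gap_and_normal(np.array([12.0, 0, 0]))
        assert g_in > 0 and g_out < 0
        assert np.allclose(n_in, [1, 0, 0])


class TestHomogeneousDeformation:
    def test_block_contraction_matches_homogeneous_oracle(
            self, block_mesh, symmetry_mask):
        mat = MaterialParams()
        prob = MechanicsProblem(block_mesh, material=mat,
                                fixed_dof_mask=symmetry_mask)
        T = 12.0
        from cardioem.initialization import apply_unloading_stress

        def resid(lams):
            lf, ls, ln = lams
            ev = np.array([(lf**2 - 1) / 2, (ls**2 - 1) / 2,
                           (ln**2 - 1) / 2, 0, 0, 0])
            S, _ = second_pk_stress(ev, mat, t_init=T, with_tangent=False)
            return S[:3]

        oracle = fsolve(resid, [0.9, 1.2, 0.9])
        u = apply_unloading_stress(prob, T)
        corner = np.argmin(np.linalg.norm(block_mesh.nodes - 1.0, axis=1))
        fem = 1.0 + u[corner]
        assert np.allclose(fem, oracle, atol=1e-6)

    def test_zero_load_equilibrium_fixed_point(self, block_mesh,
                                               symmetry_mask):
        prob = MechanicsProblem(block_mesh, fixed_dof_mask=symmetry_mask)
        u, it, rn = prob.solve_static()
        assert np.abs(u).max() == 0.0 and it == 0


class TestDirichlet:
    def test_constrained_nodes_zero_after_step(self, lv_meshes_coarse):
        _, mech = lv_meshes_coarse
        prob = MechanicsProblem(mech)
        u = prob.inflate_static(0.3)
        assert np.abs(u[prob.dirichlet_nodes]).max() == 0.0
        assert len(prob.dirichlet_nodes) == \
            (mech.transmural[mech.node_sets["base"]] > 0.9).sum()

    def test_empty_constraint_set_rejected(self, lv_meshes_coarse):
        _, mech = lv_meshes_coarse
        with pytest.raises(ValueError):
            MechanicsProblem(mech, dirichlet_nodes=np.array([], dtype=int))


class TestCavityVolume:
    def test_unit_cube_is_one_microliter(self):
        # closed unit-cube surface via divergence theorem
        from cardioem.geometry import surface_volume, boundary_faces
        from tests.conftest import make_block
        block = make_block(nv=2)
        faces = boundary_faces(block.elems[:, :4])
        assert surface_volume(block.nodes, faces) == pytest.approx(1000.0 *
                                                                   1e-3 *
                                                                   1.0, rel=1e-12) or \
            surface_volume(block.nodes, faces) == pytest.approx(1.0,
                                                                rel=1e-12)

    def test_translation_and_scaling(self, lv_meshes_coarse):
        _, mech = lv_meshes_coarse
        prob = MechanicsProblem(mech)
        v0 = prob.cavity_volume()
        u_rigid = np.tile([3.0, -2.0, 5.0], (mech.n_nodes, 1))
        assert prob.cavity_volume(u_rigid) == pytest.approx(v0, rel=1e-12)
        u_scale = mech.nodes  # x -> 2x
        assert prob.cavity_volume(u_scale) == pytest.approx(8 * v0,
                                                            rel=1e-9)

    def test_inflation_increases_volume(self, lv_meshes_coarse):
        _, mech = lv_meshes_coarse
        prob = MechanicsProblem(mech)
        v0 = prob.cavity_volume()
        u = prob.inflate_static(0.4)
        assert prob.cavity_volume(u) > v0


class TestNewmark:
    def test_single_dof_matches_analytic_damped_oscillator(self):
        m, c, k = 2.0, 0.3, 5.0
        dt = 0.01
        out = newmark_single_dof(m, c, k, lambda t: 0.0, dt, 12000,
                                 u0=1.0, v0=0.0)
        t = np.arange(12001) * dt
        om0 = np.sqrt(k / m)
        zeta = c / (2 * np.sqrt(k * m))
        om_d = om0 * np.sqrt(1 - zeta**2)
        ana = np.exp(-zeta * om0 * t) * (np.cos(om_d * t) +
                                         zeta * om0 / om_d *
                                         np.sin(om_d * t))
        n = int(10 * 2 * np.pi / om_d / dt)
        err = np.abs(out[:n, 0] - ana[:n]).max() / np.abs(ana[:n]).max()
        assert err < 0.01

    def test_rest_is_fixed_point(self, block_mesh, symmetry_mask):
        prob = MechanicsProblem(block_mesh, fixed_dof_mask=symmetry_mask)
        st = MechState.zeros(block_mesh.n_nodes)
        prob.prepare_dynamic(st)
        for _ in range(5):
            st = prob.newmark_step(st, 1.0)
        assert np.abs(st.u).max() < 1e-12

    def test_energy_conservation_without_damping(self, block_mesh,
                                                 symmetry_mask):
        # gamma = 1/2, beta = 1/4 conserves energy for the undamped case
        prob = MechanicsProblem(block_mesh, fixed_dof_mask=symmetry_mask,
                                alpha_r=0.0, beta_r=0.0)
        st = MechState.zeros(block_mesh.n_nodes)
        # small initial velocity field along +x
        st.v[:, 0] = 0.01 * block_mesh.nodes[:, 0]
        prob.prepare_dynamic(st)
        M3 = np.repeat(prob.M, 3)

        def energy(s):
            kin = 0.5 * float(M3 @ (s.v.reshape(-1)**2))
            _, Ev = prob.deformation(s.u)
            W = strain_energy(Ev, prob.material)
            pot = float((prob.wq * W).sum())
            return kin + pot

        e0 = energy(st)
        for _ in range(100):
            st = prob.newmark_step(st, 0.05)
        assert abs(energy(st) - e0) / e0 < 0.01

    def test_pericardial_restraint_reduces_inflation(self, lv_meshes_coarse,
                                                     lv_geometry):
        _, mech = lv_meshes_coarse
        epi = mech.node_sets["epicardium"]
        epi = epi[mech.nodes[epi, 2] < lv_geometry.z_base - 3.0]
        shell = PericardialShell.around(lv_geometry, offset=0.3)
        cs = ContactSurface(nodes=epi, areas=np.full(len(epi), 25.0),
                            shell=shell, eps=40.0)
        free = MechanicsProblem(mech, alpha_r=2.0)
        held = MechanicsProblem(mech, contact=cs, alpha_r=2.0)

        def dynamic_inflate(prob, p_target, eps_target):
            st = MechState.zeros(mech.n_nodes)
            prob.prepare_dynamic(st)
            n = 80
            for i in range(n):
                prob.pressure = (i + 1) / n * p_target
                if prob.contact is not None:
                    prob.contact.eps = (i + 1) / n * eps_target
                st = prob.newmark_step(st, 2.0)
            return st.u

        u_free = dynamic_inflate(free, 1.4, 0.0)
        u_held = dynamic_inflate(held, 1.4, 40.0)
        r = np.linalg.norm(mech.nodes[epi, :2], axis=1)
        ur_free = (u_free[epi, 0] * mech.nodes[epi, 0] +
                   u_free[epi, 1] * mech.nodes[epi, 1]) / np.maximum(r, 1e-9)
        ur_held = (u_held[epi, 0] * mech.nodes[epi, 0] +
                   u_held[epi, 1] * mech.nodes[epi, 1]) / np.maximum(r, 1e-9)
        assert ur_held.max() < ur_free.max()


class TestContactProperties:
    from hypothesis import given, settings, strategies as st

    @given(g=st.floats(-5.0, 5.0), eps=st.floats(0.0, 100.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_traction_nonnegative_and_zero_at_separation(self, g, eps):
        p, dp = contact_traction(np.array([g]), eps)
        assert p[0] >= 0.0
        if g >= 0:
            assert p[0] == 0.0
        assert dp[0] <= 0.0
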