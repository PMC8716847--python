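"""Total-Lagrangian finite-element mechanics on quadratic tetrahedra.

Quasi-incompressible anisotropic hyperelastic ventricular wall with
active stress on the fiber-fiber component of the second
Piola-Kirchhoff tensor, follower cavity-pressure loads, rigid-shell
pericardial penalty contact, Rayleigh damping (alpha_R M + beta_R K,
with K lagged by one step), and Newmark-beta time integration (average
acceleration, gamma = 1/2, beta = 1/4) solved by Newton iteration with
a direct sparse solver to a residual norm below 1e-8.

Elements are 10-node tetrahedra with straight edges (midside nodes at
edge midpoints), so the isoparametric map is affine and the reference
shape-function gradients are precomputed per quadrature point.  All
strain/stress algebra is carried out directly in the local fiber frame
by rotating the material gradients once during setup.

The consistent tangent of the follower pressure load is omitted (the
load stiffness is unsymmetric and small at physiological pressures);
Newton convergence is unaffected at the step sizes used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from ..geometry import HeartMesh, surface_volume
from ..units import RHO_MYOCARDIUM
from .contact import ContactSurface
from .materials import MaterialParams, second_pk_stress

__all__ = ["MechanicsProblem", "MechState", "newmark_single_dof"]

DEBUG_NEWTON = False

# 4-point Gauss rule for tetrahedra (degree 2, positive weights)
_QA = 0.5854101966249685
_QB = 0.1381966011250105
QPOINTS = np.array([
    [_QA, _QB, _QB], [_QB, _QA, _QB], [_QB, _QB, _QA], [_QB, _QB, _QB]])
QWEIGHTS = np.full(4, 0.25)

# Newmark average-acceleration parameters
NEWMARK_GAMMA = 0.5
NEWMARK_BETA = 0.25


def _tet10_dshape(xi: np.ndarray) -> np.ndarray:
    """dN/d(xi,eta,zeta) for the 10-node tet at barycentric-free coords."""
    x, y, z = xi
    l0 = 1.0 - x - y - z
    lam = np.array([l0, x, y, z])
    # dlam/dxi
    dl = np.array([[-1.0, -1.0, -1.0],
                   [1.0, 0.0, 0.0],
                   [0.0, 1.0, 0.0],
                   [0.0, 0.0, 1.0]])
    dN = np.zeros((10, 3))
    for a in range(4):
        dN[a] = (4.0 * lam[a] - 1.0) * dl[a]
    edges = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]
    for k, (a, b) in enumerate(edges):
        dN[4 + k] = 4.0 * (lam[a] * dl[b] + lam[b] * dl[a])
    return dN


def _tet10_shape(xi: np.ndarray) -> np.ndarray:
    x, y, z = xi
    l0 = 1.0 - x - y - z
    lam = np.array([l0, x, y, z])
    N = np.zeros(10)
    for a in range(4):
        N[a] = lam[a] * (2.0 * lam[a] - 1.0)
    edges = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]
    for k, (a, b) in enumerate(edges):
        N[4 + k] = 4.0 * lam[a] * lam[b]
    return N


# T6 surface triangle: nodes (a, b, c, m_ab, m_bc, m_ca)
_T6_QP = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_T6_QW = np.full(3, 1.0 / 6.0)


def _t6_shape(xi):
    r, s = xi
    t = 1.0 - r - s
    return np.array([t * (2 * t - 1), r * (2 * r - 1), s * (2 * s - 1),
                     4 * t * r, 4 * r * s, 4 * s * t])


def _t6_dshape(xi):
    r, s = xi
    t = 1.0 - r - s
    # d/dr, d/ds
    return np.array([
        [-(4 * t - 1), -(4 * t - 1)],
        [4 * r - 1, 0.0],
        [0.0, 4 * s - 1],
        [4 * (t - r), -4 * r],
        [4 * s, 4 * r],
        [-4 * s, 4 * (t - s)],
    ])


@dataclass
class MechState:
    """Nodal kinematics and last assembled quantities."""

    u: np.ndarray                 # (N, 3) displacement, mm
    v: np.ndarray                 # velocity, mm/ms
    a: np.ndarray                 # acceleration, mm/ms^2
    time: float = 0.0
    newton_iters: int = 0
    residual: float = 0.0

    @classmethod
    def zeros(cls, n: int):
        return cls(u=np.zeros((n, 3)), v=np.zeros((n, 3)),
                   a=np.zeros((n, 3)))


class MechanicsProblem:
    """Assembly and solution driver for the ventricular wall.

    Parameters
    ----------
    mesh : HeartMesh (order 2)
    material : MaterialParams
    dirichlet_nodes : array of node indices with all DOFs fixed
        (idealized setup: the basal vessel-analog ring; the pericardial
        shell itself is rigid).
    contact : ContactSurface or None
    alpha_r, beta_r : Rayleigh damping, 1/ms and ms
        (defaults = 100 1/s and 0.04 s in package units).
    """

    def __init__(self, mesh: HeartMesh, material: MaterialParams | None = None,
                 dirichlet_nodes: np.ndarray | None = None,
                 contact: ContactSurface | None = None,
                 alpha_r: float = 0.1, beta_r: float = 40.0,
                 rho: float = RHO_MYOCARDIUM,
                 fixed_dof_mask: np.ndarray | None = None):
        if mesh.order != 2:
            raise ValueError("mechanics mesh must use quadratic tetrahedra")
        self.mesh = mesh
        self.material = material or MaterialParams()
        self.alpha_r = alpha_r
        self.beta_r = beta_r
        self.contact = contact

        self._fixed_dof_mask = fixed_dof_mask
        if fixed_dof_mask is not None:
            self.dirichlet_nodes = np.flatnonzero(
                fixed_dof_mask.reshape(-1, 3).all(axis=1))
            if not fixed_dof_mask.any():
                raise ValueError("empty Dirichlet set: rigid-body motion "
                                 "would make the system singular")
        else:
            if dirichlet_nodes is None:
                dirichlet_nodes = self._default_dirichlet()
            self.dirichlet_nodes = np.asarray(dirichlet_nodes, dtype=np.int64)
            if len(self.dirichlet_nodes) == 0:
                raise ValueError("empty Dirichlet set: rigid-body motion "
                                 "would make the system singular")

        self._setup_elements()
        self._setup_mass(rho)
        self._setup_dofs()
        self._setup_faces()
        self.t_active = np.zeros(self.n_qp)
        self.t_init = 0.0
        self.pressure = 0.0
        self.body_force = None
        self._K_lagged = None
        self._K_newton = None
        self._lu = None
        self._lu_sig = None
        self._lu_age = 0

    # -- setup -------------------------------------------------------------
    def _default_dirichlet(self):
        m = self.mesh
        base = m.node_sets.get("base")
        if base is None or m.transmural is None:
            raise ValueError("mesh lacks base labels for default Dirichlet")
        e = m.transmural[base]
        ring = base[e > 0.9]
        return ring

    def _setup_elements(self):
        m = self.mesh
        E = m.n_elems
        c4 = m.elems[:, :4]
        x = m.nodes
        # affine Jacobian from corners: rows are edge vectors
        J = np.stack([x[c4[:, i]] - x[c4[:, 0]] for i in (1, 2, 3)], axis=1)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise ValueError("inverted elements in mechanics mesh")
        Jinv = np.linalg.inv(J)
        nq = len(QPOINTS)
        dN = np.stack([_tet10_dshape(q) for q in QPOINTS])  # (nq,10,3)
        # J rows are edge vectors, i.e. J = (dX/dxi)^T, so
        # dN/dX_k = sum_d dN/dxi_d (dxi/dX)_{dk} with dxi/dX = Jinv^T
        G = np.einsum("qad,ekd->eqak", dN, Jinv)
        # rotate into the fiber frame: columns of Q are (f, s, sn)
        Q = np.stack([m.fiber_f, m.fiber_s, m.fiber_sn], axis=2)  # (E,3,3)
        self.Qf = Q
        self.G = np.einsum("eqad,edk->eqak", G, Q)  # fiber-frame gradients
        # element volume = detJ/6; the four weights sum to the volume
        self.wq = QWEIGHTS[None, :] * (detJ[:, None] / 6.0)
        self.n_qp = E * nq
        self.qpoints = np.einsum("qa,eaj->eqj",
                                 np.stack([_tet10_shape(q) for q in QPOINTS]),
                                 x[m.elems]).reshape(-1, 3)
        # scatter pattern for (E,30,30) element matrices
        edof = (m.elems[:, :, None] * 3 + np.arange(3)).reshape(E, 30)
        self.edof = edof
        self._Krows = np.repeat(edof, 30, axis=1).ravel()
        self._Kcols = np.tile(edof, (1, 30)).ravel()

    def _setup_mass(self, rho):
        m = self.mesh
        Nq = np.stack([_tet10_shape(q) for q in QPOINTS])  # (nq,10)
        # quadrature-diagonal lumping, rescaled to the exact element mass
        diag_e = np.einsum("eq,qa->ea", self.wq, Nq**2)
        vol_e = self.wq.sum(axis=1)
        diag_e *= (vol_e / diag_e.sum(axis=1))[:, None]
        Mv = np.zeros(m.n_nodes)
        np.add.at(Mv, m.elems.ravel(), (rho * diag_e).ravel())
        self.M = Mv  # (N,) lumped mass, mg

    def _setup_dofs(self):
        n = self.mesh.n_nodes
        fixed = np.zeros(n, dtype=bool)
        fixed[self.dirichlet_nodes] = True
        self.fixed_nodes = fixed
        if self._fixed_dof_mask is not None:
            free = ~self._fixed_dof_mask.reshape(-1)
        else:
            free = ~np.repeat(fixed, 3)
        self.free = free
        self.n_dof = int(free.sum())

    def _setup_faces(self):
        """Quadratic endocardial faces for pressure and cavity volume."""
        m = self.mesh
        edge_mid = {}
        edges = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]
        for el in m.elems:
            for k, (a, b) in enumerate(edges):
                key = (min(el[a], el[b]), max(el[a], el[b]))
                edge_mid[key] = el[4 + k]
        self._edge_mid = edge_mid

        def quad_face(tri):
            a, b, c = tri
            mab = edge_mid[(min(a, b), max(a, b))]
            mbc = edge_mid[(min(b, c), max(b, c))]
            mca = edge_mid[(min(c, a), max(c, a))]
            return [a, b, c, mab, mbc, mca]

        endo = m.face_sets.get("endocardium")
        self.endo6 = np.array([quad_face(t) for t in endo]) \
            if endo is not None and len(endo) else None

        cav = m.face_sets.get("cavity")
        if cav is not None:
            tris = []
            for t in cav:
                key = tuple(sorted((t[0], t[1])))
                if key in edge_mid:
                    a, b, c = t
                    try:
                        f6 = quad_face(t)
                    except KeyError:
                        tris.append(list(t))
                        continue
                    a, b, c, mab, mbc, mca = f6
                    tris += [[a, mab, mca], [mab, b, mbc],
                             [mca, mbc, c], [mab, mbc, mca]]
                else:
                    tris.append(list(t))  # cap faces have no midside nodes
            self.cavity_tris = np.array(tris, dtype=np.int64)
        else:
            self.cavity_tris = None

    # -- kinematics and assembly ------------------------------------------
    def deformation(self, u: np.ndarray):
        """Per-qp fiber-frame deformation gradient Fh (E,nq,3,3) and
        engineering Voigt Green-Lagrange strain (E,nq,6)."""
        ue = u[self.mesh.elems]  # (E,10,3)
        Fh = self.Qf[:, None] + np.einsum("eai,eqak->eqik", ue, self.G)
        C = np.einsum("eqki,eqkj->eqij", Fh, Fh)
        Ev = np.empty(C.shape[:2] + (6,))
        Ev[..., 0] = 0.5 * (C[..., 0, 0] - 1.0)
        Ev[..., 1] = 0.5 * (C[..., 1, 1] - 1.0)
        Ev[..., 2] = 0.5 * (C[..., 2, 2] - 1.0)
        Ev[..., 3] = C[..., 0, 1]
        Ev[..., 4] = C[..., 0, 2]
        Ev[..., 5] = C[..., 1, 2]
        return Fh, Ev

    def fiber_stretch(self, u: np.ndarray) -> np.ndarray:
        """lambda_f at every quadrature point (flattened E*nq)."""
        _, Ev = self.deformation(u)
        return np.sqrt(2.0 * Ev[..., 0] + 1.0).ravel()

    def _bmatrix(self, Fh):
        """Engineering-Voigt B operator: dE = sum_a B[...,:,a3] du."""
        G = self.G  # (E,nq,10,3)
        E, nq = Fh.shape[:2]
        B = np.zeros((E, nq, 6, 10, 3))
        pairs = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
        for v, (i, j) in enumerate(pairs):
            if i == j:
                B[:, :, v] = Fh[:, :, None, :, i] * G[..., i, None]
            else:
                B[:, :, v] = Fh[:, :, None, :, i] * G[..., j, None] + \
                    Fh[:, :, None, :, j] * G[..., i, None]
        return B.reshape(E, nq, 6, 30)

    def stress(self, u: np.ndarray, with_tangent=True):
        Fh, Ev = self.deformation(u)
        ta = self.t_active.reshape(Ev.shape[:2])
        S, D = second_pk_stress(Ev, self.material, t_active=ta,
                                t_init=self.t_init,
                                with_tangent=with_tangent)
        return Fh, Ev, S, D

    def internal_force(self, u: np.ndarray, with_tangent=False):
        """Assembled internal force (3N,) and optionally the tangent."""
        Fh, Ev, S, D = self.stress(u, with_tangent)
        B = self._bmatrix(Fh)
        fe = np.einsum("eq,eqva,eqv->ea", self.wq, B, S)  # (E,30)
        f = np.zeros(self.mesh.n_nodes * 3)
        np.add.at(f, self.edof.ravel(), fe.ravel())
        if not with_tangent:
            return f, None
        Ke = np.einsum("eq,eqva,eqvw,eqwb->eab", self.wq, B, D, B,
                       optimize=True)
        # geometric stiffness: (G S G^T) on each displacement component
        Smat = np.zeros(S.shape[:2] + (3, 3))
        idx = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
        for v, (i, j) in enumerate(idx):
            Smat[..., i, j] = S[..., v]
            if i != j:
                Smat[..., j, i] = S[..., v]
        Kg = np.einsum("eq,eqai,eqij,eqbj->eab", self.wq, self.G, Smat,
                       self.G, optimize=True)
        Ke = Ke.reshape(-1, 10, 3, 10, 3)
        for d in range(3):
            Ke[:, :, d, :, d] += Kg
        Ke = Ke.reshape(-1, 30, 30)
        K = sparse.coo_matrix((Ke.ravel(), (self._Krows, self._Kcols)),
                              shape=(3 * self.mesh.n_nodes,) * 2).tocsr()
        return f, K

    # -- external loads ----------------------------------------------------
    def pressure_force(self, u: np.ndarray, p_kpa: float) -> np.ndarray:
        """Follower cavity-pressure load on the endocardium (deformed)."""
        f = np.zeros(self.mesh.n_nodes * 3)
        if self.endo6 is None or p_kpa == 0.0:
            return f
        x = (self.mesh.nodes + u)[self.endo6]  # (F,6,3)
        for q, wq in zip(_T6_QP, _T6_QW):
            N = _t6_shape(q)
            dN = _t6_dshape(q)
            t1 = np.einsum("a,fai->fi", dN[:, 0], x)
            t2 = np.einsum("a,fai->fi", dN[:, 1], x)
            nda = np.cross(t1, t2)  # oriented with the stored face
            fe = -p_kpa * wq * np.einsum("a,fi->fai", N, nda)
            dof = (self.endo6[:, :, None] * 3 + np.arange(3))
            np.add.at(f, dof.ravel(), fe.ravel())
        return f

    def pressure_stiffness(self, u: np.ndarray, p_kpa: float):
        """Consistent (unsymmetric) tangent of the follower pressure
        load; returns d f_pressure / d u as a sparse matrix."""
        if self.endo6 is None or p_kpa == 0.0:
            return None
        x = (self.mesh.nodes + u)[self.endo6]  # (F,6,3)
        Fn = len(self.endo6)
        blocks = np.zeros((Fn, 6, 6, 3, 3))
        eye = np.eye(3)

        def cross_mat(t):
            C = np.zeros(t.shape[:-1] + (3, 3))
            C[..., 0, 1] = -t[..., 2]
            C[..., 0, 2] = t[..., 1]
            C[..., 1, 0] = t[..., 2]
            C[..., 1, 2] = -t[..., 0]
            C[..., 2, 0] = -t[..., 1]
            C[..., 2, 1] = t[..., 0]
            return C

        for q, wq in zip(_T6_QP, _T6_QW):
            N = _t6_shape(q)
            dN = _t6_dshape(q)
            t1 = np.einsum("a,fai->fi", dN[:, 0], x)
            t2 = np.einsum("a,fai->fi", dN[:, 1], x)
            C1 = cross_mat(t1)
            C2 = cross_mat(t2)
            # d(t1 x t2) du_b = -C(t2) dN1_b + C(t1) dN2_b
            dB = -C2[:, None] * dN[None, :, 0, None, None] + \
                C1[:, None] * dN[None, :, 1, None, None]  # (F,6,3,3)
            blocks += -p_kpa * wq * np.einsum("a,fbij->fabij", N, dB)
        dof = (self.endo6[:, :, None] * 3 + np.arange(3)).reshape(Fn, 18)
        rows = np.repeat(dof, 18, axis=1).ravel()
        cols = np.tile(dof, (1, 18)).ravel()
        vals = blocks.transpose(0, 1, 3, 2, 4).reshape(Fn, 18, 18).ravel()
        del eye
        return sparse.coo_matrix((vals, (rows, cols)),
                                 shape=(3 * self.mesh.n_nodes,) * 2).tocsr()

    def contact_force(self, u: np.ndarray):
        """Contact nodal forces (3N,) and stiffness triplets."""
        f = np.zeros(self.mesh.n_nodes * 3)
        if self.contact is None or self.contact.eps == 0.0:
            return f, None
        cn = self.contact.nodes
        x = self.mesh.nodes[cn] + u.reshape(-1, 3)[cn]
        fc, k_nn, normal = self.contact.forces(x)
        dof = (cn[:, None] * 3 + np.arange(3))
        np.add.at(f, dof.ravel(), fc.ravel())
        return f, (cn, k_nn, normal)

    def _contact_stiffness(self, data):
        if data is None:
            return None
        cn, k_nn, normal = data
        nn = np.einsum("c,ci,cj->cij", k_nn, normal, normal)
        rows = np.repeat((cn[:, None] * 3 + np.arange(3)), 3, axis=1).ravel()
        cols = np.tile((cn[:, None] * 3 + np.arange(3)), (1, 3)).ravel()
        return sparse.coo_matrix((nn.ravel(), (rows, cols)),
                                 shape=(3 * self.mesh.n_nodes,) * 2).tocsr()

    def external_force(self, u: np.ndarray):
        f = self.pressure_force(u, self.pressure)
        fc, cdata = self.contact_force(u)
        f += fc
        if self.body_force is not None:
            f += self.body_force
        return f, cdata

    # -- volumes -----------------------------------------------------------
    def cavity_volume(self, u: np.ndarray | None = None) -> float:
        """Deformed cavity volume (mL)."""
        if self.cavity_tris is None:
            raise ValueError("mesh has no closed cavity surface")
        x = self.mesh.nodes if u is None else self.mesh.nodes + u
        return surface_volume(x, self.cavity_tris) / 1000.0

    # -- solvers -----------------------------------------------------------
    # The tangent is expensive to factor relative to a residual
    # evaluation, so Newton runs in modified form: the last LU is reused
    # across iterations and steps and refreshed only when the residual
    # stalls or the step signature (dt) changes.

    def _factorize(self, u, dt_sig):
        """Assemble and factor the effective tangent at u."""
        _, K = self.internal_force(u, with_tangent=True)
        _, cdata = self.external_force(u)
        Kc = self._contact_stiffness(cdata)
        A = K + Kc if Kc is not None else K
        Kp = self.pressure_stiffness(u, self.pressure)
        if Kp is not None:
            A = A - Kp
        if dt_sig is not None:
            c_a, c_v, M3, Kd = dt_sig
            A = A + sparse.diags(c_a * M3 + c_v * self.alpha_r * M3) + \
                (c_v * self.beta_r) * Kd
        self._lu = splu(A[self.free][:, self.free].tocsc())
        self._K_newton = K
        return K

    def solve_static(self, u0: np.ndarray | None = None, tol: float = 1e-8,
                     max_iter: int = 100, relax: float = 1.0,
                     reuse_lu: bool = False):
        """Newton solve of f_int(u) = f_ext(u) with fixed loads."""
        n = self.mesh.n_nodes
        u = np.zeros((n, 3)) if u0 is None else u0.copy()
        u.reshape(-1)[~self.free] = 0.0
        fresh = False
        if self._lu is None or self._lu_sig != "static" or not reuse_lu:
            self._factorize(u, None)
            self._lu_sig = "static"
            fresh = True

        ref_scale = [None]

        def residual_norm(uu):
            f_int, _ = self.internal_force(uu, with_tangent=False)
            f_ext, _ = self.external_force(uu)
            r = f_int - f_ext
            if ref_scale[0] is None:
                ref_scale[0] = max(1.0, np.linalg.norm(f_int[self.free]),
                                   np.linalg.norm(f_ext[self.free]))
            return r, np.linalg.norm(r[self.free]) / ref_scale[0]

        r, rn = residual_norm(u)
        stalled = 0
        for it in range(max_iter):
            # converged, or stagnated at the floor set by the parts of
            # the tangent that are inherently approximate (contact
            # curvature); static states are intermediate quantities
            if rn < tol or (stalled >= 4 and rn < 1e4 * tol):
                return u, it, rn
            du = relax * self._lu.solve(-r[self.free])
            # backtracking line search against divergence / inversion
            step = 1.0
            descended = False
            for _ in range(8):
                u_try = u.copy()
                u_try.reshape(-1)[self.free] += step * du
                try:
                    r_try, rn_try = residual_norm(u_try)
                except (ValueError, FloatingPointError):
                    rn_try = np.inf
                    r_try = None
                if r_try is not None and rn_try < max(rn, tol):
                    descended = True
                    break
                step *= 0.5
            if not descended:
                if fresh:
                    raise RuntimeError("static Newton failed: "
                                       "line search exhausted")
                self._factorize(u, None)
                fresh = True
                continue
            slow = rn_try > 0.33 * rn
            stalled = stalled + 1 if rn_try > 0.9 * rn else 0
            u, r, rn = u_try, r_try, rn_try
            if slow and not fresh:
                self._factorize(u, None)
                fresh = True
            else:
                fresh = False
        if rn < tol:
            return u, max_iter, rn
        raise RuntimeError(f"static Newton failed: |r| = {rn:.3e} "
                           f"after {max_iter} iterations")

    def inflate_static(self, p_kpa: float, n_steps: int = 6,
                       u0: np.ndarray | None = None):
        """Static cavity-pressure continuation to p_kpa (load stepping
        with automatic refinement); returns the displacement field."""
        u = u0
        p = 0.0
        dp = p_kpa / n_steps
        while p < p_kpa - 1e-12:
            step = min(dp, p_kpa - p)
            self.pressure = p + step
            try:
                u, _, _ = self.solve_static(u0=u, reuse_lu=True)
            except RuntimeError:
                if step < 1e-3 * abs(p_kpa):
                    raise
                dp = step / 2.0
                continue
            p += step
            dp = min(p_kpa / n_steps, dp * 1.5)
        return u if u is not None else np.zeros((self.mesh.n_nodes, 3))

    def prepare_dynamic(self, state: MechState):
        """Initialize the lagged damping stiffness."""
        _, K = self.internal_force(state.u, with_tangent=True)
        self._K_lagged = K
        self._lu_sig = None

    def newmark_step(self, state: MechState, dt: float, tol: float = 1e-8,
                     max_iter: int = 60, max_halvings: int = 4) -> MechState:
        """One Newmark-beta step with Newton iteration.

        On non-convergence the step is retried with a halved dt (up to
        ``max_halvings`` times, advancing the same total interval).
        """
        try:
            return self._newmark_one(state, dt, tol, max_iter)
        except (RuntimeError, ValueError, FloatingPointError):
            if max_halvings <= 0:
                raise
            half = dt / 2.0
            s = self.newmark_step(state, half, tol, max_iter,
                                  max_halvings - 1)
            return self.newmark_step(s, half, tol, max_iter,
                                     max_halvings - 1)

    def _newmark_one(self, state: MechState, dt, tol, max_iter) -> MechState:
        beta, gamma = NEWMARK_BETA, NEWMARK_GAMMA
        n = self.mesh.n_nodes
        M3 = np.repeat(self.M, 3)
        if self._K_lagged is None:
            self.prepare_dynamic(state)
        Kd = self._K_lagged

        u0 = state.u.reshape(-1)
        v0 = state.v.reshape(-1)
        a0 = state.a.reshape(-1)
        u = u0.copy()

        c_a = 1.0 / (beta * dt * dt)
        c_v = gamma / (beta * dt)

        def kinematics(u):
            a = c_a * (u - u0 - dt * v0) - (0.5 / beta - 1.0) * a0
            v = v0 + dt * ((1.0 - gamma) * a0 + gamma * a)
            return v, a

        dt_sig = (c_a, c_v, M3, Kd)
        sig = ("dyn", dt)
        fresh = False
        if self._lu is None or self._lu_sig != sig or self._lu_age > 5:
            self._factorize(u.reshape(n, 3), dt_sig)
            self._lu_sig = sig
            self._lu_age = 0
            fresh = True

        ref_scale = [None]

        def residual(uu):
            v, a = kinematics(uu)
            f_int, _ = self.internal_force(uu.reshape(n, 3),
                                           with_tangent=False)
            f_ext, _ = self.external_force(uu.reshape(n, 3))
            damp = self.alpha_r * M3 * v + self.beta_r * (Kd @ v)
            r = M3 * a + damp + f_int - f_ext
            # the acceptance norm is relative to the force scale of the
            # step (an absolute 1e-8 criterion is unit-system dependent);
            # the scale is frozen at the first evaluation of the step
            if ref_scale[0] is None:
                ref_scale[0] = max(1.0, np.linalg.norm(f_int[self.free]),
                                   np.linalg.norm(f_ext[self.free]),
                                   np.linalg.norm((M3 * a)[self.free]))
            return r, np.linalg.norm(r[self.free]) / ref_scale[0], v, a

        rn = np.inf
        rn_prev = np.inf
        stalled = 0
        r, rn, v, a = residual(u)
        for it in range(max_iter):
            if rn < tol or (stalled >= 3 and rn < 100.0 * tol):
                state_new = MechState(u=u.reshape(n, 3).copy(),
                                      v=v.reshape(n, 3).copy(),
                                      a=a.reshape(n, 3).copy(),
                                      time=state.time + dt,
                                      newton_iters=it, residual=rn)
                # lag the damping stiffness by one accepted step
                self._K_lagged = self._K_newton \
                    if self._K_newton is not None else Kd
                self._lu_age += 1
                return state_new
            du = self._lu.solve(-r[self.free])
            step = 1.0
            r_try = None
            descended = False
            for _ in range(8):
                u_try = u.copy()
                u_try[self.free] += step * du
                try:
                    r_try, rn_try, v_t, a_t = residual(u_try)
                except (ValueError, FloatingPointError):
                    rn_try = np.inf
                    r_try = None
                if r_try is not None and rn_try < max(rn, tol):
                    descended = True
                    break
                step *= 0.5
            if DEBUG_NEWTON:
                print(f"  it {it} rn {rn:.3e} -> {rn_try:.3e} "
                      f"step {step} fresh {fresh}")
            if not descended:
                # stale direction: refresh the tangent and retry once
                if fresh:
                    raise RuntimeError("Newmark line search exhausted")
                self._factorize(u.reshape(n, 3), dt_sig)
                self._lu_sig = sig
                self._lu_age = 0
                fresh = True
                continue
            slow = rn_try > 0.5 * rn
            stalled = stalled + 1 if rn_try > 0.9 * rn else 0
            u, r, rn, v, a = u_try, r_try, rn_try, v_t, a_t
            if slow and not fresh:
                self._factorize(u.reshape(n, 3), dt_sig)
                self._lu_sig = sig
                self._lu_age = 0
                fresh = True
            else:
                fresh = False
        raise RuntimeError(f"Newmark Newton failed: |r| = {rn:.3e}")


def newmark_single_dof(m, c, k, f_of_t, dt, n_steps, u0=0.0, v0=0.0):
    """Single-DOF mass-spring-damper through the same Newmark-beta
    (average acceleration) update used by the 3D solver."""
    beta, gamma = NEWMARK_BETA, NEWMARK_GAMMA
    u, v = u0, v0
    a = (f_of_t(0.0) - c * v0 - k * u0) / m
    out = np.empty((n_steps + 1, 3))
    out[0] = u, v, a
    for i in range(1, n_steps + 1):
        t = i * dt
        # linear problem: solve exactly
        c_a = 1.0 / (beta * dt * dt)
        c_v = gamma / (beta * dt)
        keff = k + c_a * m + c_v * c
        rhs = f_of_t(t) + \
            m * (c_a * (u + dt * v) + (0.5 / beta - 1.0) * a) + \
            c * (c_v * u + (gamma / beta - 1.0) * v +
                 dt * (gamma / (2 * beta) - 1.0) * a)
        u_new = rhs / keff
        a_new = c_a * (u_new - u - dt * v) - (0.5 / beta - 1.0) * a
        v_new = v + dt * ((1.0 - gamma) * a + gamma * a_new)
        u, v, a = u_new, v_new, a_new
        out[i] = u, v, a
    return out
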