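"""Monodomain tissue electrophysiology.

Reaction-diffusion propagation of the transmembrane voltage with an
anisotropic conductivity tensor built from the per-element fiber frame,

    sigma = sigma_l f (x) f + sigma_t (s (x) s + sn (x) sn),

first-order Godunov operator splitting (cell reaction substeps followed
by an implicit-Euler diffusion solve), no-flux boundaries, a
root-point stimulation protocol with an atrio-ventricular delay, and
conduction-velocity measurement/calibration on 1D cable and 2D sheet
fixtures.

The diffusion operator is assembled once in the reference
configuration; tissue deformation does not alter the conductivity
tensor.  Deformation feedback (fiber stretch and stretch rate) is
received once per diffusion step for the tension model; with the
feedback disabled the solver is bit-identical to a mechanics-free run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .cells.base import CellParams, get_model
from .geometry import HeartMesh

__all__ = [
    "TissueParams", "StimulusProtocol", "EPState", "MonodomainSolver",
    "assemble_diffusion", "lumped_mass", "measure_cv",
    "calibrate_conductivity", "activation_times",
    "activation_repolarization_maps", "UNACTIVATED",
]

UNACTIVATED = -1.0e30  # sentinel for nodes that never cross threshold

# detection thresholds for activation / repolarization maps (mV)
ACT_THRESHOLD = -40.0
REPOL_THRESHOLD = -70.0


@dataclass
class TissueParams:
    """Tissue-level conduction parameters.

    sigma_l / sigma_t : mS/mm — conductivities along / across the fiber.
    chi : 1/mm — membrane surface-to-volume ratio.
    cm : µF/mm² — membrane capacitance.
    dt_diffusion / dt_reaction : ms — splitting time steps.
    """

    sigma_l: float = 0.6
    sigma_t: float = 0.3
    chi: float = 140.0
    cm: float = 0.01
    dt_diffusion: float = 0.1
    dt_reaction: float = 0.02

    def __post_init__(self):
        if not self.sigma_l >= self.sigma_t > 0:
            raise ValueError("need sigma_l >= sigma_t > 0")

    @property
    def d_l(self) -> float:
        """Effective longitudinal diffusivity, mm²/ms."""
        return self.sigma_l / (self.chi * self.cm)

    @property
    def d_t(self) -> float:
        return self.sigma_t / (self.chi * self.cm)


@dataclass
class StimulusProtocol:
    """Root-point ventricular stimulation.

    Each entry of ``roots`` is (node index array, offset ms, amplitude
    µA/µF, duration ms); the offset is measured from sinus time plus
    the atrio-ventricular delay.
    """

    roots: list
    av_delay: float = 120.0
    cycle_length: float = 850.0
    sinus_time: float = 0.0

    def __post_init__(self):
        if not self.roots:
            raise ValueError("stimulation protocol needs at least one root")
        for nodes, onset, _, _ in self.roots:
            if len(np.atleast_1d(nodes)) == 0:
                raise ValueError("empty root node set")
            if onset < 0:
                raise ValueError("root offsets must be >= 0")

    def earliest_onset(self) -> float:
        return self.sinus_time + self.av_delay + \
            min(o for _, o, _, _ in self.roots)

    def stimulus_vector(self, t: float, beat_time: float, n: int) -> np.ndarray:
        """Stimulus current (µA/µF) per node at beat-local time."""
        istim = np.zeros(n)
        t0 = self.sinus_time + self.av_delay
        for nodes, onset, amp, dur in self.roots:
            if t0 + onset <= beat_time < t0 + onset + dur:
                istim[np.atleast_1d(nodes)] += amp
        return istim


@dataclass
class EPState:
    """Tissue electrophysiology state."""

    Y: np.ndarray                  # (n_nodes, n_states) cell states
    time: float = 0.0              # ms
    lam: np.ndarray | None = None  # fiber stretch per node
    dlam_dt: np.ndarray | None = None

    @property
    def vm(self) -> np.ndarray:
        return self.Y[:, 0]


def _element_gradients(mesh: HeartMesh):
    """Per-element constant shape-function gradients and measures.

    Supports line (1D), triangle (2D in-plane) and tet elements.
    Returns (grads (E, k, 3), measures (E,)).
    """
    c = mesh.corner_elems()
    x = mesh.nodes
    E, k = c.shape
    meas = mesh.element_volumes()
    grads = np.zeros((E, k, 3))
    if mesh.dim == 3:
        # rows of inv([x1-x0; x2-x0; x3-x0]) give gradients of lam1..3
        # rows of T are the edge vectors; grad(lam_i) = column i of T^-1
        T = np.stack([x[c[:, i]] - x[c[:, 0]] for i in (1, 2, 3)], axis=1)
        Tinv = np.linalg.inv(T)
        grads[:, 1:, :] = Tinv.transpose(0, 2, 1)
        grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    elif mesh.dim == 2:
        # in-plane gradient via 2x2 solve in the element plane
        e1 = x[c[:, 1]] - x[c[:, 0]]
        e2 = x[c[:, 2]] - x[c[:, 0]]
        n = np.cross(e1, e2)
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        u = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
        v = np.cross(n, u)
        M = np.stack([np.stack([(e1 * u).sum(1), (e1 * v).sum(1)], axis=1),
                      np.stack([(e2 * u).sum(1), (e2 * v).sum(1)], axis=1)],
                     axis=1)
        Minv = np.linalg.inv(M)
        # grad(lam_i) in plane coords = column i of M^-1
        grads[:, 1, :] = Minv[:, 0, 0, None] * u + Minv[:, 1, 0, None] * v
        grads[:, 2, :] = Minv[:, 0, 1, None] * u + Minv[:, 1, 1, None] * v
        grads[:, 0, :] = -(grads[:, 1, :] + grads[:, 2, :])
    else:
        L = np.linalg.norm(x[c[:, 1]] - x[c[:, 0]], axis=1, keepdims=True)
        d = (x[c[:, 1]] - x[c[:, 0]]) / L
        grads[:, 1, :] = d / L
        grads[:, 0, :] = -grads[:, 1, :]
    return grads, np.abs(meas)


def assemble_diffusion(mesh: HeartMesh, params: TissueParams) -> sparse.csr_matrix:
    """Stiffness operator K for the anisotropic diffusion term (mS·mm).

    K is symmetric with zero row sums (no-flux boundary); the monodomain
    update uses K / (chi * cm).
    """
    if mesh.fiber_f is None:
        raise ValueError("fiber frames must be assigned before assembly")
    grads, meas = _element_gradients(mesh)
    f, s, sn = mesh.fiber_f, mesh.fiber_s, mesh.fiber_sn
    sig = (params.sigma_l * np.einsum("ei,ej->eij", f, f) +
           params.sigma_t * (np.einsum("ei,ej->eij", s, s) +
                             np.einsum("ei,ej->eij", sn, sn)))
    # Ke[a,b] = meas * grad_a . sigma . grad_b
    Ke = np.einsum("e,eai,eij,ebj->eab", meas, grads, sig, grads)
    c = mesh.corner_elems()
    k = c.shape[1]
    rows = np.repeat(c, k, axis=1).ravel()
    cols = np.tile(c, (1, k)).ravel()
    K = sparse.coo_matrix((Ke.ravel(), (rows, cols)),
                          shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()
    return K


def lumped_mass(mesh: HeartMesh) -> np.ndarray:
    """Row-sum lumped mass vector (element measure split evenly)."""
    c = mesh.corner_elems()
    meas = np.abs(mesh.element_volumes())
    m = np.zeros(mesh.n_nodes)
    np.add.at(m, c.ravel(), np.repeat(meas / c.shape[1], c.shape[1]))
    return m


class MonodomainSolver:
    """Operator-split monodomain integrator on a HeartMesh."""

    def __init__(self, mesh: HeartMesh, tissue: TissueParams,
                 cell_params: CellParams, gks_field: np.ndarray | None = None,
                 initial_cell_state: np.ndarray | None = None):
        self.mesh = mesh
        self.tissue = tissue
        self.cell_params = cell_params
        self.model = get_model(cell_params.model)
        self.K = assemble_diffusion(mesh, tissue)
        self.M = lumped_mass(mesh)
        n = mesh.n_nodes
        self.gks = np.ones(n) if gks_field is None else np.asarray(gks_field)
        self.is_epi = self._epi_flags()
        if initial_cell_state is not None:
            Y0 = np.tile(initial_cell_state.reshape(1, -1), (n, 1))
        else:
            Y0 = self.model.initial_state(n, cell_params.variant)
        self.state = EPState(Y=Y0)
        self._factorize()

    def _epi_flags(self) -> np.ndarray:
        """Node-wise endo/epi variant from the element layer flags."""
        n = self.mesh.n_nodes
        if self.mesh.layer is None:
            return np.zeros(n, dtype=np.int8)
        flag = np.zeros(n)
        cnt = np.zeros(n)
        c = self.mesh.corner_elems()
        np.add.at(flag, c.ravel(), np.repeat(self.mesh.layer, c.shape[1]))
        np.add.at(cnt, c.ravel(), 1.0)
        return (flag / np.maximum(cnt, 1) >= 0.5).astype(np.int8)

    def _factorize(self):
        dt = self.tissue.dt_diffusion
        scale = self.tissue.chi * self.tissue.cm
        A = sparse.diags(self.M) + (dt / scale) * self.K
        self._lu = splu(A.tocsc())

    def set_cell_state(self, Y0: np.ndarray):
        self.state.Y[:] = Y0

    def step(self, protocol: StimulusProtocol | None, dt: float,
             tnc_flux: np.ndarray | None = None) -> EPState:
        """Advance by dt (a multiple of the diffusion step)."""
        td = self.tissue.dt_diffusion
        n_diff = max(1, int(round(dt / td)))
        n_react = max(1, int(round(td / self.tissue.dt_reaction)))
        dtr = td / n_react
        st = self.state
        n = self.mesh.n_nodes
        for _ in range(n_diff):
            beat_time = st.time % protocol.cycle_length if protocol else 0.0
            istim = protocol.stimulus_vector(st.time, beat_time, n) \
                if protocol else np.zeros(n)
            for _ in range(n_react):
                self.model.step(st.Y, dtr, istim, gks_scale=self.gks,
                                is_epi=self.is_epi,
                                strong_coupling=self.cell_params.strong_coupling,
                                tnc_flux=tnc_flux)
            # implicit diffusion on Vm
            rhs = self.M * st.Y[:, 0]
            st.Y[:, 0] = self._lu.solve(rhs)
            st.time += td
        return st

    def run(self, protocol: StimulusProtocol | None, t_end: float,
            record_every: float = 1.0):
        """Run to t_end recording Vm frames; returns (times, vm_history)."""
        frames = []
        times = []
        dt_rec = record_every
        n_chunks = int(round(t_end / dt_rec))
        for _ in range(n_chunks):
            self.step(protocol, dt_rec)
            times.append(self.state.time)
            frames.append(self.state.Y[:, 0].copy())
        return np.array(times), np.array(frames)


# ---------------------------------------------------------------------------
# conduction-velocity measurement and calibration
# ---------------------------------------------------------------------------

def activation_times(times: np.ndarray, vm_hist: np.ndarray,
                     threshold: float = ACT_THRESHOLD) -> np.ndarray:
    """First upward threshold crossing per node (UNACTIVATED sentinel)."""
    T, N = vm_hist.shape
    act = np.full(N, UNACTIVATED)
    above = vm_hist >= threshold
    first = np.argmax(above, axis=0)
    has = above.any(axis=0)
    idx = first[has]
    tprev = np.where(idx > 0, times[np.maximum(idx - 1, 0)], times[0])
    vprev = vm_hist[np.maximum(idx - 1, 0), has]
    vcur = vm_hist[idx, has]
    frac = np.where(vcur > vprev, (threshold - vprev) /
                    np.maximum(vcur - vprev, 1e-12), 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    act[has] = np.where(idx > 0, tprev + frac * (times[idx] - tprev),
                        times[0])
    return act


def activation_repolarization_maps(times: np.ndarray, vm_hist: np.ndarray):
    """Per-node activation (-40 mV upward) and repolarization
    (last -70 mV downward crossing) times; unactivated nodes get the
    UNACTIVATED sentinel."""
    act = activation_times(times, vm_hist)
    T, N = vm_hist.shape
    rep = np.full(N, UNACTIVATED)
    below = vm_hist < REPOL_THRESHOLD
    # last downward crossing: last index where prev >= thr and cur < thr
    cross = below[1:] & ~below[:-1]
    has = cross.any(axis=0)
    idx = T - 1 - np.argmax(cross[::-1], axis=0)[has]  # row in vm_hist
    vprev = vm_hist[idx - 1, has]
    vcur = vm_hist[idx, has]
    frac = (vprev - REPOL_THRESHOLD) / np.maximum(vprev - vcur, 1e-12)
    rep[has] = times[idx - 1] + np.clip(frac, 0, 1) * \
        (times[idx] - times[idx - 1])
    rep[act == UNACTIVATED] = UNACTIVATED
    return act, rep


def measure_cv(act: np.ndarray, mesh: HeartMesh, direction: np.ndarray,
               window: tuple = (0.25, 0.75)) -> float:
    """Conduction velocity (mm/s) from a planar-wave activation map.

    Linear regression of activation time against distance along
    ``direction`` over the central fraction of the fixture;
    CV = 1/slope.  Raises if activation is non-monotone in the window.
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    d = (mesh.nodes - mesh.nodes.min(axis=0)) @ direction
    lo, hi = np.quantile(d, window)
    sel = (d >= lo) & (d <= hi) & (act > UNACTIVATED / 2)
    if sel.sum() < 3:
        raise ValueError("too few activated nodes in measurement window")
    ds, ts = d[sel], act[sel]
    order = np.argsort(ds)
    # monotonicity check on binned means
    nb = max(4, min(20, sel.sum() // 5))
    bins = np.array_split(np.arange(sel.sum()), nb)
    mt = np.array([ts[order[b]].mean() for b in bins if len(b)])
    if np.any(np.diff(mt) <= 0):
        raise ValueError("non-monotone activation in measurement window")
    slope = np.polyfit(ds, ts, 1)[0]  # ms per mm
    if slope <= 0:
        raise ValueError("non-positive activation slope")
    return 1000.0 / slope  # mm/s


def _run_wave(mesh: HeartMesh, tissue: TissueParams,
              cell_params: CellParams, direction: np.ndarray,
              initial_cell_state: np.ndarray | None = None,
              t_end: float = 80.0) -> np.ndarray:
    """Stimulate one edge of a fixture and return the activation map."""
    d = (mesh.nodes - mesh.nodes.min(axis=0)) @ \
        (np.asarray(direction, float) / np.linalg.norm(direction))
    stim_nodes = np.flatnonzero(d <= d.min() + 1.5 * _typical_dx(mesh))
    protocol = StimulusProtocol(
        roots=[(stim_nodes, 0.0, -80.0, 2.0)], av_delay=0.0,
        cycle_length=1e6)
    solver = MonodomainSolver(mesh, tissue, cell_params,
                              initial_cell_state=initial_cell_state)
    times, hist = solver.run(protocol, t_end, record_every=0.5)
    return activation_times(times, hist)


def _typical_dx(mesh: HeartMesh) -> float:
    c = mesh.corner_elems()
    return float(np.linalg.norm(mesh.nodes[c[:, 1]] - mesh.nodes[c[:, 0]],
                                axis=1).mean())


def calibrate_conductivity(cable: HeartMesh, sheet: HeartMesh,
                           tissue: TissueParams | None = None,
                           cell_params: CellParams | None = None,
                           cv_l_target: float = 800.0,
                           cv_t_target: float = 550.0,
                           rel_tol: float = 0.01, max_iter: int = 20,
                           initial_cell_state: np.ndarray | None = None,
                           t_end: float = 60.0) -> TissueParams:
    """Tune sigma_l then sigma_t until measured conduction velocities
    match the targets (default 800 mm/s longitudinal on the cable,
    550 mm/s transverse on the sheet) within ``rel_tol``.

    Secant iteration exploiting the CV ∝ sqrt(sigma) scaling for the
    initial guess.  Raises RuntimeError on failure after ``max_iter``.
    """
    tissue = tissue or TissueParams()
    cell_params = cell_params or CellParams()

    def solve_axis(sig0, target, fixture, direction, set_sigma):
        sig = sig0
        cv_prev = None
        sig_prev = None
        for it in range(max_iter):
            p = set_sigma(sig)
            act = _run_wave(fixture, p, cell_params, direction,
                            initial_cell_state=initial_cell_state,
                            t_end=t_end)
            cv = measure_cv(act, fixture, direction)
            if abs(cv - target) / target < rel_tol:
                return sig, cv
            if cv_prev is None:
                sig_new = sig * (target / cv)**2  # CV ~ sqrt(sigma)
            else:
                dcv = cv - cv_prev
                if abs(dcv) < 1e-9:
                    sig_new = sig * (target / cv)**2
                else:
                    sig_new = sig + (target - cv) * (sig - sig_prev) / dcv
                if sig_new <= 0:
                    sig_new = 0.5 * sig
            sig_prev, cv_prev = sig, cv
            sig = sig_new
        raise RuntimeError(
            f"conductivity calibration failed after {max_iter} iterations "
            f"(last CV {cv:.1f} vs target {target})")

    base = dict(chi=tissue.chi, cm=tissue.cm,
                dt_diffusion=tissue.dt_diffusion,
                dt_reaction=tissue.dt_reaction)
    sig_l, _ = solve_axis(
        tissue.sigma_l, cv_l_target, cable, np.array([1.0, 0, 0]),
        lambda s: TissueParams(sigma_l=s, sigma_t=min(s, tissue.sigma_t),
                               **base))
    # transverse wave along y on the sheet probes sigma_t
    sig_t, _ = solve_axis(
        min(tissue.sigma_t, sig_l), cv_t_target, sheet,
        np.array([0.0, 1.0, 0]),
        lambda s: TissueParams(sigma_l=max(sig_l, s), sigma_t=s, **base))
    return TissueParams(sigma_l=sig_l, sigma_t=sig_t, **base)
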