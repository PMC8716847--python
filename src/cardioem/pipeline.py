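"""Coupled heart-beat pipeline.

Orchestrates the full chain on the idealized left ventricle:

1. geometry + electrodes + inter-mesh mapping,
2. conduction and repolarization-gradient calibration,
3. unloaded-state initialization with the pericardial ramp,
4. the coupled beat: per 1 ms mechanics step the monodomain tissue
   model advances (cells + diffusion), the myofilament model converts
   calcium and fiber stretch to active tension at the EP nodes, the
   tension is mapped to the mechanics quadrature points, the FEM wall
   and the closed-loop circulation exchange cavity pressure/volume by
   secant sub-iterations, and the deformation is mapped back to the EP
   mesh as fiber stretch (and to the ECG as moving sources),
5. the forward ECG for the dynamic run and for geometries frozen at
   the end-diastatic / end-diastolic / end-systolic instants, with the
   comparison table of T-wave amplitudes and end-of-T times.

Everything is deterministic: no randomness enters any stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .cells import CellParams, calibrate_gks, pace_to_limit_cycle
from .cells.protocols import gks_gradient_field
from .circulation import (CircuitParams, CirculationModel, classify_phase,
                          ejection_fraction)
from .ecg import LEAD_NAMES, LeadTraces, derive_leads
from .geometry import (LVGeometry, TorsoElectrodes, build_lv_ellipsoid,
                       build_mapping, place_electrodes)
from .initialization import UnloadConfig, run_initialization
from .mechanics import (ContactSurface, MaterialParams, MechanicsProblem,
                        PericardialShell)
from .mechanics.fem import MechState
from .metrics import (DEFAULT_FREEZE_TIMES, build_comparison_table,
                      freeze_cases)
from .monodomain import (MonodomainSolver, StimulusProtocol, TissueParams,
                         activation_repolarization_maps)
from .tension import TensionModel, TensionParams
from .units import kpa_to_mmhg, mmhg_to_kpa

log = logging.getLogger("cardioem")

__all__ = ["RunConfig", "HeartSimulation", "BeatHistory"]


@dataclass
class RunConfig:
    """Desk-scale coupled-run configuration."""

    geometry: LVGeometry = field(default_factory=LVGeometry)
    ep_edge: float = 3.0           # mm
    mech_edge: float = 10.5        # mm
    cell_model: str = "reduced"    # coupled-run default; 'ohara' available
    cycle_length: float = 850.0    # ms (~70 bpm)
    av_delay: float = 120.0        # ms
    n_beats: int = 1
    dt_mech: float = 1.0           # ms
    target_apd_shortening: float = 0.17
    endo_fraction: float = 0.2
    freeze_times: dict = field(default_factory=lambda:
                               dict(DEFAULT_FREEZE_TIMES))
    torso_scale: float = 1.0
    n_bspm: int = 64
    contractility_kpa: float = 220.0   # myofilament tension scale t_ref
    pericardial_offset: float = 0.5    # mm
    strong_coupling: bool = False
    calibrate_cv: bool = True      # CV calibration on fixtures at ep_edge
    sigma_l: float | None = None   # pre-calibrated overrides (mS/mm)
    sigma_t: float | None = None
    gks_apex_scale: float | None = None
    record_bspm: bool = True

    def __post_init__(self):
        if self.cycle_length <= 0:
            raise ValueError("cycle length must be positive")
        # mechanics step must contain an integer number of EP steps
        tissue_dt = TissueParams().dt_diffusion
        if abs(self.dt_mech / tissue_dt - round(self.dt_mech / tissue_dt)) \
                > 1e-9:
            raise ValueError("mechanics dt must be an integer multiple of "
                             "the EP diffusion dt")


@dataclass
class BeatHistory:
    """Recorded traces of a coupled run (1 ms frames)."""

    times: np.ndarray              # (T,)
    vm: np.ndarray                 # (T, N_ep) float32, mV
    ep_nodes: np.ndarray           # (T, N_ep, 3) float32 deformed positions
    lv_volume: np.ndarray          # (T,) mL
    lv_pressure: np.ndarray        # (T,) mmHg
    circ_pressures: dict           # name -> (T,) mmHg
    circ_volumes: dict             # name -> (T,) mL
    valves: dict                   # name -> (T,) bool
    atrial_active: np.ndarray      # (T,) bool
    phases: np.ndarray | None = None
    mech_u: np.ndarray | None = None  # (T, N_mech, 3) float32


class HeartSimulation:
    """Builds and runs the coupled desk-scale heart."""

    def __init__(self, config: RunConfig | None = None):
        self.config = config or RunConfig()
        self._built = False
        self._initialized = False

    # -- build -------------------------------------------------------------
    def build(self):
        cfg = self.config
        log.info("building geometry (EP %.1f mm / mech %.1f mm)",
                 cfg.ep_edge, cfg.mech_edge)
        self.ep_mesh, self.mech_mesh = build_lv_ellipsoid(
            cfg.geometry, ep_edge=cfg.ep_edge, mech_edge=cfg.mech_edge)
        self.electrodes = place_electrodes(scale=cfg.torso_scale,
                                           n_bspm=cfg.n_bspm)
        self.material = MaterialParams()
        self.contact = self._build_contact()
        self.mech = MechanicsProblem(self.mech_mesh, material=self.material,
                                     contact=self.contact)
        self.mapping = build_mapping(self.ep_mesh, self.mech_mesh,
                                     mech_qpoints=self.mech.qpoints,
                                     warn=log.warning)
        # EP setup
        self.cell_params = CellParams(model=cfg.cell_model,
                                      cycle_length=cfg.cycle_length,
                                      strong_coupling=cfg.strong_coupling)
        self._calibrate_ep()
        self.protocol = self._build_protocol()
        gks = gks_gradient_field(self.ep_mesh.apicobasal,
                                 self.gks_apex_scale)
        limit = pace_to_limit_cycle(self.cell_params, max_beats=200,
                                    warn=log.warning)
        self.ep = MonodomainSolver(self.ep_mesh, self.tissue,
                                   self.cell_params, gks_field=gks,
                                   initial_cell_state=limit.state[0])
        self.tension = TensionModel(TensionParams(
            t_ref=cfg.contractility_kpa,
            strong_coupling=cfg.strong_coupling))
        self.tension_state = self.tension.initial_state(self.ep_mesh.n_nodes)
        # circuit constants re-balanced for the desk ventricle's stroke
        # volume (the pressure anchors assume a full-size heart's output)
        self.circuit = CirculationModel(CircuitParams(
            cycle_length=cfg.cycle_length, r_sys=1.45, c_sys_art=1.2),
            external=("lv",))
        self._setup_ep_kinematics()
        self._built = True
        return self

    def _build_contact(self):
        cfg = self.config
        m = self.mech_mesh
        epi_nodes = np.intersect1d(m.node_sets["epicardium"],
                                   np.flatnonzero(m.transmural > 0.99))
        # nodal areas from epicardial corner faces
        faces = m.face_sets["epicardium"]
        x = m.nodes
        areas = 0.5 * np.linalg.norm(
            np.cross(x[faces[:, 1]] - x[faces[:, 0]],
                     x[faces[:, 2]] - x[faces[:, 0]]), axis=1)
        nodal = np.zeros(m.n_nodes)
        np.add.at(nodal, faces.ravel(), np.repeat(areas / 3.0, 3))
        sel = epi_nodes[nodal[epi_nodes] > 0]
        # keep a basal margin: no contact next to the fixed vessel ring
        sel = sel[m.nodes[sel, 2] < cfg.geometry.z_base - 3.0]
        shell = PericardialShell.around(cfg.geometry,
                                        offset=cfg.pericardial_offset)
        return ContactSurface(nodes=sel, areas=nodal[sel], shell=shell,
                              eps=0.0)

    def _calibrate_ep(self):
        cfg = self.config
        self.tissue = TissueParams()
        if cfg.calibrate_cv:
            # fixtures at the ventricular mesh resolution: conduction
            # velocities are grid-dependent, so the calibration must run
            # at the resolution it will be used at
            from .geometry import build_cable, build_sheet
            from .monodomain import calibrate_conductivity
            dx = cfg.ep_edge
            cable = build_cable(max(20.0, 25 * dx), dx)
            sheet = build_sheet(max(10.0, 8 * dx), max(20.0, 25 * dx), dx)
            log.info("calibrating conduction velocities at dx = %.2f mm",
                     dx)
            self.tissue = calibrate_conductivity(
                cable, sheet, cell_params=self.cell_params,
                t_end=40.0 + 25 * dx / 0.5)
        if cfg.sigma_l is not None:
            self.tissue = replace(self.tissue, sigma_l=cfg.sigma_l)
        if cfg.sigma_t is not None:
            self.tissue = replace(self.tissue, sigma_t=cfg.sigma_t)
        if cfg.gks_apex_scale is not None:
            self.gks_apex_scale = cfg.gks_apex_scale
        else:
            log.info("calibrating apical repolarization gradient")
            self.gks_apex_scale = calibrate_gks(
                self.cell_params, cfg.target_apd_shortening, max_beats=100)

    def _build_protocol(self) -> StimulusProtocol:
        """Default endocardial root points: three left-ventricular
        sites at distinct circumferential positions, zero offsets."""
        m = self.ep_mesh
        endo = m.node_sets["endocardium"]
        a = m.apicobasal[endo]
        phi = np.arctan2(m.nodes[endo, 1], m.nodes[endo, 0])
        roots = []
        for a0, phi0 in [(0.25, 0.0), (0.35, 2.1), (0.30, -2.1)]:
            d = (a - a0)**2 + 0.1 * (np.cos(phi) - np.cos(phi0))**2 + \
                0.1 * (np.sin(phi) - np.sin(phi0))**2
            order = np.argsort(d)
            roots.append((endo[order[:6]], 0.0, -80.0, 2.0))
        return StimulusProtocol(roots=roots, av_delay=self.config.av_delay,
                                cycle_length=self.config.cycle_length)

    def _setup_ep_kinematics(self, base_nodes: np.ndarray | None = None):
        """Precompute EP-element data for stretch evaluation.

        ``base_nodes`` is the stretch reference configuration (the
        interpolated unloaded state after initialization).
        """
        m = self.ep_mesh
        c = m.corner_elems()
        x = m.nodes if base_nodes is None else base_nodes
        self._ep_base = x
        T = np.stack([x[c[:, i]] - x[c[:, 0]] for i in (1, 2, 3)], axis=1)
        self._ep_Tinv = np.linalg.inv(T)
        self._ep_corners = c
        cnt = np.zeros(m.n_nodes)
        np.add.at(cnt, c.ravel(), 1.0)
        self._ep_ncount = np.maximum(cnt, 1.0)

    def _fiber_stretch_ep(self, ep_nodes_deformed):
        """Per-EP-node fiber stretch from deformed node positions."""
        c = self._ep_corners
        x = ep_nodes_deformed
        Td = np.stack([x[c[:, i]] - x[c[:, 0]] for i in (1, 2, 3)], axis=1)
        # F = Td^T (Tref^T)^-1 ; lam = |F f|
        F = np.einsum("eji,ekj->eik", Td, self._ep_Tinv)
        lam_e = np.linalg.norm(
            np.einsum("eik,ek->ei", F, self.ep_mesh.fiber_f), axis=1)
        lam_n = np.zeros(self.ep_mesh.n_nodes)
        np.add.at(lam_n, c.ravel(), np.repeat(lam_e, 4))
        return lam_n / self._ep_ncount

    # -- initialization ----------------------------------------------------
    def initialize(self, unload: UnloadConfig | None = None):
        if not self._built:
            self.build()
        cfg = self.config
        log.info("running unloaded-state initialization")
        self.unload_config = unload or UnloadConfig(dt=2.0)
        prob2, state, report = run_initialization(self.mech,
                                                  self.unload_config)
        self.mech = prob2
        self.mech_state = state
        self.init_report = report
        # The mapping operators are material-point correspondences fixed
        # in the build configuration, so they remain valid after the
        # reference is rebased to the unloaded state.  EP node positions
        # and fiber stretch are measured from the interpolated unloaded
        # configuration (linear fields interpolate exactly).
        ep_base = np.column_stack([
            self.mapping.mech_to_ep @ prob2.mesh.nodes[:, d]
            for d in range(3)])
        self._setup_ep_kinematics(ep_base)
        edv = self.mech.cavity_volume(state.u)
        self.circ_state = self.circuit.initial_state(edv_lv=edv)
        self._initialized = True
        return report

    # -- coupled beat -------------------------------------------------------
    def run_beat(self, n_beats: int | None = None) -> BeatHistory:
        if not self._initialized:
            self.initialize()
        cfg = self.config
        n_beats = n_beats or cfg.n_beats
        t_end = n_beats * cfg.cycle_length
        n_steps = int(round(t_end / cfg.dt_mech))
        n_frames = n_steps + 1  # frame 0 = initial (end-diastatic) state
        n_ep = self.ep_mesh.n_nodes

        vm_hist = np.empty((n_frames, n_ep), dtype=np.float32)
        pos_hist = np.empty((n_frames, n_ep, 3), dtype=np.float32)
        mech_hist = np.empty((n_frames, self.mech_mesh.n_nodes, 3),
                             dtype=np.float32)
        lvv = np.empty(n_frames)
        lvp = np.empty(n_frames)
        circP = {k: np.empty(n_frames) for k in
                 ("la", "sys_art", "sys_ven", "ra", "rv", "pul_art",
                  "pul_ven")}
        circV = {k: np.empty(n_frames) for k in ("la", "ra", "rv",
                                                 "sys_art", "pul_art")}
        valves = {k: np.zeros(n_frames, dtype=bool) for k in
                  ("mitral", "aortic", "tricuspid", "pulmonary")}
        atrial = np.zeros(n_frames, dtype=bool)
        times = np.arange(n_frames) * cfg.dt_mech

        mech = self.mech
        st_m = self.mech_state
        circ = self.circ_state
        p_lv = kpa_to_mmhg(mech.pressure)
        lam_prev = np.ones(n_ep)
        v_prev = mech.cavity_volume(st_m.u)
        mech.prepare_dynamic(st_m)
        idx_ca = self.ep.model.idx_ca
        dp_prev = 0.0

        def record(i, v_lv, p_mmhg, circ_st, u_mech):
            vm_hist[i] = self.ep.state.Y[:, 0]
            u_ep = np.column_stack([
                self.mapping.mech_to_ep @ u_mech[:, d] for d in range(3)])
            pos_hist[i] = self._ep_base + u_ep
            mech_hist[i] = u_mech
            lvv[i] = v_lv
            lvp[i] = p_mmhg
            for k in circP:
                circP[k][i] = circ_st.pressures[k]
            for k in circV:
                circV[k][i] = circ_st.volumes[k]
            for k in valves:
                valves[k][i] = circ_st.valves[k]
            t_beat = circ_st.time % cfg.cycle_length
            atrial[i] = self.circuit.params.la.activation(t_beat) > 1e-6

        # populate pressures/valve flags of the initial circulation state
        circ = self.circuit.step(circ, 1e-9, external_p={"lv": p_lv})
        circ.time = 0.0
        record(0, v_prev, p_lv, circ, st_m.u)

        log.info("running %d coupled beat(s), %d steps", n_beats, n_steps)
        for i in range(n_steps):
            # 1) EP + tension at EP nodes
            self.ep.step(self.protocol, cfg.dt_mech,
                         tnc_flux=self.tension_state.tnc_flux
                         if cfg.strong_coupling else None)
            ca = self.ep.state.Y[:, idx_ca]
            lam_raw = self.ep.state.lam if self.ep.state.lam is not None \
                else lam_prev
            # low-pass filter the stretch feedback (tau ~ 5 ms) and
            # limit the rate to the physiological sarcomere range: the
            # staggered coupling otherwise pumps the crossbridge
            # distortions with solver-scale velocity noise
            lam = lam_prev + (cfg.dt_mech / 5.0) * (lam_raw - lam_prev)
            dlam = np.clip((lam - lam_prev) / cfg.dt_mech, -0.01, 0.01)
            self.tension.step(self.tension_state, ca, lam, dlam,
                              cfg.dt_mech)
            lam_prev = lam

            # 2) active tension to mechanics quadrature points
            mech.t_active = self.mapping.ep_to_mech_q @ \
                self.tension_state.tension

            # 3) FEM <-> circulation pressure coupling
            cache = {}

            def fem_volume(p_mmhg):
                key = round(p_mmhg, 9)
                if key not in cache:
                    mech.pressure = mmhg_to_kpa(p_mmhg)
                    st_new = mech.newmark_step(st_m, cfg.dt_mech)
                    cache[key] = (st_new, mech.cavity_volume(st_new.u))
                return cache[key][1]

            # the admissible pressure change per step is bounded (the
            # staggered coupling otherwise excites non-physical
            # pressure oscillations during the isovolumetric phases)
            dp_max = 12.0 * cfg.dt_mech
            p_pred = float(np.clip(p_lv + dp_prev, p_lv - dp_max,
                                   p_lv + dp_max))
            p_new, circ, v_lv, n_iter, _ = self.circuit.couple_pressure(
                circ, cfg.dt_mech, fem_volume, p_pred, v_prev,
                p_bounds=(p_lv - dp_max, p_lv + dp_max))
            dp_prev = 0.7 * (p_new - p_lv)
            p_lv = p_new
            st_m = cache[round(p_lv, 9)][0]
            v_prev = v_lv

            # 4) deformation feedback to the EP mesh
            u_ep = np.column_stack([
                self.mapping.mech_to_ep @ st_m.u[:, d] for d in range(3)])
            self.ep.state.lam = self._fiber_stretch_ep(self._ep_base + u_ep)

            # 5) record
            record(i + 1, v_lv, p_lv, circ, st_m.u)
            if i % 100 == 99:
                log.info("t = %4.0f ms  p_lv %6.1f mmHg  V_lv %6.1f mL  "
                         "(%d coupling iters)", times[i + 1], p_lv, v_lv,
                         n_iter)

        self.mech_state = st_m
        self.circ_state = circ
        phases = classify_phase(times, valves, atrial)
        hist = BeatHistory(times=times, vm=vm_hist, ep_nodes=pos_hist,
                           lv_volume=lvv, lv_pressure=lvp,
                           circ_pressures=circP, circ_volumes=circV,
                           valves=valves, atrial_active=atrial,
                           phases=phases, mech_u=mech_hist)
        self.history = hist
        return hist

    # -- forward ECG --------------------------------------------------------
    def _observation_points(self):
        pts = [self.electrodes.positions]
        if self.config.record_bspm and \
                self.electrodes.bspm_points is not None:
            pts.append(self.electrodes.bspm_points)
        return np.concatenate(pts)

    def _static_lead_operator(self, nodes):
        """Linear operator A with potentials = vm @ A.T for a frozen
        geometry (the dipole construction is linear in Vm)."""
        from .ecg import SIGMA_B_DEFAULT, SIGMA_I_DEFAULT
        obs = self._observation_points()
        c = self._ep_corners
        x = nodes.astype(np.float64)
        Tm = np.stack([x[c[:, i]] - x[c[:, 0]] for i in (1, 2, 3)], axis=1)
        vol = np.abs(np.linalg.det(Tm)) / 6.0
        Tinv = np.linalg.inv(Tm)
        # nodal gradient operator: grad = G @ vm[corners], G (E,3,4)
        G = np.zeros((len(c), 3, 4))
        G[:, :, 1:] = Tinv
        G[:, :, 0] = -Tinv.sum(axis=2)
        pos = x[c].mean(axis=1)
        A = np.zeros((len(obs), self.ep_mesh.n_nodes))
        for p_idx in range(len(obs)):
            d = obs[p_idx] - pos
            inv3 = (np.einsum("ei,ei->e", d, d))**-1.5
            # weight of each corner-node Vm in the potential
            w = np.einsum("ei,e,e,eia->ea", d, inv3,
                          -SIGMA_I_DEFAULT * vol, G) / \
                (4 * np.pi * SIGMA_B_DEFAULT)
            np.add.at(A[p_idx], c.ravel(), w.ravel())
        return A

    def _forward_potentials(self, vm_hist, node_hist):
        """(T, n_obs) potentials; node_hist (T,N,3) or (N,3) static."""
        from .ecg import SIGMA_B_DEFAULT, SIGMA_I_DEFAULT
        obs = self._observation_points()
        c = self._ep_corners
        T_frames = vm_hist.shape[0]
        if node_hist.ndim == 2:
            # frozen geometry: the forward map is one matrix
            A = self._static_lead_operator(node_hist)
            return vm_hist.astype(np.float64) @ A.T
        out = np.empty((T_frames, len(obs)))
        chunk = 64
        for lo in range(0, T_frames, chunk):
            hi = min(lo + chunk, T_frames)
            vm = vm_hist[lo:hi].astype(np.float64)
            x = node_hist[lo:hi].astype(np.float64)
            Tm = np.stack([x[:, c[:, i]] - x[:, c[:, 0]]
                           for i in (1, 2, 3)], axis=2)
            vol6 = np.abs(np.linalg.det(Tm))
            Tinv = np.linalg.inv(Tm)
            dv = np.stack([vm[:, c[:, i]] - vm[:, c[:, 0]]
                           for i in (1, 2, 3)], axis=2)
            # rows of Tm are edge vectors: grad = Tm^-1 dv
            grad = np.einsum("teij,tej->tei", Tinv, dv)
            dip = -SIGMA_I_DEFAULT * grad * (vol6 / 6.0)[..., None]
            pos = x[:, c].mean(axis=2)
            # loop observation points to keep memory bounded
            for p_idx in range(len(obs)):
                d = obs[p_idx] - pos                     # (t, e, 3)
                inv3 = (np.einsum("tei,tei->te", d, d))**-1.5
                out[lo:hi, p_idx] = np.einsum(
                    "tei,tei,te->t", d, dip, inv3) / \
                    (4 * np.pi * SIGMA_B_DEFAULT)
        return out

    def _traces_from_potentials(self, times, pots):
        names = self.electrodes.names
        el = {n: pots[:, i] for i, n in enumerate(names)}
        leads = derive_leads(el)
        return LeadTraces(times=times, electrodes=el, leads=leads)

    def run_comparison(self, history: BeatHistory | None = None):
        """Dynamic + three frozen-geometry forward ECGs and the
        comparison table.  Uses the last beat of the history."""
        hist = history or self.history
        cfg = self.config
        # last beat only (the frame at its start included)
        t0 = hist.times[-1] - cfg.cycle_length
        sel = hist.times >= t0 - 1e-9
        times = hist.times[sel] - t0
        vm = hist.vm[sel]
        nodes = hist.ep_nodes[sel]

        log.info("forward ECG: dynamic case")
        pots_dyn = self._forward_potentials(vm, nodes)
        dyn = self._traces_from_potentials(times, pots_dyn)

        cases = freeze_cases(times, nodes, cfg.freeze_times)
        case_pots = {}
        for case in cases:
            log.info("forward ECG: frozen %s (%.0f ms)", case.label,
                     case.freeze_time)
            pots = self._forward_potentials(vm, case.nodes.astype(float))
            case.traces = self._traces_from_potentials(times, pots)
            case_pots[case.label] = pots

        # T-wave window from the repolarization map
        act, rep = activation_repolarization_maps(times, vm.astype(float))
        rep_valid = rep[rep > -1e29]
        t_rep0 = float(rep_valid.min()) if len(rep_valid) else \
            cfg.av_delay + 200.0
        t_window = (max(0.0, t_rep0 - 20.0), float(times[-1]))
        stim_time = self.protocol.earliest_onset()

        bspm_dyn = bspm_cases = None
        if cfg.record_bspm and self.electrodes.bspm_points is not None:
            from .metrics import twave_amplitude
            n_el = len(self.electrodes.names)
            wct = pots_dyn[:, :3].mean(axis=1, keepdims=True)
            sel_w = (times >= t_window[0]) & (times <= t_window[1])

            def amp_map(pots):
                w = pots[:, n_el:] - pots[:, :3].mean(axis=1, keepdims=True)
                base = w[(times >= t_window[0] - 20) &
                         (times < t_window[0])].mean(axis=0)
                devs = w[sel_w] - base
                idx = np.argmax(np.abs(devs), axis=0)
                return devs[idx, np.arange(devs.shape[1])]

            bspm_dyn = amp_map(pots_dyn)
            bspm_cases = {lbl: amp_map(p) for lbl, p in case_pots.items()}
            del wct

        table = build_comparison_table(dyn, cases, t_window, stim_time,
                                       bspm_dynamic=bspm_dyn,
                                       bspm_cases=bspm_cases)
        self.dynamic_traces = dyn
        self.frozen_cases = cases
        self.comparison = table
        self.t_window = t_window
        return dyn, cases, table

    # -- summary metrics ----------------------------------------------------
    def lv_ejection_fraction(self, history: BeatHistory | None = None
                             ) -> float:
        hist = history or self.history
        t0 = hist.times[-1] - self.config.cycle_length
        sel = hist.times >= t0 - 1e-9
        return ejection_fraction(hist.times[sel] - t0, hist.lv_volume[sel],
                                 self.protocol.earliest_onset())

    def phase_sequence(self, history: BeatHistory | None = None,
                       min_duration: float = 8.0) -> list:
        """Ordered phase labels of the last beat.

        Segments shorter than ``min_duration`` ms (valve chatter at
        phase transitions) are merged into their neighbours; the
        leading passive-filling frames before the atrial kick are
        dropped.
        """
        hist = history or self.history
        t0 = hist.times[-1] - self.config.cycle_length
        sel = hist.times >= t0 - 1e-9
        ph = hist.phases[sel]
        dt = float(hist.times[1] - hist.times[0])
        # run-length encode and drop short runs
        runs = []
        start = 0
        for i in range(1, len(ph) + 1):
            if i == len(ph) or ph[i] != ph[start]:
                runs.append((ph[start], (i - start) * dt))
                start = i
        runs = [r for r in runs if r[1] >= min_duration]
        seq = []
        for lbl, _ in runs:
            if not seq or lbl != seq[-1]:
                seq.append(lbl)
        # ignore filling frames before the atrial kick at beat start
        if len(seq) > 1 and seq[0] == "relaxation" and \
                "atrial_contraction" in seq:
            seq = seq[1:]
        return seq
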