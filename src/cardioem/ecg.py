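"""Forward ECG from moving equivalent-dipole sources.

Every EP element contributes an equivalent current dipole

    p_e = -sigma_i * grad(Vm) * vol_e,

with the gradient and volume evaluated in the *deformed* configuration
(the element-wise push-forward), so the sources move and re-orient with
the beating heart.  Electrode potentials follow the infinite
homogeneous volume conductor solution

    phi(r) = sum_e p_e . (r - r_e) / (4 pi sigma_b |r - r_e|^3),

with the dipole located at the deformed element centroid.  Standard
leads are derived against Wilson's central terminal:
I = LA - RA, II = LL - RA, III = LL - LA, WCT = (RA + LA + LL)/3,
Vi = phi_i - WCT.  The Einthoven identity II = I + III holds to
machine precision by construction.

A heterogeneous full-torso volume conductor is out of scope here, so
absolute amplitudes are not comparable to body-surface recordings;
morphologies and relative comparisons are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import HeartMesh, TorsoElectrodes

__all__ = ["SourceField", "LeadTraces", "compute_sources",
           "electrode_potential", "derive_leads", "bspm_frame",
           "ecg_frame", "SIGMA_I_DEFAULT", "SIGMA_B_DEFAULT"]

SIGMA_I_DEFAULT = 0.17   # mS/mm intracellular (bulk) conductivity
SIGMA_B_DEFAULT = 0.2    # mS/mm bath conductivity

LEAD_NAMES = ["I", "II", "III", "V1", "V2", "V3", "V4", "V5", "V6"]


@dataclass
class SourceField:
    """Per-element dipoles (mS*mV*mm) at deformed centroids (mm)."""

    dipoles: np.ndarray    # (E, 3)
    positions: np.ndarray  # (E, 3)
    time: float = 0.0
    deformed: bool = True


@dataclass
class LeadTraces:
    """Electrode potentials and derived standard leads over time."""

    times: np.ndarray            # (T,) ms
    electrodes: dict             # name -> (T,) potentials (mV)
    leads: dict                  # lead name -> (T,) mV

    def as_array(self, names=LEAD_NAMES) -> np.ndarray:
        return np.stack([self.leads[n] for n in names], axis=1)


def compute_sources(vm: np.ndarray, mesh: HeartMesh,
                    deformed_nodes: np.ndarray | None = None,
                    sigma_i: float = SIGMA_I_DEFAULT,
                    time: float = 0.0) -> SourceField:
    """Equivalent dipoles from a nodal Vm field on the EP mesh.

    ``deformed_nodes`` are the EP node positions at this instant; when
    omitted the reference configuration is used and the result is
    flagged undeformed.
    """
    deformed = deformed_nodes is not None
    x = deformed_nodes if deformed else mesh.nodes
    c = mesh.corner_elems()
    # constant gradient per linear tet in the (possibly deformed) frame
    T = np.stack([x[c[:, i]] - x[c[:, 0]] for i in (1, 2, 3)], axis=1)
    detT = np.linalg.det(T)
    vol = np.abs(detT) / 6.0
    Tinv = np.linalg.inv(T)
    # rows of T are edge vectors, so dv = T grad and grad = T^-1 dv
    dv = np.stack([vm[c[:, i]] - vm[c[:, 0]] for i in (1, 2, 3)], axis=1)
    grad = np.einsum("eij,ej->ei", Tinv, dv)
    dip = -sigma_i * grad * vol[:, None]
    pos = x[c].mean(axis=1)
    return SourceField(dipoles=dip, positions=pos, time=time,
                       deformed=deformed)


def electrode_potential(sources: SourceField, r: np.ndarray,
                        sigma_b: float = SIGMA_B_DEFAULT) -> float:
    """Potential (mV) at position r (mm) in an infinite homogeneous
    medium of conductivity sigma_b."""
    d = np.asarray(r, dtype=float) - sources.positions
    dist = np.linalg.norm(d, axis=1)
    if np.any(dist < 1e-9):
        raise ValueError("electrode coincides with a source position")
    return float(np.einsum("ei,ei->e", sources.dipoles,
                           d / dist[:, None]**3).sum() /
                 (4.0 * np.pi * sigma_b))


def _potentials_at(sources: SourceField, points: np.ndarray,
                   sigma_b: float) -> np.ndarray:
    d = points[:, None, :] - sources.positions[None, :, :]
    dist = np.linalg.norm(d, axis=2)
    if np.any(dist < 1e-9):
        raise ValueError("observation point coincides with a source")
    return np.einsum("pei,ei->p", d / dist[..., None]**3,
                     sources.dipoles) / (4.0 * np.pi * sigma_b)


def derive_leads(electrode_potentials: dict) -> dict:
    """Standard limb and precordial leads from named potentials.

    Requires RA, LA, LL and V1..V6.  Precordial leads are referenced to
    Wilson's central terminal.
    """
    need = ["RA", "LA", "LL"] + [f"V{i}" for i in range(1, 7)]
    for n in need:
        if n not in electrode_potentials:
            raise KeyError(f"missing electrode '{n}'")
    p = electrode_potentials
    wct = (np.asarray(p["RA"]) + p["LA"] + p["LL"]) / 3.0
    leads = {
        "I": np.asarray(p["LA"]) - p["RA"],
        "II": np.asarray(p["LL"]) - p["RA"],
        "III": np.asarray(p["LL"]) - p["LA"],
    }
    for i in range(1, 7):
        leads[f"V{i}"] = np.asarray(p[f"V{i}"]) - wct
    return leads


def bspm_frame(sources: SourceField, points: np.ndarray,
               wct_electrodes: dict | None = None,
               sigma_b: float = SIGMA_B_DEFAULT) -> np.ndarray:
    """Potentials at a surface point cloud, referenced to Wilson's
    central terminal when limb potentials are supplied."""
    phi = _potentials_at(sources, np.asarray(points, dtype=float), sigma_b)
    if wct_electrodes is not None:
        wct = (wct_electrodes["RA"] + wct_electrodes["LA"] +
               wct_electrodes["LL"]) / 3.0
        phi = phi - wct
    return phi


def ecg_frame(vm: np.ndarray, mesh: HeartMesh,
              electrodes: TorsoElectrodes,
              deformed_nodes: np.ndarray | None = None,
              sigma_i: float = SIGMA_I_DEFAULT,
              sigma_b: float = SIGMA_B_DEFAULT,
              bspm: bool = False):
    """One ECG time frame: electrode potentials (+ optional BSPM)."""
    src = compute_sources(vm, mesh, deformed_nodes, sigma_i)
    phi = _potentials_at(src, electrodes.positions, sigma_b)
    pots = {n: phi[i] for i, n in enumerate(electrodes.names)}
    out = {"potentials": pots}
    if bspm and electrodes.bspm_points is not None:
        out["bspm"] = bspm_frame(src, electrodes.bspm_points, pots, sigma_b)
    return out


def traces_from_history(times: np.ndarray, vm_hist: np.ndarray,
                        mesh: HeartMesh, electrodes: TorsoElectrodes,
                        deformed_hist: np.ndarray | None = None,
                        sigma_i: float = SIGMA_I_DEFAULT,
                        sigma_b: float = SIGMA_B_DEFAULT,
                        bspm_every: int = 0):
    """Lead traces (and optional BSPM frames) for a Vm history.

    ``deformed_hist`` is (T, N, 3) node positions; None = static
    reference geometry throughout.  Returns (LeadTraces, bspm array or
    None).
    """
    T = len(times)
    names = electrodes.names
    pots = {n: np.empty(T) for n in names}
    bspm_frames = []
    for i in range(T):
        xn = deformed_hist[i] if deformed_hist is not None else None
        frame = ecg_frame(vm_hist[i], mesh, electrodes, xn, sigma_i,
                          sigma_b,
                          bspm=bspm_every > 0 and i % bspm_every == 0)
        for n in names:
            pots[n][i] = frame["potentials"][n]
        if "bspm" in frame:
            bspm_frames.append((times[i], frame["bspm"]))
    leads = derive_leads(pots)
    traces = LeadTraces(times=np.asarray(times), electrodes=pots,
                        leads=leads)
    return traces, (bspm_frames or None)
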