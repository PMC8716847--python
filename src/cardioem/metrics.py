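"""Analysis metrics: dynamic-versus-frozen ECG comparison protocol and
mechanical validation measures.

The central analysis replays the membrane-voltage history of the
dynamic (deforming) run on geometries frozen at characteristic instants
— end-diastatic (0 ms), end-diastolic (150 ms) and end-systolic
(400 ms) — recomputes the forward ECG for each, and quantifies the
differences in T-wave amplitude (per lead, as % of the dynamic case)
and end-of-T-wave time (tangent method, per-lead ms offsets), plus
surface amplitude maps with points below 0.5 mV |T| excluded.

Mechanical measures: atrioventricular-plane displacement (AVPD;
positive = toward the apex) and rotation about the long axis
(counterclockwise viewed from base = positive, so the base peaks
negative and the apex positive during ejection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ecg import LEAD_NAMES, LeadTraces, traces_from_history

__all__ = [
    "FrozenCase", "ComparisonTable", "freeze_cases", "twave_amplitude",
    "qt_end_tangent", "trace_pearson", "beat_stabilization", "avpd",
    "twist", "build_comparison_table", "DEFAULT_FREEZE_TIMES",
]

DEFAULT_FREEZE_TIMES = {"end_diastatic": 0.0, "end_diastolic": 150.0,
                        "end_systolic": 400.0}
TWAVE_MASK_MV = 0.5


@dataclass
class FrozenCase:
    """A static-geometry replay of the dynamic Vm history."""

    label: str
    freeze_time: float                 # ms
    nodes: np.ndarray                  # frozen EP node positions
    traces: LeadTraces | None = None
    bspm: list | None = None


@dataclass
class ComparisonTable:
    """Per-lead T-wave amplitudes and end-of-T times, dynamic vs
    frozen cases (percent-of-dynamic and ms offsets)."""

    leads: list
    dynamic_amplitude_mv: dict
    case_amplitude_percent: dict       # case -> {lead: %}
    dynamic_t_end_ms: dict
    case_t_end_delta_ms: dict          # case -> {lead: ms}
    masked_map: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        rows = []
        for lead in self.leads:
            row = {"lead": lead,
                   "dynamic_mV": self.dynamic_amplitude_mv[lead],
                   "dynamic_t_end_ms": self.dynamic_t_end_ms[lead]}
            for case, d in self.case_amplitude_percent.items():
                row[f"{case}_pct"] = d[lead]
            for case, d in self.case_t_end_delta_ms.items():
                row[f"{case}_dt_ms"] = d[lead]
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trace metrics
# ---------------------------------------------------------------------------

def twave_amplitude(times: np.ndarray, trace: np.ndarray,
                    window: tuple) -> float:
    """Signed T-wave amplitude (mV).

    The amplitude is the signed extremum of the largest absolute
    deflection from the pre-window baseline (mean over the 20 ms before
    the window) within [t0, t1].
    """
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    t0, t1 = window
    sel = (times >= t0) & (times <= t1)
    if not sel.any():
        raise ValueError("empty T-wave window")
    base_sel = (times >= t0 - 20.0) & (times < t0)
    baseline = trace[base_sel].mean() if base_sel.any() else trace[sel][0]
    dev = trace[sel] - baseline
    return float(dev[np.argmax(np.abs(dev))])


def qt_end_tangent(times: np.ndarray, trace: np.ndarray,
                   stim_time: float, window: tuple | None = None) -> float:
    """End-of-T-wave time by the tangent method (ms).

    Finds the sample of steepest descent on the terminal T-wave slope,
    intersects the tangent there with the zero-voltage axis, and
    returns that time minus the ventricular stimulation time.
    """
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if window is not None:
        sel = (times >= window[0]) & (times <= window[1])
        times, trace = times[sel], trace[sel]
    if len(times) < 3:
        raise ValueError("trace too short")
    # steepest descent after the T-peak (largest |trace| extremum)
    ipk = int(np.argmax(np.abs(trace)))
    dv = np.gradient(trace, times)
    seg = dv[ipk:]
    sign = np.sign(trace[ipk]) or 1.0
    # terminal slope has sign opposite to the peak
    cand = seg * sign
    if (cand >= 0).all():
        raise ValueError("no descending segment after the T peak")
    i_sd = ipk + int(np.argmin(cand))
    slope = dv[i_sd]
    if slope == 0:
        raise ValueError("zero slope at steepest-descent sample")
    t_cross = times[i_sd] - trace[i_sd] / slope
    return float(t_cross - stim_time)


def trace_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation between two equal-length traces."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1-D traces (n >= 3)")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("zero variance trace")
    return float(np.corrcoef(a, b)[0, 1])


def beat_stabilization(beat1: np.ndarray, beat2: np.ndarray,
                       rmse_threshold: float = 0.1):
    """Whether two consecutive beats' standard-lead ECGs agree.

    ``beat1``/``beat2`` are (T, n_leads) arrays on the same time base;
    stabilization requires the root-mean-square error over all leads
    to fall below 0.1 mV.  Returns (stabilized, rmse).
    """
    beat1 = np.asarray(beat1, dtype=float)
    beat2 = np.asarray(beat2, dtype=float)
    if beat1.shape != beat2.shape:
        raise ValueError("beats must share shape and time base")
    rmse = float(np.sqrt(np.mean((beat1 - beat2)**2)))
    return rmse < rmse_threshold, rmse


# ---------------------------------------------------------------------------
# mechanical measures
# ---------------------------------------------------------------------------

def avpd(ref_points: np.ndarray, disp_history: np.ndarray,
         long_axis: np.ndarray = (0.0, 0.0, -1.0)) -> np.ndarray:
    """Atrioventricular-plane displacement traces (mm).

    Signed projection of each tracked point's displacement onto the
    apex-directed long axis: positive = toward the apex, negative =
    toward the atria.  ``disp_history`` is (T, n_points, 3).
    """
    axis = np.asarray(long_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return np.einsum("tpi,i->tp", np.asarray(disp_history, float), axis)


def twist(ref_points: np.ndarray, disp_history: np.ndarray,
          axis_point: np.ndarray = (0.0, 0.0, 0.0),
          long_axis: np.ndarray = (0.0, 0.0, -1.0)) -> np.ndarray:
    """Rotation angle traces (degrees) about the long axis.

    Counterclockwise viewed from base toward apex is positive (so peak
    ejection twist is negative at the base and positive at the apex).
    Raises if a tracked point lies on the axis.
    """
    axis = np.asarray(long_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # build in-plane frame; axis points from base toward apex, and the
    # sign convention is counterclockwise when viewed from the base,
    # i.e. looking along +axis
    ref = np.asarray(ref_points, dtype=float) - np.asarray(axis_point)
    ref_in = ref - np.outer(ref @ axis, axis)
    if np.any(np.linalg.norm(ref_in, axis=1) < 1e-9):
        raise ValueError("tracked point lies on the rotation axis")
    e1 = ref_in / np.linalg.norm(ref_in, axis=1, keepdims=True)
    e2 = np.cross(axis, e1)
    cur = ref[None] + np.asarray(disp_history, float)
    cur_in = cur - np.einsum("tpi,i->tp", cur, axis)[..., None] * axis
    x = np.einsum("tpi,pi->tp", cur_in, e1)
    y = np.einsum("tpi,pi->tp", cur_in, e2)
    ang = np.degrees(np.arctan2(y, x))
    # viewed from the base the +axis (toward apex) points away, so a
    # positive angle about +axis appears clockwise; flip for the
    # base-view counterclockwise-positive convention
    return -ang


# ---------------------------------------------------------------------------
# frozen-case protocol
# ---------------------------------------------------------------------------

def freeze_cases(times: np.ndarray, deformed_hist: np.ndarray,
                 freeze_times: dict | None = None) -> list:
    """Geometry snapshots of the dynamic run at the requested instants.

    ``deformed_hist`` is (T, N, 3) EP node positions of the dynamic
    run.  Raises when a requested time is outside the history.
    """
    freeze_times = freeze_times or DEFAULT_FREEZE_TIMES
    times = np.asarray(times, dtype=float)
    cases = []
    for label, t in freeze_times.items():
        if t < times[0] - 1e-9 or t > times[-1] + 1e-9:
            raise ValueError(f"freeze time {t} ms outside history")
        i = int(np.argmin(np.abs(times - t)))
        cases.append(FrozenCase(label=label, freeze_time=float(times[i]),
                                nodes=deformed_hist[i].copy()))
    return cases


def replay_on_frozen(case: FrozenCase, times, vm_hist, mesh, electrodes,
                     **ecg_kw) -> FrozenCase:
    """Recompute the forward ECG with the geometry frozen at the case's
    instant (the full dynamic Vm history is replayed unchanged, mapped
    by node identity in material coordinates)."""
    static_hist = np.broadcast_to(case.nodes,
                                  (len(times),) + case.nodes.shape)
    case.traces, case.bspm = traces_from_history(
        times, vm_hist, mesh, electrodes,
        deformed_hist=static_hist, **ecg_kw)
    return case


def build_comparison_table(dynamic: LeadTraces, cases: list,
                           t_window: tuple, stim_time: float,
                           bspm_dynamic: np.ndarray | None = None,
                           bspm_cases: dict | None = None
                           ) -> ComparisonTable:
    """Tables of per-lead T-wave amplitude (% of dynamic) and
    end-of-T-wave shifts for each frozen case.

    When BSPM T-amplitude maps are supplied, surface points whose
    dynamic |T| is below 0.5 mV are excluded from the map statistics.
    """
    leads = list(LEAD_NAMES)
    dyn_amp = {ld: twave_amplitude(dynamic.times, dynamic.leads[ld],
                                   t_window) for ld in leads}
    dyn_qt = {}
    for ld in leads:
        try:
            dyn_qt[ld] = qt_end_tangent(dynamic.times, dynamic.leads[ld],
                                        stim_time, t_window)
        except ValueError:
            dyn_qt[ld] = np.nan
    amp_pct = {}
    dt_ms = {}
    for case in cases:
        tr = case.traces
        if tr is None:
            raise ValueError(f"case '{case.label}' has no traces")
        amp_pct[case.label] = {}
        dt_ms[case.label] = {}
        for ld in leads:
            a = twave_amplitude(tr.times, tr.leads[ld], t_window)
            denom = dyn_amp[ld] if dyn_amp[ld] != 0 else np.nan
            amp_pct[case.label][ld] = 100.0 * a / denom
            try:
                qt = qt_end_tangent(tr.times, tr.leads[ld], stim_time,
                                    t_window)
            except ValueError:
                qt = np.nan
            dt_ms[case.label][ld] = qt - dyn_qt[ld]
    masked = {}
    if bspm_dynamic is not None and bspm_cases:
        keep = np.abs(bspm_dynamic) >= TWAVE_MASK_MV
        masked["mask_kept_fraction"] = float(keep.mean())
        for label, amp_map in bspm_cases.items():
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.where(keep, 100.0 * amp_map / bspm_dynamic, np.nan)
            masked[label] = rel
    return ComparisonTable(
        leads=leads, dynamic_amplitude_mv=dyn_amp,
        case_amplitude_percent=amp_pct, dynamic_t_end_ms=dyn_qt,
        case_t_end_delta_ms=dt_ms, masked_map=masked)
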