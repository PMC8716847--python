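"""Single-cell pacing protocols and action-potential measurements."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import CellParams, get_model


@dataclass
class LimitCycleResult:
    state: np.ndarray          # pre-stimulus state (1, n_states)
    converged: bool
    n_beats: int
    apd90: float               # ms, measured on the final beat
    vm_trace: np.ndarray       # final-beat Vm samples
    dt_sample: float


def _beat(model, Y, params: CellParams, dt: float, record: bool = False):
    """Advance one pacing cycle; optionally record Vm each sample."""
    return model.run_beat(Y, params, dt, record=record)


def pace_to_limit_cycle(params: CellParams, max_beats: int = 1000,
                        rel_tol: float = 1e-4, dt: float | None = None,
                        initial_state: np.ndarray | None = None,
                        warn=None) -> LimitCycleResult:
    """Pace a single cell until a limit cycle is reached.

    Convergence: the maximum relative change of every state variable
    between consecutive pre-stimulus snapshots falls below ``rel_tol``
    (relative to |x| + 1e-6).  A cap of ``max_beats`` applies; on
    non-convergence the best state is returned with ``converged False``
    and ``warn`` (if given) is called.
    """
    model = get_model(params.model)
    dt = dt or model.max_dt
    Y = model.initial_state(1, params.variant) if initial_state is None \
        else initial_state.copy()
    converged = False
    n = 0
    prev = Y.copy()
    for n in range(1, max_beats + 1):
        _beat(model, Y, params, dt)
        delta = np.abs(Y - prev) / (np.abs(prev) + 1e-6)
        prev = Y.copy()
        if delta.max() < rel_tol:
            converged = True
            break
    if not converged and warn is not None:
        warn(f"limit cycle not reached after {max_beats} beats "
             f"(max rel change {delta.max():.2e})")
    # record the final beat from the converged pre-stimulus state
    Yrec = Y.copy()
    trace = _beat(model, Yrec, params, dt, record=True)
    return LimitCycleResult(state=Y, converged=converged, n_beats=n,
                            apd90=apd90(trace, dt), vm_trace=trace,
                            dt_sample=dt)


def apd90(vm_trace: np.ndarray, dt: float, repol_level: float = 0.9) -> float:
    """Action-potential duration at 90% repolarization.

    Measured from the sample of maximum upstroke velocity (dV/dt) to
    the first crossing, after the peak, of the voltage level 90% of the
    way from the peak back to the pre-stimulus baseline, with linear
    interpolation between samples.
    """
    vm = np.asarray(vm_trace, dtype=float)
    if vm.ndim != 1 or len(vm) < 3:
        raise ValueError("need a 1-D trace with at least 3 samples")
    dv = np.diff(vm)
    i_up = int(np.argmax(dv))
    baseline = vm[0]
    i_peak = i_up + int(np.argmax(vm[i_up:]))
    peak = vm[i_peak]
    if peak <= baseline + 1.0:
        raise ValueError("no upstroke found in trace")
    level = peak - repol_level * (peak - baseline)
    below = np.flatnonzero(vm[i_peak:] <= level)
    if len(below) == 0:
        raise ValueError("no repolarization crossing found")
    k = i_peak + below[0]
    if k == 0 or vm[k] == vm[k - 1]:
        t_cross = k * dt
    else:
        frac = (vm[k - 1] - level) / (vm[k - 1] - vm[k])
        t_cross = (k - 1 + frac) * dt
    return t_cross - i_up * dt


def calibrate_gks(base_params: CellParams, target_shortening: float = 0.17,
                  tol: float = 0.005, max_iter: int = 40,
                  max_beats: int = 200) -> float:
    """Find the apical gKs multiplier producing the requested APD90
    shortening relative to the baseline parameterization.

    Returns m >= 1 with limit-cycle APD90(m) = (1 - target) * APD90(1)
    within ``tol`` (relative), found by monotone bisection on m in
    [1, 20].  APD90 decreases monotonically in m over this range.
    """
    if not 0.0 <= target_shortening < 0.5:
        raise ValueError("target shortening must lie in [0, 0.5)")
    base = pace_to_limit_cycle(base_params, max_beats=max_beats)
    apd_base = base.apd90
    target_apd = (1.0 - target_shortening) * apd_base
    if target_shortening == 0.0:
        return 1.0

    def apd_of(m):
        p = CellParams(**{**base_params.__dict__, "gks_scale":
                          base_params.gks_scale * m})
        # warm start from the baseline limit cycle
        r = pace_to_limit_cycle(p, max_beats=max_beats,
                                initial_state=base.state)
        return r.apd90

    lo, hi = 1.0, 20.0
    apd_hi = apd_of(hi)
    if apd_hi > target_apd:
        raise ValueError("target shortening unreachable for m in [1, 20]")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        apd_mid = apd_of(mid)
        if abs(apd_mid - target_apd) / target_apd < tol:
            return mid
        if apd_mid > target_apd:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gks_gradient_field(apicobasal: np.ndarray, apex_scale: float) -> np.ndarray:
    """Per-node gKs multiplier, linear in the apico-basal coordinate
    from ``apex_scale`` at the apex (a = 0) to 1 at the base (a = 1)."""
    a = np.asarray(apicobasal, dtype=float)
    return apex_scale + a * (1.0 - apex_scale)
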