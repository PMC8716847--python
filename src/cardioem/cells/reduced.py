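"""Fast phenomenological ventricular test double.

A two-variable excitation model (cubic-like ingoing/outgoing current
balance with a recovery gate) mapped onto the physiological voltage
range, plus a prescribed intracellular calcium transient triggered at
activation.  It runs orders of magnitude faster than the full ionic
model and exposes the same stepping interface, so the complete coupled
chain (tissue EP, tension, mechanics, circulation, ECG) can be
exercised quickly.

Action-potential duration is governed by the gate closing time constant
``tau_close``; the per-cell ``gks_scale`` multiplier divides it, so a
multiplier > 1 shortens the action potential exactly like an increased
repolarizing conductance would, and the apico-basal heterogeneity
machinery applies unchanged.

The calcium transient is Ca(t) = ca_dias + ca_amp * ((t/tau_ca) *
exp(1 - t/tau_ca))^2 with t the time since activation; it peaks at
``ca_amp`` above diastolic at t = tau_ca.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .base import check_finite

STATE_NAMES = ["v", "h", "t_act", "cai"]
N_STATES = 4
IDX_V = 0
IDX_CAI = 3

V_REST = -85.0
V_AMP = 110.0  # mV; peak = -85 + 110 = +25 mV

# kinetics (ms)
TAU_IN = 0.3
TAU_OUT = 6.0
TAU_OPEN = 120.0
TAU_CLOSE = 175.0
V_GATE = 0.13

# calcium transient
CA_DIAS = 1.0e-4   # mM
CA_AMP = 6.0e-4    # mM above diastolic at the peak
TAU_CA = 60.0      # ms to peak


@njit(cache=True, fastmath=True)
def _step_reduced(Y, dt, istim, gks_scale):
    n = Y.shape[0]
    for ic in range(n):
        v = (Y[ic, 0] - V_REST) / V_AMP
        h = Y[ic, 1]
        ta = Y[ic, 2]
        dv = h * v * v * (1.0 - v) / TAU_IN - v / TAU_OUT \
            - istim[ic] / V_AMP
        if v < V_GATE:
            dh = (1.0 - h) / TAU_OPEN
        else:
            dh = -h / (TAU_CLOSE / gks_scale[ic])
        v_new = v + dt * dv
        # activation bookkeeping: upward crossing of the gate threshold
        if v < 0.5 and v_new >= 0.5 and ta > 300.0:
            ta = 0.0
        ta += dt
        ca = CA_DIAS
        if ta < 8.0 * TAU_CA:
            x = ta / TAU_CA
            ca += CA_AMP * (x * np.exp(1.0 - x))**2
        Y[ic, 0] = V_REST + V_AMP * v_new
        Y[ic, 1] = h + dt * dh
        Y[ic, 2] = ta
        Y[ic, 3] = ca


@njit(cache=True)
def _beat_kernel_reduced(Y, dt, n_steps, stim_amp, stim_dur, gks, trace,
                         sample_every):
    istim_on = np.full(Y.shape[0], stim_amp)
    istim_off = np.zeros(Y.shape[0])
    k = 0
    for i in range(n_steps):
        t = i * dt
        istim = istim_on if t < stim_dur else istim_off
        _step_reduced(Y, dt, istim, gks)
        if sample_every > 0 and (i + 1) % sample_every == 0:
            trace[k] = Y[0, 0]
            k += 1


class ReducedModel:
    """Two-variable excitation model with a prescribed Ca transient."""

    name = "reduced"
    n_states = N_STATES
    state_names = STATE_NAMES
    idx_v = IDX_V
    idx_ca = IDX_CAI
    max_dt = 0.1

    def initial_state(self, n: int, variant: str = "endo") -> np.ndarray:
        Y = np.zeros((n, N_STATES))
        Y[:, 0] = V_REST
        Y[:, 1] = 1.0
        Y[:, 2] = 1.0e4  # long since last activation
        Y[:, 3] = CA_DIAS
        return Y

    def step(self, Y, dt, istim, gks_scale=None, is_epi=None,
             strong_coupling: bool = False, tnc_flux=None,
             check: bool = False) -> None:
        n = Y.shape[0]
        istim = np.ascontiguousarray(
            np.broadcast_to(np.asarray(istim, dtype=np.float64), (n,)))
        gks = np.ones(n) if gks_scale is None else np.ascontiguousarray(
            np.broadcast_to(np.asarray(gks_scale, dtype=np.float64), (n,)))
        nsub = max(1, int(np.ceil(dt / self.max_dt - 1e-12)))
        h = dt / nsub
        for _ in range(nsub):
            _step_reduced(Y, h, istim, gks)
        if check:
            check_finite(Y, STATE_NAMES)

    def run_beat(self, Y, params, dt, record=False):
        n_steps = int(round(params.cycle_length / dt))
        gks = np.full(Y.shape[0], params.gks_scale)
        trace = np.empty(n_steps if record else 0)
        _beat_kernel_reduced(Y, dt, n_steps, params.stim_amplitude,
                             params.stim_duration, gks, trace,
                             1 if record else 0)
        return trace if record else None
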