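"""Myofilament active tension (Rice-type mean-field crossbridge model).

Converts the intracellular calcium transient and the fiber stretch
(plus stretch rate) into active tension.  The model follows the
published mean-field approximation of cooperative thin-filament
activation and crossbridge cycling: calcium binds troponin-C with a
low- and a high-affinity regulatory fraction, filament-overlap
functions of sarcomere length weight their contribution, a steeply
cooperative permissive/non-permissive transition gates a three-state
crossbridge cycle (permissive -> pre-rotated -> post-rotated), and the
mean crossbridge distortions carry the strain/velocity dependence of
force.  Rate constants are effective body-temperature (37 °C) values.

Sarcomere length is prescribed as SL = lambda * SL_ref by the mechanics
model (no internal series elasticity).  With strong coupling enabled,
the net troponin-C calcium binding flux (mM/ms) computed here — which
is length and velocity dependent through the overlap weighting — is
returned so the electrophysiological cell model can use it in place of
its internal, length-independent troponin buffer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = ["TensionParams", "TensionState", "TensionModel",
           "isometric_twitch"]

STATE_NAMES = ["trpn_ca_l", "trpn_ca_h", "n_nonperm",
               "xb_prer", "xb_postr", "x_prer", "x_postr"]
N_STATES = len(STATE_NAMES)


@dataclass
class TensionParams:
    """Myofilament parameters (rates in 1/ms, lengths in µm).

    The defaults are the published parameter family adjusted to 37 °C;
    ``t_ref`` scales normalized force to tension in kPa.
    """

    temperature: float = 37.0
    sl_ref: float = 1.9          # µm, reference sarcomere length at lambda=1
    sl_min: float = 1.4
    sl_max: float = 2.4
    # troponin-C kinetics
    k_on: float = 50.0           # 1/(mM*ms)
    k_off_l: float = 0.07        # 1/ms, low-affinity
    k_off_h: float = 0.04        # 1/ms, high-affinity
    trpn_total: float = 0.07     # mM regulatory troponin concentration
    # permissive transition
    perm50: float = 0.22
    n_perm: float = 8.0
    k_np: float = 0.15           # 1/ms
    k_pn: float = 0.03           # 1/ms
    # crossbridge cycle
    f_app: float = 0.10          # 1/ms  P -> prerotated
    g_app: float = 0.03          # 1/ms  prerotated -> P
    h_f: float = 0.40            # 1/ms  prerotated -> postrotated
    h_b: float = 0.08            # 1/ms  postrotated -> prerotated
    g_xb: float = 0.03           # 1/ms  postrotated -> detached
    g_slmod: float = 2.0         # detachment increase at low overlap
    hf_mdc: float = 5.0          # strain sensitivity of rotation
    sigma_p: float = 8.0         # strain sensitivity of detachment (+)
    sigma_n: float = 1.0
    x0: float = 0.007            # µm, power-stroke distortion
    phi: float = 2.0             # mean-strain relaxation factor
    # filament geometry (µm)
    len_thick: float = 1.65
    len_hbare: float = 0.1
    len_thin: float = 1.2
    # tension scaling
    t_ref: float = 135.0         # kPa at full overlap and saturation
    strong_coupling: bool = False

    def __post_init__(self):
        if self.temperature != 37.0:
            raise ValueError("only the 37 °C parameterization is shipped")
        for name in ("k_on", "k_off_l", "k_off_h", "k_np", "k_pn",
                     "f_app", "g_app", "h_f", "h_b", "g_xb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"rate {name} must be positive")

    def duty_fractions(self):
        """Steady-state pre/post-rotated occupancies of a fully
        permissive pool, used to normalize force and mean strain."""
        A, B, F, H, G = self.f_app, self.g_app, self.h_f, self.h_b, self.g_xb
        # solve dR = A(1-R-S) - (B+F)R + HS = 0 ; dS = FR - (H+G)S = 0
        M = np.array([[A + B + F, A - H], [-F, H + G]])
        r, s = np.linalg.solve(M, np.array([A, 0.0]))
        return float(r), float(s)


@dataclass
class TensionState:
    """Per-cell myofilament state plus last outputs."""

    Y: np.ndarray                # (n, N_STATES)
    tension: np.ndarray          # kPa
    tnc_flux: np.ndarray         # mM/ms, net TnC Ca binding

    @classmethod
    def zeros(cls, n: int):
        Y = np.zeros((n, N_STATES))
        Y[:, 2] = 1.0  # fully non-permissive at rest
        return cls(Y=Y, tension=np.zeros(n), tnc_flux=np.zeros(n))


@njit(cache=True, fastmath=True)
def _tension_kernel(Y, ca, lam, dlam, dt, out_T, out_flux,
                    k_on, k_off_l, k_off_h, trpn_total, perm50, n_perm,
                    k_np, k_pn, f_app, g_app, h_f, h_b, g_xb, g_slmod,
                    hf_mdc, sigma_p, sigma_n, x0, phi,
                    len_thick, len_hbare, len_thin, sl_ref, sl_min, sl_max,
                    t_ref, duty_prer, duty_postr):
    n = Y.shape[0]
    fnorm = duty_postr * x0  # normalization: max postr occupancy * stroke
    for ic in range(n):
        sl = lam[ic] * sl_ref
        if sl < sl_min:
            sl = sl_min
        elif sl > sl_max:
            sl = sl_max
        dsl = dlam[ic] * sl_ref

        # single/double overlap fractions
        sovr_ze = min(len_thick / 2.0, sl / 2.0)
        sovr_cle = max(sl / 2.0 - (sl - len_thin), len_hbare / 2.0)
        len_sovr = max(sovr_ze - sovr_cle, 0.0)
        sovf_thick = 2.0 * len_sovr / (len_thick - len_hbare)
        sovf_thin = len_sovr / len_thin

        trl = Y[ic, 0]; trh = Y[ic, 1]
        nn = Y[ic, 2]; xbpr = Y[ic, 3]; xbpo = Y[ic, 4]
        xpr = Y[ic, 5]; xpo = Y[ic, 6]
        perm_pool = 1.0 - nn - xbpr - xbpo  # permissive, unattached

        # troponin-C calcium binding
        dtrl = k_on * ca[ic] * (1.0 - trl) - k_off_l * trl
        dtrh = k_on * ca[ic] * (1.0 - trh) - k_off_h * trh
        trop_reg = (1.0 - sovf_thin) * trl + sovf_thin * trh
        if trop_reg < 1e-9:
            trop_reg = 1e-9
        permtot = np.sqrt(1.0 / (1.0 + (perm50 / trop_reg)**n_perm))
        inprmt = 1.0 / permtot
        if inprmt > 100.0:
            inprmt = 100.0

        # crossbridge cycling with strain-dependent rates
        # (exponent arguments clamped for numerical robustness)
        xpr_n = xpr / x0
        arg = hf_mdc * xpr_n * xpr_n
        if arg > 5.0:
            arg = 5.0
        hfmd = np.exp(-arg if xpr_n > 0.0 else arg)
        dxo = (x0 - xpo) / x0
        arg = (sigma_p if xpo < x0 else sigma_n) * dxo * dxo
        if arg > 5.0:
            arg = 5.0
        gxbmd = np.exp(arg)
        gappsl = g_app * (1.0 + (1.0 - sovf_thick) * g_slmod)
        hf_eff = h_f * hfmd
        gxb_eff = g_xb * gxbmd

        dnn = -k_np * permtot * nn + k_pn * inprmt * perm_pool

        trl += dt * dtrl
        trh += dt * dtrh
        nn += dt * dnn

        # implicit Euler on the (stiff) attached-state pair
        # xbpr' = f_app*(1-nn-xbpr-xbpo) - (gappsl+hf_eff)*xbpr + h_b*xbpo
        # xbpo' = hf_eff*xbpr - (h_b+gxb_eff)*xbpo
        a11 = 1.0 + dt * (f_app + gappsl + hf_eff)
        a12 = dt * (f_app - h_b)
        a21 = -dt * hf_eff
        a22 = 1.0 + dt * (h_b + gxb_eff)
        b1 = xbpr + dt * f_app * (1.0 - nn)
        b2 = xbpo
        det = a11 * a22 - a12 * a21
        xbpr = (b1 * a22 - a12 * b2) / det
        xbpo = (a11 * b2 - a21 * b1) / det

        # mean distortions: advected by half the SL rate, relaxed toward
        # their steady offsets (implicit in the linear relaxation)
        c1 = phi / duty_prer
        c2 = phi / duty_postr
        xpr = (xpr + dt * (0.5 * dsl + c1 * h_b * (xpo - x0))) / \
            (1.0 + dt * c1 * (f_app + h_b))
        xpo = (xpo + dt * (0.5 * dsl + c2 * h_f * (xpr + x0))) / \
            (1.0 + dt * c2 * h_f)
        # mean distortions beyond a few power strokes are unphysical
        # (crossbridges detach); bound them for robustness
        lim = 3.0 * x0
        if xpr > lim:
            xpr = lim
        elif xpr < -lim:
            xpr = -lim
        if xpo > lim:
            xpo = lim
        elif xpo < -lim:
            xpo = -lim
        # clip occupancies into the simplex (Euler safeguards)
        if nn < 0.0:
            nn = 0.0
        if xbpr < 0.0:
            xbpr = 0.0
        if xbpo < 0.0:
            xbpo = 0.0
        tot = nn + xbpr + xbpo
        if tot > 1.0:
            nn /= tot; xbpr /= tot; xbpo /= tot

        Y[ic, 0] = trl; Y[ic, 1] = trh; Y[ic, 2] = nn
        Y[ic, 3] = xbpr; Y[ic, 4] = xbpo; Y[ic, 5] = xpr; Y[ic, 6] = xpo

        T = t_ref * sovf_thick * (xbpr * xpr + xbpo * xpo) / fnorm
        out_T[ic] = T if T > 0.0 else 0.0
        out_flux[ic] = trpn_total * ((1.0 - sovf_thin) * dtrl +
                                     sovf_thin * dtrh)


class TensionModel:
    """Steps the myofilament state for an array of cells."""

    max_dt = 0.05  # ms

    def __init__(self, params: TensionParams | None = None):
        self.params = params or TensionParams()
        self._duty = self.params.duty_fractions()

    def initial_state(self, n: int) -> TensionState:
        return TensionState.zeros(n)

    def step(self, state: TensionState, ca, lam, dlam_dt, dt: float
             ) -> TensionState:
        """Advance by dt (ms); ca in mM, lam dimensionless, dlam_dt 1/ms.

        Updates ``state`` in place and returns it; ``state.tension``
        (kPa) and ``state.tnc_flux`` (mM/ms) hold the outputs.
        """
        p = self.params
        n = state.Y.shape[0]
        ca = np.ascontiguousarray(np.broadcast_to(
            np.asarray(ca, dtype=np.float64), (n,)))
        lam = np.ascontiguousarray(np.broadcast_to(
            np.asarray(lam, dtype=np.float64), (n,)))
        dlam = np.ascontiguousarray(np.broadcast_to(
            np.asarray(dlam_dt, dtype=np.float64), (n,)))
        if (lam <= 0).any():
            raise ValueError("fiber stretch must be positive")
        if (ca < 0).any():
            raise ValueError("calcium concentration must be non-negative")
        nsub = max(1, int(np.ceil(dt / self.max_dt - 1e-12)))
        h = dt / nsub
        for _ in range(nsub):
            _tension_kernel(
                state.Y, ca, lam, dlam, h, state.tension, state.tnc_flux,
                p.k_on, p.k_off_l, p.k_off_h, p.trpn_total, p.perm50,
                p.n_perm, p.k_np, p.k_pn, p.f_app, p.g_app, p.h_f, p.h_b,
                p.g_xb, p.g_slmod, p.hf_mdc, p.sigma_p, p.sigma_n, p.x0,
                p.phi, p.len_thick, p.len_hbare, p.len_thin, p.sl_ref,
                p.sl_min, p.sl_max, p.t_ref, self._duty[0], self._duty[1])
        if not np.isfinite(state.Y).all():
            bad = np.argwhere(~np.isfinite(state.Y))[0]
            raise FloatingPointError(
                f"non-finite tension state '{STATE_NAMES[bad[1]]}' "
                f"of cell {bad[0]}")
        return state


def isometric_twitch(params: TensionParams, ca_transient: np.ndarray,
                     dt: float, lam: float = 1.0):
    """Fixed-length twitch driven by a prescribed calcium transient.

    Returns (tension trace kPa, summary dict with peak tension,
    time-to-peak and 50% relaxation time in ms).
    """
    model = TensionModel(params)
    st = model.initial_state(1)
    T = np.empty(len(ca_transient))
    for i, ca in enumerate(ca_transient):
        model.step(st, ca, lam, 0.0, dt)
        T[i] = st.tension[0]
    ipk = int(np.argmax(T))
    peak = float(T[ipk])
    t_peak = ipk * dt
    rt50 = np.nan
    if peak > 0:
        below = np.flatnonzero(T[ipk:] <= 0.5 * peak)
        if len(below):
            rt50 = below[0] * dt
    return T, {"peak_kpa": peak, "time_to_peak_ms": t_peak,
               "relax50_ms": rt50}
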