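"""Human ventricular myocyte membrane kinetics (endo/epi variants).

Implements the published human ventricular ionic model with fast and
late sodium, transient outward, L-type calcium (with CaMK-phosphorylated
channel fractions), rapid and slow delayed rectifier, inward rectifier,
Na/Ca exchange (myoplasmic and subspace), Na/K pump, background and pump
currents, subspace calcium handling with SR release/uptake, and CaMK
dynamics.  Gates are advanced with the Rush-Larsen scheme, everything
else with forward Euler; the kernel is numba-compiled and vectorized
over cells.

The fast-sodium conductance is exposed as a scale factor so tissue-level
conduction can be tuned at coarse resolutions; the default of 1.0 is the
published value.  The slow delayed-rectifier conductance g_Ks carries a
per-cell multiplier used for apico-basal repolarization heterogeneity.

With strong coupling enabled, the troponin-C buffer inside the
myoplasmic calcium ODE is removed and replaced by the net TnC binding
flux supplied by the tension model.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .base import check_finite

# state layout
STATE_NAMES = [
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1", "Jrelnp", "Jrelp", "CaMKt",
]
N_STATES = len(STATE_NAMES)
IDX_V = 0
IDX_CAI = 5

# physical constants
_R, _T, _F = 8314.0, 310.0, 96485.0
_NAO, _CAO, _KO = 140.0, 1.8, 5.4

# cell geometry (cm based, matching the published µA/µF normalization)
_L, _RAD = 0.01, 0.0011
_VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L
_AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L
_ACAP = 2.0 * _AGEO
_VMYO = 0.68 * _VCELL
_VNSR = 0.0552 * _VCELL
_VJSR = 0.0048 * _VCELL
_VSS = 0.02 * _VCELL


@njit(cache=True, fastmath=True)
def _step_kernel(Y, dt, istim, gks_scale, is_epi, gna_scale,
                 strong, tnc_flux):  # noqa: C901  (single hot kernel)
    n = Y.shape[0]
    for ic in range(n):
        v = Y[ic, 0]
        nai = Y[ic, 1]; nass = Y[ic, 2]; ki = Y[ic, 3]; kss = Y[ic, 4]
        cai = Y[ic, 5]; cass = Y[ic, 6]; cansr = Y[ic, 7]; cajsr = Y[ic, 8]
        m = Y[ic, 9]; hf = Y[ic, 10]; hs = Y[ic, 11]; j = Y[ic, 12]
        hsp = Y[ic, 13]; jp = Y[ic, 14]; mL = Y[ic, 15]; hL = Y[ic, 16]
        hLp = Y[ic, 17]; a = Y[ic, 18]; iF = Y[ic, 19]; iS = Y[ic, 20]
        ap = Y[ic, 21]; iFp = Y[ic, 22]; iSp = Y[ic, 23]
        d = Y[ic, 24]; ff = Y[ic, 25]; fs = Y[ic, 26]; fcaf = Y[ic, 27]
        fcas = Y[ic, 28]; jca = Y[ic, 29]; nca = Y[ic, 30]
        ffp = Y[ic, 31]; fcafp = Y[ic, 32]; xrf = Y[ic, 33]; xrs = Y[ic, 34]
        xs1 = Y[ic, 35]; xs2 = Y[ic, 36]; xk1 = Y[ic, 37]
        Jrelnp = Y[ic, 38]; Jrelp = Y[ic, 39]; CaMKt = Y[ic, 40]
        epi = is_epi[ic] != 0

        # CaMK
        KmCaMK = 0.15
        CaMKb = 0.05 * (1.0 - CaMKt) / (1.0 + 0.0015 / cass)
        CaMKa = CaMKb + CaMKt
        dCaMKt = 0.05 * CaMKb * (CaMKb + CaMKt) - 0.00068 * CaMKt
        fp = 1.0 / (1.0 + KmCaMK / CaMKa)

        # reversal potentials
        ENa = _R * _T / _F * np.log(_NAO / nai)
        EK = _R * _T / _F * np.log(_KO / ki)
        EKs = _R * _T / _F * np.log((_KO + 0.01833 * _NAO) /
                                    (ki + 0.01833 * nai))
        vfrt = v * _F / (_R * _T)
        vffrt = v * _F * _F / (_R * _T)

        # --- INa ---
        mss = 1.0 / (1.0 + np.exp(-(v + 39.57) / 9.871))
        tm = 1.0 / (6.765 * np.exp((v + 11.64) / 34.77) +
                    8.552 * np.exp(-(v + 77.42) / 5.955))
        hss = 1.0 / (1.0 + np.exp((v + 82.90) / 6.086))
        thf = 1.0 / (1.432e-5 * np.exp(-(v + 1.196) / 6.285) +
                     6.149 * np.exp((v + 0.5096) / 20.27))
        ths = 1.0 / (0.009794 * np.exp(-(v + 17.95) / 28.05) +
                     0.3343 * np.exp((v + 5.730) / 56.66))
        h = 0.99 * hf + 0.01 * hs
        jss = hss
        tj = 2.038 + 1.0 / (0.02136 * np.exp(-(v + 100.6) / 8.281) +
                            0.3052 * np.exp((v + 0.9941) / 38.45))
        hssp = 1.0 / (1.0 + np.exp((v + 89.1) / 6.086))
        thsp = 3.0 * ths
        hp = 0.99 * hf + 0.01 * hsp
        tjp = 1.46 * tj
        GNa = 75.0 * gna_scale
        INa = GNa * (v - ENa) * m**3 * ((1.0 - fp) * h * j + fp * hp * jp)

        # --- INaL ---
        mLss = 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264))
        tmL = tm
        hLss = 1.0 / (1.0 + np.exp((v + 87.61) / 7.488))
        thL = 200.0
        hLssp = 1.0 / (1.0 + np.exp((v + 93.81) / 7.488))
        thLp = 3.0 * thL
        GNaL = 0.0075 * (0.6 if epi else 1.0)
        INaL = GNaL * (v - ENa) * mL * ((1.0 - fp) * hL + fp * hLp)

        # --- Ito ---
        ass = 1.0 / (1.0 + np.exp(-(v - 14.34) / 14.82))
        ta = 1.0515 / (1.0 / (1.2089 * (1.0 + np.exp(-(v - 18.41) / 29.38)))
                       + 3.5 / (1.0 + np.exp((v + 100.0) / 29.38)))
        iss = 1.0 / (1.0 + np.exp((v + 43.94) / 5.711))
        delta_epi = (1.0 - 0.95 / (1.0 + np.exp((v + 70.0) / 5.0))) \
            if epi else 1.0
        tiF = (4.562 + 1.0 / (0.3933 * np.exp(-(v + 100.0) / 100.0) +
                              0.08004 * np.exp((v + 50.0) / 16.59))) * delta_epi
        tiS = (23.62 + 1.0 / (0.001416 * np.exp(-(v + 96.52) / 59.05) +
                              1.780e-8 * np.exp((v + 114.1) / 8.079))) * delta_epi
        AiF = 1.0 / (1.0 + np.exp((v - 213.6) / 151.2))
        AiS = 1.0 - AiF
        i_gate = AiF * iF + AiS * iS
        assp = 1.0 / (1.0 + np.exp(-(v - 24.34) / 14.82))
        dti_develop = 1.354 + 1e-4 / (np.exp((v - 167.4) / 15.89) +
                                      np.exp(-(v - 12.23) / 0.2154))
        dti_recover = 1.0 - 0.5 / (1.0 + np.exp((v + 70.0) / 20.0))
        tiFp = dti_develop * dti_recover * tiF
        tiSp = dti_develop * dti_recover * tiS
        ip_gate = AiF * iFp + AiS * iSp
        Gto = 0.02 * (4.0 if epi else 1.0)
        Ito = Gto * (v - EK) * ((1.0 - fp) * a * i_gate + fp * ap * ip_gate)

        # --- ICaL / ICaNa / ICaK ---
        dss = 1.0 / (1.0 + np.exp(-(v + 3.940) / 4.230))
        td = 0.6 + 1.0 / (np.exp(-0.05 * (v + 6.0)) + np.exp(0.09 * (v + 14.0)))
        fss = 1.0 / (1.0 + np.exp((v + 19.58) / 3.696))
        tff = 7.0 + 1.0 / (0.0045 * np.exp(-(v + 20.0) / 10.0) +
                           0.0045 * np.exp((v + 20.0) / 10.0))
        tfs = 1000.0 + 1.0 / (3.5e-5 * np.exp(-(v + 5.0) / 4.0) +
                              3.5e-5 * np.exp((v + 5.0) / 6.0))
        f_gate = 0.6 * ff + 0.4 * fs
        fcass_ss = fss
        tfcaf = 7.0 + 1.0 / (0.04 * np.exp(-(v - 4.0) / 7.0) +
                             0.04 * np.exp((v - 4.0) / 7.0))
        tfcas = 100.0 + 1.0 / (0.00012 * np.exp(-v / 3.0) +
                               0.00012 * np.exp(v / 7.0))
        Afcaf = 0.3 + 0.6 / (1.0 + np.exp((v - 10.0) / 10.0))
        Afcas = 1.0 - Afcaf
        fca = Afcaf * fcaf + Afcas * fcas
        tjca = 75.0
        tffp = 2.5 * tff
        fp_gate = 0.6 * ffp + 0.4 * fs
        tfcafp = 2.5 * tfcaf
        fcap = Afcaf * fcafp + Afcas * fcas
        km2n = jca * 1.0
        anca = 1.0 / (1000.0 / km2n + (1.0 + 0.002 / cass)**4)
        dnca = anca * 1000.0 - nca * km2n

        e2v = np.exp(2.0 * vfrt)
        e1v = np.exp(vfrt)
        PhiCaL = 4.0 * vffrt * (cass * e2v - 0.341 * _CAO) / (e2v - 1.0)
        PhiCaNa = vffrt * (0.75 * nass * e1v - 0.75 * _NAO) / (e1v - 1.0)
        PhiCaK = vffrt * (0.75 * kss * e1v - 0.75 * _KO) / (e1v - 1.0)
        PCa = 0.0001 * (1.2 if epi else 1.0)
        PCap = 1.1 * PCa
        PCaNa = 0.00125 * PCa
        PCaK = 3.574e-4 * PCa
        PCaNap = 0.00125 * PCap
        PCaKp = 3.574e-4 * PCap
        g_open = d * (f_gate * (1.0 - nca) + jca * fca * nca)
        g_openp = d * (fp_gate * (1.0 - nca) + jca * fcap * nca)
        ICaL = (1.0 - fp) * PCa * PhiCaL * g_open + fp * PCap * PhiCaL * g_openp
        ICaNa = (1.0 - fp) * PCaNa * PhiCaNa * g_open + \
            fp * PCaNap * PhiCaNa * g_openp
        ICaK = (1.0 - fp) * PCaK * PhiCaK * g_open + fp * PCaKp * PhiCaK * g_openp

        # --- IKr ---
        xrss = 1.0 / (1.0 + np.exp(-(v + 8.337) / 6.789))
        txrf = 12.98 + 1.0 / (0.3652 * np.exp((v - 31.66) / 3.869) +
                              4.123e-5 * np.exp(-(v - 47.78) / 20.38))
        txrs = 1.865 + 1.0 / (0.06629 * np.exp((v - 34.70) / 7.355) +
                              1.128e-5 * np.exp(-(v - 29.74) / 25.94))
        Axrf = 1.0 / (1.0 + np.exp((v + 54.81) / 38.21))
        Axrs = 1.0 - Axrf
        xr = Axrf * xrf + Axrs * xrs
        rkr = 1.0 / ((1.0 + np.exp((v + 55.0) / 75.0)) *
                     (1.0 + np.exp((v - 10.0) / 30.0)))
        GKr = 0.046 * (1.3 if epi else 1.0)
        IKr = GKr * np.sqrt(_KO / 5.4) * xr * rkr * (v - EK)

        # --- IKs (with per-cell apico-basal scale) ---
        xs1ss = 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932))
        txs1 = 817.3 + 1.0 / (2.326e-4 * np.exp((v + 48.28) / 17.80) +
                              0.001292 * np.exp(-(v + 210.0) / 230.0))
        xs2ss = xs1ss
        txs2 = 1.0 / (0.01 * np.exp((v - 50.0) / 20.0) +
                      0.0193 * np.exp(-(v + 66.54) / 31.0))
        KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai)**1.4)
        GKs = 0.0034 * (1.4 if epi else 1.0) * gks_scale[ic]
        IKs = GKs * KsCa * xs1 * xs2 * (v - EKs)

        # --- IK1 ---
        xk1ss = 1.0 / (1.0 + np.exp(-(v + 2.5538 * _KO + 144.59) /
                                    (1.5692 * _KO + 3.8115)))
        txk1 = 122.2 / (np.exp(-(v + 127.2) / 20.36) +
                        np.exp((v + 236.8) / 69.33))
        rk1 = 1.0 / (1.0 + np.exp((v + 105.8 - 2.6 * _KO) / 9.493))
        GK1 = 0.1908 * (1.2 if epi else 1.0)
        IK1 = GK1 * np.sqrt(_KO) * rk1 * xk1 * (v - EK)

        # --- INaCa (myoplasmic and subspace) ---
        kna1, kna2, kna3 = 15.0, 5.0, 88.12
        kasymm = 12.5
        wna, wca, wnaca = 6.0e4, 6.0e4, 5.0e3
        kcaon, kcaoff = 1.5e6, 5.0e3
        qna, qca = 0.5224, 0.1670
        hca = np.exp(qca * vfrt)
        hna = np.exp(qna * vfrt)
        Gncx = 0.0008 * (1.1 if epi else 1.0)
        INaCa_i = 0.0
        INaCa_ss = 0.0
        for pool in range(2):
            na_ = nai if pool == 0 else nass
            ca_ = cai if pool == 0 else cass
            h1 = 1.0 + na_ / kna3 * (1.0 + hna)
            h2 = na_ * hna / (kna3 * h1)
            h3 = 1.0 / h1
            h4 = 1.0 + na_ / kna1 * (1.0 + na_ / kna2)
            h5 = na_ * na_ / (h4 * kna1 * kna2)
            h6 = 1.0 / h4
            h7 = 1.0 + _NAO / kna3 * (1.0 + 1.0 / hna)
            h8 = _NAO / (kna3 * hna * h7)
            h9 = 1.0 / h7
            h10 = kasymm + 1.0 + _NAO / kna1 * (1.0 + _NAO / kna2)
            h11 = _NAO * _NAO / (h10 * kna1 * kna2)
            h12 = 1.0 / h10
            k1 = h12 * _CAO * kcaon
            k2 = kcaoff
            k3p = h9 * wca
            k3pp = h8 * wnaca
            k3 = k3p + k3pp
            k4p = h3 * wca / hca
            k4pp = h2 * wnaca
            k4 = k4p + k4pp
            k5 = kcaoff
            k6 = h6 * ca_ * kcaon
            k7 = h5 * h2 * wna
            k8 = h8 * h11 * wna
            x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
            x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
            x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
            x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
            s = x1 + x2 + x3 + x4
            E1 = x1 / s; E2 = x2 / s; E3 = x3 / s; E4 = x4 / s
            allo = 1.0 / (1.0 + (150.0e-6 / ca_)**2)
            JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
            JncxCa = E2 * k2 - E1 * k1
            if pool == 0:
                INaCa_i = 0.8 * Gncx * allo * (JncxNa + 2.0 * JncxCa)
            else:
                INaCa_ss = 0.2 * Gncx * allo * (JncxNa + 2.0 * JncxCa)

        # --- INaK ---
        k1p, k1m = 949.5, 182.4
        k2p, k2m = 687.2, 39.4
        k3p_, k3m = 1899.0, 79300.0
        k4p_, k4m = 639.0, 40.0
        Knai = 9.073 * np.exp(-0.155 * vfrt / 3.0)
        Knao = 27.78 * np.exp((1.0 + 0.155) * vfrt / 3.0)
        Kki, Kko = 0.5, 0.3582
        MgADP, MgATP = 0.05, 9.8
        Kmgatp = 1.698e-7
        H_ = 1.0e-7
        eP, Khp = 4.2, 1.698e-7
        Knap, Kxkur = 224.0, 292.0
        P_ = eP / (1.0 + H_ / Khp + nai / Knap + ki / Kxkur)
        dni = (1.0 + nai / Knai)
        dki_ = (1.0 + ki / Kki)
        a1 = k1p * (nai / Knai)**3 / (dni**3 + dki_**2 - 1.0)
        b1 = k1m * MgADP
        a2 = k2p
        dno = (1.0 + _NAO / Knao)
        dko = (1.0 + _KO / Kko)
        b2 = k2m * (_NAO / Knao)**3 / (dno**3 + dko**2 - 1.0)
        a3 = k3p_ * (_KO / Kko)**2 / (dno**3 + dko**2 - 1.0)
        b3 = k3m * P_ * H_ / (1.0 + MgATP / Kmgatp)
        a4 = k4p_ * MgATP / Kmgatp / (1.0 + MgATP / Kmgatp)
        b4 = k4m * (ki / Kki)**2 / (dni**3 + dki_**2 - 1.0)
        x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
        x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
        x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
        x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
        s = x1 + x2 + x3 + x4
        E1 = x1 / s; E2 = x2 / s; E3 = x3 / s; E4 = x4 / s
        JnakNa = 3.0 * (E1 * a3 - E2 * b3)
        JnakK = 2.0 * (E4 * b1 - E3 * a1)
        Pnak = 30.0 * (0.9 if epi else 1.0)
        INaK = Pnak * (JnakNa + JnakK)

        # --- minor currents ---
        xkb = 1.0 / (1.0 + np.exp(-(v - 14.48) / 18.34))
        GKb = 0.003 * (0.6 if epi else 1.0)
        IKb = GKb * xkb * (v - EK)
        INab = 3.75e-10 * vffrt * (nai * e1v - _NAO) / (e1v - 1.0)
        ICab = 2.5e-8 * 4.0 * vffrt * (cai * e2v - 0.341 * _CAO) / (e2v - 1.0)
        IpCa = 0.0005 * cai / (0.0005 + cai)

        # --- diffusion fluxes ---
        JdiffNa = (nass - nai) / 2.0
        JdiffK = (kss - ki) / 2.0
        Jdiff = (cass - cai) / 0.2

        # --- SR release ---
        bt = 4.75
        a_rel = 0.5 * bt
        Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr)**8)
        tau_rel = bt / (1.0 + 0.0123 / cajsr)
        if tau_rel < 0.001:
            tau_rel = 0.001
        btp = 1.25 * bt
        a_relp = 0.5 * btp
        Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr)**8)
        tau_relp = btp / (1.0 + 0.0123 / cajsr)
        if tau_relp < 0.001:
            tau_relp = 0.001
        Jrel = (1.0 - fp) * Jrelnp + fp * Jrelp

        # --- SR uptake ---
        upscale = 1.3 if epi else 1.0
        Jupnp = upscale * 0.004375 * cai / (cai + 0.00092)
        Jupp = upscale * 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
        Jleak = 0.0039375 * cansr / 15.0
        Jup = (1.0 - fp) * Jupnp + fp * Jupp - Jleak
        Jtr = (cansr - cajsr) / 100.0

        # --- membrane potential ---
        Itot = (INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1 +
                INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab +
                istim[ic])
        v_new = v - dt * Itot

        # --- ionic concentrations (forward Euler) ---
        cmdnmax = 0.05 * (1.3 if epi else 1.0)
        kmcmdn = 0.00238
        trpnmax, kmtrpn = 0.07, 0.0005
        BSRmax, KmBSR = 0.047, 0.00087
        BSLmax, KmBSL = 1.124, 0.0087
        csqnmax, kmcsqn = 10.0, 0.8

        dnai = -(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab) * \
            _ACAP / (_F * _VMYO) + JdiffNa * _VSS / _VMYO
        dnass = -(ICaNa + 3.0 * INaCa_ss) * _ACAP / (_F * _VSS) - JdiffNa
        dki = -(Ito + IKr + IKs + IK1 + IKb + istim[ic] - 2.0 * INaK) * \
            _ACAP / (_F * _VMYO) + JdiffK * _VSS / _VMYO
        dkss = -ICaK * _ACAP / (_F * _VSS) - JdiffK

        buf = cmdnmax * kmcmdn / (kmcmdn + cai)**2
        if not strong:
            buf += trpnmax * kmtrpn / (kmtrpn + cai)**2
        Bcai = 1.0 / (1.0 + buf)
        rhs_cai = -(IpCa + ICab - 2.0 * INaCa_i) * _ACAP / (2.0 * _F * _VMYO) \
            - Jup * _VNSR / _VMYO + Jdiff * _VSS / _VMYO
        if strong:
            rhs_cai -= tnc_flux[ic]
        dcai = Bcai * rhs_cai

        Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass)**2 +
                       BSLmax * KmBSL / (KmBSL + cass)**2)
        dcass = Bcass * (-(ICaL - 2.0 * INaCa_ss) * _ACAP / (2.0 * _F * _VSS)
                         + Jrel * _VJSR / _VSS - Jdiff)
        dcansr = Jup - Jtr * _VJSR / _VNSR
        Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr)**2)
        dcajsr = Bcajsr * (Jtr - Jrel)

        # --- Rush-Larsen gate updates ---
        Y[ic, 9] = mss + (m - mss) * np.exp(-dt / tm)
        Y[ic, 10] = hss + (hf - hss) * np.exp(-dt / thf)
        Y[ic, 11] = hss + (hs - hss) * np.exp(-dt / ths)
        Y[ic, 12] = jss + (j - jss) * np.exp(-dt / tj)
        Y[ic, 13] = hssp + (hsp - hssp) * np.exp(-dt / thsp)
        Y[ic, 14] = jss + (jp - jss) * np.exp(-dt / tjp)
        Y[ic, 15] = mLss + (mL - mLss) * np.exp(-dt / tmL)
        Y[ic, 16] = hLss + (hL - hLss) * np.exp(-dt / thL)
        Y[ic, 17] = hLssp + (hLp - hLssp) * np.exp(-dt / thLp)
        Y[ic, 18] = ass + (a - ass) * np.exp(-dt / ta)
        Y[ic, 19] = iss + (iF - iss) * np.exp(-dt / tiF)
        Y[ic, 20] = iss + (iS - iss) * np.exp(-dt / tiS)
        Y[ic, 21] = assp + (ap - assp) * np.exp(-dt / ta)
        Y[ic, 22] = iss + (iFp - iss) * np.exp(-dt / tiFp)
        Y[ic, 23] = iss + (iSp - iss) * np.exp(-dt / tiSp)
        Y[ic, 24] = dss + (d - dss) * np.exp(-dt / td)
        Y[ic, 25] = fss + (ff - fss) * np.exp(-dt / tff)
        Y[ic, 26] = fss + (fs - fss) * np.exp(-dt / tfs)
        Y[ic, 27] = fcass_ss + (fcaf - fcass_ss) * np.exp(-dt / tfcaf)
        Y[ic, 28] = fcass_ss + (fcas - fcass_ss) * np.exp(-dt / tfcas)
        Y[ic, 29] = fcass_ss + (jca - fcass_ss) * np.exp(-dt / tjca)
        Y[ic, 30] = nca + dt * dnca
        Y[ic, 31] = fss + (ffp - fss) * np.exp(-dt / tffp)
        Y[ic, 32] = fcass_ss + (fcafp - fcass_ss) * np.exp(-dt / tfcafp)
        Y[ic, 33] = xrss + (xrf - xrss) * np.exp(-dt / txrf)
        Y[ic, 34] = xrss + (xrs - xrss) * np.exp(-dt / txrs)
        Y[ic, 35] = xs1ss + (xs1 - xs1ss) * np.exp(-dt / txs1)
        Y[ic, 36] = xs2ss + (xs2 - xs2ss) * np.exp(-dt / txs2)
        Y[ic, 37] = xk1ss + (xk1 - xk1ss) * np.exp(-dt / txk1)
        Y[ic, 38] = Jrel_inf + (Jrelnp - Jrel_inf) * np.exp(-dt / tau_rel)
        Y[ic, 39] = Jrel_infp + (Jrelp - Jrel_infp) * np.exp(-dt / tau_relp)

        # --- Euler updates ---
        Y[ic, 0] = v_new
        Y[ic, 1] = nai + dt * dnai
        Y[ic, 2] = nass + dt * dnass
        Y[ic, 3] = ki + dt * dki
        Y[ic, 4] = kss + dt * dkss
        Y[ic, 5] = cai + dt * dcai
        Y[ic, 6] = cass + dt * dcass
        Y[ic, 7] = cansr + dt * dcansr
        Y[ic, 8] = cajsr + dt * dcajsr
        Y[ic, 40] = CaMKt + dt * dCaMKt


@njit(cache=True)
def _beat_kernel(Y, dt, n_steps, stim_amp, stim_dur, gks, epi, gna_scale,
                 trace, sample_every):
    istim_on = np.full(Y.shape[0], stim_amp)
    istim_off = np.zeros(Y.shape[0])
    flux = np.zeros(Y.shape[0])
    k = 0
    for i in range(n_steps):
        t = i * dt
        istim = istim_on if t < stim_dur else istim_off
        _step_kernel(Y, dt, istim, gks, epi, gna_scale, False, flux)
        if sample_every > 0 and (i + 1) % sample_every == 0:
            trace[k] = Y[0, 0]
            k += 1


class OharaRudyModel:
    """Full human ventricular ionic model (endo/epi variants)."""

    name = "ohara"
    n_states = N_STATES
    state_names = STATE_NAMES
    idx_v = IDX_V
    idx_ca = IDX_CAI
    max_dt = 0.005  # ms; first-order substeps, APD-converged

    def __init__(self, gna_scale: float = 2.5):
        self.gna_scale = gna_scale

    def initial_state(self, n: int, variant: str = "endo") -> np.ndarray:
        """Resting initial conditions (gates at their rest steady state)."""
        Y = np.zeros((n, N_STATES))
        v = -87.84
        Y[:, 0] = v
        Y[:, 1] = Y[:, 2] = 7.268
        Y[:, 3] = Y[:, 4] = 144.65
        Y[:, 5] = 8.6e-5
        Y[:, 6] = 8.49e-5
        Y[:, 7] = 1.619
        Y[:, 8] = 1.571
        # gate rest values
        rest = {
            "m": 1.0 / (1.0 + np.exp(-(v + 39.57) / 9.871)),
            "hf": 1.0 / (1.0 + np.exp((v + 82.90) / 6.086)),
            "hs": 1.0 / (1.0 + np.exp((v + 82.90) / 6.086)),
            "j": 1.0 / (1.0 + np.exp((v + 82.90) / 6.086)),
            "hsp": 1.0 / (1.0 + np.exp((v + 89.1) / 6.086)),
            "jp": 1.0 / (1.0 + np.exp((v + 82.90) / 6.086)),
            "mL": 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264)),
            "hL": 1.0 / (1.0 + np.exp((v + 87.61) / 7.488)),
            "hLp": 1.0 / (1.0 + np.exp((v + 93.81) / 7.488)),
            "a": 1.0 / (1.0 + np.exp(-(v - 14.34) / 14.82)),
            "iF": 1.0 / (1.0 + np.exp((v + 43.94) / 5.711)),
            "iS": 1.0 / (1.0 + np.exp((v + 43.94) / 5.711)),
            "ap": 1.0 / (1.0 + np.exp(-(v - 24.34) / 14.82)),
            "iFp": 1.0 / (1.0 + np.exp((v + 43.94) / 5.711)),
            "iSp": 1.0 / (1.0 + np.exp((v + 43.94) / 5.711)),
            "d": 1.0 / (1.0 + np.exp(-(v + 3.940) / 4.230)),
            "ff": 1.0 / (1.0 + np.exp((v + 19.58) / 3.696)),
            "fs": 1.0 / (1.0 + np.exp((v + 19.58) / 3.696)),
            "fcaf": 1.0 / (1.0 + np.exp((v + 19.58) / 3.696)),
            "fcas": 1.0 / (1.0 + np.exp((v + 19.58) / 3.696)),
            "jca": 1.0 / (1.0 + np.exp((v + 19.58) / 3.696)),
            "ffp": 1.0 / (1.0 + np.exp((v + 19.58) / 3.696)),
            "fcafp": 1.0 / (1.0 + np.exp((v + 19.58) / 3.696)),
            "xrf": 1.0 / (1.0 + np.exp(-(v + 8.337) / 6.789)),
            "xrs": 1.0 / (1.0 + np.exp(-(v + 8.337) / 6.789)),
            "xs1": 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932)),
            "xs2": 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932)),
            "xk1": 1.0 / (1.0 + np.exp(-(v + 2.5538 * _KO + 144.59) /
                                       (1.5692 * _KO + 3.8115))),
        }
        for k, val in rest.items():
            Y[:, STATE_NAMES.index(k)] = val
        return Y

    def step(self, Y: np.ndarray, dt: float, istim, gks_scale=None,
             is_epi=None, strong_coupling: bool = False, tnc_flux=None,
             check: bool = False) -> None:
        """Advance all cells by dt in-place, substepping to <= max_dt."""
        n = Y.shape[0]
        istim = np.broadcast_to(np.asarray(istim, dtype=np.float64), (n,))
        gks = np.ones(n) if gks_scale is None else \
            np.broadcast_to(np.asarray(gks_scale, dtype=np.float64), (n,))
        epi = np.zeros(n, dtype=np.int8) if is_epi is None else \
            np.asarray(is_epi, dtype=np.int8)
        flux = np.zeros(n) if tnc_flux is None else \
            np.asarray(tnc_flux, dtype=np.float64)
        if check:
            check_finite(Y, STATE_NAMES)
        nsub = max(1, int(np.ceil(dt / self.max_dt - 1e-12)))
        h = dt / nsub
        for _ in range(nsub):
            _step_kernel(Y, h, np.ascontiguousarray(istim),
                         np.ascontiguousarray(gks), epi,
                         self.gna_scale, strong_coupling, flux)
        if check:
            check_finite(Y, STATE_NAMES)

    def run_beat(self, Y, params, dt, record=False):
        """Advance one full pacing cycle inside a compiled loop.

        Returns the Vm trace sampled every dt when ``record`` is True.
        """
        n_steps = int(round(params.cycle_length / dt))
        gks = np.full(Y.shape[0], params.gks_scale)
        epi = np.full(Y.shape[0], 1 if params.variant == "epi" else 0,
                      dtype=np.int8)
        trace = np.empty(n_steps if record else 0)
        _beat_kernel(Y, dt, n_steps, params.stim_amplitude,
                     params.stim_duration, gks, epi, self.gna_scale,
                     trace, 1 if record else 0)
        return trace if record else None
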