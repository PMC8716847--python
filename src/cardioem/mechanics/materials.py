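"""Constitutive laws for the passive myocardium and surrounding tissue.

The ventricular wall uses the orthotropic Fung-type exponential energy

    W = C0/2 * (exp(Q) - 1),
    Q = b_ff E_ff^2 + b_ss E_ss^2 + b_nn E_nn^2
        + b_fs (E_fs^2 + E_sf^2) + b_fn (E_fn^2 + E_nf^2)
        + b_sn (E_sn^2 + E_ns^2),

with the Green-Lagrange strain E expressed in the local fiber frame
(f, s, sn), plus a volumetric penalty kappa/2 (J - 1)^2 enforcing near
incompressibility.  Active tension is added to the fiber-fiber
component of the second Piola-Kirchhoff stress (and, during unloaded-
state estimation, also to the sheet-sheet component).

A compressible neo-Hookean law is provided for non-cardiac tissue.

Everything here works in "fiber Voigt" notation: strains are
[E_ff, E_ss, E_nn, 2E_fs, 2E_fn, 2E_sn] (engineering shears) and
stresses [S_ff, S_ss, S_nn, S_fs, S_fn, S_sn]; the 6x6 tangent is
d S / d E_engineering, which maps directly onto the fourth-order
material tangent.

Coefficient provenance: the scaling/exponent values are shipped as
data with source tags (the orthotropic set from the cardiac literature
commonly used with this law); see the ``source`` fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MaterialParams", "second_pk_stress", "strain_energy",
           "neo_hookean_stress", "VOIGT_IDX"]

# Voigt index map: a -> (i, j)
VOIGT_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


@dataclass
class MaterialParams:
    """Orthotropic exponential coefficients + volumetric penalty (kPa)."""

    c0: float = 0.5             # kPa, stress scaling; chosen so that
    # re-pressurizing the estimated unloaded state recovers the
    # diastatic volume of the idealized ventricle (see docs/methods.md)
    b_ff: float = 8.0           # along fiber
    b_ss: float = 3.0           # sheet = transmural in this package
    b_nn: float = 6.0           # sheet-normal = second in-plane axis
    b_fs: float = 3.0           # fiber-transmural shear
    b_fn: float = 12.0          # in-plane shear
    b_sn: float = 3.0
    kappa: float = 650.0        # kPa, incompressibility penalty
    # neo-Hookean (non-cardiac tissue)
    nh_mu: float = 10.0         # kPa
    nh_lam: float = 100.0       # kPa
    source: dict = field(default_factory=lambda: {
        "c0_bxx": "orthotropic exponential law, standard cardiac set",
        "kappa": "package choice (penalty formulation)",
        "nh": "package choice (soft surrounding tissue)",
    })

    def __post_init__(self):
        if self.c0 <= 0 or self.kappa < 0:
            raise ValueError("scaling and penalty must be positive")

    @property
    def b_matrix(self) -> np.ndarray:
        return np.array([
            [self.b_ff, self.b_fs, self.b_fn],
            [self.b_fs, self.b_ss, self.b_sn],
            [self.b_fn, self.b_sn, self.b_nn],
        ])

    @property
    def b_voigt(self) -> np.ndarray:
        return np.array([self.b_ff, self.b_ss, self.b_nn,
                         self.b_fs, self.b_fn, self.b_sn])


def _voigt_to_tensor(ev: np.ndarray) -> np.ndarray:
    """(..., 6) engineering Voigt strain -> (..., 3, 3) tensor."""
    E = np.zeros(ev.shape[:-1] + (3, 3))
    for a, (i, j) in enumerate(VOIGT_IDX):
        if i == j:
            E[..., i, j] = ev[..., a]
        else:
            E[..., i, j] = E[..., j, i] = 0.5 * ev[..., a]
    return E


def _cinv_voigt(Ci: np.ndarray):
    """C^-1 as Voigt vector and the 6x6 'H' tensor
    H_ab = Ci_ik Ci_jl + Ci_il Ci_jk for a=(ij), b=(kl)."""
    lead = Ci.shape[:-2]
    ci = np.empty(lead + (6,))
    for a, (i, j) in enumerate(VOIGT_IDX):
        ci[..., a] = Ci[..., i, j]
    H = np.empty(lead + (6, 6))
    for a, (i, j) in enumerate(VOIGT_IDX):
        for b, (k, l) in enumerate(VOIGT_IDX):
            H[..., a, b] = Ci[..., i, k] * Ci[..., j, l] + \
                Ci[..., i, l] * Ci[..., j, k]
    return ci, H


def second_pk_stress(ev: np.ndarray, material: MaterialParams,
                     t_active=0.0, t_init=0.0, with_tangent: bool = True):
    """Second Piola-Kirchhoff stress (fiber Voigt) and material tangent.

    Parameters
    ----------
    ev : (..., 6) array
        Green-Lagrange strain in the fiber frame, engineering Voigt.
    t_active : scalar or (...) array, kPa
        Active tension added to the ff component.
    t_init : scalar or (...) array, kPa
        Unloading stress added to both the ff and ss components.

    Returns
    -------
    (S (...,6) kPa, D (...,6,6) kPa or None)

    Raises if any deformation state has det C <= 0.
    """
    ev = np.asarray(ev, dtype=float)
    E = _voigt_to_tensor(ev)
    C = 2.0 * E + np.eye(3)
    detC = np.linalg.det(C)
    if np.any(detC <= 0.0):
        raise ValueError("non-positive-definite right Cauchy-Green tensor")
    J = np.sqrt(detC)
    Ci = np.linalg.inv(C)

    bv = material.b_voigt
    w = np.array([1.0, 1.0, 1.0, 0.5, 0.5, 0.5])  # engineering weights
    Q = np.einsum("...a,a,a,...a->...", ev, bv, w, ev)
    Q = np.minimum(Q, 80.0)  # overflow guard; ~1e34 kPa is already failure
    eQ = np.exp(Q)
    q = 2.0 * w * bv * ev  # dQ/de
    S_aniso = 0.5 * material.c0 * eQ[..., None] * q

    ci, H = _cinv_voigt(Ci)
    k = material.kappa
    S_vol = (k * (J - 1.0) * J)[..., None] * ci

    S = S_aniso + S_vol
    S[..., 0] += np.asarray(t_active) + np.asarray(t_init)
    # The unloading stress acts on both in-wall directions.  In this
    # package's frame convention the sheet axis is transmural, so the
    # second stressed direction is the sheet-normal (in-plane) axis.
    S[..., 2] += np.asarray(t_init)

    if not with_tangent:
        return S, None
    Dq = np.diag(2.0 * w * bv)
    D_aniso = 0.5 * material.c0 * eQ[..., None, None] * \
        (Dq + np.einsum("...a,...b->...ab", q, q))
    jf1 = k * (2.0 * J - 1.0) * J
    jf2 = k * (J - 1.0) * J
    D_vol = jf1[..., None, None] * np.einsum("...a,...b->...ab", ci, ci) \
        - jf2[..., None, None] * H
    return S, D_aniso + D_vol


def strain_energy(ev: np.ndarray, material: MaterialParams) -> np.ndarray:
    """Energy density W(E) (kPa) for the passive wall law."""
    ev = np.asarray(ev, dtype=float)
    E = _voigt_to_tensor(ev)
    C = 2.0 * E + np.eye(3)
    detC = np.linalg.det(C)
    if np.any(detC <= 0.0):
        raise ValueError("non-positive-definite right Cauchy-Green tensor")
    J = np.sqrt(detC)
    bv = material.b_voigt
    w = np.array([1.0, 1.0, 1.0, 0.5, 0.5, 0.5])
    Q = np.einsum("...a,a,a,...a->...", ev, bv, w, ev)
    return 0.5 * material.c0 * (np.exp(Q) - 1.0) + \
        0.5 * material.kappa * (J - 1.0)**2


def neo_hookean_stress(ev: np.ndarray, material: MaterialParams,
                       with_tangent: bool = True):
    """Compressible neo-Hookean stress for non-cardiac tissue.

    W = mu/2 (I1 - 3 - 2 ln J) + lam/2 (ln J)^2.
    """
    ev = np.asarray(ev, dtype=float)
    E = _voigt_to_tensor(ev)
    C = 2.0 * E + np.eye(3)
    detC = np.linalg.det(C)
    if np.any(detC <= 0.0):
        raise ValueError("non-positive-definite right Cauchy-Green tensor")
    J = np.sqrt(detC)
    lnJ = np.log(J)
    Ci = np.linalg.inv(C)
    ci, H = _cinv_voigt(Ci)
    mu, lam = material.nh_mu, material.nh_lam
    ident = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    S = mu * (ident - ci) + (lam * lnJ)[..., None] * ci
    if not with_tangent:
        return S, None
    D = lam[..., None, None] * np.einsum("...a,...b->...ab", ci, ci) \
        if np.ndim(lam) else lam * np.einsum("...a,...b->...ab", ci, ci)
    D = D + (mu - lam * lnJ)[..., None, None] * H
    return S, D


def nh_strain_energy(ev: np.ndarray, material: MaterialParams) -> np.ndarray:
    ev = np.asarray(ev, dtype=float)
    E = _voigt_to_tensor(ev)
    C = 2.0 * E + np.eye(3)
    J = np.sqrt(np.linalg.det(C))
    I1 = np.trace(C, axis1=-2, axis2=-1)
    return 0.5 * material.nh_mu * (I1 - 3.0 - 2.0 * np.log(J)) + \
        0.5 * material.nh_lam * np.log(J)**2
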