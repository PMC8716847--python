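"""Frictionless pericardial penalty contact.

The heart's epicardial surface interacts with the pericardium through a
normal penalty force governed by the gap function g_N (mm, negative =
penetration).  The hard hinge max(0, -g) is replaced by a C1-continuous
quadratically-smoothed hinge, which converges much better:

    p(g) = 0                         for g >= 0
    p(g) = eps * g^2 / (2 w)         for -w < g < 0
    p(g) = eps * (-g - w/2)          for g <= -w

with smoothing width w (mm) and penalty factor eps (kPa/mm equivalent;
the traction is eps-scaled per mm of penetration in the linear range).
Tangential traction is identically zero (frictionless).

In the idealized setup the pericardium is a rigid analytic ellipsoidal
shell slightly outside the epicardium; the gap is evaluated by a
first-order signed-distance approximation to the shell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["contact_traction", "PericardialShell", "ContactSurface"]


def contact_traction(g: np.ndarray, eps: float, width: float = 0.5):
    """Normal traction magnitude p(g) >= 0 and dp/dg for gap g (mm).

    p is zero for non-negative gaps, C1 at g = 0 and g = -width, and
    monotonically non-decreasing with penetration depth.
    """
    if eps < 0:
        raise ValueError("penalty factor must be non-negative")
    g = np.asarray(g, dtype=float)
    p = np.zeros_like(g)
    dp = np.zeros_like(g)
    mid = (g < 0) & (g > -width)
    p[mid] = eps * g[mid]**2 / (2.0 * width)
    dp[mid] = eps * g[mid] / width
    deep = g <= -width
    p[deep] = eps * (-g[deep] - width / 2.0)
    dp[deep] = -eps
    return p, dp


@dataclass
class PericardialShell:
    """Rigid analytic ellipsoidal pericardium.

    Semi-axes (mm); points with phi = sqrt((x/a)^2+(y/b)^2+(z/c)^2) < 1
    are inside the shell (positive gap).
    """

    a: float
    b: float
    c: float
    z_max: float = np.inf  # informational basal cut; node selection is
    #                        done once in the reference configuration

    @classmethod
    def around(cls, geom, offset: float = 0.5):
        """Shell offset outward from the epicardial ellipsoid."""
        return cls(a=geom.ax + offset, b=geom.by + offset,
                   c=geom.cz + offset, z_max=geom.z_base)

    def gap_and_normal(self, x: np.ndarray):
        """Signed gap (mm, positive = separation) and outward normal."""
        x = np.asarray(x, dtype=float)
        s = np.array([self.a, self.b, self.c])
        y = x / s
        phi = np.linalg.norm(y, axis=-1)
        grad = y / s  # gradient of phi*phi/... actually of phi via chain
        with np.errstate(invalid="ignore", divide="ignore"):
            grad = (x / s**2) / np.maximum(phi, 1e-12)[..., None]
        gn = np.linalg.norm(grad, axis=-1)
        gap = (1.0 - phi) / np.maximum(gn, 1e-12)
        normal = grad / np.maximum(gn, 1e-12)[..., None]
        return gap, normal


@dataclass
class ContactSurface:
    """Epicardial node set tied to a pericardial shell."""

    nodes: np.ndarray            # node indices on the epicardium
    areas: np.ndarray            # reference nodal areas (mm^2)
    shell: PericardialShell
    eps: float = 20.0            # kPa penalty factor (ramped from 0)
    width: float = 0.5           # mm smoothing width

    def forces(self, x: np.ndarray):
        """Nodal contact forces (n_contact, 3) and stiffness data.

        Returns (f, k_nn, normals): f the force on each contact node,
        k_nn >= 0 the scalar stiffness to be scattered as k * n (x) n.
        """
        gap, normal = self.shell.gap_and_normal(x)
        p, dp = contact_traction(np.where(np.isfinite(gap), gap, 1.0),
                                 self.eps, self.width)
        p = np.where(np.isfinite(gap), p, 0.0)
        dp = np.where(np.isfinite(gap), dp, 0.0)
        f = -(p * self.areas)[:, None] * normal
        k_nn = -dp * self.areas  # >= 0
        return f, k_nn, normal
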