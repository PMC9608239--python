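"""Surface differential geometry at patch evaluation points.

Given the control points of a patch and basis weights/derivatives at a
parametric point, compute the covariant tangents ``a_alpha = f,alpha``,
metric ``g_ab = a_a . a_b``, unit normal ``d = a1 x a2 / sqrt(g)``, second
fundamental form ``b_ab = d . a_a,b``, mean curvature ``H = b^a_a / 2``,
Gaussian curvature ``K = det(b^a_b)`` and the area Jacobian
``J = sqrt(g/G)`` relative to the reference configuration.

Sign convention: with the outward normal, the *unit sphere parametrized by
the identity map has H = -1* (the second derivatives of an outward-facing
sphere point inward).  The preferred curvature C0 is interpreted in this
same convention; the shipped studies use C0 = 0, where the sign is inert.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import PatchEvaluation

__all__ = ["LocalGeometry", "local_geometry", "GeometryDegeneracyError"]


class GeometryDegeneracyError(FloatingPointError):
    """Tangent vectors (near-)parallel: the element is geometrically degenerate."""


@dataclass(frozen=True)
class LocalGeometry:
    """First and second fundamental forms at one surface point."""

    a1: np.ndarray        # covariant tangents f,1 and f,2
    a2: np.ndarray
    g_cov: np.ndarray     # metric g_ab (2, 2)
    g_con: np.ndarray     # inverse metric g^ab (2, 2)
    sqrt_g: float         # area measure factor ||a1 x a2||
    d: np.ndarray         # outward unit normal
    d1: np.ndarray        # normal derivatives d,alpha (Weingarten)
    d2: np.ndarray
    b: np.ndarray         # second fundamental form b_ab (2, 2)
    H: float              # mean curvature (unit sphere: -1)
    K: float              # Gaussian curvature
    J: float              # area Jacobian sqrt(g) / sqrt(G)


def local_geometry(control_points: np.ndarray, ev: PatchEvaluation,
                   ref_sqrt_G: float, element: int | None = None) -> LocalGeometry:
    """Evaluate :class:`LocalGeometry` from one patch evaluation.

    ``ref_sqrt_G`` is the reference area factor obtained by applying the
    *same* patch evaluation to the reference control points, so that the
    identity configuration has J = 1 exactly at the discrete level.
    """
    C = np.asarray(control_points, dtype=float)
    if C.shape != (len(ev.basis), 3):
        raise ValueError("control point array does not match the patch stencil")
    if not ref_sqrt_G > 0:
        raise ValueError("ref_sqrt_G must be positive")
    a = ev.d_basis.T @ C                 # (2, 3)
    aab = ev.dd_basis.T @ C              # (3, 3): rows vv, vw, ww
    nx = np.cross(a[0], a[1])
    sqrt_g = float(np.linalg.norm(nx))
    if sqrt_g < 1e-14:
        raise GeometryDegeneracyError(
            f"degenerate tangents at element {element}: |a1 x a2| = {sqrt_g:.3e}"
        )
    d = nx / sqrt_g
    g_cov = a @ a.T
    det_g = sqrt_g * sqrt_g
    g_con = np.array([[g_cov[1, 1], -g_cov[0, 1]],
                      [-g_cov[0, 1], g_cov[0, 0]]]) / det_g
    bv = aab @ d                          # (b_vv, b_vw, b_ww)
    b = np.array([[bv[0], bv[1]], [bv[1], bv[2]]])
    bmix = g_con @ b                      # b^a_b
    H = 0.5 * float(np.trace(bmix))
    K = float(np.linalg.det(bmix))
    # Weingarten: d,alpha = -b_ab g^bc a_c
    dd = -(b @ g_con) @ a                 # (2, 3)
    return LocalGeometry(a1=a[0], a2=a[1], g_cov=g_cov, g_con=g_con,
                         sqrt_g=sqrt_g, d=d, d1=dd[0], d2=dd[1], b=b,
                         H=H, K=K, J=sqrt_g / ref_sqrt_G)
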