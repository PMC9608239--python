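"""Loop limit-surface basis functions and their parametric derivatives.

The limit surface of Loop subdivision restricted to a face of a *regular*
patch (all three corners valence six) is a single quartic polynomial in
the barycentric coordinates of that face, spanned by the 12 translates of
the quartic three-direction box spline.  On an *irregular* patch (one
extraordinary corner of valence ``n``) the surface is evaluated by
conceptually subdividing the patch until the point of interest falls in a
regular sub-patch; the required products of subdivision matrices are
precomputed per valence and applied through their eigendecomposition, so
no explicit mesh refinement happens at evaluation time.

Chart convention: a face with (possibly rotated) corners ``(c0, c1, c2)``
is parametrized by ``(v, w)``, the barycentric weights of ``c1`` and
``c2`` (``u = 1 - v - w`` at ``c0``).  For irregular patches ``c0`` is the
extraordinary vertex, anchored at ``(v, w) = (0, 0)``.

All tabulated polynomial coefficients and subdivision matrices are derived
at import/build time from the subdivision masks themselves (template
meshes, valence-6 limit stencil, exact quartic fit), not copied from
published tables; correctness is pinned by the explicit
repeated-subdivision oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .mesh import (MeshStructureError, SurfaceMesh, face_stencil, loop_beta,
                   loop_limit_weight, loop_subdivide, surface_mesh)

__all__ = [
    "PatchEvaluation",
    "eval_regular",
    "eval_irregular",
    "eval_regular_many",
    "eval_irregular_many",
    "subdivision_oracle",
    "MIN_VALENCE",
    "MAX_VALENCE",
]

MIN_VALENCE, MAX_VALENCE = 3, 12

_EPS_VERTEX = 1e-12   # (v + w) below this counts as "at the extraordinary vertex"
_MAX_SUBDIV = 24      # depth cap near the extraordinary vertex


@dataclass(frozen=True)
class PatchEvaluation:
    """Basis weights and parametric derivatives at one point of a patch.

    ``basis`` has one weight per control point of the patch stencil
    (12 for regular, valence+6 for irregular patches); ``d_basis`` holds
    the (v, w) gradients and ``dd_basis`` the second derivatives packed as
    ``[vv, vw, ww]``.  Weights sum to one (partition of unity), each
    derivative column sums to zero.
    """

    basis: np.ndarray      # (s,)
    d_basis: np.ndarray    # (s, 2)
    dd_basis: np.ndarray   # (s, 3)


def _check_simplex(v, w):
    if v < -1e-14 or w < -1e-14 or v + w > 1.0 + 1e-14:
        raise ValueError(f"(v, w) = ({v}, {w}) outside the parameter triangle")


# ---------------------------------------------------------------------------
# Regular patch: quartic box-spline basis fitted from the subdivision masks.

def _planar_template(grid: int = 11):
    """Planar three-direction lattice with a deep-interior central face."""
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.5, np.sqrt(3.0) / 2.0, 0.0])
    idx = {}
    verts = []
    for i in range(grid):
        for j in range(grid):
            idx[(i, j)] = len(verts)
            verts.append(i * e1 + j * e2)
    faces = []
    center_face = None
    ci = grid // 2
    for i in range(grid - 1):
        for j in range(grid - 1):
            up = (idx[(i, j)], idx[(i + 1, j)], idx[(i + 1, j + 1)])
            if (i, j) == (ci, ci):
                center_face = len(faces)
            faces.append(up)
            faces.append((idx[(i, j)], idx[(i + 1, j + 1)], idx[(i, j + 1)]))
    mesh = surface_mesh(np.array(verts), np.array(faces), allow_boundary=True)
    return mesh, center_face


_DEG = 4
_TERMS = np.array([(i, j) for i in range(_DEG + 1) for j in range(_DEG + 1 - i)])
_TI, _TJ = _TERMS[:, 0], _TERMS[:, 1]


def _monomials(v, w):
    """Quartic monomial rows [v^i w^j, i+j<=4] with 1st/2nd derivative rows."""
    v = np.atleast_1d(np.asarray(v, dtype=float))
    w = np.atleast_1d(np.asarray(w, dtype=float))
    pv = np.vander(v, _DEG + 3, increasing=True)   # columns v^0 .. v^6
    pw = np.vander(w, _DEG + 3, increasing=True)

    def at(di, dj):
        ci = np.where(_TI - di >= 0, _TI - di, 0)
        cj = np.where(_TJ - dj >= 0, _TJ - dj, 0)
        coef = np.ones(len(_TI))
        for k in range(di):
            coef = coef * np.maximum(_TI - k, 0)
        for k in range(dj):
            coef = coef * np.maximum(_TJ - k, 0)
        return coef * pv[:, ci] * pw[:, cj]

    return at(0, 0), at(1, 0), at(0, 1), at(2, 0), at(1, 1), at(0, 2)


@lru_cache(maxsize=1)
def _regular_coefficients() -> np.ndarray:
    """(12, 15) quartic coefficients of the regular-patch basis functions.

    Derived by subdividing a planar template three times with the Loop
    masks, reading off limit weights at the dyadic vertices inside the
    central face via the valence-6 limit stencil, and solving for the
    unique interpolating quartics.  The fit residual and the vanishing of
    all non-stencil weights are asserted to 1e-9.
    """
    mesh, cf = _planar_template()
    stencil = face_stencil(mesh, cf, 0)
    corners = mesh.vertices[mesh.faces[cf]]
    V0 = mesh.n_vertices
    W = np.eye(V0)
    for _ in range(3):
        mesh, Wk = loop_subdivide(mesh, return_weights=True, allow_boundary=True)
        W = Wk @ W
    # barycentric coordinates of refined vertices w.r.t. the central face
    E = np.stack([corners[1] - corners[0], corners[2] - corners[0]], axis=1)[:2, :]
    rel = (mesh.vertices - corners[0])[:, :2]
    vw = rel @ np.linalg.inv(E.T)
    inside = (vw[:, 0] > -1e-9) & (vw[:, 1] > -1e-9) & (vw.sum(1) < 1 + 1e-9)
    ids = np.flatnonzero(inside)
    # limit weights via the regular limit stencil (1/2 center, 1/12 ring)
    lw = loop_limit_weight(6)
    L = np.zeros((len(ids), V0))
    for k, vid in enumerate(ids):
        ring = mesh.ordered_ring(int(vid), _first_neighbor(mesh, int(vid)))
        L[k] = (1 - 6 * lw) * W[vid] + lw * W[ring].sum(axis=0)
    off = np.delete(L, stencil, axis=1)
    assert np.abs(off).max() < 1e-9, "basis support leaked outside the 12-stencil"
    M, *_ = _monomials(vw[ids, 0], vw[ids, 1])
    coef, res, *_ = np.linalg.lstsq(M, L[:, stencil], rcond=None)
    assert np.abs(M @ coef - L[:, stencil]).max() < 1e-9, "regular basis not quartic"
    return np.ascontiguousarray(coef.T)  # (12, 15)


def _first_neighbor(mesh, v):
    for (a, b) in mesh._third:
        if a == v:
            return b
    raise MeshStructureError(f"isolated vertex {v}")


def eval_regular_many(v, w) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized regular-patch evaluation.

    Returns ``(basis (P, 12), d_basis (P, 12, 2), dd_basis (P, 12, 3))``.
    """
    C = _regular_coefficients()
    M, Dv, Dw, Dvv, Dvw, Dww = _monomials(v, w)
    basis = M @ C.T
    d = np.stack([Dv @ C.T, Dw @ C.T], axis=2)
    dd = np.stack([Dvv @ C.T, Dvw @ C.T, Dww @ C.T], axis=2)
    return basis, d, dd


def eval_regular(v: float, w: float) -> PatchEvaluation:
    """Quartic box-spline basis on a regular patch at barycentric (v, w).

    The 12 weights follow the stencil ordering of
    :func:`loopshell.mesh.face_stencil`.
    """
    _check_simplex(v, w)
    b, d, dd = eval_regular_many([v], [w])
    return PatchEvaluation(b[0], d[0], dd[0])


# ---------------------------------------------------------------------------
# Irregular patch: per-valence subdivision matrices from a disk template.

def _disk_template(n: int, rings: int = 4):
    """Triangulated disk: center of valence n, interior vertices valence 6."""
    verts = [np.zeros(3)]
    ring_ids = [[0]]
    for r in range(1, rings + 1):
        ids = []
        for s in range(n):
            for t in range(r):
                ang = 2.0 * np.pi * (s + t / r) / n
                ids.append(len(verts))
                verts.append(np.array([r * np.cos(ang), r * np.sin(ang), 0.0]))
        ring_ids.append(ids)
    faces = []
    inner = ring_ids[1]
    for s in range(n):
        faces.append((0, inner[s], inner[(s + 1) % n]))
    for r in range(1, rings):
        I, O = ring_ids[r], ring_ids[r + 1]
        for s in range(n):
            Iv = [I[(s * r + t) % (n * r)] for t in range(r)] + [I[((s + 1) * r) % (n * r)]]
            Ov = [O[(s * (r + 1) + t) % (n * (r + 1))] for t in range(r + 1)] \
                + [O[((s + 1) * (r + 1)) % (n * (r + 1))]]
            for t in range(r + 1):
                faces.append((Ov[t], Ov[t + 1], Iv[t]))
            for t in range(r):
                faces.append((Iv[t], Ov[t + 1], Iv[t + 1]))
    mesh = surface_mesh(np.array(verts), np.array(faces), allow_boundary=True)
    return mesh, 0  # face 0 is (center, ring1[0], ring1[1])


class _IrregularPatch:
    """Per-valence evaluation operator for patches with one extraordinary
    vertex, built once from a single subdivision of a disk template.

    ``A`` maps patch control weights to the sub-patch at the extraordinary
    corner; ``B[j]`` (j = 1, 2, 3) extract the 12-point regular stencils of
    the remaining three sub-faces.  Powers of ``A`` are applied through its
    eigendecomposition (validated at build time; a cached-power fallback
    guards against ill-conditioned eigenbases).
    """

    def __init__(self, n: int):
        if not (MIN_VALENCE <= n <= MAX_VALENCE):
            raise ValueError(f"valence {n} outside supported range "
                             f"[{MIN_VALENCE}, {MAX_VALENCE}]")
        self.valence = n
        mesh, f0 = _disk_template(n)
        S0 = face_stencil(mesh, f0, 0)
        fine, W = loop_subdivide(mesh, return_weights=True, allow_boundary=True)
        children = [4 * f0 + k for k in range(4)]
        S1 = [face_stencil(fine, c, 0) for c in children]
        for S in S1:
            off = np.delete(W[S], S0, axis=1)
            assert np.abs(off).max() < 1e-14, "sub-patch stencil escaped the patch"
        self.A = np.ascontiguousarray(W[np.asarray(S1[0])][:, S0])
        self.B = [np.ascontiguousarray(W[np.asarray(S)][:, S0]) for S in S1[1:]]
        # limit weights at the extraordinary vertex
        lw = loop_limit_weight(n)
        lim = np.zeros(n + 6)
        lim[0] = 1.0 - n * lw
        lim[1:n + 1] = lw
        self.vertex_limit = lim
        # eigendecomposition of A for fast powers
        evals, V = np.linalg.eig(self.A)
        ok = (np.linalg.cond(V) < 1e8)
        if ok:
            Vi = np.linalg.inv(V)
            ok = np.abs((V * evals) @ Vi - self.A).max() < 1e-10
        if ok:
            self._eig = (evals, V, Vi)
        else:  # pragma: no cover - all valences 3..12 are well conditioned
            self._eig = None
        self._powers = {0: np.eye(n + 6), 1: self.A}
        self._BAk = {}      # (j, k) -> B_j @ A^k, the per-depth operators

    def _A_power(self, k: int) -> np.ndarray:
        if k in self._powers:
            return self._powers[k]
        if self._eig is not None:
            evals, V, Vi = self._eig
            out = np.real((V * evals ** k) @ Vi)
        else:  # pragma: no cover
            out = self.A @ self._A_power(k - 1)
        self._powers[k] = out
        return out

    def _operator(self, j: int, k: int) -> np.ndarray:
        key = (j, k)
        if key not in self._BAk:
            self._BAk[key] = np.ascontiguousarray(self.B[j] @ self._A_power(k))
        return self._BAk[key]

    def __call__(self, v: float, w: float) -> PatchEvaluation:
        _check_simplex(v, w)
        if v + w < _EPS_VERTEX:
            # Eigen-limit at the extraordinary vertex itself.  Derivatives
            # are not defined there in general; quadrature points and
            # particle evaluations avoid the vertex by construction, so a
            # nudged evaluation is returned for the derivative slots.
            near = self.__call__(1e-9, 1e-9)
            return PatchEvaluation(self.vertex_limit, near.d_basis, near.dd_basis)
        k = 0
        u = 1.0 - v - w
        while u > 0.5 and k < _MAX_SUBDIV:
            v, w = 2.0 * v, 2.0 * w
            u = 2.0 * u - 1.0
            k += 1
        # select the regular sub-face and its affine chart
        if v > 0.5:
            j, cv, cw, G = 0, 2 * v - 1, 2 * w, np.array([[2.0, 0.0], [0.0, 2.0]])
        elif w > 0.5:
            j, cv, cw, G = 1, 2 * v, 2 * w - 1, np.array([[2.0, 0.0], [0.0, 2.0]])
        else:
            j, cv, cw, G = 2, 2 * v + 2 * w - 1, 1 - 2 * v, \
                np.array([[2.0, 2.0], [-2.0, 0.0]])
        Gtot = G * (2.0 ** k)
        M = self._operator(j, k)              # (12, n+6)
        bC, dC, ddC = eval_regular_many([cv], [cw])
        basis = M.T @ bC[0]
        d = (M.T @ dC[0]) @ Gtot               # rows: controls, cols: (v, w)
        H = np.empty((len(basis), 3))
        for i, h in enumerate(M.T @ ddC[0]):
            Hc = np.array([[h[0], h[1]], [h[1], h[2]]])
            Hp = Gtot.T @ Hc @ Gtot
            H[i] = (Hp[0, 0], Hp[0, 1], Hp[1, 1])
        return PatchEvaluation(basis, d, H)


@lru_cache(maxsize=16)
def _irregular_patch(n: int) -> _IrregularPatch:
    return _IrregularPatch(n)


def eval_irregular(valence: int, v: float, w: float) -> PatchEvaluation:
    """Basis over the (valence+6)-point irregular stencil at (v, w).

    The extraordinary vertex sits at ``(v, w) = (0, 0)``; stencil ordering
    follows :func:`loopshell.mesh.face_stencil` with the extraordinary
    vertex first.  Valence six reproduces :func:`eval_regular` exactly.
    """
    return _irregular_patch(int(valence))(v, w)


def eval_irregular_many(valence: int, pts) -> list[PatchEvaluation]:
    patch = _irregular_patch(int(valence))
    return [patch(v, w) for v, w in pts]


# ---------------------------------------------------------------------------
# Slow reference oracle: explicit repeated subdivision of the template mesh.

def subdivision_oracle(valence: int, v: float, w: float,
                       levels: int = 2) -> np.ndarray:
    """Basis weights by explicit mesh refinement (test oracle).

    The valence-``valence`` disk template is Loop-subdivided ``levels``
    times while tracking the dense weight matrix; the target point is
    tracked through the nested parameter triangles, and the regular basis
    is evaluated on the leaf face.  Independent of the cached subdivision
    matrices used by :func:`eval_irregular`.  Raises if the leaf face is
    still irregular (increase ``levels``).
    """
    mesh, face = _disk_template(valence)
    S0 = face_stencil(mesh, face, 0)
    W = np.eye(mesh.n_vertices)
    u = 1.0 - v - w
    bary = np.array([u, v, w])
    child_corners = np.array([
        [[1, 0, 0], [.5, .5, 0], [.5, 0, .5]],
        [[.5, .5, 0], [0, 1, 0], [0, .5, .5]],
        [[.5, 0, .5], [0, .5, .5], [0, 0, 1]],
        [[.5, .5, 0], [0, .5, .5], [.5, 0, .5]],
    ])
    for _ in range(levels):
        mesh, Wk = loop_subdivide(mesh, return_weights=True, allow_boundary=True)
        W = Wk @ W
        for j in range(4):
            alpha = np.linalg.solve(child_corners[j].T, bary)
            if alpha.min() > -1e-12:
                bary = alpha
                face = 4 * face + j
                break
        else:  # pragma: no cover
            raise RuntimeError("point not found in any sub-face")
    f = mesh.faces[face]
    if np.any(mesh.valence[f] != 6):
        raise ValueError(f"leaf face still irregular after {levels} subdivisions")
    S = face_stencil(mesh, face, 0)
    b, _, _ = eval_regular_many([bary[1]], [bary[2]])
    return b[0] @ W[np.asarray(S)][:, S0]
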