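"""Particles moving on the membrane via referential coordinates.

Each particle carries global spherical coordinates ``(theta, phi)`` on
the *reference* sphere as its degrees of freedom.  Its physical position
is the limit-surface evaluation of the deformation at those reference
coordinates, ``x_i = f(X_i)``: no constraint is needed to keep particles
on the surface.  A variation of the reference coordinates is pushed
forward to the deformed surface by the tangents ``a_alpha = f,alpha``,
which yields the particle block of the energy gradient; a variation of
the nodal positions reaches the particle through the basis weights at
its (fixed) local coordinates.

Particles near a coordinate pole (|cos theta| > 0.99) are differentiated
in a per-particle rotated spherical chart to avoid the azimuth
degeneracy; the stored state convention remains global (theta, phi).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .basis import eval_irregular, eval_regular, eval_regular_many
from .locator import HashGrid, locate
from .mesh import SurfaceMesh

__all__ = ["PairPotential", "ParticleSet", "potential_value_and_slope",
           "interaction_energy", "pair_forces", "interaction_gradient",
           "ParticleFrame", "evaluate_particles", "sample_uniform_sphere",
           "POLE_COS_LIMIT", "MIN_PAIR_DISTANCE"]

POLE_COS_LIMIT = 0.99
MIN_PAIR_DISTANCE = 1e-9


@dataclass(frozen=True)
class PairPotential:
    """Isotropic pair potential Phi(r) of the 3D Euclidean distance.

    kinds:
      ``coulomb``        Phi = 1/r                      (Thomson validation)
      ``lennard_jones``  Phi = eps[(re/r)^12 - 2 (re/r)^6]  (minimum -eps at re)
      ``harmonic``       Phi = k (r - re)^2 / 2
    """

    kind: str
    epsilon: float = 1.0
    re: float = 1.0
    spring: float = 1.0

    def __post_init__(self):
        if self.kind not in ("coulomb", "lennard_jones", "harmonic"):
            raise ValueError(f"unknown potential kind {self.kind!r}")

    def with_(self, **kw) -> "PairPotential":
        return replace(self, **kw)


def potential_value_and_slope(pot: PairPotential, r):
    """Analytic (Phi(r), Phi'(r)); rejects r <= 0 (coincident particles)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("coincident particles: pair distance must be positive")
    if pot.kind == "coulomb":
        return 1.0 / r, -1.0 / r ** 2
    if pot.kind == "lennard_jones":
        s6 = (pot.re / r) ** 6
        val = pot.epsilon * (s6 * s6 - 2.0 * s6)
        slope = 12.0 * pot.epsilon * (s6 - s6 * s6) / r
        return val, slope
    # harmonic
    return 0.5 * pot.spring * (r - pot.re) ** 2, pot.spring * (r - pot.re)


def _pair_distances(positions):
    x = np.asarray(positions, float)
    diff = x[:, None, :] - x[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(len(x), k=1)
    return diff, r, iu


def interaction_energy(positions, pot: PairPotential) -> float:
    """U = sum over unordered pairs of Phi(|x_i - x_j|)."""
    _, r, iu = _pair_distances(positions)
    if len(iu[0]) == 0:
        return 0.0
    val, _ = potential_value_and_slope(pot, r[iu])
    return float(val.sum())


def pair_forces(positions, pot: PairPotential):
    """Interaction energy and per-particle Euclidean gradient dU/dx_i.

    dU/dx_i = sum_{j != i} Phi'(r_ij) (x_i - x_j)/r_ij.
    """
    diff, r, iu = _pair_distances(positions)
    n = len(positions)
    if len(iu[0]) == 0:
        return 0.0, np.zeros((n, 3))
    vals, slopes = potential_value_and_slope(pot, r[iu])
    G = np.zeros((n, 3))
    unit = diff[iu] / r[iu][:, None]
    gij = slopes[:, None] * unit
    np.add.at(G, iu[0], gij)
    np.add.at(G, iu[1], -gij)
    return float(vals.sum()), G


def sample_uniform_sphere(n, rng, hemisphere=False, min_dist=MIN_PAIR_DISTANCE):
    """Area-uniform (theta, phi) samples, rejecting near-coincident pairs.

    ``hemisphere`` restricts to the upper half sphere (z > 0), used by the
    substrate-enveloping study's initial state.
    """
    out = []
    while len(out) < n:
        z = rng.uniform(0.0 if hemisphere else -1.0, 1.0)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        th = np.arccos(z)
        p = np.array([np.sin(th) * np.cos(phi), np.sin(th) * np.sin(phi), z])
        if all(np.linalg.norm(p - q) > min_dist for _, q in out):
            out.append(((th, phi), p))
    return np.array([a for a, _ in out])


def angles_to_unit(angles):
    th, ph = np.asarray(angles, float).T
    return np.stack([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                     np.cos(th)], axis=1)


def unit_to_angles(vecs):
    v = np.asarray(vecs, float)
    th = np.arccos(np.clip(v[:, 2], -1.0, 1.0))
    ph = np.mod(np.arctan2(v[:, 1], v[:, 0]), 2.0 * np.pi)
    return np.stack([th, ph], axis=1)


@dataclass
class ParticleSet:
    """Particle reference coordinates plus cached locator/surface data.

    ``angles`` are global (theta in (0, pi), phi in [0, 2 pi)); the caches
    (element id, barycentric coordinates, 3D positions) are refreshed by
    :func:`evaluate_particles` at every energy/gradient evaluation, so
    element hopping needs no event detection.
    """

    angles: np.ndarray                     # (N, 2)
    element_id: np.ndarray | None = None   # (N,)
    barycentric: np.ndarray | None = None  # (N, 3) in stored face order
    positions: np.ndarray | None = None    # (N, 3)

    def __post_init__(self):
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        if self.angles.shape[1] != 2:
            raise ValueError("angles must be (N, 2) = (theta, phi)")
        self.normalize()
        u = angles_to_unit(self.angles)
        d = np.linalg.norm(u[:, None] - u[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if len(u) > 1 and d.min() < MIN_PAIR_DISTANCE:
            raise ValueError("two particles share identical reference coordinates")

    def __len__(self):
        return len(self.angles)

    def normalize(self):
        """Fold angles into theta in [0, pi], phi in [0, 2 pi).

        Angles already in the canonical ranges are left untouched, so
        normalization is idempotent and serialization round-trips are
        bit-faithful.
        """
        th, ph = self.angles[:, 0], self.angles[:, 1]
        if ((th >= 0) & (th <= np.pi) & (ph >= 0) & (ph < 2 * np.pi)).all():
            return
        self.angles = unit_to_angles(angles_to_unit(self.angles))

    @classmethod
    def random(cls, n, seed=None, rng=None, hemisphere=False) -> "ParticleSet":
        rng = rng if rng is not None else np.random.default_rng(seed)
        return cls(sample_uniform_sphere(n, rng, hemisphere=hemisphere))

    def to_csv(self, path):
        """index, theta, phi, element, u, v, w, x, y, z (restartable)."""
        cols = [np.arange(len(self)), self.angles[:, 0], self.angles[:, 1]]
        header = "index,theta,phi"
        if self.element_id is not None:
            cols += [self.element_id] + list(self.barycentric.T) \
                + list(self.positions.T)
            header += ",element,u,v,w,x,y,z"
        arr = np.column_stack(cols)
        np.savetxt(path, arr, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path) -> "ParticleSet":
        arr = np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1))
        return cls(arr[:, 1:3])


@dataclass(frozen=True)
class ParticleFrame:
    """Everything needed to couple one particle into the energy gradient."""

    element: int
    stencil: np.ndarray        # control-point ids of the patch
    basis: np.ndarray          # weights at the particle's local coordinates
    a: np.ndarray              # (2, 3) surface tangents in the patch chart
    position: np.ndarray       # (3,) x_i = f(X_i)
    dvw_dangles: np.ndarray    # (2, 2) d(patch v, w)/d(chart theta, phi)


def _patch_eval(mesh, face, bary):
    """Patch chart (v, w) and basis at a face-local barycentric point."""
    rot = int(mesh.patch_rotation[face])
    if rot < 0:
        raise ValueError(f"face {face} has no single-corner patch (subdivide mesh)")
    b = np.asarray(bary, float)
    v, w = b[(rot + 1) % 3], b[(rot + 2) % 3]
    v = min(max(v, 0.0), 1.0)
    w = min(max(w, 0.0), 1.0 - v)
    if mesh.patch_regular[face]:
        ev = eval_regular(v, w)
    else:
        n = int(mesh.valence[mesh.faces[face][rot]])
        ev = eval_irregular(n, v, w)
    return rot, ev


def _locate_batch(grid, mesh, svecs):
    """Vectorized hash-grid location of many unit vectors at once."""
    from .locator import BARY_TOL, locate

    N = len(svecs)
    T = grid._tri
    boxes = np.floor((svecs - grid.offset) * grid.scale).astype(int)
    boxes = np.clip(boxes, 0, np.asarray(grid.dims) - 1)
    cand, owner = [], []
    misses = []
    for i in range(N):
        lst = grid.table.get(tuple(boxes[i]))
        if lst is None:
            misses.append(i)
            continue
        cand.append(lst)
        owner.append(np.full(len(lst), i))
    faces = np.full(N, -1, dtype=np.int64)
    bary = np.zeros((N, 3))
    if cand:
        ids = np.concatenate(cand)
        own = np.concatenate(owner)
        s = svecs[own]
        denom = np.einsum("fk,fk->f", T["n"][ids], s)
        ok = np.abs(denom) > 1e-14
        t = np.where(ok, T["c"][ids] / np.where(ok, denom, 1.0), -1.0)
        rel = t[:, None] * s - T["p0"][ids]
        r1 = np.einsum("fk,fk->f", T["e1"][ids], rel)
        r2 = np.einsum("fk,fk->f", T["e2"][ids], rel)
        v = (T["g22"][ids] * r1 - T["g12"][ids] * r2) / T["det"][ids]
        w = (T["g11"][ids] * r2 - T["g12"][ids] * r1) / T["det"][ids]
        u = 1.0 - v - w
        inside = ok & (t > 0) & (u >= -BARY_TOL) & (v >= -BARY_TOL) \
            & (w >= -BARY_TOL) & (u <= 1 + BARY_TOL) & (v <= 1 + BARY_TOL) \
            & (w <= 1 + BARY_TOL)
        hit = np.flatnonzero(inside)
        # smallest face index per particle among hits
        order = np.lexsort((ids[hit], own[hit]))
        hit = hit[order]
        first = np.unique(own[hit], return_index=True)[1]
        for k in hit[first]:
            i = own[k]
            faces[i] = ids[k]
            bary[i] = (u[k], v[k], w[k])
    for i in np.flatnonzero(faces < 0):
        faces[i], bary[i] = locate(grid, mesh, svecs[i])
    return faces, bary


def evaluate_particles(mesh: SurfaceMesh, grid: HashGrid, X, svecs,
                       charts=None) -> list[ParticleFrame]:
    """Locate every particle and build its coupling frame.

    ``svecs`` are unit reference vectors (one per particle); ``charts``
    optionally gives per-particle rotation matrices R so that the
    differentiation chart is ``s = R sph(theta', phi')`` (pole avoidance).
    The chain d(v, w)/d(theta, phi) runs through the central-ray/flat-
    triangle intersection of the locator, keeping the locator and the
    evaluation charts exactly consistent.
    """
    svecs = np.atleast_2d(np.asarray(svecs, float))
    svecs = svecs / np.linalg.norm(svecs, axis=1, keepdims=True)
    N = len(svecs)
    faces, bary = _locate_batch(grid, mesh, svecs)
    rots = mesh.patch_rotation[faces]
    if np.any(rots < 0):
        bad = int(faces[np.argmax(rots < 0)])
        raise ValueError(f"face {bad} has no single-corner patch (subdivide mesh)")
    ar = np.arange(N)
    v = np.clip(bary[ar, (rots + 1) % 3], 0.0, 1.0)
    w = np.clip(bary[ar, (rots + 2) % 3], 0.0, 1.0)
    w = np.minimum(w, 1.0 - v)
    regular = np.asarray(mesh.patch_regular)[faces]
    basis_list = [None] * N
    dbasis_list = [None] * N
    ii = np.flatnonzero(regular)
    if len(ii):
        B, D, _ = eval_regular_many(v[ii], w[ii])
        for k, i in enumerate(ii):
            basis_list[i], dbasis_list[i] = B[k], D[k]
    for i in np.flatnonzero(~regular):
        n = int(mesh.valence[mesh.faces[faces[i]][rots[i]]])
        ev = eval_irregular(n, v[i], w[i])
        basis_list[i], dbasis_list[i] = ev.basis, ev.d_basis
    # --- chain: (theta, phi) -> s -> plane point -> barycentric ----------
    T = grid._tri
    nT = T["n"][faces]
    c = T["c"][faces]
    ns = np.einsum("nk,nk->n", nT, svecs)
    dp_ds = (c / ns)[:, None, None] * (np.eye(3)[None]
                                       - svecs[:, :, None] * nT[:, None, :]
                                       / ns[:, None, None])
    e1, e2 = T["e1"][faces], T["e2"][faces]
    g11, g12, g22 = T["g11"][faces], T["g12"][faces], T["g22"][faces]
    det = T["det"][faces]
    row1 = (g22[:, None] * e1 - g12[:, None] * e2) / det[:, None]  # d b1 / dp
    row2 = (g11[:, None] * e2 - g12[:, None] * e1) / det[:, None]  # d b2 / dp
    db_dp = np.stack([-(row1 + row2), row1, row2], axis=1)         # (N, 3, 3)
    dvw_dp = db_dp[ar[:, None], np.stack([(rots + 1) % 3, (rots + 2) % 3], 1)]
    if charts is not None:
        loc = np.einsum("nij,ni->nj", charts, svecs)   # R^T s
    else:
        loc = svecs
    th = np.arccos(np.clip(loc[:, 2], -1, 1))
    ph = np.arctan2(loc[:, 1], loc[:, 0])
    st_, ct = np.sin(th), np.cos(th)
    sp, cp = np.sin(ph), np.cos(ph)
    dloc = np.stack([np.stack([ct * cp, -st_ * sp], 1),
                     np.stack([ct * sp, st_ * cp], 1),
                     np.stack([-st_, np.zeros(N)], 1)], axis=1)    # (N, 3, 2)
    if charts is not None:
        dloc = np.einsum("nij,njk->nik", charts, dloc)
    dvw_dang = np.einsum("nab,nbc,nck->nak", dvw_dp, dp_ds, dloc)
    frames = []
    for i in range(N):
        st = np.asarray(mesh.patch_stencil[faces[i]])
        C = X[st]
        frames.append(ParticleFrame(
            element=int(faces[i]), stencil=st, basis=basis_list[i],
            a=dbasis_list[i].T @ C, position=basis_list[i] @ C,
            dvw_dangles=dvw_dang[i]))
    return frames


def interaction_gradient(frames: list[ParticleFrame], n_vertices: int,
                         pot: PairPotential):
    """(U, nodal gradient (V, 3), particle gradient (N, 2)).

    The nodal part distributes each particle's Euclidean force through
    the basis weights of its patch; the particle part projects the force
    on the surface tangents and chains into the differentiation chart.
    """
    positions = np.array([f.position for f in frames])
    U, G = pair_forces(positions, pot)
    grad_X = np.zeros((n_vertices, 3))
    grad_ang = np.zeros((len(frames), 2))
    for i, fr in enumerate(frames):
        np.add.at(grad_X, fr.stencil, np.outer(fr.basis, G[i]))
        grad_ang[i] = (fr.a @ G[i]) @ fr.dvw_dangles
    return U, grad_X, grad_ang
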