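"""Spatial-hash point location on the reference mesh.

Particle degrees of freedom are global spherical coordinates on the
reference sphere; evaluating the shell basis at a particle requires the
element containing it and the local barycentric coordinates.  The search
runs entirely on the *reference* mesh: the axis-aligned box lattice and
the box -> face-list hash table are built once per discretization and
never touched again, no matter how the deformed shape or the particles
evolve.

Construction: the mesh is scaled (per axis) so its bounding box spans
``MX x MY x MZ`` unit boxes indexed by their minimum-corner integer
coordinates; every face is entered into each box overlapped by the
floor/ceil bounds of its vertices; the table is then inverted to map
boxes to face lists, empty boxes omitted.  Query: the box containing a
particle's reference point gives a candidate face list which is scanned
with a ray-triangle intersection test along the central ray from the
origin; candidates the ray misses report barycentric coordinates outside
[0, 1] and are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import SurfaceMesh

__all__ = ["HashGrid", "build_hash_grid", "ray_triangle", "locate",
           "brute_force_locate", "grid_statistics", "LocatorError"]

BARY_TOL = 1e-10   # containment tolerance on barycentric coordinates


class LocatorError(RuntimeError):
    """No element found for a query point (inconsistent grid/mesh)."""


@dataclass(frozen=True)
class HashGrid:
    """Box -> face-list table over the scaled reference mesh."""

    dims: tuple          # (MX, MY, MZ)
    scale: np.ndarray    # per-axis factors mapping mesh coords to box coords
    offset: np.ndarray   # bounding-box minimum (subtracted before scaling)
    table: dict          # (p, q, r) -> int array of face indices (sorted)
    n_faces: int
    _tri: dict = None    # cached per-face ray-test arrays (vectorized scan)

    build_count = [0]    # class-level instrumentation: grids built per process

    def box_of(self, point: np.ndarray) -> tuple:
        """Integer box index of a point, clamped onto the lattice."""
        ijk = np.floor((np.asarray(point) - self.offset) * self.scale).astype(int)
        ijk = np.clip(ijk, 0, np.asarray(self.dims) - 1)
        return tuple(int(x) for x in ijk)

    def statistics(self) -> dict:
        sizes = np.array([len(v) for v in self.table.values()])
        return dict(entries=len(self.table), min_faces=int(sizes.min()),
                    mean_faces=float(sizes.mean()), max_faces=int(sizes.max()))


def build_hash_grid(mesh: SurfaceMesh, MX: int, MY: int, MZ: int) -> HashGrid:
    """Construct the box -> face hash table (one-time, reference mesh only).

    Scaling spans the mesh bounding box across the ``MX x MY x MZ`` box
    lattice; the stored factors are reused by :func:`locate`.  A face is
    associated with every box between the floor of its minimum and the
    ceil of its maximum vertex coordinate on each axis (boxes indexed by
    their minimum corner, so index ``p`` covers ``[p, p+1)``); boxes that
    intersect no face do not appear in the table.
    """
    if min(MX, MY, MZ) < 1:
        raise ValueError("box counts must be positive")
    dims = np.array([MX, MY, MZ], dtype=int)
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    scale = dims / (hi - lo)
    V = (mesh.vertices - lo) * scale          # box coordinates in [0, M]
    tri = V[mesh.faces]                       # (F, 3, 3)
    fmin = np.floor(tri.min(axis=1)).astype(int)
    fmax = np.ceil(tri.max(axis=1)).astype(int) - 1
    fmin = np.clip(fmin, 0, dims - 1)
    fmax = np.clip(np.maximum(fmax, fmin), 0, dims - 1)
    boxes: dict[tuple, list] = {}
    for f in range(len(tri)):
        x0, y0, z0 = fmin[f]
        x1, y1, z1 = fmax[f]
        for p in range(x0, x1 + 1):
            for q in range(y0, y1 + 1):
                for r in range(z0, z1 + 1):
                    boxes.setdefault((p, q, r), []).append(f)
    table = {k: np.array(v, dtype=np.int64) for k, v in boxes.items()}
    HashGrid.build_count[0] += 1
    return HashGrid(dims=(MX, MY, MZ), scale=scale, offset=lo, table=table,
                    n_faces=mesh.n_faces, _tri=_triangle_arrays(mesh))


def _triangle_arrays(mesh):
    """Per-face quantities for the vectorized central-ray test."""
    tri = mesh.vertices[mesh.faces]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    n = np.cross(e1, e2)
    g11 = np.einsum("fk,fk->f", e1, e1)
    g12 = np.einsum("fk,fk->f", e1, e2)
    g22 = np.einsum("fk,fk->f", e2, e2)
    return dict(p0=np.ascontiguousarray(tri[:, 0]), e1=e1, e2=e2, n=n,
                c=np.einsum("fk,fk->f", n, tri[:, 0]),
                g11=g11, g12=g12, g22=g22, det=g11 * g22 - g12 * g12)


def grid_statistics(grid: HashGrid) -> str:
    """Human-readable one-line summary of the table (regression aid)."""
    s = grid.statistics()
    return ("entries=%d min=%d mean=%.2f max=%d"
            % (s["entries"], s["min_faces"], s["mean_faces"], s["max_faces"]))


def ray_triangle(origin, direction, triangle):
    """Barycentric intersection of a ray with a triangle's plane.

    Returns ``((u, v, w), hit)``: the barycentric coordinates of the
    ray/plane intersection w.r.t. the triangle's three vertices and a hit
    flag that is true when the crossing lies inside the triangle (within
    tolerance ``BARY_TOL``) at a positive ray parameter.  A ray parallel
    to the plane is a miss.
    """
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    A, B, C = np.asarray(triangle, float)
    e1, e2 = B - A, C - A
    n = np.cross(e1, e2)
    denom = float(n @ direction)
    scale = np.linalg.norm(n) * np.linalg.norm(direction)
    if abs(denom) < 1e-14 * max(scale, 1e-300):
        return (np.array([np.nan] * 3), False)
    t = float(n @ (A - origin)) / denom
    p = origin + t * direction
    # barycentric via the edge Gram system
    g11, g12, g22 = e1 @ e1, e1 @ e2, e2 @ e2
    r1, r2 = e1 @ (p - A), e2 @ (p - A)
    det = g11 * g22 - g12 * g12
    v = (g22 * r1 - g12 * r2) / det
    w = (g11 * r2 - g12 * r1) / det
    bary = np.array([1.0 - v - w, v, w])
    hit = bool(t > 0 and bary.min() >= -BARY_TOL and bary.max() <= 1.0 + BARY_TOL)
    return bary, hit


def _scan(mesh, candidates, direction, grid=None):
    """Ray-test candidate faces from the origin; smallest hit index wins."""
    ids = np.fromiter((int(x) for x in candidates), dtype=np.int64)
    if len(ids) == 0:
        return None
    if grid is not None and grid._tri is not None:
        T = grid._tri
        s = direction
        denom = T["n"][ids] @ s
        ok = np.abs(denom) > 1e-14
        t = np.where(ok, T["c"][ids] / np.where(ok, denom, 1.0), -1.0)
        p = t[:, None] * s[None, :]
        rel = p - T["p0"][ids]
        r1 = np.einsum("fk,fk->f", T["e1"][ids], rel)
        r2 = np.einsum("fk,fk->f", T["e2"][ids], rel)
        v = (T["g22"][ids] * r1 - T["g12"][ids] * r2) / T["det"][ids]
        w = (T["g11"][ids] * r2 - T["g12"][ids] * r1) / T["det"][ids]
        u = 1.0 - v - w
        inside = ok & (t > 0) & (u >= -BARY_TOL) & (v >= -BARY_TOL) \
            & (w >= -BARY_TOL) & (u <= 1 + BARY_TOL) & (v <= 1 + BARY_TOL) \
            & (w <= 1 + BARY_TOL)
        hits = np.flatnonzero(inside)
        if len(hits) == 0:
            return None
        k = hits[np.argmin(ids[hits])]
        return int(ids[k]), np.array([u[k], v[k], w[k]])
    best = None
    for f in sorted(ids.tolist()):
        bary, hit = ray_triangle(np.zeros(3), direction, mesh.vertices[mesh.faces[f]])
        if hit:
            best = (f, bary)
            break
    return best


def locate(grid: HashGrid, mesh: SurfaceMesh, point) -> tuple[int, np.ndarray]:
    """Element id and barycentric coordinates of a reference point.

    ``point`` is either a 3-vector (direction from the mesh center) or a
    ``(theta, phi)`` pair of spherical coordinates.  The point is located
    on the *flat* reference triangle hit by the central ray; those
    barycentric coordinates then serve directly as the element's local
    coordinates for limit-surface evaluation.  On a shared edge or vertex
    the lowest-index incident element is returned.  If the point's box is
    absent or yields no hit, neighboring boxes and finally a brute-force
    scan are tried before failing.
    """
    point = np.asarray(point, dtype=float)
    if point.shape == (2,):
        th, ph = point
        point = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                          np.cos(th)])
    s = point / np.linalg.norm(point)
    box = grid.box_of(s)
    hit = _scan(mesh, grid.table.get(box, ()), s, grid)
    if hit is None:
        neigh = set()
        for dp in (-1, 0, 1):
            for dq in (-1, 0, 1):
                for dr in (-1, 0, 1):
                    b = (box[0] + dp, box[1] + dq, box[2] + dr)
                    neigh.update(grid.table.get(b, ()))
        hit = _scan(mesh, neigh, s, grid)
    if hit is None:   # inconsistent grid/mesh; last resort, logged
        import logging
        logging.getLogger(__name__).warning(
            "hash-grid lookup missed; falling back to brute force")
        hit = _scan(mesh, range(mesh.n_faces), s, grid)
    if hit is None:
        raise LocatorError("central ray hits no element: mesh is not "
                           "watertight around the origin")
    return hit


def brute_force_locate(mesh: SurfaceMesh, point) -> tuple[int, np.ndarray]:
    """Reference implementation: scan all faces (vectorized), same tie-break."""
    point = np.asarray(point, dtype=float)
    if point.shape == (2,):
        th, ph = point
        point = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                          np.cos(th)])
    s = point / np.linalg.norm(point)
    tri = mesh.vertices[mesh.faces]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    n = np.cross(e1, e2)
    denom = n @ s
    ok = np.abs(denom) > 1e-14
    t = np.where(ok, np.einsum("fk,fk->f", n, tri[:, 0]) / np.where(ok, denom, 1.0),
                 -1.0)
    p = t[:, None] * s[None, :]
    g11 = np.einsum("fk,fk->f", e1, e1)
    g12 = np.einsum("fk,fk->f", e1, e2)
    g22 = np.einsum("fk,fk->f", e2, e2)
    r1 = np.einsum("fk,fk->f", e1, p - tri[:, 0])
    r2 = np.einsum("fk,fk->f", e2, p - tri[:, 0])
    det = g11 * g22 - g12 * g12
    v = (g22 * r1 - g12 * r2) / det
    w = (g11 * r2 - g12 * r1) / det
    u = 1.0 - v - w
    inside = ok & (t > 0) & (u >= -BARY_TOL) & (v >= -BARY_TOL) & (w >= -BARY_TOL) \
        & (u <= 1 + BARY_TOL) & (v <= 1 + BARY_TOL) & (w <= 1 + BARY_TOL)
    ids = np.flatnonzero(inside)
    if not len(ids):
        raise LocatorError("central ray hits no element")
    f = int(ids.min())
    return f, np.array([u[f], v[f], w[f]])
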