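"""Topologically spherical triangle meshes for subdivision shell elements.

The reference configuration of the membrane is the unit sphere, discretized
by an icosahedrally symmetric triangulation obtained by Loop-refining an
icosahedron and projecting the vertices back onto the sphere.  Any closed
orientable triangulation can also be loaded from OBJ/OFF.  The mesh is
immutable after construction: the deformation is carried separately as a
nodal position array (see :mod:`loopshell.solver`).

Every face is annotated with its one-ring control stencil, the set of
vertices whose quartic box-spline basis functions are supported on that
face.  A face is *regular* when all three corners have valence six
(stencil of 12 points); otherwise it is *irregular* and the stencil has
``valence + 6`` points with the extraordinary vertex anchored first.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SurfaceMesh",
    "MeshStructureError",
    "make_icosphere",
    "make_icosahedron",
    "loop_subdivide",
    "build_patches",
    "loop_beta",
    "loop_limit_weight",
    "read_mesh",
    "write_mesh",
    "write_vtk",
]


class MeshStructureError(ValueError):
    """Raised when a mesh is not a closed orientable triangulated 2-manifold."""


def loop_beta(n: int) -> float:
    """Loop's valence-dependent vertex-mask weight beta(n).

    beta(n) = (1/n) * (5/8 - (3/8 + cos(2 pi / n)/4)**2); beta(6) = 1/16.
    """
    c = 3.0 / 8.0 + np.cos(2.0 * np.pi / n) / 4.0
    return (5.0 / 8.0 - c * c) / n


def loop_limit_weight(n: int) -> float:
    """Ring weight of the Loop limit-position stencil at a valence-n vertex.

    The limit position is ``(1 - n*l) v + l * sum(ring)`` with
    ``l = 1 / (3/(8 beta(n)) + n)``; for n = 6 this is the familiar
    1/2, 1/12,...,1/12 stencil.
    """
    return 1.0 / (3.0 / (8.0 * loop_beta(n)) + n)


@dataclass(frozen=True)
class SurfaceMesh:
    """Closed orientable triangulation with subdivision-shell connectivity.

    Attributes
    ----------
    vertices : (V, 3) float array
        Reference positions.  For icospheres these lie on the unit sphere.
    faces : (F, 3) int array
        Counter-clockwise corner indices viewed from outside (outward
        normal ``a1 x a2``), enforced at construction via positive
        enclosed volume.
    valence : (V,) int array
    patches : populated by :func:`build_patches`; per face the ordered
        control stencil, the corner rotation placing the extraordinary
        vertex first, and the regular/irregular flag.
    """

    vertices: np.ndarray
    faces: np.ndarray
    valence: np.ndarray = field(repr=False)
    # directed edge (a, b) -> third vertex x of the face cycled as (a, b, x)
    _third: dict = field(repr=False)
    _edge_face: dict = field(repr=False)
    # patch annotation (filled in by build_patches)
    patch_stencil: list | None = field(default=None, repr=False)
    patch_rotation: np.ndarray | None = field(default=None, repr=False)
    patch_regular: np.ndarray | None = field(default=None, repr=False)
    boundary_ok: bool = field(default=False, repr=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_edges(self) -> int:
        return len(self._edge_face) // (1 if self.boundary_ok else 2)

    def euler_characteristic(self) -> int:
        ne = len({frozenset(e) for e in self._edge_face})
        return self.n_vertices - ne + self.n_faces

    def next_around(self, v: int, u: int) -> int:
        """Third vertex of the face with directed edge ``v -> u``.

        Successive calls traverse the one-ring of ``v`` counter-clockwise
        as seen from outside the surface.
        """
        return self._third[(v, u)]

    def ordered_ring(self, v: int, start: int) -> list[int]:
        """One-ring of ``v`` in ccw order beginning at neighbor ``start``."""
        ring = [start]
        cur = start
        for _ in range(self.valence[v] - 1):
            cur = self._third[(v, cur)]
            ring.append(cur)
        if self._third[(v, cur)] != start:
            raise MeshStructureError(f"open vertex fan at vertex {v}")
        return ring

    def enclosed_volume(self) -> float:
        """Signed volume of the faceted control mesh (positive = outward)."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def _build_connectivity(vertices, faces, allow_boundary=False):
    third = {}
    edge_face = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v, w in ((a, b, c), (b, c, a), (c, a, b)):
            key = (int(u), int(v))
            if key in third:
                raise MeshStructureError(
                    f"directed edge {key} appears twice: inconsistent orientation"
                )
            third[key] = int(w)
            edge_face[key] = fi
    if not allow_boundary:
        for (u, v) in third:
            if (v, u) not in third:
                raise MeshStructureError(
                    f"edge {(u, v)} has no opposite partner: surface not closed"
                )
    valence = np.zeros(len(vertices), dtype=np.int64)
    for (u, _v) in third:
        valence[u] += 1
    return third, edge_face, valence


def surface_mesh(vertices, faces, allow_boundary=False, check_volume=True) -> SurfaceMesh:
    """Validate connectivity and assemble a :class:`SurfaceMesh`."""
    vertices = np.ascontiguousarray(vertices, dtype=np.float64)
    faces = np.ascontiguousarray(faces, dtype=np.int64)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise MeshStructureError("faces must be an (F, 3) index array")
    third, edge_face, valence = _build_connectivity(vertices, faces, allow_boundary)
    mesh = SurfaceMesh(vertices, faces, valence, third, edge_face,
                       boundary_ok=allow_boundary)
    if not allow_boundary:
        chi = mesh.euler_characteristic()
        if chi != 2:
            raise MeshStructureError(f"Euler characteristic {chi} != 2 (not a sphere)")
        if check_volume and mesh.enclosed_volume() <= 0:
            raise MeshStructureError("negative enclosed volume: faces oriented inward")
    return mesh


def make_icosahedron() -> SurfaceMesh:
    """Regular icosahedron on the unit sphere, apices on the +/-z axis."""
    top, bot = np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])
    zu, r = 1.0 / np.sqrt(5.0), 2.0 / np.sqrt(5.0)
    ang_u = 2.0 * np.pi * np.arange(5) / 5.0
    ang_l = ang_u + np.pi / 5.0
    upper = np.stack([r * np.cos(ang_u), r * np.sin(ang_u), np.full(5, zu)], axis=1)
    lower = np.stack([r * np.cos(ang_l), r * np.sin(ang_l), np.full(5, -zu)], axis=1)
    verts = np.vstack([top[None], upper, lower, bot[None]])
    U = lambda k: 1 + k % 5        # noqa: E731
    L = lambda k: 6 + k % 5        # noqa: E731
    faces = []
    for k in range(5):
        faces.append((0, U(k), U(k + 1)))          # top cap
        faces.append((U(k), L(k), U(k + 1)))       # upper band
        faces.append((U(k + 1), L(k), L(k + 1)))   # lower band
        faces.append((11, L(k + 1), L(k)))         # bottom cap
    return surface_mesh(verts, np.array(faces))


def loop_subdivide(mesh: SurfaceMesh, project_to_sphere: bool = False,
                   return_weights: bool = False, allow_boundary: bool = False):
    """One level of Loop subdivision.

    Old vertices are repositioned with the valence-dependent vertex mask
    ``(1 - n beta(n)) v + beta(n) sum(ring)``; a new vertex is inserted on
    every edge with the 3/8-3/8-1/8-1/8 mask.  Each face is split into four
    children emitted in the fixed order ``(a, m_ab, m_ca), (m_ab, b, m_bc),
    (m_ca, m_bc, c), (m_ab, m_bc, m_ca)``.

    With ``project_to_sphere`` the result is renormalized to unit length
    (used to construct reference icospheres).  With ``return_weights`` the
    dense matrix ``W`` with ``vertices_out = W @ vertices_in`` is returned
    as well — used internally to derive basis-function weights.
    ``allow_boundary`` admits open template meshes (boundary vertices and
    edges get simple averaging masks; only interior weights are ever used).
    """
    V = mesh.n_vertices
    old = mesh.vertices
    third = mesh._third

    rows = []  # (weights row) only when requested
    W = np.zeros((0, 0))
    new_pos = np.empty((V, 3))
    if return_weights:
        Wv = np.zeros((V, V))
    # --- repositioned old vertices -------------------------------------
    boundary_vertex = np.zeros(V, dtype=bool)
    if allow_boundary:
        for (u, v) in third:
            if (v, u) not in third:
                boundary_vertex[u] = True
                boundary_vertex[v] = True
    for v in range(V):
        if allow_boundary and boundary_vertex[v]:
            new_pos[v] = old[v]
            if return_weights:
                Wv[v, v] = 1.0
            continue
        n = mesh.valence[v]
        ring = _any_ring(mesh, v)
        b = loop_beta(n)
        new_pos[v] = (1.0 - n * b) * old[v] + b * old[ring].sum(axis=0)
        if return_weights:
            Wv[v, v] = 1.0 - n * b
            Wv[v, ring] += b
    # --- edge vertices --------------------------------------------------
    edge_ids = {}
    epos = []
    erows = []
    for (u, v) in list(third):
        key = (u, v) if u < v else (v, u)
        if key in edge_ids:
            continue
        u, v = key
        if (u, v) not in third:  # only the reversed direction exists (boundary)
            u, v = v, u
        opp1 = third[(u, v)]
        if (v, u) in third:
            opp2 = third[(v, u)]
            p = 0.375 * (old[u] + old[v]) + 0.125 * (old[opp1] + old[opp2])
            wr = [(u, 0.375), (v, 0.375), (opp1, 0.125), (opp2, 0.125)]
        else:
            p = 0.5 * (old[u] + old[v])
            wr = [(u, 0.5), (v, 0.5)]
        edge_ids[key] = V + len(epos)
        epos.append(p)
        erows.append(wr)
    new_pos = np.vstack([new_pos, np.array(epos)])
    if return_weights:
        We = np.zeros((len(epos), V))
        for i, wr in enumerate(erows):
            for j, w in wr:
                We[i, j] += w
        W = np.vstack([Wv, We])

    def eid(a, b):
        return edge_ids[(a, b) if a < b else (b, a)]

    faces = []
    for (a, b, c) in mesh.faces:
        a, b, c = int(a), int(b), int(c)
        mab, mbc, mca = eid(a, b), eid(b, c), eid(c, a)
        faces.extend([(a, mab, mca), (mab, b, mbc), (mca, mbc, c), (mab, mbc, mca)])
    if project_to_sphere:
        new_pos = new_pos / np.linalg.norm(new_pos, axis=1, keepdims=True)
    out = surface_mesh(new_pos, np.array(faces), allow_boundary=allow_boundary,
                       check_volume=False)
    if return_weights:
        return out, W
    return out


def _any_ring(mesh, v):
    for (a, b) in mesh._third:
        if a == v:
            return mesh.ordered_ring(v, b)
    raise MeshStructureError(f"isolated vertex {v}")


def make_icosphere(level: int) -> SurfaceMesh:
    """Icosahedrally symmetric sphere mesh: ``10 * 4**level + 2`` vertices.

    Constructed by ``level`` rounds of Loop refinement of the icosahedron
    with projection of every vertex back onto the unit sphere.  Exactly 12
    vertices (the icosahedron corners) have valence five; all others have
    valence six.  Patches are annotated for levels >= 1.
    """
    if not (0 <= int(level) <= 7):
        raise ValueError("icosphere level must be in 0..7")
    mesh = make_icosahedron()
    for _ in range(int(level)):
        mesh = loop_subdivide(mesh, project_to_sphere=True)
    return build_patches(mesh) if level >= 1 else mesh


def face_stencil(mesh: SurfaceMesh, face_index: int, first_corner: int = 0) -> list[int]:
    """Ordered one-ring control stencil of a face.

    For corners ``(c0, c1, c2)`` (the face cycled so that ``first_corner``
    leads) the stencil is ``[c0; ring of c0 starting c1, c2, x3..xn;
    w1, w2, y; z1, z2]`` where ``w*``/``y`` come from the ring of ``c1``
    and ``z*`` from the ring of ``c2``, traversed consistently with the
    face orientation.  Length is ``valence(c0) + 6``; for a regular face
    (all valences six) this is the classic 12-point box-spline stencil.
    ``c1`` and ``c2`` must have valence six.
    """
    f = [int(x) for x in mesh.faces[face_index]]
    c0, c1, c2 = f[first_corner:] + f[:first_corner]
    if mesh.valence[c1] != 6 or mesh.valence[c2] != 6:
        raise MeshStructureError(
            f"face {face_index}: corners {c1},{c2} must be regular "
            "(more than one extraordinary corner per face; subdivide once)"
        )
    ring0 = mesh.ordered_ring(c0, c1)
    assert ring0[1] == c2, "ring orientation inconsistent with face orientation"
    ring1 = mesh.ordered_ring(c1, c0)
    ring2 = mesh.ordered_ring(c2, c1)
    assert ring1[-1] == c2 and ring2[-1] == c0
    stencil = [c0] + ring0 + [ring1[2], ring1[3], ring1[4], ring2[2], ring2[3]]
    # A vertex may fill two control slots when a low-valence vertex sits in
    # the two-ring (valence 3/4 nearby); the slot structure stays valid and
    # its weights simply accumulate.
    assert len(stencil) == mesh.valence[c0] + 6
    return stencil


def build_patches(mesh: SurfaceMesh) -> SurfaceMesh:
    """Annotate every face with its control stencil and regularity flag.

    Faces with more than one extraordinary corner (e.g. the raw
    icosahedron) are flagged with a ``None`` stencil; they cannot occur on
    icospheres of level >= 1 and shell evaluation refuses them.
    """
    stencils, rots, regular = [], [], []
    for fi, f in enumerate(mesh.faces):
        val = mesh.valence[f]
        irr = np.flatnonzero(val != 6)
        if len(irr) == 0:
            rots.append(0)
            regular.append(True)
            stencils.append(np.array(face_stencil(mesh, fi, 0), dtype=np.int64))
        elif len(irr) == 1:
            r = int(irr[0])
            rots.append(r)
            regular.append(False)
            stencils.append(np.array(face_stencil(mesh, fi, r), dtype=np.int64))
        else:
            rots.append(-1)
            regular.append(False)
            stencils.append(None)
    object.__setattr__(mesh, "patch_stencil", stencils)
    object.__setattr__(mesh, "patch_rotation", np.array(rots, dtype=np.int64))
    object.__setattr__(mesh, "patch_regular", np.array(regular, dtype=bool))
    return mesh


# ---------------------------------------------------------------------------
# I/O: OBJ/OFF through trimesh, legacy ASCII VTK written directly.

def read_mesh(path) -> SurfaceMesh:
    """Read an OBJ or OFF triangulation (closed, consistently oriented)."""
    import trimesh

    tm = trimesh.load_mesh(str(path), process=False)
    mesh = surface_mesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    return build_patches(mesh)


def write_mesh(mesh_or_arrays, path):
    """Write OBJ/OFF (by extension) via trimesh; '.vtk' falls through to VTK."""
    import trimesh

    vertices, faces = _as_arrays(mesh_or_arrays)
    path = str(path)
    if path.endswith(".vtk"):
        return write_vtk((vertices, faces), path)
    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    tm.export(path)


def write_vtk(mesh_or_arrays, path, point_data: dict | None = None,
              comment: str = "loopshell surface"):
    """Legacy ASCII VTK polydata writer (points, triangles, point scalars)."""
    vertices, faces = _as_arrays(mesh_or_arrays)
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\n%s\nASCII\nDATASET POLYDATA\n" % comment)
    buf.write("POINTS %d double\n" % len(vertices))
    for p in vertices:
        buf.write("%.17g %.17g %.17g\n" % tuple(p))
    buf.write("POLYGONS %d %d\n" % (len(faces), 4 * len(faces)))
    for f in faces:
        buf.write("3 %d %d %d\n" % tuple(f))
    if point_data:
        buf.write("POINT_DATA %d\n" % len(vertices))
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            buf.write("SCALARS %s double 1\nLOOKUP_TABLE default\n" % name)
            for x in arr:
                buf.write("%.17g\n" % x)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _as_arrays(mesh_or_arrays):
    if isinstance(mesh_or_arrays, SurfaceMesh):
        return mesh_or_arrays.vertices, mesh_or_arrays.faces
    vertices, faces = mesh_or_arrays
    return np.asarray(vertices), np.asarray(faces)
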