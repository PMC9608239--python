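"""Visualization export: the limit surface, not the control mesh.

On coarse meshes, plotting the control mesh makes particles appear to
hover below the surface — the particles live on the box-spline *limit*
surface, which lies inside the faceted control polyhedron.  Export
therefore Loop-subdivides the deformed control mesh a few times and
pushes the refined vertices onto the limit surface with the
valence-dependent limit stencil, so every exported vertex lies exactly
on the surface the particles move on.
"""

from __future__ import annotations

import numpy as np

from .mesh import (SurfaceMesh, build_patches, loop_limit_weight,
                   loop_subdivide, surface_mesh, write_mesh, write_vtk)

__all__ = ["limit_surface_mesh", "export_limit_surface", "limit_positions"]


def limit_positions(mesh: SurfaceMesh, X: np.ndarray) -> np.ndarray:
    """Push control positions onto the Loop limit surface (per-vertex stencil)."""
    out = np.empty_like(X)
    for v in range(mesh.n_vertices):
        ring = _ring(mesh, v)
        lw = loop_limit_weight(len(ring))
        out[v] = (1.0 - len(ring) * lw) * X[v] + lw * X[ring].sum(axis=0)
    return out


def _ring(mesh, v):
    for (a, b) in mesh._third:
        if a == v:
            return np.array(mesh.ordered_ring(v, b))
    raise ValueError(f"isolated vertex {v}")


def limit_surface_mesh(mesh: SurfaceMesh, X: np.ndarray, refine: int = 1):
    """(vertices, faces) of the refined deformed surface.

    ``refine`` Loop subdivisions are applied to the deformed control mesh
    and the result is projected onto the limit surface.  ``refine=0``
    returns the control mesh unchanged (which is *not* the physical
    surface; callers get a metadata warning from
    :func:`export_limit_surface`).
    """
    cur = surface_mesh(X, mesh.faces)
    for _ in range(int(refine)):
        cur = loop_subdivide(cur)
    if refine > 0:
        pos = limit_positions(cur, cur.vertices)
    else:
        pos = cur.vertices
    return pos, cur.faces


def export_limit_surface(state, path, refine: int = 1,
                         particles_path: str | None = None) -> dict:
    """Write the deformed surface (VTK/OBJ/OFF by extension) + particles.

    Particle physical positions (limit-surface evaluations at their
    reference coordinates) are written as a CSV point set next to the
    surface file (or to ``particles_path``).  Returns a small manifest
    dict, including a warning when ``refine=0`` exports the raw control
    mesh.
    """
    pos, faces = limit_surface_mesh(state.mesh, state.X, refine)
    comment = ("loopshell limit surface (refine=%d)" % refine if refine > 0 else
               "loopshell CONTROL mesh (refine=0): not the physical surface")
    path = str(path)
    if path.endswith(".vtk"):
        write_vtk((pos, faces), path, comment=comment)
    else:
        write_mesh((pos, faces), path)
    manifest = {"surface": path, "refine": int(refine),
                "n_vertices": int(len(pos)), "n_faces": int(len(faces))}
    if refine == 0:
        manifest["warning"] = ("refine=0 exports the control mesh; particles "
                               "lie on the limit surface and may appear "
                               "detached from it")
    if state.particles is not None and len(state.particles) > 0:
        from .locator import build_hash_grid
        from .particles import angles_to_unit, evaluate_particles
        from .solver import default_hash_dims
        d = default_hash_dims(state.mesh)
        grid = build_hash_grid(state.mesh, d, d, d)
        frames = evaluate_particles(state.mesh, grid, state.X,
                                    angles_to_unit(state.particles.angles))
        pts = np.array([f.position for f in frames])
        ppath = particles_path or (path.rsplit(".", 1)[0] + "_particles.csv")
        np.savetxt(ppath, np.column_stack([np.arange(len(pts)), pts]),
                   delimiter=",", header="index,x,y,z", comments="")
        manifest["particles"] = ppath
    return manifest
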