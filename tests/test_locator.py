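"""Hash-grid construction and global-to-local particle search."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from loopshell.locator import (HashGrid, brute_force_locate, build_hash_grid,
                               grid_statistics, locate, ray_triangle)
from loopshell.particles import ParticleSet, angles_to_unit


def test_single_box_contains_all_faces(sphere2):
    g = build_hash_grid(sphere2, 1, 1, 1)
    assert len(g.table) == 1
    (faces,) = g.table.values()
    assert len(faces) == sphere2.n_faces


def test_every_face_covered(grid4, sphere4):
    covered = set()
    for faces in grid4.table.values():
        covered.update(int(f) for f in faces)
    assert covered == set(range(sphere4.n_faces))


def test_faces_appear_in_their_bbox_boxes(grid4, sphere4):
    """Each face is listed in every box overlapped by its AABB."""
    V = (sphere4.vertices - grid4.offset) * grid4.scale
    rng = np.random.default_rng(0)
    dims = np.asarray(grid4.dims)
    for f in rng.integers(0, sphere4.n_faces, 50):
        tri = V[sphere4.faces[f]]
        lo = np.clip(np.floor(tri.min(axis=0)).astype(int), 0, dims - 1)
        hi = np.clip(np.ceil(tri.max(axis=0)).astype(int) - 1, lo, dims - 1)
        for p in range(lo[0], hi[0] + 1):
            for q in range(lo[1], hi[1] + 1):
                for r in range(lo[2], hi[2] + 1):
                    assert int(f) in grid4.table[(p, q, r)]


def test_empty_boxes_not_listed(grid4):
    assert all(len(v) > 0 for v in grid4.table.values())
    # the level-4 sphere surface misses the lattice center box
    assert (7, 7, 7) not in grid4.table


def test_invalid_box_counts(sphere2):
    with pytest.raises(ValueError):
        build_hash_grid(sphere2, 0, 5, 5)


def test_statistics_dump(grid4):
    s = grid_statistics(grid4)
    assert "entries=" in s and "mean=" in s
    st_ = grid4.statistics()
    assert st_["entries"] == len(grid4.table)
    assert st_["min_faces"] >= 1


def test_ray_triangle_vertex_and_centroid():
    tri = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
    bary, hit = ray_triangle(np.zeros(3), np.array([1.0, 0, 0]), tri)
    assert hit and bary == pytest.approx([1, 0, 0], abs=1e-12)
    c = tri.mean(axis=0)
    bary, hit = ray_triangle(np.zeros(3), c, tri)
    assert hit and bary == pytest.approx([1 / 3, 1 / 3, 1 / 3], abs=1e-12)


def test_ray_triangle_parallel_misses():
    tri = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
    d = tri[1] - tri[0]  # direction lying in the triangle plane
    _, hit = ray_triangle(np.array([5.0, 5.0, 5.0]), d, tri)
    assert not hit


@given(st.integers(0, 10 ** 6))
def test_ray_triangle_barycentric_round_trip(seed):
    """Reconstructing an interior point from its weights recovers them."""
    rng = np.random.default_rng(seed)
    tri = rng.standard_normal((3, 3)) + np.array([3.0, 0, 0])
    u, v = sorted(rng.uniform(0, 1, 2))
    bary0 = np.array([u, v - u, 1 - v])
    p = bary0 @ tri
    bary, hit = ray_triangle(np.zeros(3), p, tri)
    if hit:  # the ray may legitimately exit through the far side first
        assert np.abs(bary - bary0).max() < 1e-9


def test_locate_agrees_with_brute_force(sphere2, grid2, rng):
    pts = rng.standard_normal((400, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    for s in pts:
        f1, b1 = locate(grid2, sphere2, s)
        f2, b2 = brute_force_locate(sphere2, s)
        assert f1 == f2
        assert np.abs(b1 - b2).max() < 1e-10


def test_locate_poles_and_angle_input(sphere4, grid4):
    """theta = 0 resolves deterministically to the brute-force element."""
    for ang in ([0.0, 0.0], [np.pi, 1.0], [1e-12, 2.0]):
        f1, b1 = locate(grid4, sphere4, np.array(ang))
        f2, b2 = brute_force_locate(sphere4, np.array(ang))
        assert f1 == f2
        assert np.abs(b1 - b2).max() < 1e-10


def test_shared_edge_tie_break(sphere2, grid2):
    """A point on a shared edge returns the lowest-index incident face."""
    for (a, b), f1 in list(sphere2._edge_face.items())[:20]:
        f2 = sphere2._edge_face[(b, a)]
        mid = 0.5 * (sphere2.vertices[a] + sphere2.vertices[b])
        f, bary = locate(grid2, sphere2, mid)
        assert f == min(f1, f2)
        bf, _ = brute_force_locate(sphere2, mid)
        assert f == bf


def test_grid_built_once_per_reference_mesh(sphere2):
    """Minimization and continuation never rebuild a supplied grid."""
    from loopshell import ShellParams, SystemState, minimize
    from loopshell.particles import PairPotential

    g = build_hash_grid(sphere2, 8, 8, 8)
    before = HashGrid.build_count[0]
    st_ = SystemState.identity(sphere2, ParticleSet.random(3, seed=0))
    minimize(st_, ShellParams(kappa=1.0, lambda_g=2.0),
             PairPotential("coulomb"), tol=1e-2, max_iter=30, grid=g)
    assert HashGrid.build_count[0] == before
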