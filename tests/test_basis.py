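"""Limit-surface basis functions against oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from loopshell.basis import (eval_irregular, eval_regular, eval_regular_many,
                             subdivision_oracle, _planar_template)
from loopshell.mesh import face_stencil


def simplex_points():
    return st.tuples(st.floats(0.0, 1.0), st.floats(0.0, 1.0)).map(
        lambda t: (t[0] * (1 - t[1] / 2), t[1] * (1 - t[0] / 2))
    ).filter(lambda vw: vw[0] + vw[1] <= 1.0)


@given(simplex_points())
def test_regular_partition_of_unity(vw):
    ev = eval_regular(*vw)
    assert ev.basis.sum() == pytest.approx(1.0, abs=1e-10)
    assert np.abs(ev.d_basis.sum(axis=0)).max() < 1e-9
    assert np.abs(ev.dd_basis.sum(axis=0)).max() < 1e-8


@pytest.mark.parametrize("valence", [3, 4, 5, 7, 9, 12])
@given(vw=simplex_points())
def test_irregular_partition_of_unity(valence, vw):
    from hypothesis import assume

    ev = eval_irregular(valence, *vw)
    assert len(ev.basis) == valence + 6
    assert ev.basis.sum() == pytest.approx(1.0, abs=1e-10)
    # derivatives are not defined at the extraordinary vertex itself
    assume(vw[0] + vw[1] > 1e-6)
    assert np.abs(ev.d_basis.sum(axis=0)).max() < 1e-8


@pytest.mark.parametrize("valence,vw", [
    (None, (0.21, 0.33)),       # regular quartic
    (5, (0.13, 0.27)),          # irregular, extraordinary-corner region
    (5, (0.35, 0.40)),          # irregular, central sub-triangle
    (7, (0.05, 0.08)),          # one subdivision level deep
])
def test_derivatives_match_finite_differences(valence, vw):
    f = (lambda v, w: eval_regular(v, w)) if valence is None else \
        (lambda v, w: eval_irregular(valence, v, w))
    v, w = vw
    h = 1e-5
    ev = f(v, w)
    dv = (f(v + h, w).basis - f(v - h, w).basis) / (2 * h)
    dw = (f(v, w + h).basis - f(v, w - h).basis) / (2 * h)
    assert np.abs(dv - ev.d_basis[:, 0]).max() < 1e-6
    assert np.abs(dw - ev.d_basis[:, 1]).max() < 1e-6
    dvv = (f(v + h, w).basis - 2 * ev.basis + f(v - h, w).basis) / h ** 2
    dww = (f(v, w + h).basis - 2 * ev.basis + f(v, w - h).basis) / h ** 2
    assert np.abs(dvv - ev.dd_basis[:, 0]).max() < 1e-4
    assert np.abs(dww - ev.dd_basis[:, 2]).max() < 1e-4


def test_regular_barycenter_matches_subdivision_oracle():
    # one explicit Loop subdivision + evaluation on the child element
    got = eval_regular(1 / 3, 1 / 3).basis
    want = subdivision_oracle(6, 1 / 3, 1 / 3, levels=1)
    assert np.abs(got - want).max() < 1e-12


@pytest.mark.parametrize("valence", [3, 4, 5, 7, 9, 12])
def test_irregular_matches_repeated_subdivision(valence):
    got = eval_irregular(valence, 0.3, 0.3).basis
    want = subdivision_oracle(valence, 0.3, 0.3, levels=2)
    assert np.abs(got - want).max() < 1e-8


def test_valence_six_reduces_to_regular():
    for vw in [(0.2, 0.5), (0.05, 0.1), (0.6, 0.3)]:
        a = eval_irregular(6, *vw)
        b = eval_regular(*vw)
        assert np.abs(a.basis - b.basis).max() < 1e-12
        assert np.abs(a.d_basis - b.d_basis).max() < 1e-11
        assert np.abs(a.dd_basis - b.dd_basis).max() < 1e-9


def test_extraordinary_vertex_limit():
    ev = eval_irregular(5, 0.0, 0.0)
    assert ev.basis.sum() == pytest.approx(1.0, abs=1e-12)
    # limit weights are supported on the vertex and its ring only
    assert np.abs(ev.basis[6:]).max() < 1e-15


def test_domain_and_valence_errors():
    with pytest.raises(ValueError):
        eval_regular(0.7, 0.7)
    with pytest.raises(ValueError):
        eval_regular(-0.1, 0.2)
    with pytest.raises(ValueError):
        eval_irregular(13, 0.1, 0.1)
    with pytest.raises(ValueError):
        eval_irregular(2, 0.1, 0.1)


def test_linear_precision_on_plane():
    # control points sampled from a plane reproduce the plane exactly
    tmpl, cf = _planar_template()
    stencil = face_stencil(tmpl, cf, 0)
    corners = tmpl.vertices[tmpl.faces[cf]]
    plane = tmpl.vertices @ np.array([[1.0, 0.2], [0.3, -0.7], [0.0, 0.0]])
    C = plane[stencil]
    for v, w in [(0.3, 0.45), (1 / 3, 1 / 3), (0.05, 0.9)]:
        ev = eval_regular(v, w)
        exact = (1 - v - w) * plane[tmpl.faces[cf][0]] \
            + v * plane[tmpl.faces[cf][1]] + w * plane[tmpl.faces[cf][2]]
        assert np.abs(ev.basis @ C - exact).max() < 1e-12


def _edge_eval(mesh, face, shared, t):
    """Evaluate position and tangents at parameter t along a shared edge."""
    from loopshell.basis import eval_irregular, eval_regular

    f = mesh.faces[face]
    rot = int(mesh.patch_rotation[face])
    order = [f[rot], f[(rot + 1) % 3], f[(rot + 2) % 3]]
    i0, i1 = order.index(shared[0]), order.index(shared[1])
    bary = np.zeros(3)
    bary[i0], bary[i1] = 1 - t, t
    v, w = bary[1], bary[2]
    if mesh.patch_regular[face]:
        ev = eval_regular(v, w)
    else:
        ev = eval_irregular(int(mesh.valence[order[0]]), v, w)
    C = mesh.vertices[mesh.patch_stencil[face]]
    pos = ev.basis @ C
    a = ev.d_basis.T @ C
    n = np.cross(a[0], a[1])
    return pos, n / np.linalg.norm(n)


def test_c1_continuity_across_edges(sphere2):
    """Position and tangent plane agree from both sides of shared edges,
    including regular-irregular interfaces."""
    mesh = sphere2
    pairs = []
    reg_irr = reg_reg = None
    for (a, b), f1 in mesh._edge_face.items():
        if a > b:
            continue
        f2 = mesh._edge_face[(b, a)]
        key = (bool(mesh.patch_regular[f1]), bool(mesh.patch_regular[f2]))
        if key == (True, True) and reg_reg is None:
            reg_reg = ((a, b), f1, f2)
        if sorted(key) == [False, True] and reg_irr is None:
            reg_irr = ((a, b), f1, f2)
    for (edge, f1, f2) in (reg_reg, reg_irr):
        for t in (0.25, 0.5, 0.8):
            p1, n1 = _edge_eval(mesh, f1, edge, t)
            p2, n2 = _edge_eval(mesh, f2, edge, t)
            assert np.abs(p1 - p2).max() < 1e-8
            assert min(np.abs(n1 - n2).max(), np.abs(n1 + n2).max()) < 1e-8


def test_vectorized_regular_matches_scalar():
    v = np.array([0.1, 0.4, 0.0])
    w = np.array([0.2, 0.3, 0.9])
    B, D, DD = eval_regular_many(v, w)
    for k in range(3):
        ev = eval_regular(v[k], w[k])
        assert np.allclose(B[k], ev.basis)
        assert np.allclose(D[k], ev.d_basis)
        assert np.allclose(DD[k], ev.dd_basis)
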