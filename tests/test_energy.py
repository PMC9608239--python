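"""Membrane energy assembly, quadrature and the analytic gradient."""

import numpy as np
import pytest

from loopshell.energy import (FOUR_PI, ShellModel, ShellParams,
                              quadrature_scheme)
from loopshell.mesh import make_icosphere


def test_quadrature_rules(sphere2):
    q1 = quadrature_scheme(sphere2, 1)
    assert len(q1) == sphere2.n_faces
    e0 = [t for t in q1 if t[0] == 0]
    assert e0[0][1] == pytest.approx((1 / 3, 1 / 3, 1 / 3))
    assert e0[0][2] == pytest.approx(0.5)
    q3 = quadrature_scheme(sphere2, 3)
    assert len(q3) == 3 * sphere2.n_faces
    per_elem = sum(t[2] for t in q3 if t[0] == 5)
    assert per_elem == pytest.approx(0.5, abs=1e-14)
    for _, bary, wq in q3[:9]:
        assert wq > 0
        assert min(bary) > 0.05  # interior points, never on a vertex
    with pytest.raises(ValueError):
        quadrature_scheme(sphere2, 2)


def test_order3_integrates_quadratics_exactly():
    # integrate v^2, v*w over the reference triangle: 1/12 and 1/24... times 2A
    pts = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
    wts = np.full(3, 1 / 6)
    assert np.dot(wts, pts[:, 0] ** 2) == pytest.approx(1 / 12, abs=1e-15)
    assert np.dot(wts, pts[:, 0] * pts[:, 1]) == pytest.approx(1 / 24, abs=1e-15)
    assert np.dot(wts, pts[:, 0]) == pytest.approx(1 / 6, abs=1e-15)


def test_identity_sphere_energies(model4):
    """Analytic sphere identities on the identity configuration (level 4)."""
    rep = model4.energy(model4.mesh.vertices, ShellParams(kappa=1.0))
    assert rep.area == pytest.approx(FOUR_PI, rel=5e-3)
    assert rep.volume == pytest.approx(FOUR_PI / 3, rel=5e-3)
    assert rep.e_bend == pytest.approx(FOUR_PI, rel=5e-3)
    assert rep.e_hm == pytest.approx(FOUR_PI, rel=5e-3)
    assert np.linalg.norm(rep.zero_mass) < 1e-10
    assert rep.e_bend >= 0 and rep.area > 0 and rep.volume > 0


def test_limit_area_converges_monotonically():
    areas = []
    for level in (2, 3, 4):
        m = make_icosphere(level)
        areas.append(ShellModel.for_mesh(m, 3).energy(
            m.vertices, ShellParams()).area)
    assert areas[0] < areas[1] < areas[2] < FOUR_PI


def test_total_is_sum_of_parts(model2, rng):
    X = model2.mesh.vertices * (1 + 0.03 * rng.standard_normal(
        (model2.mesh.n_vertices, 1)))
    p = ShellParams(kappa=1.2, kappa_g=0.4, pressure=0.1, lambda_g=3.0)
    rep = model2.energy(X, p, e_interaction=1.5)
    expect = (rep.e_bend + rep.e_gauss + rep.e_interaction + rep.e_pressure
              + p.lambda_g * rep.e_hm ** 2 + rep.pen_area + rep.pen_mass
              + rep.pen_volume)
    assert rep.e_total == pytest.approx(expect, abs=1e-12)
    assert rep.e_pressure == pytest.approx(-p.pressure * rep.volume, abs=1e-12)


@pytest.mark.parametrize("params", [
    ShellParams(kappa=1.3, kappa_g=0.7, C0=0.2, pressure=0.5, lambda_g=7.0),
    ShellParams(kappa=1.0, reduced_volume=0.9, lambda_g=5.0),
])
def test_gradient_matches_finite_differences(model2, params, rng):
    mesh = model2.mesh
    X = mesh.vertices * (1 + 0.05 * rng.standard_normal((mesh.n_vertices, 1))) \
        + 0.03 * rng.standard_normal((mesh.n_vertices, 3))
    _, g = model2.energy_and_gradient(X, params)
    h = 1e-6
    for vi in rng.integers(0, mesh.n_vertices, 5):
        for c in range(3):
            Xp, Xm = X.copy(), X.copy()
            Xp[vi, c] += h
            Xm[vi, c] -= h
            fd = (model2.energy(Xp, params).e_total
                  - model2.energy(Xm, params).e_total) / (2 * h)
            assert abs(fd - g[vi, c]) / max(1.0, abs(fd)) < 1e-5


@pytest.mark.parametrize("quad_order", [1, 3])
def test_gradient_on_irregular_elements(sphere1, quad_order, rng):
    """Level-1 icosphere: 60 of 80 elements are irregular; the gradient
    must remain FD-consistent there and at both quadrature orders."""
    model = ShellModel.for_mesh(sphere1, quad_order)
    X = sphere1.vertices * (1 + 0.04 * rng.standard_normal((42, 1)))
    p = ShellParams(kappa=1.0, lambda_g=2.0)
    _, g = model.energy_and_gradient(X, p)
    h = 1e-6
    for vi in rng.integers(0, 42, 6):
        for c in range(3):
            Xp, Xm = X.copy(), X.copy()
            Xp[vi, c] += h
            Xm[vi, c] -= h
            fd = (model.energy(Xp, p).e_total - model.energy(Xm, p).e_total) \
                / (2 * h)
            assert abs(fd - g[vi, c]) / max(1.0, abs(fd)) < 1e-5


def test_translation_invariance(model2, rng):
    """All terms except the zero-mass penalty are translation invariant;
    at the symmetric reference the mass-penalty contribution vanishes too."""
    p = ShellParams(kappa=1.0, lambda_g=3.0, mu_mass=0.0)
    X = model2.mesh.vertices * (1 + 0.02 * rng.standard_normal(
        (model2.mesh.n_vertices, 1)))
    _, g = model2.energy_and_gradient(X, p)
    assert abs(g.sum(axis=0)).max() < 1e-8
    # with the mass penalty on, at the symmetric reference the derivative
    # along a uniform translation is zero to quadrature tolerance
    p2 = ShellParams(kappa=1.0, lambda_g=3.0)
    _, g2 = model2.energy_and_gradient(model2.mesh.vertices, p2)
    assert abs(g2.sum(axis=0)).max() < 1e-6


def test_area_penalty_stationary_under_inflation(model4):
    """d/de [mu (A(1+e)^2 - 4 pi)^2] = 0 at the reference when A = 4 pi."""
    mesh = model4.mesh
    p = ShellParams(kappa=0.0, lambda_g=0.0, mu_mass=0.0, mu_area=1000.0)
    rep, g = model4.energy_and_gradient(mesh.vertices, p)
    # radial inflation direction
    eta = mesh.vertices
    deriv = float((g * eta).sum())
    # analytic: 4 mu (A - 4pi) * A; A is within 0.5% of 4 pi at level 4
    expect = 4.0 * p.mu_area * (rep.area - FOUR_PI) * rep.area
    assert deriv == pytest.approx(expect, rel=1e-6)


def test_kappa_g_does_not_move_equilibria(model2, rng):
    """Gauss-Bonnet: int K da is a topological constant, so the energy
    difference between configurations is kappa_g-independent."""
    X1 = model2.mesh.vertices
    X2 = X1 * (1 + 0.05 * rng.standard_normal((model2.mesh.n_vertices, 1)))
    for kg in (0.0, 1.0, 5.0):
        p = ShellParams(kappa_g=kg)
        d = model2.energy(X2, p).e_gauss - model2.energy(X1, p).e_gauss
        assert abs(d) < kg * 0.05 * FOUR_PI + 1e-12


def test_multi_irregular_mesh_rejected():
    from loopshell.mesh import build_patches, make_icosahedron
    with pytest.raises(ValueError):
        ShellModel(build_patches(make_icosahedron()), 3)
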