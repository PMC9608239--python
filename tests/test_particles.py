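"""Pair potentials, Lagrangian particle coupling, push-forward gradients."""

import numpy as np
import pytest

from loopshell.energy import ShellParams
from loopshell.particles import (PairPotential, ParticleSet, angles_to_unit,
                                 evaluate_particles, interaction_energy,
                                 interaction_gradient, pair_forces,
                                 potential_value_and_slope, unit_to_angles)
from loopshell.solver import _Objective


@pytest.mark.parametrize("pot,r,expect", [
    (PairPotential("coulomb"), 2.0, (0.5, -0.25)),
    (PairPotential("lennard_jones", epsilon=0.7, re=1.3), 1.3, (-0.7, 0.0)),
    (PairPotential("harmonic", re=0.8), 0.8, (0.0, 0.0)),
    (PairPotential("harmonic", re=0.8, spring=2.0), 1.0, (0.04, 0.4)),
])
def test_potential_values_and_slopes(pot, r, expect):
    val, slope = potential_value_and_slope(pot, r)
    assert val == pytest.approx(expect[0], abs=1e-12)
    assert slope == pytest.approx(expect[1], abs=1e-12)


def test_potential_slope_is_derivative():
    h = 1e-7
    for pot in (PairPotential("coulomb"),
                PairPotential("lennard_jones", epsilon=0.3, re=1.1),
                PairPotential("harmonic", re=0.9, spring=1.7)):
        for r in (0.5, 0.9, 1.4, 3.0):
            v1, _ = potential_value_and_slope(pot, r + h)
            v0, _ = potential_value_and_slope(pot, r - h)
            _, s = potential_value_and_slope(pot, r)
            assert (v1 - v0) / (2 * h) == pytest.approx(s, rel=1e-4, abs=1e-6)


def test_coincident_particles_rejected():
    with pytest.raises(ValueError):
        potential_value_and_slope(PairPotential("coulomb"), 0.0)
    with pytest.raises(ValueError):
        ParticleSet(np.array([[1.0, 2.0], [1.0, 2.0]]))


def test_unknown_potential_rejected():
    with pytest.raises(ValueError):
        PairPotential("yukawa")


def test_interaction_energy_antipodal_and_triangle():
    pot = PairPotential("coulomb")
    anti = np.array([[0, 0, 1.0], [0, 0, -1.0]])
    assert interaction_energy(anti, pot) == pytest.approx(0.5, abs=1e-14)
    # equilateral triangle on a great circle: chords sqrt(3)
    ang = 2 * np.pi * np.arange(3) / 3
    tri = np.stack([np.cos(ang), np.sin(ang), np.zeros(3)], axis=1)
    assert interaction_energy(tri, pot) == pytest.approx(np.sqrt(3.0), abs=1e-12)


def test_pair_forces_match_energy_gradient(rng):
    pot = PairPotential("lennard_jones", epsilon=0.5, re=1.0)
    x = rng.standard_normal((6, 3))
    U, G = pair_forces(x, pot)
    h = 1e-7
    for i in (0, 3):
        for c in range(3):
            xp, xm = x.copy(), x.copy()
            xp[i, c] += h
            xm[i, c] -= h
            fd = (interaction_energy(xp, pot) - interaction_energy(xm, pot)) \
                / (2 * h)
            assert fd == pytest.approx(G[i, c], rel=1e-5, abs=1e-8)


def test_angle_round_trip(rng):
    ang = ParticleSet.random(20, rng=rng).angles
    back = unit_to_angles(angles_to_unit(ang))
    assert np.allclose(back, ang, atol=1e-12)


def test_uniform_sampling_covers_hemisphere_flag():
    ps = ParticleSet.random(50, seed=0, hemisphere=True)
    assert (angles_to_unit(ps.angles)[:, 2] > 0).all()


def test_particles_live_on_limit_surface(sphere2, grid2):
    """Cached particle positions equal a recomputed limit-surface
    evaluation at the located element/barycentric coordinates."""
    from loopshell.basis import eval_irregular, eval_regular
    from loopshell.locator import locate

    sv = angles_to_unit(ParticleSet.random(10, seed=3).angles)
    frames = evaluate_particles(sphere2, grid2, sphere2.vertices, sv)
    for s, fr in zip(sv, frames):
        face, bary = locate(grid2, sphere2, s)
        assert face == fr.element
        rot = int(sphere2.patch_rotation[face])
        v, w = bary[(rot + 1) % 3], bary[(rot + 2) % 3]
        if sphere2.patch_regular[face]:
            ev = eval_regular(v, w)
        else:
            ev = eval_irregular(int(sphere2.valence[sphere2.faces[face][rot]]),
                                v, w)
        pos = ev.basis @ sphere2.vertices[sphere2.patch_stencil[face]]
        assert np.abs(pos - fr.position).max() < 1e-10


def test_antipodal_particle_gradient_vanishes(sphere2, grid2):
    """Two antipodal particles on the identity sphere: tangential forces
    cancel by symmetry, so the particle block of the gradient is ~0."""
    eps = 1e-3  # nudge off the exact pole to stay in a generic chart
    ps = ParticleSet(np.array([[eps, 0.3], [np.pi - eps, 0.3 + np.pi]]))
    frames = evaluate_particles(sphere2, grid2, sphere2.vertices,
                                angles_to_unit(ps.angles))
    _, _, g_ang = interaction_gradient(frames, sphere2.n_vertices,
                                       PairPotential("coulomb"))
    # residual ~1e-5 reflects the slight asphericity of the discrete
    # limit surface, not the coupling algebra
    assert np.abs(g_ang).max() < 1e-4


def test_nodal_interaction_gradient_translation_consistency(sphere2, grid2):
    """U depends on position differences only, so the nodal gradient sums
    to zero over the mesh (constant nodal shift changes U at zero rate)."""
    sv = angles_to_unit(ParticleSet.random(7, seed=9).angles)
    frames = evaluate_particles(sphere2, grid2, sphere2.vertices, sv)
    _, gX, _ = interaction_gradient(frames, sphere2.n_vertices,
                                    PairPotential("coulomb"))
    assert np.abs(gX.sum(axis=0)).max() < 1e-10


def test_coupled_gradient_finite_differences(sphere2, grid2, rng):
    """Analytic (nodal, particle) gradient vs central differences on a
    random deformed state with N = 5 particles."""
    params = ShellParams(kappa=1.0, lambda_g=5.0, pressure=0.3)
    obj = _Objective(sphere2, params, PairPotential("coulomb"), grid2, 3)
    sv = angles_to_unit(ParticleSet.random(5, seed=7).angles)
    obj.set_charts(sv)
    X = sphere2.vertices * (1 + 0.04 * rng.standard_normal(
        (sphere2.n_vertices, 1))) + 0.02 * rng.standard_normal(
        (sphere2.n_vertices, 3))
    x0 = obj.pack(X, sv)
    _, g = obj(x0)
    h = 1e-6
    idx = list(rng.integers(0, 3 * sphere2.n_vertices, 15)) \
        + list(range(3 * sphere2.n_vertices, len(x0)))
    for i in idx:
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h
        xm[i] -= h
        fd = (obj(xp)[0] - obj(xm)[0]) / (2 * h)
        assert abs(fd - g[i]) / max(1.0, abs(fd)) < 1e-5


def test_csv_round_trip(tmp_path, sphere2, grid2):
    ps = ParticleSet.random(6, seed=4)
    frames = evaluate_particles(sphere2, grid2, sphere2.vertices,
                                angles_to_unit(ps.angles))
    ps.element_id = np.array([f.element for f in frames])
    ps.barycentric = np.zeros((6, 3))
    ps.positions = np.array([f.position for f in frames])
    p = tmp_path / "p.csv"
    ps.to_csv(p)
    back = ParticleSet.from_csv(p)
    assert np.allclose(back.angles, ps.angles, atol=1e-12)


@pytest.mark.parametrize("n", [4, 6, 12])
def test_rigid_sphere_limit_thomson_symmetries(n):
    """Rigid-substrate limit on the exact sphere: particle-only
    minimization reproduces the Thomson polyhedra to high precision."""
    from loopshell.experiments import (THOMSON_GROUPS,
                                       distance_multiset_spreads,
                                       rigid_sphere_thomson)

    _, sv = rigid_sphere_thomson(n, seed=1, starts=3)
    for s in distance_multiset_spreads(sv, THOMSON_GROUPS[n]):
        assert s < 1e-4


def test_frozen_mesh_thomson_icosahedron(sphere3, grid3):
    """Particle-only minimization on the frozen discrete surface: N = 12
    lands exactly on the icosahedron (the configuration shares the mesh
    symmetry, so the surface ripple does not distort it).  Configurations
    not aligned with the mesh symmetry (N = 4, 6) inherit a relative
    distortion of order the surface ripple (~1e-3 at desk resolutions),
    which the rigid-sphere test above excludes."""
    from loopshell.experiments import (THOMSON_GROUPS,
                                       distance_multiset_spreads,
                                       frozen_mesh_particle_relax)

    pot = PairPotential("coulomb")
    sv0 = angles_to_unit(ParticleSet.random(12, seed=1).angles)
    _, sv = frozen_mesh_particle_relax(sphere3, grid3, sphere3.vertices,
                                       sv0, pot)
    frames = evaluate_particles(sphere3, grid3, sphere3.vertices, sv)
    pos = np.array([f.position for f in frames])
    for s in distance_multiset_spreads(pos, THOMSON_GROUPS[12]):
        assert s < 1e-4
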