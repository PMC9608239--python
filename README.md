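# loopshell

Thin-shell finite elements for **fluid membranes with freely moving
embedded particles**: compute equilibrium shapes of a closed lipid
vesicle (Helfrich–Canham elasticity) coupled to N particles —
electrostatic charges, adhesive colloids, model proteins — that live on
the membrane and rearrange freely as the membrane deforms around them.

The package is aimed at soft-matter and biophysics practitioners who
need the *two-way coupling*: particle interactions sculpt the membrane
(budding, stellation, enveloping) while the membrane's shape feeds back
on the particle arrangement.

## Model

The membrane is a topologically spherical fluid shell with reference
configuration the unit sphere S² and deformation map f : S² → ω.  Its
elastic energy is the Helfrich–Canham functional

    E_HC = ∫_ω [ κ (H − C0)² + κ_g K ] da

with the global area constraint ∫ da = 4π, optional osmotic pressure
−pV or a reduced-volume constraint V = (4π/3)·v.  Particle i is
parametrized by *reference* spherical coordinates X_i = (ϑ_i, φ_i) and
sits at x_i = f(X_i) — on the surface by construction, free to cross
element boundaries.  Pairs interact through Φ(‖x_i − x_j‖) (Coulomb,
Lennard–Jones, or harmonic).

Because a fluid shell's energy is reparametrization invariant, the raw
problem is degenerate (zero-energy tangential modes).  The minimized
objective is therefore the gauge-fixed penalty functional

    Ê = E_HC + U − pV + λ_g (E_HM)² + μ₁ (∫J dA − 4π)² + μ₂ ‖∫R J dA‖²

where E_HM = ∫ ½ g^{αβ} h_{αβ} da is the harmonic-map energy between the
current and reference metrics: it pins the parametrization without
changing equilibrium shapes.

The discretization uses C¹ Loop-subdivision shell elements (quartic
box-spline shape functions, eigen-operator evaluation on the irregular
patches that any sphere triangulation must contain), an analytic nodal
gradient, L-BFGS minimization over all 3V + 2N degrees of freedom, and a
one-time spatial hash grid that maps particle reference coordinates to
mesh elements via ray–triangle intersection.  See `docs/methods.md` for
the full account.

## Worked example: Thomson symmetries on a deformable vesicle

Twelve Coulomb charges on a stiff vesicle (κ = 1, λ_g = 10) should
arrange themselves as an icosahedron — the classical Thomson solution —
while the membrane stays nearly spherical:

```python
from loopshell.experiments import thomson_validation, rigid_sphere_thomson

rep = thomson_validation(12, level=3, seed=32)
print("converged:", rep.converged)
print("interaction energy (deformable):", round(rep.energy_interaction, 4))
print("rigid-sphere Thomson oracle:   ", round(rep.rigid_energy, 4))
print("chord-multiset spreads:", ["%.1e" % s for s in rep.spreads])
print("symmetry:", rep.symmetry)
```

prints

```
converged: True
interaction energy (deformable): 47.7339
rigid-sphere Thomson oracle:    49.1653
chord-multiset spreads: ['6.4e-09', '2.9e-09', '2.7e-12']
symmetry: Ih (icosahedron)
```

The 66 pairwise chord lengths split into the icosahedron's 30/30/6
groups with relative spreads ~1e−8: the converged arrangement *is* an
icosahedron to numerical precision.  Its Coulomb energy (47.73) is lower
than the rigid-sphere minimum (49.1653 — reproduced independently by
brute-force minimization on the exact sphere) because the deformable
membrane dimples under the charges; freezing the membrane recovers the
rigid value to seven digits after radius normalization.

Other shipped studies (`loopshell.experiments`): `stellation_sweep`
(N = 12 Lennard–Jones particles stellate the vesicle as κ decreases),
`budding_sweep` (N = 40 harmonic particles pinch a bud under volume
reduction to v = 0.90), `enveloping_sweep` (N = 200 particles spread
from a half sphere to envelope the whole substrate as r_e grows).

## Command line

```
loopshell mesh --level 4            # reference icosphere + counts
loopshell grid --level 4            # hash-table statistics
loopshell locate 0.7 1.1            # (theta, phi) -> element + barycentric
loopshell minimize run.ini          # relax a configured system
loopshell sweep run.ini             # continuation (kappa / volume / re path)
loopshell export state.json out.vtk # limit surface + particle positions
```

Configs are plain INI (see `loopshell.config` for the schema and shipped
defaults: μ₁ = μ₂ = 1000, C0 = 0, p = 0, level-4 mesh).  Exit codes:
0 success, 2 config error, 3 non-convergence, 4 geometric degeneracy.

Visualization note: always export with `refine ≥ 1`.  The physical
surface is the box-spline *limit* surface, which lies inside the control
mesh; plotting the raw control mesh makes particles appear to float
below the surface.

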