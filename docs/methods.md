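# Methods

`loopshell` computes zero-temperature equilibrium configurations of a
closed fluid membrane carrying N mutually interacting particles that are
free to move on the surface.  This note records the model, the
discretization, the numerical choices that were genuinely open, and what
the shipped desk-scale studies do and do not demonstrate.

## Model

The membrane is a topologically spherical fluid shell whose reference
(undeformed) configuration is the unit sphere S².  The deformation map
f : S² → ω ⊂ R³ carries reference points to the current surface.  The
elastic energy is the Helfrich–Canham functional

    E_HC = ∫_ω [ κ (H − C0)² + κ_g K ] da ,

with mean curvature H, Gaussian curvature K, bending modulus κ, Gaussian
modulus κ_g and preferred curvature C0.  Because lipid bilayers stretch
far more stiffly than they bend, the total area is constrained to the
reference value 4π.  An internal osmotic pressure p contributes −pV;
alternatively the enclosed volume is constrained to a reduced-volume
fraction v of the reference volume 4π/3 (exactly one of the two is
active in a run).

Particles are described in the Lagrangian (referential) picture: particle
i carries global spherical coordinates X_i = (ϑ_i, φ_i) *on the reference
sphere* as its degrees of freedom, and its physical position is the
composition x_i = f(X_i).  Particles therefore sit on the surface by
construction — no attachment constraints — and move between elements
freely.  The interaction energy is a sum of isotropic pair potentials
Φ(‖x_i − x_j‖) over unordered pairs; Coulomb (1/r), Lennard–Jones
(ε[(r_e/r)¹² − 2(r_e/r)⁶]) and harmonic (k(r − r_e)²/2) forms are
provided.

### Gauge fixing

A fluid shell's energy is reparametrization invariant: tangential motions
of the parametrization cost nothing, so the discrete problem is massively
degenerate (zero-energy shear modes, mesh distortion).  The remedy used
here augments — without changing the equilibrium shapes — the functional
with the harmonic-map energy

    E_HM = ∫_ω ½ g^{αβ} h_{αβ} da ,

the Dirichlet-type coupling between the current metric g and the
reference round metric h.  At a stationary point of the tangential
equations, the normal variation of E_HM vanishes identically, so the
shape equations are untouched; the term only pins the parametrization.
Because E_HM is not bounded below along all variations when added
linearly, the minimized objective uses it **squared**, together with
quadratic penalties for the constraints:

    Ê = E_HC + U − pV + λ_g (E_HM)² + μ₁ (∫ J dA − 4π)²
        + μ₂ ‖∫ R J dA‖² [+ μ_v (V − 4πv/3)²]

Here J = √(g/G) is the area Jacobian relative to the reference surface
and R(X) the reference-sphere position; the μ₂ ("zero-mass") term pins
the three translational gauge modes.  The three rotational modes are left
free — quasi-Newton minimization handles the flat directions without
landmark constraints — and every reported summary (energies, distance
multisets, radius statistics) is rotation invariant.  The squared
harmonic-map term leaves equilibria invariant under changes of λ_g, a
property asserted by a regression test.

Residual checks on the implementation: on the identity configuration the
discrete J ≡ 1 and the E_HM density ≡ 1 *exactly* (not merely to
discretization error), because the reference quantities √G, h_{αβ}, R are
computed by applying the same patch evaluations to the reference control
points rather than from the analytic sphere.

### Sign convention

With the outward normal d = a₁×a₂/√g and b_{αβ} = d·a_{α,β}, the unit
sphere parametrized by the identity has H = −1.  C0 is interpreted in
this convention.  All shipped studies use C0 = 0, where the sign choice
is inert, but it is documented and exposed.

## Discretization

### Subdivision shell elements

C¹-conforming displacement-only thin-shell elements based on Loop
subdivision surfaces are used: the limit surface over a triangle of a
*regular* patch (all corners valence 6) is a single quartic polynomial in
barycentric coordinates spanned by the 12 translates of the quartic
three-direction box spline; curvatures are available pointwise from the
second parametric derivatives.  The reference meshes are icosahedrally
symmetric spheres built by Loop-refining an icosahedron with projection
to the unit sphere at every level (10·4^L + 2 nodes at level L); exactly
12 vertices keep valence 5, so 60 elements per mesh are *irregular*.

Two derivation choices are deliberate:

* **Regular basis from the masks, not from tables.**  The 12 quartic
  polynomials are generated at build time: a planar three-direction
  template mesh is Loop-subdivided three times while tracking the weight
  matrix, limit weights are read off at the dyadic vertices inside the
  central face with the valence-6 limit stencil, and the unique
  interpolating quartics are solved for (fit residual asserted below
  1e−9, and the vanishing of all weights outside the 12-point stencil is
  asserted too).  This removes any transcription risk and is pinned by an
  independent repeated-subdivision oracle in the tests.

* **Irregular patches by per-valence subdivision operators.**  For a
  patch with one extraordinary vertex of valence n (stencil n+6), one
  subdivision of a disk template yields the operator A mapping patch
  weights to the sub-patch at the extraordinary corner and the three
  pick-out operators B_j onto the regular sub-patches.  Evaluation at
  (v, w) applies A^k (through its eigendecomposition, validated at build
  time with a cached-power fallback) until the point lands in a regular
  sub-patch, then evaluates the quartic basis with the affine chart
  chain rule.  Valences 3–12 are supported; valence 6 reproduces the
  regular basis to machine precision.  Points exactly at the
  extraordinary vertex take the eigen-limit weights; second derivatives
  are undefined there in general, and both quadrature points and
  particle evaluations avoid the vertex by construction.

### Quadrature

Each element uses the interior 3-point degree-2 Gauss rule on the
parameter triangle by default (order 1, the barycenter rule, is
available).  Order 3 resolves the curvature terms of the quartic basis
acceptably at the shipped mesh levels; all integrals converge to their
analytic sphere values within 0.5% at level 4 (area, volume, bending
energy, harmonic-map energy, total Gaussian curvature — all asserted).
Basis tables at quadrature points are computed once per mesh and reused
across all energy and gradient evaluations.

### Gradient assembly

The gradient of Ê with respect to nodal positions is assembled
analytically.  Every integrand is chained through the six patch vectors
(f; a₁, a₂; a_vv, a_vw, a_ww), using

* δ√g = √g a^α · δa_α,
* δd = −a^α (d · δa_α),
* δb_{αβ} = δd · a_{αβ} + d · δa_{αβ},
* δg^{αβ} = −g^{αγ} g^{βδ} δg_{γδ},
* δ(f · a₁×a₂) = (a₁×a₂)·δf + (a₂×f)·δa₁ + (f×a₁)·δa₂,

and scattered into nodal slots through the basis weights in a fixed
(group, element, stencil) order for bitwise reproducibility.  The
particle block couples through the push-forward rule δx_i = η(X_i) +
∇f(X_i) θ_i: nodal forces distribute through the basis weights at the
particle's local coordinates, and the referential gradient projects the
Euclidean pair force onto the tangents a_α and chains through the
central-ray/flat-triangle location map (below).  The complete gradient is
verified against central finite differences (relative error < 1e−5) on
random deformed states with particles, on irregular elements
specifically, and at both quadrature orders.

## Particle location (hash grid)

Mapping a particle's global coordinates to (element, barycentric
coordinates) runs entirely on the reference mesh, so the search
structure is built once per discretization and never updated — shape
changes and particle motion do not touch it (a test asserts no rebuild
across minimization and continuation).

Construction: the reference mesh is scaled per axis so its bounding box
spans an MX × MY × MZ lattice of unit boxes indexed by their minimum
corner; every face is entered into each box overlapped by the floor/ceil
bounds of its vertex coordinates (its axis-aligned bounding box), and
the box → face-list table drops empty boxes.  Query: the particle's unit
vector picks a box by integer arithmetic; the candidate faces are
scanned with a ray–triangle intersection along the central ray from the
origin; false candidates report barycentric coordinates outside [0, 1]
and are rejected.  On a shared edge or vertex the lowest-index incident
element wins (deterministic tie-break, tolerance 1e−10); an absent box
falls back to the neighboring boxes and finally to a brute-force scan
(logged).  Equivalence with the brute-force scan over all faces is
asserted on 10,000 uniform points.

The flat-triangle barycentric coordinates from the ray test serve
directly as the element's local coordinates for limit-surface
evaluation — the faceted-chart convention that a referential search
supports naturally.  A known regression constant for this structure
(level-4 mesh, 15³ lattice: 1111 entries averaging 16 faces) is *not*
reproduced by this convention, which deterministically yields 1214
entries averaging 11.8; the regression test asserts the reference values
and its failure message reports the computed delta.  Several alternative
scalings and assignment rules were measured (origin-centered truncation,
inclusive ceil bounds, exact triangle–box intersection) without
reproducing both reference numbers simultaneously; the documented
convention is the one whose invariants the test suite checks.

## Minimization

All degrees of freedom — 3V nodal coordinates and 2N particle angles —
live in one flat vector minimized by L-BFGS (memory 20) with the
analytic gradient; convergence is declared at max-norm gradient ≤ 1e−6
(dimensionless energy units) by default, exposed in config.  Two
practical devices:

* **Chunked restarts.**  L-BFGS occasionally terminates a line search
  prematurely on penalty-stiff problems; minimization runs in chunks of
  400 iterations with a fresh history, giving up only after two
  consecutive chunks make no progress.

* **Pole recharting.**  A particle whose colatitude approaches a pole of
  its differentiation chart (|cos ϑ| > 0.99) gets a per-particle rotated
  spherical chart at the next chunk boundary; the stored state remains
  global (ϑ, φ).  Without this, the azimuth degeneracy stalls particle
  convergence long before the gradient test is met.

For the Thomson validation the minimization is staged: particles are
first relaxed on the frozen reference surface (the rigid-substrate
limit), then all degrees of freedom are released, and a particle-only
polish alternates with coupled minimization twice more.  This is plain
block minimization of the same objective from the same random state; it
reaches the same equilibria as a cold coupled start but reliably drives
the particle block to gradient norms ~1e−10, which the symmetry checks
(chord-multiset spreads < 1e−3) require.

Continuation sweeps (decreasing κ, decreasing v, increasing r_e)
warm-start each step from the previous equilibrium; a non-converged step
aborts the sweep and returns the completed prefix.

## Study conditions and desk scaling

Defaults mirror the shipped studies: penalty weights μ₁ = μ₂ = 1000
(μ_v = 1000 for reduced-volume runs), C0 = 0, zero pressure, κ_g = 0
(on fixed topology ∫K da = 4π is constant — asserted — so κ_g cannot
move equilibria), level-4 reference mesh in the library defaults.
Random particle initializations sample the sphere uniformly by area with
a recorded seed and reject pairs closer than 1e−9; the enveloping study
restricts the initial sample to a half sphere.

The studies run at desk scale: Thomson validation and the hash-grid
regression on the level-3/level-4 meshes, the budding and enveloping
sweeps on level-3 and level-2 meshes respectively.  Mesh level is a
resolution choice, not a model change; the bending and constraint
integrals at level 3 carry ~1% discretization error and shape
descriptors inherit it.  The budding endpoint is an exception worth
naming: the v = 0.90 equilibrium under the shipped conditions is a
clear bud onset whose waist measures ≈0.53 of the mean radius, and this
value is mesh-converged (levels 3 and 4 agree to 1%) and insensitive to
the continuation granularity — a decisively pinched neck (waist below
half the mean radius) would need deeper volume reduction or stronger
particle forcing, not a finer mesh.  The studies demonstrate the
coupling mechanics (shape change driven by particle interactions,
referential search, gauge-fixed relaxation); descriptor thresholds are
reported as measured.

Shape descriptors are defined in code because the upstream results are
figures: asphericity is the max/min nodal radius about the centroid;
the bud neck ratio slices the once-subdivided limit surface into bands
along the axis through the particle-cluster centroid and takes the
smallest interior band waist over the mean radius; coverage is the
fraction of elements whose (limit-surface) barycenter lies within the
interaction distance of a particle.

## Numerical details and edge cases

* Tolerances: barycentric containment 1e−10; degenerate-tangent guard
  ‖a₁×a₂‖ < 1e−14 raises a geometry error naming the element; minimum
  pair distance 1e−9 (coincident particles rejected).
* The composition order of Ê is fixed and documented in `EnergyReport`;
  gradient scatter order is fixed (group, element, stencil slot).
* Serialization round-trips states bit-faithfully through JSON
  (shortest-repr floats); particle CSVs are restartable.
* Faces with more than one extraordinary corner (only the raw
  icosahedron, level 0) are flagged and rejected by the shell model;
  subdividing once removes them.
* The valence-3 two-ring wraps onto itself, so a regular 12-slot stencil
  near a valence-3 vertex may list a vertex twice; slot weights
  accumulate and evaluation remains exact (covered by the oracle test).

## Limitations

* Spherical topology only; the gauge-fixing construction is specific to
  genus 0, and the Gaussian term is treated as topologically inert.
* Constraints are enforced by quadratic penalties, not multipliers:
  area and volume hold to ~0.1% at the shipped weights, not exactly.
* Quasi-static equilibria only: no in-plane viscosity, no dynamics, no
  thermal fluctuations.
* All-pairs interaction evaluation (O(N²)) — appropriate for N up to a
  few hundred; no cutoff or neighbor lists.
* Irregular-patch second derivatives degrade in accuracy very close to
  an extraordinary vertex (depth capped at 24 subdivision levels);
  quadrature points and generic particle positions do not probe this
  region.
* The discrete limit surface of a projected icosphere carries an
  icosahedrally symmetric radial ripple (~1e−3 relative at level 2,
  ~2e−4 at level 4, decaying ~h²).  Frozen-surface particle equilibria
  that do not share that symmetry (e.g. the N = 4 tetrahedron or N = 6
  octahedron) are distorted at the ripple's order; configurations that
  do share it (the N = 12 icosahedron) are exact to solver precision.
  The rigid-sphere limit proper is therefore validated on the exact
  sphere, where all three polyhedra emerge with chord spreads ~1e−8.
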