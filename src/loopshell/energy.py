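"""Gauge-fixed membrane energy and its analytic nodal gradient.

The objective minimized by the solver is the penalty functional

    E_hat = E_HC + U - p V
            + lambda_g * E_HM**2
            + mu_area * (area - 4 pi)**2
            + mu_mass * |integral R J dA|**2
            [+ mu_volume * (V - 4 pi v_t / 3)**2 when a reduced-volume
               target v_t replaces the pressure]

with E_HC the Helfrich-Canham bending energy ``int kappa (H - C0)^2 +
kappa_g K  da``, E_HM the harmonic-map energy ``int (1/2) g^ab h_ab da``
between the current metric g and the reference (round-sphere) metric h,
V the enclosed volume ``(1/3) int f . d  da`` and R the reference-sphere
parametrization (zero-mass constraint pinning rigid translations).  The
squared harmonic-map term breaks the tangential reparametrization
redundancy of the fluid membrane without altering equilibrium *shapes*.

This module assembles the membrane terms (everything except the particle
interaction U, which :mod:`loopshell.solver` adds) over Gauss points of
every element, evaluating basis functions of irregular patches through
the per-valence subdivision operators.  The gradient is assembled
analytically by chaining each integrand through the five patch vectors
(a1, a2, a_vv, a_vw, a_ww) and the position f, then scattering through
the basis weights into nodal slots; it is verified against central finite
differences in the test suite.  Reference quantities (sqrt(G), h_ab, R)
come from applying the same patch evaluations to the reference control
points, making J = 1 and E_HM-density = 1 exact on the identity map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .basis import eval_irregular, eval_regular
from .geometry import GeometryDegeneracyError
from .mesh import SurfaceMesh

__all__ = ["ShellParams", "EnergyReport", "ShellModel", "quadrature_scheme"]

FOUR_PI = 4.0 * np.pi

# Gauss rules on the reference triangle in the (v, w) chart; weights sum
# to the reference-triangle area 1/2.  Order 3 integrates quadratics
# exactly; all points are interior (they never touch the extraordinary
# vertex of an irregular patch).
_QUAD = {
    1: (np.array([[1 / 3, 1 / 3]]), np.array([0.5])),
    3: (np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]]),
        np.array([1 / 6, 1 / 6, 1 / 6])),
}


def quadrature_scheme(mesh: SurfaceMesh, order: int = 3):
    """Per-element Gauss points as ``(element, (u, v, w), weight)`` tuples.

    Barycentric coordinates are in the patch chart of each face (for
    irregular faces the extraordinary corner carries the ``u`` weight).
    """
    if order not in _QUAD:
        raise ValueError(f"unsupported quadrature order {order}; choose 1 or 3")
    pts, wts = _QUAD[order]
    out = []
    for e in range(mesh.n_faces):
        for (v, w), wt in zip(pts, wts):
            out.append((e, (1.0 - v - w, v, w), float(wt)))
    return out


@dataclass(frozen=True)
class ShellParams:
    """Physical and penalty parameters of the gauge-fixed functional.

    kappa / kappa_g : bending and Gaussian-curvature moduli.  On fixed
        (spherical) topology ``int K da = 4 pi`` is a constant, so kappa_g
        does not move equilibria; it defaults to zero.
    C0 : preferred curvature in the outward-normal convention (unit sphere
        has H = -1); the shipped studies use 0.
    pressure : internal osmotic pressure p (energy contribution -p V).
    reduced_volume : target enclosed volume as a fraction of 4 pi / 3; when
        set, the pressure must be zero and a quadratic volume penalty with
        weight mu_volume is applied instead.
    mu_area, mu_mass : penalty weights of the global area constraint
        (area = 4 pi) and the zero-mass constraint.
    lambda_g : weight of the squared harmonic-map (gauge-fixing) term.
    """

    kappa: float = 1.0
    kappa_g: float = 0.0
    C0: float = 0.0
    pressure: float = 0.0
    reduced_volume: float | None = None
    mu_area: float = 1000.0
    mu_mass: float = 1000.0
    mu_volume: float = 1000.0
    lambda_g: float = 10.0

    def __post_init__(self):
        if self.reduced_volume is not None and self.pressure != 0.0:
            raise ValueError("specify either a pressure or a reduced volume, not both")

    def with_(self, **kw) -> "ShellParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class EnergyReport:
    """Itemized energies of one configuration.

    ``e_total`` is composed, in this fixed order, as
    ``e_bend + e_gauss + e_interaction + e_pressure + lambda_g * e_hm**2
    + pen_area + pen_mass + pen_volume``.
    """

    e_bend: float
    e_gauss: float
    e_hm: float
    area: float
    volume: float
    e_pressure: float
    zero_mass: np.ndarray = field(repr=False)
    e_interaction: float
    pen_area: float
    pen_mass: float
    pen_volume: float
    e_total: float


def _compose_total(params: ShellParams, e_bend, e_gauss, e_hm, area, volume,
                   zero_mass, e_interaction):
    e_pressure = -params.pressure * volume
    pen_area = params.mu_area * (area - FOUR_PI) ** 2
    pen_mass = params.mu_mass * float(zero_mass @ zero_mass)
    if params.reduced_volume is not None:
        pen_volume = params.mu_volume * (volume - FOUR_PI / 3.0
                                         * params.reduced_volume) ** 2
    else:
        pen_volume = 0.0
    e_total = (e_bend + e_gauss + e_interaction + e_pressure
               + params.lambda_g * e_hm ** 2 + pen_area + pen_mass + pen_volume)
    return EnergyReport(e_bend=e_bend, e_gauss=e_gauss, e_hm=e_hm, area=area,
                        volume=volume, e_pressure=e_pressure,
                        zero_mass=zero_mass, e_interaction=e_interaction,
                        pen_area=pen_area, pen_mass=pen_mass,
                        pen_volume=pen_volume, e_total=e_total)


class _PatchGroup:
    """Faces sharing one basis table (regular, or irregular of one valence)."""

    def __init__(self, mesh, faces, valence, quad_order):
        self.faces = np.asarray(faces, dtype=np.int64)
        self.valence = valence                      # None => regular
        self.stencil = np.stack([mesh.patch_stencil[f] for f in faces])
        pts, self.wq = _QUAD[quad_order]
        evs = [eval_regular(v, w) if valence is None else eval_irregular(valence, v, w)
               for v, w in pts]
        self.N = np.stack([e.basis for e in evs])       # (q, s)
        self.dN = np.stack([e.d_basis for e in evs])    # (q, s, 2)
        self.ddN = np.stack([e.dd_basis for e in evs])  # (q, s, 3)


def _first_fundamentals(group, X):
    """Batched surface quantities at the group's Gauss points."""
    C = X[group.stencil]                                  # (F, s, 3)
    f = np.einsum("qs,fsk->fqk", group.N, C)
    a = np.einsum("qsa,fsk->fqak", group.dN, C)           # (F, q, 2, 3)
    aab = np.einsum("qsm,fsk->fqmk", group.ddN, C)        # (F, q, 3, 3)
    nx = np.cross(a[..., 0, :], a[..., 1, :])
    sg = np.linalg.norm(nx, axis=-1)                      # sqrt(g)
    if np.any(sg < 1e-14):
        fi = int(group.faces[np.argwhere(sg < 1e-14)[0][0]])
        raise GeometryDegeneracyError(f"degenerate tangents at element {fi}")
    d = nx / sg[..., None]
    g = np.einsum("fqak,fqbk->fqab", a, a)                # metric
    det_g = sg * sg
    g_con = np.empty_like(g)
    g_con[..., 0, 0] = g[..., 1, 1]
    g_con[..., 1, 1] = g[..., 0, 0]
    g_con[..., 0, 1] = g_con[..., 1, 0] = -g[..., 0, 1]
    g_con /= det_g[..., None, None]
    bv = np.einsum("fqmk,fqk->fqm", aab, d)               # (b_vv, b_vw, b_ww)
    H = 0.5 * (g_con[..., 0, 0] * bv[..., 0]
               + 2.0 * g_con[..., 0, 1] * bv[..., 1]
               + g_con[..., 1, 1] * bv[..., 2])
    K = (bv[..., 0] * bv[..., 2] - bv[..., 1] ** 2) / det_g
    return dict(C=C, f=f, a=a, aab=aab, nx=nx, sg=sg, d=d, g=g, det_g=det_g,
                g_con=g_con, bv=bv, H=H, K=K)


class ShellModel:
    """Discretized membrane on a fixed reference mesh.

    Precomputes, once per mesh and quadrature order: patch groups with
    their basis tables, and the reference-surface quantities sqrt(G),
    h_ab and R at every Gauss point.  ``energy`` / ``gradient`` then
    evaluate the membrane part of E_hat for arbitrary nodal positions.
    """

    _cache: dict = {}

    def __init__(self, mesh: SurfaceMesh, quad_order: int = 3):
        if mesh.patch_stencil is None:
            raise ValueError("mesh has no patch annotation; call build_patches")
        if any(s is None for s in mesh.patch_stencil):
            raise ValueError("mesh has faces with more than one extraordinary "
                             "corner; subdivide once before building a model")
        if quad_order not in _QUAD:
            raise ValueError(f"unsupported quadrature order {quad_order}")
        self.mesh = mesh
        self.quad_order = quad_order
        reg = np.flatnonzero(mesh.patch_regular)
        self.groups = []
        if len(reg):
            self.groups.append(_PatchGroup(mesh, reg, None, quad_order))
        irr = np.flatnonzero(~mesh.patch_regular)
        if len(irr):
            val = np.array([mesh.valence[mesh.faces[f][mesh.patch_rotation[f]]]
                            for f in irr])
            for n in np.unique(val):
                self.groups.append(
                    _PatchGroup(mesh, irr[val == n], int(n), quad_order))
        # reference quantities at every Gauss point
        self._ref = []
        for gr in self.groups:
            q = _first_fundamentals(gr, mesh.vertices)
            self._ref.append(dict(sg=q["sg"], h=q["g"], R=q["f"]))
        self.reference_area = float(sum(
            (gr.wq[None, :] * r["sg"]).sum() for gr, r in zip(self.groups, self._ref)))

    @classmethod
    def for_mesh(cls, mesh: SurfaceMesh, quad_order: int = 3) -> "ShellModel":
        key = (id(mesh), quad_order)
        hit = cls._cache.get(key)
        if hit is None or hit.mesh is not mesh:
            hit = cls(mesh, quad_order)
            cls._cache[key] = hit
        return hit

    # -- energy ---------------------------------------------------------

    def _globals(self, X):
        """Per-group fundamentals plus the global integrals of E_hat."""
        per = [_first_fundamentals(gr, X) for gr in self.groups]
        e_hm = int_K = area = volume = 0.0
        Z = np.zeros(3)
        for gr, ref, q in zip(self.groups, self._ref, per):
            w = gr.wq[None, :]
            sg, K = q["sg"], q["K"]
            area += float((w * sg).sum())
            int_K += float((w * sg * K).sum())
            volume += float((w * np.einsum("fqk,fqk->fq", q["f"], q["nx"])).sum()) / 3.0
            Z += (w[..., None] * sg[..., None] * ref["R"]).sum(axis=(0, 1))
            # harmonic-map density (1/2) g^ab h_ab
            phi = 0.5 * np.einsum("fqab,fqab->fq", q["g_con"], ref["h"])
            q["phi_hm"] = phi
            e_hm += float((w * sg * phi).sum())
        return per, dict(int_K=int_K, area=area, volume=volume, Z=Z, e_hm=e_hm)

    def energy(self, X: np.ndarray, params: ShellParams,
               e_interaction: float = 0.0) -> EnergyReport:
        """Itemized membrane energy at nodal positions ``X`` (V, 3)."""
        per, gl = self._globals(X)
        c0 = params.C0
        e_bend = 0.0
        for gr, q in zip(self.groups, per):
            w = gr.wq[None, :]
            e_bend += float((w * q["sg"] * (q["H"] - c0) ** 2).sum())
        e_bend *= params.kappa
        return _compose_total(params, e_bend, params.kappa_g * gl["int_K"],
                              gl["e_hm"], gl["area"], gl["volume"], gl["Z"],
                              e_interaction)

    def energy_and_gradient(self, X: np.ndarray, params: ShellParams):
        """Membrane energy report and its gradient w.r.t. nodal positions.

        The gradient chains every integrand through the patch vectors
        (f; a1, a2; a_vv, a_vw, a_ww):

        * d sqrt(g)        = sqrt(g) a^alpha . d a_alpha
        * d(unit normal)   = -a^alpha (d . d a_alpha)
        * d b_ab           = d(d) . a_ab + d . d a_ab
        * d g^ab           = -g^ac g^bd d g_cd
        * d(f . a1 x a2)   = (a1 x a2) . df + (a2 x f) . da1 + (f x a1) . da2

        and scatters per-Gauss-point contributions through the basis
        weights into nodal slots in fixed (group, element, stencil) order.
        """
        per, gl = self._globals(X)
        kappa, kg, c0 = params.kappa, params.kappa_g, params.C0
        e_bend = 0.0
        for gr, q in zip(self.groups, per):
            w = gr.wq[None, :]
            e_bend += float((w * q["sg"] * (q["H"] - c0) ** 2).sum())
        e_bend *= kappa
        report = _compose_total(params, e_bend, kg * gl["int_K"], gl["e_hm"],
                                gl["area"], gl["volume"], gl["Z"], 0.0)
        # outer-chain coefficients
        c_hm = 2.0 * params.lambda_g * gl["e_hm"]
        c_area = 2.0 * params.mu_area * (gl["area"] - FOUR_PI)
        c_massv = 2.0 * params.mu_mass * gl["Z"]
        c_vol = -params.pressure
        if params.reduced_volume is not None:
            c_vol += 2.0 * params.mu_volume * (gl["volume"]
                                               - FOUR_PI / 3.0 * params.reduced_volume)
        grad = np.zeros_like(X)
        for gr, ref, q in zip(self.groups, self._ref, per):
            w = gr.wq[None, :]
            sg, H, K, bv = q["sg"], q["H"], q["K"], q["bv"]
            g_con, a, aab, d, f = q["g_con"], q["a"], q["aab"], q["d"], q["f"]
            dual = np.einsum("fqab,fqbk->fqak", g_con, a)      # a^alpha
            Hc0 = H - c0
            # -- sqrt(g)-slot scalar --------------------------------------
            C_sg = w * (kappa * Hc0 ** 2 - kg * K + c_hm * q["phi_hm"] + c_area
                        + np.einsum("k,fqk->fq", c_massv, ref["R"]))
            da = C_sg[..., None, None] * sg[..., None, None] * dual  # (F,q,2,3)
            # -- mean-curvature chain -------------------------------------
            cH = w * kappa * 2.0 * Hc0 * sg                      # d/dH weight
            # through b_ab (s = cH/2 g^ab) and through g^ab (-b^ab contra)
            s_b = 0.5 * cH[..., None, None] * g_con              # (F,q,2,2)
            # -- Gaussian-curvature chain (det b / sqrt g) ----------------
            cK = w * kg / sg
            adjb = np.empty_like(g_con)
            adjb[..., 0, 0] = bv[..., 2]
            adjb[..., 1, 1] = bv[..., 0]
            adjb[..., 0, 1] = adjb[..., 1, 0] = -bv[..., 1]
            s_b = s_b + cK[..., None, None] * adjb
            daab = np.empty_like(aab)
            daab[..., 0, :] = s_b[..., 0, 0, None] * d
            daab[..., 2, :] = s_b[..., 1, 1, None] * d
            daab[..., 1, :] = 2.0 * s_b[..., 0, 1, None] * d
            # normal-variation backchain: m = s_b : a_ab
            m = (s_b[..., 0, 0, None] * aab[..., 0, :]
                 + 2.0 * s_b[..., 0, 1, None] * aab[..., 1, :]
                 + s_b[..., 1, 1, None] * aab[..., 2, :])
            da += -np.einsum("fqk,fqak->fqa", m, dual)[..., None] * d[..., None, :]
            # -- inverse-metric chains ------------------------------------
            b_mat = np.empty_like(g_con)
            b_mat[..., 0, 0] = bv[..., 0]
            b_mat[..., 0, 1] = b_mat[..., 1, 0] = bv[..., 1]
            b_mat[..., 1, 1] = bv[..., 2]
            b_con = np.einsum("fqac,fqcd,fqdb->fqab", g_con, b_mat, g_con)
            h_con = np.einsum("fqac,fqcd,fqdb->fqab", g_con, ref["h"], g_con)
            Q = -(cH[..., None, None] * b_con
                  + (c_hm * w * sg)[..., None, None] * h_con)
            da += np.einsum("fqab,fqbk->fqak", Q, a)
            # -- volume / pressure chain ----------------------------------
            cv = (c_vol / 3.0) * w
            df = cv[..., None] * q["nx"]
            da[..., 0, :] += cv[..., None] * np.cross(a[..., 1, :], f)
            da[..., 1, :] += cv[..., None] * np.cross(f, a[..., 0, :])
            # -- scatter ----------------------------------------------------
            contrib = (np.einsum("qs,fqk->fsk", gr.N, df)
                       + np.einsum("qsa,fqak->fsk", gr.dN, da)
                       + np.einsum("qsm,fqmk->fsk", gr.ddN, daab))
            np.add.at(grad, gr.stencil.ravel(),
                      contrib.reshape(-1, 3))
        return report, grad

    def gradient(self, X: np.ndarray, params: ShellParams) -> np.ndarray:
        """Gradient of the membrane part of E_hat w.r.t. nodal positions."""
        return self.energy_and_gradient(X, params)[1]


def energy(state, params: ShellParams, quad_order: int = 3) -> EnergyReport:
    """Membrane energy of a system state (particle terms excluded).

    Convenience wrapper over :class:`ShellModel`; ``state`` needs ``mesh``
    and ``X`` attributes (see :class:`loopshell.solver.SystemState`).
    """
    return ShellModel.for_mesh(state.mesh, quad_order).energy(state.X, params)


def gradient(state, params: ShellParams, quad_order: int = 3) -> np.ndarray:
    """Nodal gradient of the membrane part of E_hat for a system state."""
    return ShellModel.for_mesh(state.mesh, quad_order).gradient(state.X, params)
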