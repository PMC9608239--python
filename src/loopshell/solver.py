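"""Equilibrium search: L-BFGS on the gauge-fixed functional.

The degree-of-freedom vector stacks the nodal positions of the deformed
control mesh (3 V entries) and the particles' reference spherical
coordinates (2 N entries).  The objective is the penalty functional
assembled by :class:`loopshell.energy.ShellModel` plus the particle
interaction energy; its analytic gradient feeds scipy's L-BFGS-B
(memory 20, no bound constraints, no landmark constraints — the residual
rigid-rotation gauge modes are left free and all reported summaries are
rotation invariant).

The hash grid used to locate particles is built once per reference mesh
and never rebuilt during minimization or continuation.  Minimization
runs in chunks; between chunks, particles that drifted into a coordinate
pole of their differentiation chart get a freshly rotated chart (the
stored state stays in global coordinates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .energy import EnergyReport, ShellModel, ShellParams
from .locator import HashGrid, build_hash_grid
from .mesh import SurfaceMesh, build_patches, make_icosphere, surface_mesh
from .particles import (POLE_COS_LIMIT, PairPotential, ParticleSet,
                        angles_to_unit, evaluate_particles,
                        interaction_gradient, unit_to_angles)

__all__ = ["SystemState", "MinimizeResult", "minimize", "continuation",
           "default_hash_dims"]

DEFAULT_TOL = 1e-6          # max-norm of the assembled gradient
_CHUNK = 400                # L-BFGS iterations between chart refreshes


def default_hash_dims(mesh: SurfaceMesh) -> int:
    """Box count per axis scaling with mesh resolution (15 at 5120 faces)."""
    return max(4, int(round(15.0 * (mesh.n_faces / 5120.0) ** (1.0 / 3.0))))


@dataclass
class SystemState:
    """Full configuration: deformed nodal positions + particle coordinates.

    The DOF vector has length ``3 V + 2 N``.  ``metadata`` records seeds,
    iteration counts and parameter snapshots of the run that produced the
    state.  Serialization (`to_dict`/`save`) round-trips bit-faithfully
    through JSON (shortest-repr floats).
    """

    mesh: SurfaceMesh
    X: np.ndarray                       # (V, 3) deformed nodal positions
    particles: ParticleSet | None = None
    metadata: dict = field(default_factory=dict)

    @classmethod
    def identity(cls, mesh: SurfaceMesh, particles=None, **meta) -> "SystemState":
        return cls(mesh, mesh.vertices.copy(), particles, dict(meta))

    @property
    def n_dof(self) -> int:
        n = 3 * len(self.X)
        if self.particles is not None:
            n += 2 * len(self.particles)
        return n

    def copy(self) -> "SystemState":
        p = None
        if self.particles is not None:
            p = ParticleSet(self.particles.angles.copy())
        return SystemState(self.mesh, self.X.copy(), p, dict(self.metadata))

    def to_dict(self) -> dict:
        d = {
            "X": self.X.tolist(),
            "metadata": self.metadata,
            "mesh": {"level": self.metadata.get("mesh_level")},
        }
        if self.metadata.get("mesh_level") is None:
            d["mesh"] = {"vertices": self.mesh.vertices.tolist(),
                         "faces": self.mesh.faces.tolist()}
        if self.particles is not None:
            d["particles"] = self.particles.angles.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SystemState":
        if "level" in d["mesh"] and d["mesh"]["level"] is not None:
            mesh = make_icosphere(d["mesh"]["level"])
        else:
            mesh = build_patches(surface_mesh(np.array(d["mesh"]["vertices"]),
                                              np.array(d["mesh"]["faces"])))
        particles = None
        if "particles" in d:
            particles = ParticleSet(np.array(d["particles"]))
        return cls(mesh, np.array(d["X"]), particles, d.get("metadata", {}))

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "SystemState":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class MinimizeResult:
    state: SystemState
    report: EnergyReport
    trace: list                 # EnergyReport per accepted iteration
    converged: bool
    n_iter: int
    grad_norm: float


class _Objective:
    """Packs/unpacks the DOF vector and evaluates E_hat with its gradient."""

    def __init__(self, mesh, params, potential, grid, quad_order):
        self.mesh = mesh
        self.model = ShellModel.for_mesh(mesh, quad_order)
        self.params = params
        self.potential = potential
        self.grid = grid
        self.nv = mesh.n_vertices
        self.charts = None          # (N, 3, 3) per-particle rotations
        self.last_report = None

    def set_charts(self, svecs):
        """Rotated differentiation charts for particles near a pole."""
        n = len(svecs)
        self.charts = np.tile(np.eye(3), (n, 1, 1))
        for i, s in enumerate(svecs):
            if abs(s[2]) > POLE_COS_LIMIT:
                c1 = s / np.linalg.norm(s)
                helper = np.array([1.0, 0.0, 0.0])
                if abs(c1 @ helper) > 0.9:
                    helper = np.array([0.0, 1.0, 0.0])
                c3 = np.cross(c1, helper)
                c3 /= np.linalg.norm(c3)
                c2 = np.cross(c3, c1)
                self.charts[i] = np.stack([c1, c2, c3], axis=1)

    def pack(self, X, svecs):
        parts = [X.ravel()]
        if svecs is not None:
            loc = np.einsum("nij,nj->ni", self.charts.transpose(0, 2, 1), svecs)
            parts.append(unit_to_angles(loc).ravel())
        return np.concatenate(parts)

    def unpack(self, x):
        X = x[:3 * self.nv].reshape(-1, 3)
        svecs = None
        if len(x) > 3 * self.nv:
            ang = x[3 * self.nv:].reshape(-1, 2)
            loc = angles_to_unit(ang)
            svecs = np.einsum("nij,nj->ni", self.charts, loc)
        return X, svecs

    def __call__(self, x):
        X, svecs = self.unpack(x)
        if svecs is None:
            report, grad = self.model.energy_and_gradient(X, self.params)
            self.last_report = report
            return report.e_total, grad.ravel()
        frames = evaluate_particles(self.mesh, self.grid, X, svecs, self.charts)
        U, gX_p, g_ang = interaction_gradient(frames, self.nv, self.potential)
        report, grad = self.model.energy_and_gradient(X, self.params)
        report = _with_interaction(report, U)
        self.last_report = report
        return report.e_total, np.concatenate([(grad + gX_p).ravel(),
                                               g_ang.ravel()])


def _with_interaction(report: EnergyReport, U: float) -> EnergyReport:
    from dataclasses import replace

    return replace(report, e_interaction=U, e_total=report.e_total + U)


def minimize(state: SystemState, params: ShellParams,
             potential: PairPotential | None = None,
             tol: float = DEFAULT_TOL, max_iter: int = 20000,
             quad_order: int = 3, grid: HashGrid | None = None,
             callback=None, checkpoint_every: int = 0,
             checkpoint_path: str | None = None) -> MinimizeResult:
    """Minimize E_hat over nodal positions and particle coordinates.

    Returns the relaxed state with its energy trace (one
    :class:`EnergyReport` per accepted L-BFGS iteration; energies are
    non-increasing).  ``converged`` reflects the max-norm gradient test
    against ``tol``; hitting ``max_iter`` leaves it false.
    """
    mesh = state.mesh
    has_particles = state.particles is not None and len(state.particles) > 0
    if has_particles and potential is None:
        raise ValueError("particles present but no interaction potential given")
    if has_particles and grid is None:
        d = default_hash_dims(mesh)
        grid = build_hash_grid(mesh, d, d, d)
    obj = _Objective(mesh, params, potential, grid, quad_order)
    X = state.X.copy()
    svecs = angles_to_unit(state.particles.angles) if has_particles else None
    trace = []
    total_iter = 0
    converged = False

    def _cb(xk):
        if obj.last_report is not None:
            trace.append(obj.last_report)
        if callback is not None:
            callback(obj.last_report)
        if checkpoint_every and checkpoint_path and \
                len(trace) % checkpoint_every == 0:
            Xk, sk = obj.unpack(xk)
            _snapshot(state, Xk, sk, checkpoint_path)

    last_f = np.inf
    stalls = 0
    while total_iter < max_iter and not converged:
        if has_particles:
            obj.set_charts(svecs)
        x0 = obj.pack(X, svecs)
        res = _scipy_minimize(obj, x0, jac=True, method="L-BFGS-B",
                              callback=_cb,
                              options=dict(maxiter=min(_CHUNK, max_iter - total_iter),
                                           maxcor=20, gtol=tol, ftol=0.0))
        X, svecs = obj.unpack(res.x)
        total_iter += max(res.nit, 1)
        gnorm = float(np.abs(res.jac).max())
        converged = gnorm <= tol
        # A chunk may end early on a line-search failure (stiff penalties);
        # restarting with a fresh L-BFGS history usually recovers.  Give up
        # only when two consecutive restarts make no progress at all.
        if res.nit < _CHUNK and not converged:
            stalls = stalls + 1 if res.fun >= last_f - 1e-14 * abs(last_f) else 0
            if stalls >= 2:
                break
        else:
            stalls = 0
        last_f = res.fun

    out = state.copy()
    out.X = X
    if has_particles:
        out.particles = ParticleSet(unit_to_angles(svecs))
    out.metadata = dict(state.metadata, iterations=total_iter,
                        converged=bool(converged), grad_norm=gnorm,
                        params=_params_dict(params, potential))
    obj(obj.pack(X, svecs) if has_particles else X.ravel())
    report = obj.last_report
    return MinimizeResult(state=out, report=report, trace=trace,
                          converged=converged, n_iter=total_iter,
                          grad_norm=gnorm)


def _snapshot(state, X, svecs, path):
    s = state.copy()
    s.X = X.copy()
    if svecs is not None:
        s.particles = ParticleSet(unit_to_angles(svecs))
    s.save(path)


def _params_dict(params, potential):
    d = {k: getattr(params, k) for k in
         ("kappa", "kappa_g", "C0", "pressure", "reduced_volume",
          "mu_area", "mu_mass", "mu_volume", "lambda_g")}
    if potential is not None:
        d["potential"] = {"kind": potential.kind, "epsilon": potential.epsilon,
                          "re": potential.re, "spring": potential.spring}
    return d


def continuation(state: SystemState, params: ShellParams,
                 potential: PairPotential | None, sweep: list[dict],
                 tol: float = DEFAULT_TOL, max_iter: int = 20000,
                 quad_order: int = 3, callback=None):
    """Warm-started parameter sweep.

    ``sweep`` is a list of parameter updates (e.g. ``{"kappa": 2.5}`` or
    ``{"re": 0.2}``); keys are matched to :class:`ShellParams` fields or,
    failing that, to the potential.  Each step starts from the previous
    equilibrium; a non-converged step aborts the sweep and the completed
    prefix is returned.
    """
    grid = None
    if state.particles is not None and len(state.particles) > 0:
        d = default_hash_dims(state.mesh)
        grid = build_hash_grid(state.mesh, d, d, d)
    results = []
    current = state
    for step in sweep:
        pkw = {k: v for k, v in step.items() if hasattr(params, k)}
        if pkw:
            params = params.with_(**pkw)
        rest = {k: v for k, v in step.items() if k not in pkw}
        if rest:
            if potential is None:
                raise ValueError(f"sweep keys {sorted(rest)} match no parameter")
            potential = potential.with_(**rest)
        res = minimize(current, params, potential, tol=tol, max_iter=max_iter,
                       quad_order=quad_order, grid=grid, callback=callback)
        results.append(res)
        if not res.converged:
            break
        current = res.state
    return results
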