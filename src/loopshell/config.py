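"""Plain-text run configuration (INI sections).

A run is fully described by a config file::

    [mesh]
    level = 4                 ; or: file = sphere.obj

    [particles]
    n = 12
    potential = coulomb       ; coulomb | lennard_jones | harmonic
    epsilon = 1.0
    re = 1.0
    seed = 0                  ; or: coords_file = particles.csv
    hemisphere = false

    [physics]
    kappa = 1.0
    kappa_g = 0.0
    c0 = 0.0
    pressure = 0.0            ; exactly one of pressure / reduced_volume
    ; reduced_volume = 0.9

    [penalties]
    mu_area = 1000.0
    mu_mass = 1000.0
    mu_volume = 1000.0
    lambda_g = 10.0

    [solver]
    tol = 1e-6
    max_iter = 20000
    quad_order = 3
    ; continuation = reduced_volume: 1.0, 0.95, 0.90

    [output]
    dir = .
    refine = 1
    checkpoint_every = 0

Defaults match the shipped study settings: level-4 mesh, mu_area =
mu_mass = 1000, C0 = 0, zero pressure.
"""

from __future__ import annotations

import configparser
import io as _io
from dataclasses import dataclass, field

import numpy as np

from .energy import ShellParams
from .mesh import SurfaceMesh, make_icosphere, read_mesh
from .particles import PairPotential, ParticleSet

__all__ = ["RunConfig", "ConfigError", "load_config", "parse_config",
           "dump_config"]


class ConfigError(ValueError):
    """Malformed or inconsistent run configuration."""


_DEFAULTS = {
    "mesh": {"level": "4"},
    "particles": {"n": "0", "potential": "coulomb", "epsilon": "1.0",
                  "re": "1.0", "spring": "1.0", "seed": "0",
                  "hemisphere": "false"},
    "physics": {"kappa": "1.0", "kappa_g": "0.0", "c0": "0.0",
                "pressure": "0.0"},
    "penalties": {"mu_area": "1000.0", "mu_mass": "1000.0",
                  "mu_volume": "1000.0", "lambda_g": "10.0"},
    "solver": {"tol": "1e-6", "max_iter": "20000", "quad_order": "3"},
    "output": {"dir": ".", "refine": "1", "checkpoint_every": "0"},
}


@dataclass
class RunConfig:
    """Parsed configuration; `build_*` methods assemble the run objects."""

    mesh_level: int | None
    mesh_file: str | None
    n_particles: int
    potential: PairPotential
    particle_seed: int
    hemisphere: bool
    coords_file: str | None
    params: ShellParams
    tol: float
    max_iter: int
    quad_order: int
    continuation: list = field(default_factory=list)
    output_dir: str = "."
    refine: int = 1
    checkpoint_every: int = 0

    def build_mesh(self) -> SurfaceMesh:
        if self.mesh_file:
            return read_mesh(self.mesh_file)
        return make_icosphere(self.mesh_level)

    def build_particles(self) -> ParticleSet | None:
        if self.coords_file:
            return ParticleSet.from_csv(self.coords_file)
        if self.n_particles <= 0:
            return None
        return ParticleSet.random(self.n_particles, seed=self.particle_seed,
                                  hemisphere=self.hemisphere)


def _parser(text=None):
    cp = configparser.ConfigParser(inline_comment_prefixes=(";", "#"))
    cp.read_dict(_DEFAULTS)
    if text is not None:
        cp.read_string(text)
    return cp


def parse_config(text: str) -> RunConfig:
    try:
        cp = _parser(text)
    except configparser.Error as exc:
        raise ConfigError(str(exc)) from exc
    mesh_file = cp.get("mesh", "file", fallback=None)
    mesh_level = None if mesh_file else cp.getint("mesh", "level")
    has_rv = cp.has_option("physics", "reduced_volume")
    pressure = cp.getfloat("physics", "pressure")
    if has_rv and pressure != 0.0:
        raise ConfigError("specify either pressure or reduced_volume, not both")
    params = ShellParams(
        kappa=cp.getfloat("physics", "kappa"),
        kappa_g=cp.getfloat("physics", "kappa_g"),
        C0=cp.getfloat("physics", "c0"),
        pressure=0.0 if has_rv else pressure,
        reduced_volume=cp.getfloat("physics", "reduced_volume") if has_rv else None,
        mu_area=cp.getfloat("penalties", "mu_area"),
        mu_mass=cp.getfloat("penalties", "mu_mass"),
        mu_volume=cp.getfloat("penalties", "mu_volume"),
        lambda_g=cp.getfloat("penalties", "lambda_g"),
    )
    for name, sec in (("kappa", "physics"), ("lambda_g", "penalties")):
        if not np.isfinite(getattr(params, name)):
            raise ConfigError(f"non-finite {name} in [{sec}]")
    pot = PairPotential(cp.get("particles", "potential"),
                        epsilon=cp.getfloat("particles", "epsilon"),
                        re=cp.getfloat("particles", "re"),
                        spring=cp.getfloat("particles", "spring"))
    sweep = []
    if cp.has_option("solver", "continuation"):
        raw = cp.get("solver", "continuation")
        try:
            key, values = raw.split(":")
            sweep = [{key.strip(): float(v)} for v in values.split(",")]
        except ValueError as exc:
            raise ConfigError(f"bad continuation spec {raw!r} "
                              "(expected 'name: v1, v2, ...')") from exc
    return RunConfig(
        mesh_level=mesh_level, mesh_file=mesh_file,
        n_particles=cp.getint("particles", "n"), potential=pot,
        particle_seed=cp.getint("particles", "seed"),
        hemisphere=cp.getboolean("particles", "hemisphere"),
        coords_file=cp.get("particles", "coords_file", fallback=None),
        params=params, tol=cp.getfloat("solver", "tol"),
        max_iter=cp.getint("solver", "max_iter"),
        quad_order=cp.getint("solver", "quad_order"),
        continuation=sweep, output_dir=cp.get("output", "dir"),
        refine=cp.getint("output", "refine"),
        checkpoint_every=cp.getint("output", "checkpoint_every"),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return parse_config(fh.read())


def dump_config(cfg: RunConfig) -> str:
    """Serialize back to INI text; parse(dump(parse(x))) is the identity."""
    cp = _parser()
    if cfg.mesh_file:
        cp.set("mesh", "file", cfg.mesh_file)
        cp.remove_option("mesh", "level")
    else:
        cp.set("mesh", "level", str(cfg.mesh_level))
    p = cfg.potential
    cp["particles"].update({"n": str(cfg.n_particles), "potential": p.kind,
                            "epsilon": repr(p.epsilon), "re": repr(p.re),
                            "spring": repr(p.spring),
                            "seed": str(cfg.particle_seed),
                            "hemisphere": str(cfg.hemisphere).lower()})
    if cfg.coords_file:
        cp.set("particles", "coords_file", cfg.coords_file)
    pr = cfg.params
    cp["physics"].update({"kappa": repr(pr.kappa), "kappa_g": repr(pr.kappa_g),
                          "c0": repr(pr.C0), "pressure": repr(pr.pressure)})
    if pr.reduced_volume is not None:
        cp.set("physics", "reduced_volume", repr(pr.reduced_volume))
        cp.set("physics", "pressure", "0.0")
    cp["penalties"].update({"mu_area": repr(pr.mu_area),
                            "mu_mass": repr(pr.mu_mass),
                            "mu_volume": repr(pr.mu_volume),
                            "lambda_g": repr(pr.lambda_g)})
    cp["solver"].update({"tol": repr(cfg.tol), "max_iter": str(cfg.max_iter),
                         "quad_order": str(cfg.quad_order)})
    if cfg.continuation:
        key = next(iter(cfg.continuation[0]))
        cp.set("solver", "continuation",
               key + ": " + ", ".join(repr(s[key]) for s in cfg.continuation))
    cp["output"].update({"dir": cfg.output_dir, "refine": str(cfg.refine),
                         "checkpoint_every": str(cfg.checkpoint_every)})
    buf = _io.StringIO()
    cp.write(buf)
    return buf.getvalue()
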