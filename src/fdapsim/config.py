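"""Run configuration: YAML-backed, defaulting to the reference experiment.

The defaults reproduce the reference photoactivation setup: D = 3 um^2/s,
200 uM total actin, 65-ms pulse, first frame at 0.035 s, 25-s recording,
rounded 20/3.5/0.3-um cell with a 2-um ROI 10 um from the center, the
19 x 20 (F x K_dep) library grid, and the 0.05 s / 0.2 s fit grid.  Any
override is carried into output provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import geometry as geo
from .fitting import FitGrid
from .library import GridSpec
from .simulate import DEFAULT_LASER_RATE, SimulationParams, TimeStepping

__all__ = ["RunConfig", "load_config"]


@dataclass
class GeometryConfig:
    kind: str = "round_cell"          # round_cell | axon | projection_cell
    R: float = 20.0
    H: float = 3.5
    t_e: float = 0.3
    exponent: float = 2.0
    L: float = 40.0
    r_a: float = 0.5
    n_projections: int = 4
    proj_length: float = 25.0
    proj_radius: float = 0.75
    spacing: float = 0.35
    spacing_z: float = 0.2
    half_cell: bool = True
    roi_offset: float = 10.0
    roi_radius: float = 1.0

    def build(self):
        """Return (CellGeometry, ROISpec, VoxelGrid)."""
        if self.kind == "round_cell":
            g = geo.make_round_cell(self.R, self.H, self.t_e, self.exponent)
            roi = geo.ROISpec(center=(self.roi_offset, 0.0),
                              radius=self.roi_radius)
        elif self.kind == "axon":
            g, roi = geo.make_axon(self.L, self.r_a, self.roi_radius)
            # the thin axon needs finer cross-sectional resolution
            grid = geo.voxelize(g, min(self.spacing, self.r_a / 4),
                                half_cell=self.half_cell,
                                spacing_z=min(self.spacing_z, self.r_a / 4),
                                roi=roi)
            return g, roi, grid
        elif self.kind == "projection_cell":
            g = geo.make_projection_cell(self.R, self.n_projections,
                                         self.proj_length, self.proj_radius,
                                         body_height=self.H)
            roi = geo.projection_roi(g, radius=self.roi_radius)
        else:
            raise ValueError(f"geometry.kind: unknown kind {self.kind!r}")
        grid = geo.voxelize(g, self.spacing, half_cell=self.half_cell,
                            spacing_z=self.spacing_z, roi=roi)
        return g, roi, grid

    @property
    def geometry_id(self) -> str:
        if self.kind == "round_cell":
            return f"round_cell_{self.R:g}_{self.H:g}_{self.t_e:g}"
        if self.kind == "axon":
            return f"axon_{self.L:g}_{self.r_a:g}"
        return f"projection_{self.R:g}_{self.n_projections}"


@dataclass
class SimulationConfig:
    D: float = 3.0
    A_tot: float = 200.0
    F0: float = 100.0
    K_dep: float = 0.06
    t_pulse: float = 0.065
    laser_rate: float = DEFAULT_LASER_RATE
    t_post: float = 25.0
    t_norm: float = 0.035

    def params(self, **over) -> SimulationParams:
        d = dataclasses.asdict(self)
        d.update(over)
        return SimulationParams(**d)


@dataclass
class LibraryGridConfig:
    F_min: float = 10.0
    F_max: float = 190.0
    F_step: float = 10.0
    K_min: float = 0.01
    K_max: float = 0.20
    K_step: float = 0.01
    include_zero_K: bool = False

    def spec(self, sim: SimulationConfig, geometry_id: str) -> GridSpec:
        F = np.arange(self.F_min, self.F_max + 1e-9, self.F_step)
        K = np.round(np.arange(self.K_min, self.K_max + 1e-9, self.K_step), 10)
        if self.include_zero_K:
            K = np.concatenate([[0.0], K])
        if np.any(K < 0):
            raise ValueError("grid.K_min: negative K_dep is not allowed")
        return GridSpec(A_tot=sim.A_tot, F_values=tuple(F),
                        K_values=tuple(K), D=sim.D, geometry_id=geometry_id)


@dataclass
class FitConfig:
    breakpoint: float = 3.0
    fine_step: float = 0.05
    coarse_step: float = 0.2
    end: float = 25.0
    k: int = 9

    def grid(self) -> FitGrid:
        return FitGrid(breakpoint=self.breakpoint, fine_step=self.fine_step,
                       coarse_step=self.coarse_step, end=self.end)


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    grid: LibraryGridConfig = field(default_factory=LibraryGridConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 0
    verbosity: str = "INFO"
    overrides: dict = field(default_factory=dict)   # provenance

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("overrides", None)
        return d


_SECTIONS = {
    "geometry": GeometryConfig,
    "simulation": SimulationConfig,
    "grid": LibraryGridConfig,
    "fit": FitConfig,
}


def _build_section(cls, data: dict, section: str, strict: bool):
    valid = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in valid:
            if strict:
                raise ValueError(f"unknown config key {section}.{key}")
            continue
        want = valid[key].type
        if want in ("float", float) and isinstance(value, (int, float)) \
                and not isinstance(value, bool):
            value = float(value)
        elif want in ("int", int) and isinstance(value, bool):
            raise ValueError(f"type mismatch for {section}.{key}")
        elif want in ("int", int) and not isinstance(value, int):
            raise ValueError(f"type mismatch for {section}.{key}")
        elif want in ("float", float):
            raise ValueError(f"type mismatch for {section}.{key}")
        kwargs[key] = value
    return cls(**kwargs), set(kwargs)


def load_config(path=None, data: dict | None = None,
                strict: bool = True) -> RunConfig:
    """Load a YAML config; unspecified keys fall back to the defaults.

    Validation errors name the offending key.  ``data`` may be passed
    directly (already-parsed mapping) instead of a file path.
    """
    if data is None:
        if path is None:
            data = {}
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    cfg = RunConfig()
    overrides = {}
    for section, content in data.items():
        if section in ("seed", "verbosity"):
            if section == "seed" and not isinstance(content, int):
                raise ValueError("type mismatch for seed")
            setattr(cfg, section, content)
            overrides[section] = content
            continue
        if section not in _SECTIONS:
            if strict:
                raise ValueError(f"unknown config section {section!r}")
            continue
        if not isinstance(content, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        built, set_keys = _build_section(_SECTIONS[section], content,
                                         section, strict)
        setattr(cfg, section, built)
        for k in set_keys:
            overrides[f"{section}.{k}"] = content[k]
    cfg.overrides = overrides
    # cross-field validation with named keys
    if cfg.simulation.D < 0:
        raise ValueError("simulation.D must be non-negative")
    if not 0 <= cfg.simulation.F0 < cfg.simulation.A_tot:
        raise ValueError("simulation.F0 must satisfy 0 <= F0 < A_tot")
    if cfg.grid.K_min < 0:
        raise ValueError("grid.K_min must be non-negative")
    return cfg
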