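"""Simulation library: sweep of (F-actin concentration x K_dep) scenarios.

The default grid spans F = 10..190 uM in 10-uM steps (19 values, i.e. G:F
ratios 19:1 down to 1:19 at 200 uM total actin) and K_dep = 0.01..0.20 1/s
in 0.01 steps (20 values) — 380 scenarios.  Each cell stores the
first-frame-normalized ROI decay curve on a shared output time vector.
Libraries persist to a single HDF5 file with embedded JSON metadata and can
be exported as wide CSV for interoperability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .curves import DecayCurve
from .geometry import ROISpec, VoxelGrid
from .simulate import SimulationParams, Simulator

__all__ = [
    "GridSpec",
    "SimulationLibrary",
    "default_output_times",
    "generate_library",
    "complete_library",
    "save_library",
    "load_library",
]

FORMAT_VERSION = 1


def default_output_times(t_norm: float = 0.035, t_end: float = 25.0):
    """Shared output schedule: t_norm, then 30 Hz to 3 s, then 10 Hz."""
    fine = t_norm + np.arange(1, int(np.floor((3.0 - t_norm) * 30)) + 1) / 30.0
    coarse = np.arange(np.ceil(fine[-1] * 10 + 1) / 10, t_end + 1e-9, 0.1)
    return np.unique(np.concatenate([[t_norm], fine, coarse]))


@dataclass(frozen=True)
class GridSpec:
    """Parameter grid of the library (uM, 1/s)."""

    A_tot: float = 200.0
    F_values: tuple = tuple(np.arange(10.0, 190.0 + 1e-9, 10.0))
    K_values: tuple = tuple(np.round(np.arange(0.01, 0.20 + 1e-9, 0.01), 10))
    D: float = 3.0
    geometry_id: str = "round_cell_20_3.5_0.3"

    def __post_init__(self):
        F = np.asarray(self.F_values, dtype=float)
        K = np.asarray(self.K_values, dtype=float)
        if F.size == 0 or K.size == 0:
            raise ValueError("empty parameter grid")
        if np.any(F <= 0) or np.any(F >= self.A_tot):
            raise ValueError("need 0 < F < A_tot for every F value")
        if np.any(K < 0):
            raise ValueError("negative K_dep values are not allowed")
        object.__setattr__(self, "F_values", tuple(F))
        object.__setattr__(self, "K_values", tuple(K))

    @property
    def n_cells(self) -> int:
        return len(self.F_values) * len(self.K_values)

    def cells(self):
        """All (F, K_dep) pairs, F-major."""
        return [(F, K) for F in self.F_values for K in self.K_values]

    def ratio(self, F: float) -> float:
        return (self.A_tot - F) / F


@dataclass
class SimulationLibrary:
    """Grid of normalized decay curves on a shared time vector.

    ``values`` has shape (n_F, n_K, n_times); missing (not yet simulated)
    cells are NaN.
    """

    spec: GridSpec
    times: np.ndarray
    values: np.ndarray
    t_norm: float = 0.035
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        nF, nK = len(self.spec.F_values), len(self.spec.K_values)
        if self.values.shape != (nF, nK, self.times.size):
            raise ValueError("values shape inconsistent with grid and times")

    @property
    def n_curves(self) -> int:
        return int(np.isfinite(self.values).all(axis=2).sum())

    @property
    def complete(self) -> bool:
        return bool(np.isfinite(self.values).all())

    def missing_cells(self):
        miss = ~np.isfinite(self.values).all(axis=2)
        F, K = self.spec.F_values, self.spec.K_values
        return [(F[i], K[j]) for i, j in zip(*np.nonzero(miss))]

    def index_of(self, F: float, K_dep: float):
        i = int(np.argmin(np.abs(np.asarray(self.spec.F_values) - F)))
        j = int(np.argmin(np.abs(np.asarray(self.spec.K_values) - K_dep)))
        if abs(self.spec.F_values[i] - F) > 1e-6 or \
           abs(self.spec.K_values[j] - K_dep) > 1e-9:
            raise KeyError(f"({F}, {K_dep}) not on the library grid")
        return i, j

    def curve(self, F: float, K_dep: float) -> DecayCurve:
        i, j = self.index_of(F, K_dep)
        vals = self.values[i, j]
        if not np.isfinite(vals).all():
            raise KeyError(f"cell ({F}, {K_dep}) has not been simulated")
        return DecayCurve(self.times.copy(), vals.copy(), t_norm=self.t_norm,
                          meta={"F0": F, "K_dep": K_dep,
                                "ratio": self.spec.ratio(F)})

    def iter_curves(self):
        for i, F in enumerate(self.spec.F_values):
            for j, K in enumerate(self.spec.K_values):
                if np.isfinite(self.values[i, j]).all():
                    yield (F, K), self.values[i, j]

    def to_frame(self) -> pd.DataFrame:
        """Wide CSV-friendly table: one column per (F, K_dep) scenario."""
        cols = {"time_s": self.times}
        for (F, K), vals in self.iter_curves():
            cols[f"F{F:g}_K{K:g}"] = vals
        return pd.DataFrame(cols)


def _simulate_cell(sim: Simulator, spec: GridSpec, F: float, K: float,
                   times: np.ndarray, t_norm: float) -> np.ndarray:
    params = SimulationParams(D=spec.D, A_tot=spec.A_tot, F0=F, K_dep=K,
                              t_post=float(times[-1]), t_norm=t_norm)
    curve = sim.run(params).decay_curve(t_norm)
    return np.interp(times, curve.times, curve.values)


def generate_library(spec: GridSpec, grid: VoxelGrid, roi: ROISpec,
                     t_norm: float = 0.035, times: np.ndarray | None = None,
                     simulator: Simulator | None = None,
                     progress=None) -> SimulationLibrary:
    """Run one simulation per grid cell and collect the normalized curves.

    Deterministic given the grid and solver settings; cells are computed
    independently, so a partial library can be completed later with
    :func:`complete_library`.
    """
    times = default_output_times(t_norm) if times is None else np.asarray(times)
    sim = simulator or Simulator(grid, roi)
    nF, nK = len(spec.F_values), len(spec.K_values)
    values = np.full((nF, nK, times.size), np.nan)
    for i, F in enumerate(spec.F_values):
        for j, K in enumerate(spec.K_values):
            try:
                values[i, j] = _simulate_cell(sim, spec, F, K, times, t_norm)
            except Exception as exc:
                raise RuntimeError(
                    f"simulation failed at F={F} uM, K_dep={K} 1/s") from exc
            if progress is not None:
                progress(F, K)
    meta = {
        "geometry": grid.geometry.describe() if grid.geometry else {},
        "spacings": list(grid.spacings), "half_cell": grid.half_cell,
        "roi_center": list(roi.center), "roi_radius": roi.radius,
        "format_version": FORMAT_VERSION,
    }
    return SimulationLibrary(spec=spec, times=times, values=values,
                             t_norm=t_norm, meta=meta)


def complete_library(lib: SimulationLibrary, grid: VoxelGrid, roi: ROISpec,
                     simulator: Simulator | None = None) -> SimulationLibrary:
    """Fill in any missing (NaN) cells of a partially generated library."""
    sim = simulator or Simulator(grid, roi)
    for F, K in lib.missing_cells():
        i, j = lib.index_of(F, K)
        lib.values[i, j] = _simulate_cell(sim, lib.spec, F, K,
                                          lib.times, lib.t_norm)
    return lib


def save_library(lib: SimulationLibrary, path):
    """Persist to a single HDF5 file (curves + grid + JSON metadata)."""
    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = FORMAT_VERSION
        h5.attrs["t_norm"] = lib.t_norm
        h5.attrs["meta_json"] = json.dumps(lib.meta)
        h5.attrs["spec_json"] = json.dumps({
            "A_tot": lib.spec.A_tot, "D": lib.spec.D,
            "geometry_id": lib.spec.geometry_id})
        h5.create_dataset("times", data=lib.times)
        h5.create_dataset("F_values", data=np.asarray(lib.spec.F_values))
        h5.create_dataset("K_values", data=np.asarray(lib.spec.K_values))
        h5.create_dataset("curves", data=lib.values)


def load_library(path) -> SimulationLibrary:
    with h5py.File(path, "r") as h5:
        for key in ("times", "F_values", "K_values", "curves"):
            if key not in h5:
                raise ValueError(f"not a library file: missing dataset {key!r}")
        if "spec_json" not in h5.attrs or "meta_json" not in h5.attrs:
            raise ValueError("library file is missing metadata attributes")
        version = int(h5.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported library format version {version}")
        spec_d = json.loads(h5.attrs["spec_json"])
        spec = GridSpec(A_tot=spec_d["A_tot"],
                        F_values=tuple(h5["F_values"][...]),
                        K_values=tuple(h5["K_values"][...]),
                        D=spec_d["D"], geometry_id=spec_d["geometry_id"])
        return SimulationLibrary(
            spec=spec, times=h5["times"][...], values=h5["curves"][...],
            t_norm=float(h5.attrs["t_norm"]),
            meta=json.loads(h5.attrs["meta_json"]))
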