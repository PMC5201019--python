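"""Finite-difference sensitivity of library decay curves.

For each pair of adjacent library cells along one axis (F concentration or
K_dep) the differential curve is the absolute per-time-point difference of
the two normalized decay curves; averaging a differential curve over the
fit grid yields one scalar, and the collection of scalars over the whole
library is the sensitivity map.  High map values mean the curve shape
responds strongly to that parameter there, i.e. the fit is well
conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import FitGrid
from .library import SimulationLibrary

__all__ = ["SensitivityMap", "differential_curves", "time_averaged_sensitivity"]


@dataclass
class SensitivityMap:
    """Time-averaged sensitivity per adjacent parameter pair.

    ``matrix`` has shape (n_axis_values - 1, n_other_values); entry (i, j)
    is the averaged |curve difference| between axis values i and i+1 at the
    j-th value of the other axis.
    """

    axis: str                        # "F" | "K_dep"
    pairs: list                      # [(low, high), ...] along the axis
    other_values: np.ndarray
    matrix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        other = "K_dep" if self.axis == "F" else "F"
        rows = []
        for i, (lo, hi) in enumerate(self.pairs):
            for j, ov in enumerate(self.other_values):
                rows.append({"axis": self.axis, "pair_low": lo, "pair_high": hi,
                             other: ov, "sensitivity": self.matrix[i, j]})
        return pd.DataFrame(rows)


def _axis_arrays(library: SimulationLibrary, axis: str):
    F = np.asarray(library.spec.F_values)
    K = np.asarray(library.spec.K_values)
    if axis == "F":
        return F, K
    if axis == "K_dep":
        return K, F
    raise ValueError("axis must be 'F' or 'K_dep'")


def differential_curves(library: SimulationLibrary, axis: str,
                        fixed_value: float):
    """|Adjacent-cell curve differences| along ``axis`` at one fixed value
    of the other axis.

    Returns a list of ``(pair, times, diff)`` with ``pair`` the two axis
    values, ``diff`` the absolute difference per time point.
    """
    ax_vals, other_vals = _axis_arrays(library, axis)
    if ax_vals.size < 2:
        raise ValueError(f"axis {axis!r} has fewer than 2 values")
    j = int(np.argmin(np.abs(other_vals - fixed_value)))
    if abs(other_vals[j] - fixed_value) > 1e-9:
        raise KeyError(f"{fixed_value} not on the library grid")
    out = []
    for i in range(ax_vals.size - 1):
        if axis == "F":
            a = library.values[i, j]
            b = library.values[i + 1, j]
        else:
            a = library.values[j, i]
            b = library.values[j, i + 1]
        out.append(((float(ax_vals[i]), float(ax_vals[i + 1])),
                    library.times, np.abs(b - a)))
    return out


def time_averaged_sensitivity(library: SimulationLibrary, axis: str,
                              fit_grid: FitGrid | None = None) -> SensitivityMap:
    """Average each differential curve over the fit-grid time points.

    Differences are taken on the normalized curves — the quantities the
    fitter actually compares.
    """
    ax_vals, other_vals = _axis_arrays(library, axis)
    if ax_vals.size < 2:
        raise ValueError(f"axis {axis!r} has fewer than 2 values")
    grid = fit_grid or FitGrid(end=min(25.0, float(library.times[-1])))
    ts = grid.times(library.t_norm)
    ts = ts[(ts >= library.times[0] - 1e-9) & (ts <= library.times[-1] + 1e-9)]
    matrix = np.empty((ax_vals.size - 1, other_vals.size))
    for j, ov in enumerate(other_vals):
        for i, ((lo, hi), times, diff) in enumerate(
                differential_curves(library, axis, ov)):
            matrix[i, j] = np.interp(ts, times, diff).mean()
    pairs = [(float(ax_vals[i]), float(ax_vals[i + 1]))
             for i in range(ax_vals.size - 1)]
    return SensitivityMap(axis=axis, pairs=pairs,
                          other_values=other_vals.copy(), matrix=matrix)
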