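"""Decay-curve container, normalization and plain-text I/O.

A :class:`DecayCurve` holds the ROI-mean photoactivated-actin signal versus
time, with t = 0 at the end of the activation pulse.  Curves used for
fitting are dimensionless, normalized to 1 at ``t_norm`` (0.035 s by
default, the first frame recorded at 30 frames/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DecayCurve", "normalize_curve", "read_curve", "write_curve"]


@dataclass
class DecayCurve:
    times: np.ndarray                 # s, relative to pulse end, increasing
    values: np.ndarray                # dimensionless (or uM for raw curves)
    t_norm: float | None = None       # normalization time; None for raw curves
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if self.times.size < 2:
            raise ValueError("a decay curve needs at least two samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def value_at(self, t):
        """Linear interpolation of the curve (no extrapolation)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0] - 1e-12) or np.any(t > self.times[-1] + 1e-12):
            raise ValueError("requested time outside the curve support")
        return np.interp(t, self.times, self.values)

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def normalized(self, t_norm: float) -> "DecayCurve":
        return normalize_curve(self, t_norm)


def normalize_curve(curve, t_norm: float, values=None) -> DecayCurve:
    """Divide a raw curve by its (interpolated) value at ``t_norm``.

    Accepts either a :class:`DecayCurve` or a pair of arrays
    ``(times, values)``.
    """
    if values is not None:
        curve = DecayCurve(np.asarray(curve), np.asarray(values))
    ref = float(curve.value_at(t_norm))
    if ref <= 0:
        raise ValueError(f"normalizer at t={t_norm} s is non-positive ({ref})")
    return DecayCurve(curve.times.copy(), curve.values / ref,
                      t_norm=float(t_norm), meta=dict(curve.meta))


def read_curve(path, renormalize_at: float | None = None) -> DecayCurve:
    """Read a two-column (time_s, intensity) delimited text curve.

    Lines starting with '#' are comments; ``# key: value`` comments are
    collected into the curve metadata.  Comma or whitespace delimited, with
    an optional single header line.
    """
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.replace(",", " ").split()
            try:
                rows.append([float(p) for p in parts[:2]])
            except ValueError:
                if rows:
                    raise ValueError(f"malformed data line in {path}: {line!r}")
                continue  # header line
    if len(rows) < 2:
        raise ValueError(f"no data rows found in {path}")
    arr = np.asarray(rows)
    curve = DecayCurve(arr[:, 0], arr[:, 1], meta=meta)
    if renormalize_at is not None:
        curve = normalize_curve(curve, renormalize_at)
    else:
        # experimental convention: already normalized to the first frame
        curve.t_norm = float(curve.times[0])
    return curve


def write_curve(curve: DecayCurve, path, extra_meta: dict | None = None):
    """Write a curve as commented CSV (times in s, header block with '#')."""
    meta = dict(curve.meta)
    if extra_meta:
        meta.update(extra_meta)
    if curve.t_norm is not None:
        meta.setdefault("t_norm_s", curve.t_norm)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("time_s,intensity\n")
        pd.DataFrame({"t": curve.times, "v": curve.values}).to_csv(
            fh, header=False, index=False)
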