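"""Analytic 3-D cell shapes, voxelization and photoactivation-ROI placement.

All geometries sit on the substrate plane z = 0 with the cell center at the
origin; the cytoplasm occupies 0 <= z <= h(x, y).  Units are micrometres
throughout.

Three procedural shapes are provided:

* a rounded, fully spread cell whose height falls from ``H`` at the center to
  the lamellipodium thickness ``t_e`` at the edge following a smooth dome
  profile ``h(r) = t_e + (H - t_e) * (1 - (r/R)**2)**p``,
* an axon-like cylinder of radius ``r_a`` lying on the substrate, and
* an amoeboid body with several long, narrow cylindrical projections.

An arbitrary occupancy mask can be wrapped in a :class:`CellGeometry` of kind
``"mask"`` for shapes imported from segmented images.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellGeometry",
    "ROISpec",
    "VoxelGrid",
    "make_round_cell",
    "make_axon",
    "make_projection_cell",
    "make_mask_geometry",
    "projection_roi",
    "voxelize",
]

_DEFAULT_DOME_EXPONENT = 2.0


@dataclass(frozen=True)
class CellGeometry:
    """Analytic membrane-bounded cytoplasm with a point-membership predicate.

    Only the fields relevant to ``kind`` are meaningful; the rest stay at
    their defaults.
    """

    kind: str  # "round_cell" | "axon" | "projection_cell" | "mask"
    R: float = 0.0           # round/projection body radius
    H: float = 0.0           # center height
    t_e: float = 0.0         # edge (lamellipodium) thickness
    exponent: float = _DEFAULT_DOME_EXPONENT
    L: float = 0.0           # axon length
    r_a: float = 0.0         # axon radius
    n_projections: int = 0
    proj_length: float = 0.0
    proj_radius: float = 0.0
    mask: np.ndarray | None = None        # for kind == "mask"
    mask_spacings: tuple | None = None    # (hx, hy, hz) of the imported mask

    # ---- analytic profile -------------------------------------------------

    def height_at(self, r):
        """Dome height profile h(r) for round-cell-like shapes."""
        if self.kind not in ("round_cell", "projection_cell"):
            raise ValueError(f"height_at undefined for kind={self.kind!r}")
        r = np.asarray(r, dtype=float)
        u = np.clip((r / self.R) ** 2, 0.0, 1.0)
        return self.t_e + (self.H - self.t_e) * (1.0 - u) ** self.exponent

    def contains(self, x, y, z):
        """Vectorized point-membership predicate for the cytoplasm."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        if self.kind == "round_cell":
            r = np.hypot(x, y)
            return (r < self.R) & (z >= 0.0) & (z < self.height_at(r))
        if self.kind == "axon":
            # cylinder along x, axis at (y=0, z=r_a), resting on the substrate
            return (
                (x >= 0.0)
                & (x < self.L)
                & (y**2 + (z - self.r_a) ** 2 < self.r_a**2)
            )
        if self.kind == "projection_cell":
            r = np.hypot(x, y)
            inside = (r < self.R) & (z >= 0.0) & (z < self.height_at(r))
            for theta in self._projection_angles():
                ux, uy = np.cos(theta), np.sin(theta)
                s = x * ux + y * uy            # axial coordinate
                d = -x * uy + y * ux           # in-plane perpendicular
                in_cyl = (
                    (s >= self.R - self.proj_radius)
                    & (s < self.R + self.proj_length)
                    & (d**2 + (z - self.proj_radius) ** 2 < self.proj_radius**2)
                )
                inside = inside | in_cyl
            return inside
        if self.kind == "mask":
            hx, hy, hz = self.mask_spacings
            nx, ny, nz = self.mask.shape
            i = np.floor(x / hx + nx / 2).astype(int)
            j = np.floor(y / hy + ny / 2).astype(int)
            k = np.floor(z / hz).astype(int)
            ok = (i >= 0) & (i < nx) & (j >= 0) & (j < ny) & (k >= 0) & (k < nz)
            out = np.zeros(np.broadcast(x, y, z).shape, dtype=bool)
            out[ok] = self.mask[i[ok], j[ok], k[ok]]
            return out
        raise ValueError(f"unknown geometry kind {self.kind!r}")

    def _projection_angles(self):
        n = self.n_projections
        return [2.0 * np.pi * k / n for k in range(n)] if n else []

    def bounding_box(self):
        """((xmin, xmax), (ymin, ymax), (zmin, zmax)) enclosing the cytoplasm."""
        if self.kind == "round_cell":
            return (-self.R, self.R), (-self.R, self.R), (0.0, self.H)
        if self.kind == "axon":
            return (0.0, self.L), (-self.r_a, self.r_a), (0.0, 2.0 * self.r_a)
        if self.kind == "projection_cell":
            ext = self.R + self.proj_length
            zmax = max(self.H, 2.0 * self.proj_radius)
            return (-ext, ext), (-ext, ext), (0.0, zmax)
        if self.kind == "mask":
            hx, hy, hz = self.mask_spacings
            nx, ny, nz = self.mask.shape
            return (
                (-nx * hx / 2, nx * hx / 2),
                (-ny * hy / 2, ny * hy / 2),
                (0.0, nz * hz),
            )
        raise ValueError(f"unknown geometry kind {self.kind!r}")

    def min_feature(self):
        """Smallest geometric length that the voxel grid must resolve."""
        if self.kind == "round_cell":
            return self.t_e
        if self.kind == "axon":
            return self.r_a
        if self.kind == "projection_cell":
            return min(self.t_e, self.proj_radius)
        return min(self.mask_spacings) if self.mask_spacings else np.inf

    def describe(self):
        d = {"kind": self.kind}
        for f in dataclasses.fields(self):
            if f.name in ("kind", "mask", "mask_spacings"):
                continue
            v = getattr(self, f.name)
            if v:
                d[f.name] = v
        return d


@dataclass(frozen=True)
class ROISpec:
    """Photoactivated region: a vertical cylinder through the cytoplasm.

    ``center`` is the (x, y) offset of the cylinder axis from the cell
    center; the cylinder spans the full local cell height.
    """

    center: tuple = (10.0, 0.0)
    radius: float = 1.0
    shape: str = "cylinder"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")
        if self.shape != "cylinder":
            raise ValueError("only through-cytoplasm cylinder ROIs are supported")

    def mask(self, grid: "VoxelGrid") -> np.ndarray:
        """Boolean mask over the grid's interior voxels (flat, interior order)."""
        m = self.weights(grid) > 0
        if not m.any():
            raise ValueError("ROI does not overlap any interior voxel")
        return m

    def weights(self, grid: "VoxelGrid", supersample: int = 4) -> np.ndarray:
        """Fractional in-plane coverage of each interior voxel by the ROI disc.

        Computed by ``supersample x supersample`` sub-sampling of each voxel
        footprint; boundary voxels get partial weight, which removes most of
        the staircase discretization error of the activation disc.
        """
        x0, y0 = self.center
        hx, hy, _ = grid.spacings
        offs = ((np.arange(supersample) + 0.5) / supersample - 0.5)
        Xc, Yc = np.meshgrid(grid.x, grid.y, indexing="ij")
        cover = np.zeros(Xc.shape)
        for ox in offs * hx:
            for oy in offs * hy:
                cover += ((Xc + ox - x0) ** 2 + (Yc + oy - y0) ** 2
                          <= self.radius**2)
        cover /= supersample**2
        w3 = np.repeat(cover[:, :, None], grid.z.size, axis=2)
        return w3[grid.mask]


@dataclass
class VoxelGrid:
    """Regular rectangular voxelization of a cell geometry.

    ``mask`` marks cytoplasm voxels (decided at voxel centers).  With
    ``half_cell`` set, only the y >= 0 half is represented and the plane
    y = 0 acts as a mirror (zero-flux) boundary; it must contain both the
    cell center and the ROI axis.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    mask: np.ndarray           # 3-D bool, shape (nx, ny, nz)
    spacings: tuple            # (hx, hy, hz)
    half_cell: bool = False
    geometry: CellGeometry | None = None

    @property
    def n_interior(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume(self) -> float:
        hx, hy, hz = self.spacings
        return hx * hy * hz

    @property
    def interior_volume(self) -> float:
        """Voxel-counted cytoplasm volume (doubled when half_cell)."""
        v = self.n_interior * self.voxel_volume
        return 2.0 * v if self.half_cell else v

    def center_arrays(self):
        return np.meshgrid(self.x, self.y, self.z, indexing="ij")

    def interior_points(self) -> np.ndarray:
        X, Y, Z = self.center_arrays()
        return np.column_stack([X[self.mask], Y[self.mask], Z[self.mask]])


def make_round_cell(R: float, H: float, t_e: float,
                    exponent: float = _DEFAULT_DOME_EXPONENT) -> CellGeometry:
    """Rounded spread cell: dome profile h(0) = H falling to h(R) = t_e."""
    if R <= 0 or H <= 0:
        raise ValueError("R and H must be positive")
    if not 0 < t_e <= H:
        raise ValueError("edge thickness must satisfy 0 < t_e <= H")
    return CellGeometry(kind="round_cell", R=R, H=H, t_e=t_e, exponent=exponent)


def make_axon(L: float, r_a: float, roi_radius: float,
              roi_position: float | None = None):
    """Axon-like cylinder plus its photoactivation ROI (mid-length default)."""
    if L <= 0 or r_a <= 0:
        raise ValueError("axon length and radius must be positive")
    if roi_radius <= 0:
        raise ValueError("ROI radius must be positive")
    if roi_radius > r_a:
        raise ValueError("ROI radius exceeds the axon radius")
    pos = L / 2.0 if roi_position is None else roi_position
    if pos < 2 * roi_radius or pos > L - 2 * roi_radius:
        raise ValueError("ROI must sit at least 2 radii from either axon end")
    geom = CellGeometry(kind="axon", L=L, r_a=r_a)
    roi = ROISpec(center=(pos, 0.0), radius=roi_radius)
    return geom, roi


def make_projection_cell(body_radius: float, n_projections: int,
                         proj_length: float = 0.0, proj_radius: float = 0.0,
                         body_height: float = 3.0,
                         edge_thickness: float | None = None) -> CellGeometry:
    """Amoeboid body plus ``n_projections`` radial narrow cylinders.

    Projections rest on the substrate (axis height = proj_radius) and start
    just inside the body rim so the domain stays connected.  With
    ``n_projections == 0`` this degenerates to the round body alone.
    """
    if body_radius <= 0 or body_height <= 0:
        raise ValueError("body dimensions must be positive")
    if n_projections < 0:
        raise ValueError("n_projections must be non-negative")
    if n_projections > 0 and (proj_length <= 0 or proj_radius <= 0):
        raise ValueError("projection dimensions must be positive")
    if edge_thickness is None:
        edge_thickness = min(body_height,
                             2.0 * proj_radius if n_projections else body_height)
    if n_projections and edge_thickness < 2.0 * proj_radius:
        raise ValueError(
            "body rim thinner than the projection diameter: domain disconnected")
    return CellGeometry(
        kind="projection_cell", R=body_radius, H=body_height,
        t_e=edge_thickness, n_projections=n_projections,
        proj_length=proj_length, proj_radius=proj_radius)


def projection_roi(geom: CellGeometry, frac: float = 0.5,
                   radius: float = 1.0) -> ROISpec:
    """ROI inside the +x projection, a fraction ``frac`` along its length."""
    if geom.kind != "projection_cell" or geom.n_projections == 0:
        raise ValueError("geometry has no projections")
    return ROISpec(center=(geom.R + frac * geom.proj_length, 0.0), radius=radius)


def make_mask_geometry(mask: np.ndarray, spacings) -> CellGeometry:
    """Wrap an imported 3-D occupancy array (e.g. from a segmented image)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3 or not mask.any():
        raise ValueError("mask must be a non-empty 3-D boolean array")
    return CellGeometry(kind="mask", mask=mask,
                        mask_spacings=tuple(float(s) for s in spacings))


def voxelize(geometry: CellGeometry, spacing: float,
             half_cell: bool = False, spacing_z: float | None = None,
             roi: ROISpec | None = None) -> VoxelGrid:
    """Voxelize a geometry on a regular grid with voxel-center membership.

    ``spacing`` is the in-plane voxel size; ``spacing_z`` (default: equal)
    the axial one.  The grid is laid out so that x = 0 and y = 0 fall on
    voxel boundaries, which makes the half-cell mirror plane y = 0 exact.
    Raises if the spacing cannot resolve the thinnest geometric feature or
    the ROI radius.
    """
    hx = hy = float(spacing)
    hz = float(spacing_z) if spacing_z is not None else float(spacing)
    if hx <= 0 or hz <= 0:
        raise ValueError("spacing must be positive")
    feat = geometry.min_feature()
    if hz >= feat and geometry.kind in ("round_cell", "projection_cell"):
        raise ValueError(
            f"axial spacing {hz} um cannot resolve edge thickness {feat} um")
    if geometry.kind == "axon" and min(hy, hz) >= geometry.r_a:
        raise ValueError(
            f"spacing {min(hy, hz)} um cannot resolve axon radius {geometry.r_a} um")
    if roi is not None and hx >= roi.radius:
        raise ValueError(
            f"in-plane spacing {hx} um cannot resolve ROI radius {roi.radius} um")

    (x0, x1), (y0, y1), (z0, z1) = geometry.bounding_box()

    def _axis(lo, hi, h, symmetric):
        if symmetric:
            n = int(np.ceil(max(abs(lo), abs(hi)) / h))
            return (np.arange(-n, n) + 0.5) * h
        n = int(np.ceil((hi - lo) / h))
        return lo + (np.arange(n) + 0.5) * h

    x = _axis(x0, x1, hx, symmetric=geometry.kind != "axon")
    if half_cell:
        y = (np.arange(int(np.ceil(y1 / hy))) + 0.5) * hy
    else:
        y = _axis(y0, y1, hy, symmetric=True)
    z = (np.arange(int(np.ceil((z1 - z0) / hz))) + 0.5) * hz

    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    mask = geometry.contains(X, Y, Z)
    if not mask.any():
        raise ValueError("voxelization produced an empty interior")
    return VoxelGrid(x=x, y=y, z=z, mask=mask, spacings=(hx, hy, hz),
                     half_cell=half_cell, geometry=geometry)
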