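"""Voxel phantom: density, body mask, material labels and the MPAX.

The phantom is a regular lattice (same conventions as
:class:`~oofdose.grids.DoseGrid`) carrying a mass density per voxel
(g/cm^3), a boolean body mask, and a material label per voxel.  Lung
voxels have 0.25 times the soft-tissue density, the density-scaling rule
used to compute radiological depth through the chest.

The MPAX (medial patient axis) is the ordered longitudinal midline of the
body along which profiles are reported; here it is a straight longitudinal
line through the isocenter's transverse position (configurable), ordered
inferior to superior.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .grids import DoseGrid, GridError
from .raytrace import SOFT_TISSUE_DENSITY, OutsideGridError, path_integral

MATERIALS = {"air": 0, "soft_tissue": 1, "lung": 2}
LUNG_RELATIVE_DENSITY = 0.25  # lung rho = 0.25 x soft tissue


@dataclass
class SourcePoint:
    """The X-ray producing target position for a given gantry angle.

    Room coordinates, cm.  Located at the source-axis distance from the
    isocenter; gantry 0 deg places the source anterior (+y), rotating
    about the longitudinal axis (IEC convention, viewed from the couch foot).
    """

    position: np.ndarray

    @classmethod
    def from_gantry_angle(cls, gantry_deg: float, sad: float = 100.0) -> "SourcePoint":
        g = np.deg2rad(gantry_deg)
        return cls(position=np.array([sad * np.sin(g), sad * np.cos(g), 0.0]))


@dataclass
class VoxelPhantom:
    """Density grid + body mask + material labels + MPAX polyline."""

    density: np.ndarray          # g/cm^3, (nx, ny, nz)
    body_mask: np.ndarray        # bool, same shape
    material: np.ndarray         # int labels per MATERIALS, same shape
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mpax: np.ndarray | None = None   # (n, 3) ordered inferior -> superior

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        self.body_mask = np.asarray(self.body_mask, dtype=bool)
        self.material = np.asarray(self.material, dtype=np.int8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if not (self.density.shape == self.body_mask.shape == self.material.shape):
            raise GridError("density, body_mask and material must share one shape")
        if np.any(self.density[~self.body_mask] != 0):
            raise GridError("density must be 0 outside the body mask")
        if self.mpax is not None:
            self.mpax = np.atleast_2d(np.asarray(self.mpax, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.density.shape

    def grid_like(self, values: np.ndarray, unit: str = "Gy") -> DoseGrid:
        return DoseGrid(values, self.spacing, self.origin, unit)

    def same_lattice(self, grid: DoseGrid) -> bool:
        return (
            self.shape == grid.shape
            and self.spacing == grid.spacing
            and self.origin == grid.origin
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)
        hi = lo + np.asarray(self.spacing) * np.asarray(self.shape)
        return lo, hi

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def contains(self, points: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds()
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.all((pts >= lo) & (pts < hi), axis=1)

    # -- I/O ---------------------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("density", data=self.density)
            f.create_dataset("body_mask", data=self.body_mask)
            f.create_dataset("material", data=self.material)
            if self.mpax is not None:
                f.create_dataset("mpax", data=self.mpax)
            f.attrs["spacing"] = self.spacing
            f.attrs["origin"] = self.origin

    @classmethod
    def load(cls, path) -> "VoxelPhantom":
        with h5py.File(path, "r") as f:
            return cls(
                density=f["density"][()],
                body_mask=f["body_mask"][()],
                material=f["material"][()],
                spacing=tuple(f.attrs["spacing"]),
                origin=tuple(f.attrs["origin"]),
                mpax=f["mpax"][()] if "mpax" in f else None,
            )


def radiological_depth(
    source: SourcePoint, point, phantom: VoxelPhantom
) -> float:
    """Soft-tissue-equivalent depth (cm) from the source to ``point``.

    Line integral of density / soft-tissue density along the segment from
    the phantom entry to the point; 0 if the segment never enters the body
    before reaching the point.
    """
    pt = np.asarray(point, dtype=float)
    if not phantom.contains(pt)[0]:
        raise OutsideGridError(f"point {pt} outside phantom grid bounds")
    d = path_integral(source.position, pt, phantom.density,
                      phantom.spacing, phantom.origin)
    return float(d[0]) / SOFT_TISSUE_DENSITY


def radiological_depths(
    source: SourcePoint, points: np.ndarray, phantom: VoxelPhantom
) -> np.ndarray:
    """Vectorized :func:`radiological_depth` over an (n, 3) point array."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = path_integral(source.position, pts, phantom.density,
                      phantom.spacing, phantom.origin)
    return d / SOFT_TISSUE_DENSITY


def mpax_profile(grid: DoseGrid, phantom: VoxelPhantom):
    """Sample ``grid`` along the phantom's MPAX, inferior to superior.

    Returns an array of (longitudinal position cm, value) rows, one per
    MPAX point, read by trilinear interpolation.
    """
    if not phantom.same_lattice(grid):
        raise GridError("grid lattice does not match phantom lattice")
    if phantom.mpax is None or len(phantom.mpax) == 0:
        return np.empty((0, 2))
    pts = phantom.mpax[np.argsort(phantom.mpax[:, 2], kind="stable")]
    vals = grid.sample(pts)
    return np.column_stack([pts[:, 2], vals])
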