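"""Regular-lattice scalar dose grids.

A :class:`DoseGrid` is a 3D scalar field (absorbed dose in Gy, dose
equivalent in Sv, or a mean photon energy in MeV) sampled at voxel centers
on a regular lattice.  Room coordinates are used throughout the package:
the isocenter is the origin, ``z`` is the longitudinal (inferior->superior)
patient axis, and all lengths are in cm.  Voxel ``(0, 0, 0)`` has its
center at ``origin``; off-lattice values are obtained by trilinear
interpolation.

Two grids are combinable (addable, comparable voxel-by-voxel) only if
their lattices -- shape, spacing and origin -- match exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.ndimage import map_coordinates

VALID_UNITS = ("Gy", "Sv", "MeV")


class GridError(ValueError):
    """Raised for invalid grid definitions or incompatible lattices."""


@dataclass
class DoseGrid:
    """Scalar field on a regular voxel lattice with physical spacing/origin.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        One scalar per voxel; finite and non-negative.
    spacing : tuple of float
        Voxel spacing ``(dx, dy, dz)`` in cm, strictly positive.
    origin : tuple of float
        Room coordinates (cm) of the center of voxel ``(0, 0, 0)``.
    unit : str
        One of ``"Gy"``, ``"Sv"`` or ``"MeV"``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "Gy"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise GridError(f"values must be 3D, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise GridError("grid values must be finite")
        if np.any(self.values < 0):
            raise GridError("grid values must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GridError(f"spacing must be three positive lengths, got {self.spacing}")
        if self.unit not in VALID_UNITS:
            raise GridError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")

    # -- lattice geometry --------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def same_lattice(self, other: "DoseGrid") -> bool:
        return (
            self.shape == other.shape
            and self.spacing == other.spacing
            and self.origin == other.origin
        )

    def require_same_lattice(self, other: "DoseGrid") -> None:
        if not self.same_lattice(other):
            raise GridError(
                "grids are combinable only on identical lattices: "
                f"{self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1D coordinate arrays of voxel centers along each axis (cm)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of room-coordinate points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical grid extent (cm): outer voxel faces, half-open convention."""
        lo = np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)
        hi = lo + np.asarray(self.spacing) * np.asarray(self.shape)
        return lo, hi

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at room-coordinate ``points`` (n, 3)."""
        idx = self.to_index(points)
        return map_coordinates(self.values, idx.T, order=1, mode="nearest")

    # -- arithmetic --------------------------------------------------------

    def copy_with(self, values: np.ndarray, unit: str | None = None) -> "DoseGrid":
        return DoseGrid(values, self.spacing, self.origin, unit or self.unit)

    def __add__(self, other: "DoseGrid") -> "DoseGrid":
        self.require_same_lattice(other)
        if self.unit != other.unit:
            raise GridError(f"cannot add {self.unit} grid to {other.unit} grid")
        return self.copy_with(self.values + other.values)

    def scaled(self, factor: float) -> "DoseGrid":
        if factor < 0:
            raise GridError("scale factor must be non-negative")
        return self.copy_with(self.values * factor)

    # -- I/O ---------------------------------------------------------------

    def save(self, path) -> None:
        """Write the grid to a self-describing HDF5 container (bit-exact)."""
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.attrs["spacing"] = self.spacing
            f.attrs["origin"] = self.origin
            f.attrs["unit"] = self.unit

    @classmethod
    def load(cls, path) -> "DoseGrid":
        with h5py.File(path, "r") as f:
            return cls(
                values=f["values"][()],
                spacing=tuple(f.attrs["spacing"]),
                origin=tuple(f.attrs["origin"]),
                unit=str(f.attrs["unit"]),
            )

    @classmethod
    def from_dicom_rtdose(cls, path) -> "DoseGrid":
        """Import a DICOM RT Dose file into the internal grid format.

        The DICOM frame is mapped as stored: pixel spacing (mm) and the
        GridFrameOffsetVector give the lattice; values are scaled by
        DoseGridScaling.  Lengths are converted mm -> cm.
        """
        import pydicom

        ds = pydicom.dcmread(path)
        scaling = float(getattr(ds, "DoseGridScaling", 1.0))
        # DICOM stores frames as (z, y, x); transpose to (x, y, z).
        arr = ds.pixel_array.astype(float) * scaling
        values = np.transpose(arr, (2, 1, 0))
        dy, dx = (float(v) for v in ds.PixelSpacing)
        offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
        dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
        ox, oy, oz = (float(v) for v in ds.ImagePositionPatient)
        unit = "Gy" if getattr(ds, "DoseUnits", "GY").upper() == "GY" else "Sv"
        return cls(
            values=values,
            spacing=(dx / 10.0, dy / 10.0, dz / 10.0),
            origin=(ox / 10.0, oy / 10.0, oz / 10.0),
            unit=unit,
        )


def zeros_like(grid: DoseGrid, unit: str | None = None) -> DoseGrid:
    return DoseGrid(np.zeros(grid.shape), grid.spacing, grid.origin, unit or grid.unit)
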