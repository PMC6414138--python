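"""Whole-body imaging dose of a full-trajectory kV cone-beam CT.

The dose of a full-rotation CBCT is, to first approximation, homogeneous
within a transversal slice, so the 3D imaging dose is built by
interpolating per-slice mean doses along the longitudinal (MPAX) axis:
every voxel of a transversal grid slice receives the same value.  Beyond
the last sampled slice the dose decays exponentially with a configurable
tail length, reflecting the measured falloff outside the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import DoseGrid
from .phantom import VoxelPhantom


class CbctProfileError(ValueError):
    """Invalid per-slice dose profile."""


@dataclass
class CbctProfile:
    """Per-slice mean CBCT doses plus field-of-view geometry.

    slice_positions : longitudinal positions (cm), strictly increasing.
    slice_mean_dose : Gy per scan, one per position.
    fov_longitudinal : +- cm covered by the scan from the isocenter.
    fov_diameter : transversal field-of-view, cm.
    tail_decay_length : cm, exponential falloff outside the sampled range.
    """

    slice_positions: np.ndarray
    slice_mean_dose: np.ndarray
    fov_longitudinal: float = 8.75
    fov_diameter: float = 46.5
    tail_decay_length: float = 6.0

    def __post_init__(self) -> None:
        self.slice_positions = np.asarray(self.slice_positions, dtype=float)
        self.slice_mean_dose = np.asarray(self.slice_mean_dose, dtype=float)
        if self.slice_positions.ndim != 1 or len(self.slice_positions) == 0:
            raise CbctProfileError("slice_positions must be a non-empty 1D array")
        if len(self.slice_positions) != len(self.slice_mean_dose):
            raise CbctProfileError("positions and doses must have equal length")
        if np.any(np.diff(self.slice_positions) <= 0):
            raise CbctProfileError("slice_positions must be strictly increasing")
        if np.any(self.slice_mean_dose < 0):
            raise CbctProfileError("slice doses must be non-negative")
        if self.fov_longitudinal <= 0 or self.tail_decay_length <= 0:
            raise CbctProfileError("FOV extent and tail length must be positive")

    def dose_at(self, z: np.ndarray) -> np.ndarray:
        """Per-scan slice dose at longitudinal position(s) z (cm):
        linear interpolation inside the sampled range, exponential tail
        outside it."""
        z = np.asarray(z, dtype=float)
        pos, dose = self.slice_positions, self.slice_mean_dose
        out = np.interp(z, pos, dose)
        below = z < pos[0]
        above = z > pos[-1]
        out = np.where(below, dose[0] * np.exp(-(pos[0] - z) / self.tail_decay_length), out)
        out = np.where(above, dose[-1] * np.exp(-(z - pos[-1]) / self.tail_decay_length), out)
        return out

    # -- CSV interface -----------------------------------------------------

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"position_cm": self.slice_positions, "mean_dose_gy": self.slice_mean_dose}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CbctProfile":
        df = pd.read_csv(path)
        return cls(df["position_cm"].to_numpy(), df["mean_dose_gy"].to_numpy(), **kwargs)


def default_pelvis_profile() -> CbctProfile:
    """Synthetic per-slice doses for a full-trajectory pelvis CBCT:
    a flat ~20 mGy plateau across the +-8.75 cm field of view with soft
    shoulders at the sampled edges.  Stands in for a measured profile,
    which is a required input for real use."""
    positions = np.arange(-10.0, 10.1, 2.5)
    plateau = 0.020  # Gy per scan
    dose = np.where(np.abs(positions) <= 8.75, plateau, 0.6 * plateau)
    return CbctProfile(positions, dose)


def cbct_dose_grid(profile: CbctProfile, phantom: VoxelPhantom) -> DoseGrid:
    """Per-scan 3D CBCT dose (Gy): constant within each transversal slice
    inside the body, zero outside the body mask."""
    _, _, zs = phantom.voxel_centers()
    slice_dose = profile.dose_at(zs)
    arr = np.broadcast_to(
        slice_dose[None, None, :], phantom.shape
    ).copy()
    arr[~phantom.body_mask] = 0.0
    return phantom.grid_like(arr, unit="Gy")


def scale_by_sessions(grid: DoseGrid, n_sessions: int) -> DoseGrid:
    """Voxelwise multiplication by the number of imaging sessions."""
    if n_sessions < 0:
        raise ValueError("n_sessions must be non-negative")
    return grid.scaled(float(n_sessions))
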