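"""Dose fusion, whole-body dose equivalent, DEVHs and deviation statistics.

Treatment planning systems are accurate near the target but unreliable
in the far out-of-field region, while the analytical stray model is
built for the out-of-field region only.  The two are therefore fused at
a longitudinal boundary a fixed distance (default 4 cm) from the
treatment volume: inside the boundary the planning-system dose is used,
beyond it the stray-model dose.  The per-session photon, neutron and
imaging doses are then summed voxelwise (photon Gy counted as Sv with
radiation weighting factor 1) and multiplied by the number of sessions
to give the dose equivalent per treatment.

Plan comparisons use cumulative dose-equivalent volume histograms
(DEVHs): the fraction of the body volume receiving at least each dose
level, on logarithmically spaced dose bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import DoseGrid, GridError


@dataclass
class FusionSpec:
    """Target-volume mask plus the longitudinal fusion boundary (cm)."""

    target_mask: np.ndarray
    boundary_distance: float = 4.0

    def __post_init__(self) -> None:
        self.target_mask = np.asarray(self.target_mask, dtype=bool)
        if self.boundary_distance <= 0:
            raise ValueError("boundary_distance must be positive")
        if not self.target_mask.any():
            raise ValueError("target mask is empty")

    def inner_region(self, grid: DoseGrid) -> np.ndarray:
        """Boolean mask of voxels with longitudinal distance < boundary
        from the target volume (these take the planning-system dose)."""
        if self.target_mask.shape != grid.shape:
            raise GridError("target mask shape does not match grid")
        _, _, zs = grid.voxel_centers()
        z_target = zs[self.target_mask.any(axis=(0, 1))]
        z_lo, z_hi = z_target.min(), z_target.max()
        dist = np.maximum.reduce([z_lo - zs, zs - z_hi, np.zeros_like(zs)])
        return np.broadcast_to((dist < self.boundary_distance)[None, None, :],
                               grid.shape)


@dataclass
class SeamReport:
    """Relative dose step across the fusion boundary plane(s)."""

    mean_relative_step: float
    max_relative_step: float
    n_voxels: int


def fuse(
    tps_grid: DoseGrid,
    stray_grid: DoseGrid,
    spec: FusionSpec,
    body_mask: np.ndarray | None = None,
    return_seam: bool = False,
):
    """Hard-switch fusion of planning-system and stray-model dose.

    Voxels with longitudinal distance < boundary from the target volume
    take the planning-system value; all others the stray-model value.
    With ``return_seam`` also returns a :class:`SeamReport` of the
    relative step |tps - stray| / max(tps, stray) evaluated on the
    boundary-adjacent slices (restricted to ``body_mask`` if given).
    """
    tps_grid.require_same_lattice(stray_grid)
    inner = spec.inner_region(tps_grid)
    fused = tps_grid.copy_with(
        np.where(inner, tps_grid.values, stray_grid.values)
    )
    if not return_seam:
        return fused
    inner_z = inner[0, 0, :]
    seam_slices = np.flatnonzero(np.diff(inner_z.astype(int)) != 0)
    sel = np.zeros(tps_grid.shape, dtype=bool)
    for k in seam_slices:
        sel[:, :, k] = True
        sel[:, :, k + 1] = True
    if body_mask is not None:
        sel &= body_mask
    t = tps_grid.values[sel]
    s = stray_grid.values[sel]
    denom = np.maximum(np.maximum(t, s), 1e-300)
    rel = np.abs(t - s) / denom
    keep = (t > 0) | (s > 0)
    rel = rel[keep]
    report = SeamReport(
        mean_relative_step=float(rel.mean()) if rel.size else 0.0,
        max_relative_step=float(rel.max()) if rel.size else 0.0,
        n_voxels=int(rel.size),
    )
    return fused, report


def total_dose_equivalent(
    photon_fused: DoseGrid,
    neutron: DoseGrid | None,
    cbct: DoseGrid | None,
    n_fractions: int,
) -> DoseGrid:
    """Per-treatment dose equivalent (Sv): (photon + neutron + cbct) per
    session/scan, times the number of sessions.  Photon Gy enters with
    radiation weighting factor 1; neutron grids are dose equivalent
    already."""
    if n_fractions < 0:
        raise ValueError("n_fractions must be non-negative")
    total = photon_fused.values.copy()
    for other in (neutron, cbct):
        if other is not None:
            photon_fused.require_same_lattice(other)
            total = total + other.values
    return DoseGrid(total * n_fractions, photon_fused.spacing,
                    photon_fused.origin, unit="Sv")


@dataclass
class DEVH:
    """Cumulative dose-equivalent volume histogram.

    ``volume_fraction[i]`` is the fraction of the masked volume receiving
    at least ``dose_edges[i]``; non-increasing in dose, 1 at 0 Sv.
    """

    dose_edges: np.ndarray
    volume_fraction: np.ndarray
    n_voxels: int
    unit: str = "Sv"

    def fraction_at(self, dose: float) -> float:
        """Volume fraction receiving at least ``dose`` (interpolated)."""
        if dose <= self.dose_edges[0]:
            return 1.0
        if dose > self.dose_edges[-1]:
            return 0.0
        return float(np.interp(dose, self.dose_edges, self.volume_fraction))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"dose": self.dose_edges, "volume_fraction": self.volume_fraction}
        ).to_csv(path, index=False)


def devh(
    grid: DoseGrid,
    mask: np.ndarray,
    n_bins: int = 200,
    dose_floor: float = 1e-4,
) -> DEVH:
    """Cumulative DEVH of ``grid`` over ``mask``: log-spaced dose bins from
    ``dose_floor`` to the grid maximum, preceded by a 0-dose edge at
    fraction 1."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise GridError("mask shape does not match grid")
    if not mask.any():
        raise ValueError("mask is empty")
    vals = grid.values[mask]
    top = float(vals.max())
    if top <= dose_floor:
        top = dose_floor * 10.0
    edges = np.concatenate(
        [[0.0], np.logspace(np.log10(dose_floor), np.log10(top), n_bins)]
    )
    order = np.sort(vals)
    # fraction of voxels with value >= edge
    frac = 1.0 - np.searchsorted(order, edges, side="left") / len(vals)
    return DEVH(edges, frac, n_voxels=len(vals), unit=grid.unit)


@dataclass
class DeviationStats:
    """Mean and sample SD of per-location percent deviations."""

    mean_percent: float
    sd_percent: float
    n: int


def deviation_stats(calculated, measured) -> DeviationStats:
    """Percent deviation 100 (calc - meas) / meas per location; mean and
    sample SD (ddof=1; 0 for a single location)."""
    calc = np.asarray(calculated, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if calc.shape != meas.shape or calc.size == 0:
        raise ValueError("calculated and measured must be equal-length, non-empty")
    if np.any(meas <= 0):
        raise ValueError("measured values must be positive")
    dev = 100.0 * (calc - meas) / meas
    sd = float(np.std(dev, ddof=1)) if dev.size > 1 else 0.0
    return DeviationStats(float(dev.mean()), sd, int(dev.size))


def band_median_dose(h: DEVH, dose_band: tuple[float, float]) -> float:
    """Median dose received by the volume fraction falling inside the band."""
    lo, hi = dose_band
    if not 0 <= lo < hi:
        raise ValueError("dose band must satisfy 0 <= lo < hi")
    f_lo = h.fraction_at(lo)
    f_hi = h.fraction_at(hi)
    in_band = f_lo - f_hi
    if in_band <= 0:
        raise ValueError(f"no volume falls in the dose band [{lo}, {hi}]")
    f_med = f_hi + in_band / 2.0
    # invert the non-increasing cumulative curve at f_med within the band
    edges = h.dose_edges
    frac = h.volume_fraction
    sel = (edges >= lo) & (edges <= hi)
    e = np.concatenate([[lo], edges[sel], [hi]])
    f = np.concatenate([[f_lo], frac[sel], [f_hi]])
    # make strictly monotone for interpolation (frac decreases with dose)
    idx = np.argsort(f)
    return float(np.interp(f_med, f[idx], e[idx]))


def band_ratio(devh_a: DEVH, devh_b: DEVH, dose_band: tuple[float, float]) -> float:
    """Ratio of the band-median doses of two DEVHs on one body mask: the
    operational form of 'the dose in the low/intermediate region is a
    factor X higher' comparisons."""
    return band_median_dose(devh_a, dose_band) / band_median_dose(devh_b, dose_band)


def min_dose_ratio(devh_a: DEVH, devh_b: DEVH, coverage: float = 0.98) -> float:
    """Ratio of near-minimum doses (dose received by ``coverage`` of the
    volume), an alternative operationalization of minimum-dose factors."""
    def near_min(h: DEVH) -> float:
        edges, frac = h.dose_edges, h.volume_fraction
        idx = np.argsort(frac)
        return float(np.interp(coverage, frac[idx], edges[idx]))
    return near_min(devh_a) / near_min(devh_b)
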