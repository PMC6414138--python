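"""Synthetic study inputs: phantom, probes, in-field grid, measurements.

Everything the pipeline consumes can be generated here with the
statistical structure the analysis assumes:

* an anthropomorphic-phantom surrogate built from stacked elliptical
  cylinders (pelvis, abdomen, thorax with two lung lobes flanking the
  midline, neck, head), soft tissue at 1.0 g/cm^3 and lungs at 0.25;
* a pelvic target ellipsoid (prostate-region sarcoma surrogate) at the
  isocenter;
* TLD-like probe locations distributed through the body interior
  (>= 1 cm deep), 189 by default of which ~150 lie out of field;
* a synthetic planning-system dose grid: the prescription in the target,
  a steep penumbra, plus the stray-model dose (slightly underweighted,
  as planning systems underestimate out-of-field dose), so the fusion
  seam is consistent by construction;
* pseudo-measurements = model prediction x multiplicative lognormal
  noise (10% SD by default, the agreement level of TLD dosimetry).

All outputs are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .grids import DoseGrid
from .phantom import MATERIALS, VoxelPhantom
from .plans import TreatmentPlan
from .stray import StrayModelConfig, component_doses, default_config


@dataclass
class BodySection:
    """Elliptical cylinder: z range (cm) and transverse semi-axes (cm)."""

    z_min: float
    z_max: float
    semi_x: float
    semi_y: float


@dataclass
class SyntheticSpec:
    """Geometry, sampling and noise parameters of the synthetic study.

    The default body emulates an adult anthropomorphic phantom from
    mid-thigh (z = -20) to the vertex (z = +86) with the isocenter in
    the pelvic target; the neck is the thinnest section, so the
    radiological depth to the body midline is smallest there.
    """

    sections: tuple[BodySection, ...] = (
        BodySection(-20.0, 12.0, 17.0, 12.0),   # pelvis
        BodySection(12.0, 30.0, 15.0, 11.0),    # abdomen
        BodySection(30.0, 58.0, 16.0, 11.0),    # thorax
        BodySection(58.0, 68.0, 5.5, 6.0),      # neck
        BodySection(68.0, 86.0, 8.5, 10.5),     # head
    )
    # two lung lobes flanking the midline (center x, y, z and semi-axes, cm)
    lung_centers: tuple[tuple[float, float, float], ...] = (
        (-8.0, 0.0, 44.0), (8.0, 0.0, 44.0)
    )
    lung_semi_axes: tuple[float, float, float] = (6.0, 7.0, 11.0)
    target_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    target_semi_axes: tuple[float, float, float] = (3.0, 3.0, 4.0)
    spacing: tuple[float, float, float] = (0.8, 0.8, 1.0)
    soft_tissue_density: float = 1.0
    lung_relative_density: float = 0.25
    n_probe_locations: int = 189
    min_probe_depth: float = 1.0      # cm below the surface
    noise_sd: float = 0.10            # multiplicative lognormal sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if any(s.semi_x <= 0 or s.semi_y <= 0 or s.z_max <= s.z_min
               for s in self.sections):
            raise ValueError("degenerate body section dimensions")


def build_phantom(spec: SyntheticSpec | None = None) -> VoxelPhantom:
    """Stacked-ellipse body with lungs at 0.25 density and a straight
    longitudinal MPAX through the isocenter's transverse position."""
    spec = spec or SyntheticSpec()
    dx, dy, dz = spec.spacing
    max_x = max(s.semi_x for s in spec.sections)
    max_y = max(s.semi_y for s in spec.sections)
    z_min = min(s.z_min for s in spec.sections)
    z_max = max(s.z_max for s in spec.sections)
    xs = np.arange(-max_x - dx, max_x + 1.5 * dx, dx)
    ys = np.arange(-max_y - dy, max_y + 1.5 * dy, dy)
    zs = np.arange(z_min - dz, z_max + 1.5 * dz, dz)
    origin = (xs[0], ys[0], zs[0])
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")

    body = np.zeros(gx.shape, dtype=bool)
    for s in spec.sections:
        in_z = (gz >= s.z_min) & (gz < s.z_max)
        in_ellipse = (gx / s.semi_x) ** 2 + (gy / s.semi_y) ** 2 <= 1.0
        body |= in_z & in_ellipse

    lung = np.zeros(gx.shape, dtype=bool)
    ax, ay, az = spec.lung_semi_axes
    for cx, cy, cz in spec.lung_centers:
        lung |= (
            ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 + ((gz - cz) / az) ** 2
            <= 1.0
        )
    lung &= body

    density = np.where(body, spec.soft_tissue_density, 0.0)
    density[lung] = spec.lung_relative_density * spec.soft_tissue_density
    material = np.full(gx.shape, MATERIALS["air"], dtype=np.int8)
    material[body] = MATERIALS["soft_tissue"]
    material[lung] = MATERIALS["lung"]

    mpax_z = np.arange(z_min + 1.0, z_max - 0.5, 1.0)
    mpax = np.column_stack(
        [np.zeros_like(mpax_z), np.zeros_like(mpax_z), mpax_z]
    )
    return VoxelPhantom(density, body, material, spec.spacing, origin, mpax=mpax)


def target_mask(spec: SyntheticSpec, phantom: VoxelPhantom) -> np.ndarray:
    """Boolean voxel mask of the target ellipsoid."""
    xs, ys, zs = phantom.voxel_centers()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    cx, cy, cz = spec.target_center
    ax, ay, az = spec.target_semi_axes
    return (
        ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 + ((gz - cz) / az) ** 2
        <= 1.0
    ) & phantom.body_mask


def _depth_map(phantom: VoxelPhantom) -> np.ndarray:
    """Distance (cm) of each voxel center to the body surface."""
    return distance_transform_edt(phantom.body_mask, sampling=phantom.spacing)


def probe_locations(
    spec: SyntheticSpec | None = None,
    phantom: VoxelPhantom | None = None,
    boundary_distance: float = 4.0,
) -> pd.DataFrame:
    """TLD-like measurement sites through the body interior.

    Sites are laid out on regularly spaced transversal slices, five per
    slice (midline plus four offsets at half the local cross-section),
    keeping every site at least ``min_probe_depth`` below the surface.
    A site is out-of-field if its longitudinal distance from the target
    volume is at least ``boundary_distance`` (the fusion boundary).
    Columns: id, x, y, z, out_of_field.  Deterministic given the spec.
    """
    spec = spec or SyntheticSpec()
    phantom = phantom or build_phantom(spec)
    depth = _depth_map(phantom)
    n_per_slice = 5
    n_slices = int(np.ceil(spec.n_probe_locations / n_per_slice))
    z_lo = min(s.z_min for s in spec.sections) + 1.5
    z_hi = max(s.z_max for s in spec.sections) - 1.5
    z_positions = np.linspace(z_lo, z_hi, n_slices)

    def section_at(z: float) -> BodySection:
        for s in spec.sections:
            if s.z_min <= z < s.z_max:
                return s
        return spec.sections[-1]

    rows = []
    for z in z_positions:
        s = section_at(z)
        offsets = [
            (0.0, 0.0),
            (0.5 * s.semi_x, 0.0),
            (-0.5 * s.semi_x, 0.0),
            (0.0, 0.5 * s.semi_y),
            (0.0, -0.5 * s.semi_y),
        ]
        for ox, oy in offsets:
            rows.append((ox, oy, z))
    pts = np.array(rows[: spec.n_probe_locations])

    # keep sites >= min depth below the surface (nudge shallow ones inward)
    idx = np.clip(
        np.round((pts - np.asarray(phantom.origin)) / np.asarray(phantom.spacing)),
        0, np.asarray(phantom.shape) - 1,
    ).astype(int)
    d = depth[idx[:, 0], idx[:, 1], idx[:, 2]]
    shallow = d < spec.min_probe_depth
    pts[shallow, :2] *= 0.7

    cz = spec.target_center[2]
    az = spec.target_semi_axes[2]
    z_dist = np.maximum.reduce(
        [(cz - az) - pts[:, 2], pts[:, 2] - (cz + az), np.zeros(len(pts))]
    )
    return pd.DataFrame(
        {
            "id": np.arange(len(pts)),
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
            "out_of_field": z_dist >= boundary_distance,
        }
    )


def synthetic_tps_grid(
    plan: TreatmentPlan,
    phantom: VoxelPhantom,
    target: np.ndarray,
    config: StrayModelConfig | None = None,
    penumbra_length: float = 0.55,
    scatter_fidelity: float = 0.92,
) -> DoseGrid:
    """Stand-in for a treatment-planning-system dose grid (Gy per session).

    The prescription ``fraction_dose`` fills the target, decays with a
    steep exponential penumbra of ``penumbra_length`` cm outside it, and
    the stray-model dose is added outside the target scaled by
    ``scatter_fidelity`` (planning systems track the out-of-field dose
    but underestimate it slightly near the boundary and grossly far
    away — only the near-boundary behaviour matters, as the grid is used
    inside the fusion boundary).  Deterministic.
    """
    config = config or default_config()
    target = np.asarray(target, dtype=bool)
    dist = distance_transform_edt(~target, sampling=phantom.spacing)
    primary = plan.fraction_dose * np.exp(-dist / penumbra_length)
    from .stray import stray_dose_grid

    stray = stray_dose_grid(plan, phantom, config)
    values = primary + scatter_fidelity * np.where(target, 0.0, stray.values)
    values[~phantom.body_mask] = 0.0
    return phantom.grid_like(values, unit="Gy")


def pseudo_measurements(
    truth: np.ndarray,
    probes: pd.DataFrame,
    noise_sd: float = 0.10,
    seed: int = 0,
    detector: str = "TLD700H",
) -> pd.DataFrame:
    """Measurement table: truth x multiplicative lognormal noise per probe.

    Columns: id, x, y, z, dose, detector.  With ``noise_sd`` = 0 the
    table equals the truth; a fixed seed reproduces the table exactly.
    """
    truth = np.asarray(truth, dtype=float)
    if len(truth) != len(probes):
        raise ValueError("truth length must match the probe table")
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    rng = np.random.default_rng(seed)
    factors = np.exp(rng.normal(0.0, noise_sd, size=len(truth))) if noise_sd > 0 \
        else np.ones(len(truth))
    return pd.DataFrame(
        {
            "id": probes["id"].to_numpy(),
            "x": probes["x"].to_numpy(),
            "y": probes["y"].to_numpy(),
            "z": probes["z"].to_numpy(),
            "dose": truth * factors,
            "detector": detector,
        }
    )
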