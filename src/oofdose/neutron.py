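"""Peripheral photoneutron dose equivalent for 15 MV beams.

Photoneutrons are produced in the treatment head when the nominal beam
energy exceeds the (gamma, n) thresholds of the head materials; at 6 MV
production is negligible and the model returns zero.  The model assumes
a point source of neutrons at the X-ray producing target.  The neutron
fluence falls with the inverse square of the distance to the source and
is attenuated exponentially with the radiological (density-scaled) depth
in tissue, with the lungs at 0.25 times the soft-tissue density.  The
fluence is converted to dose equivalent with a fluence-to-dose-equivalent
factor.  Only the peripheral dose is modelled: inside the primary beam
the neutron contribution is negligible against the photon dose, and
voxels flagged as in-field are set to zero.

The shipped default constants (source yield, attenuation length,
conversion factor, depth-dependent TLD600 conversion table) are
order-of-magnitude placeholders flagged ``calibrated=False``; absolute
neutron dose equivalents from the defaults are indicative only, while
ratios and spatial shapes are parameter-robust.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .grids import DoseGrid
from .phantom import SourcePoint, VoxelPhantom, radiological_depths
from .plans import TreatmentPlan


class NeutronConfigError(ValueError):
    """Invalid neutron-model configuration or table coverage."""


def _default_depth_table() -> pd.DataFrame:
    # synthetic placeholder: TLD600-signal -> dose-equivalent factor falling
    # with depth as the neutron spectrum thermalises (Sv per unit residual
    # signal); real use supplies a measured two-column table
    depth = np.arange(0.0, 41.0, 2.0)
    factor = 0.4 * np.exp(-depth / 18.0) + 0.05
    return pd.DataFrame({"depth_cm": depth, "factor": factor})


def _default_fluence_to_h() -> pd.DataFrame:
    # synthetic placeholder shaped like the fluence-to-dose-equivalent
    # conversion for fast neutrons (Sv cm^2 vs neutron energy in MeV)
    energy = np.array([0.01, 0.1, 0.5, 1.0, 2.0, 5.0])
    factor = np.array([0.6e-10, 1.8e-10, 3.5e-10, 4.2e-10, 4.6e-10, 4.0e-10])
    return pd.DataFrame({"energy_mev": energy, "sv_cm2": factor})


@dataclass
class NeutronModelConfig:
    """Point-source neutron model constants.

    source_strength : Sv cm^2 per MU — point-source amplitude, i.e. the
        unattenuated dose equivalent at 1 cm from the target per MU
        (fluence yield folded with the fluence-to-dose-equivalent
        conversion at the effective spectrum energy).
    tissue_attenuation_length : cm of soft-tissue-equivalent depth.
    fluence_to_doseequiv : tabulated conversion (energy MeV -> Sv cm^2),
        kept for re-deriving source_strength from a fluence yield.
    depth_conversion_table : depth (cm) -> TLD600-signal-to-dose-equivalent
        factor, used by the paired-TLD signal conversion.
    calibrated : False marks order-of-magnitude placeholder constants.
    """

    source_strength: float = 0.03          # Sv cm^2 / MU  (placeholder)
    tissue_attenuation_length: float = 9.0  # cm            (placeholder)
    fluence_to_doseequiv: pd.DataFrame = field(default_factory=_default_fluence_to_h)
    depth_conversion_table: pd.DataFrame = field(default_factory=_default_depth_table)
    neutron_energies: tuple[int, ...] = (15,)  # MV energies that produce neutrons
    sad: float = 100.0
    calibrated: bool = False

    def __post_init__(self) -> None:
        if self.source_strength <= 0 or self.tissue_attenuation_length <= 0:
            raise NeutronConfigError("model constants must be positive")
        t = self.depth_conversion_table
        if np.any(t["factor"].to_numpy() <= 0):
            raise NeutronConfigError("depth conversion factors must be positive")

    def depth_factor(self, depth: float) -> float:
        t = self.depth_conversion_table
        d = t["depth_cm"].to_numpy()
        if depth < d.min() or depth > d.max():
            raise NeutronConfigError(
                f"depth {depth} cm outside conversion table range "
                f"[{d.min()}, {d.max()}] cm"
            )
        return float(np.interp(depth, d, t["factor"].to_numpy()))


def neutron_dose_equivalent(
    plan: TreatmentPlan,
    phantom: VoxelPhantom,
    points: np.ndarray,
    config: NeutronModelConfig | None = None,
) -> np.ndarray | float:
    """Peripheral neutron dose equivalent per session (Sv) at point(s).

    H = MU_session x source_strength / r^2 x exp(-depth / lambda), summed
    over fields with per-field source positions from the gantry angles
    (VMAT arcs should be pre-discretized into static fields).  Returns 0
    for energies that do not produce photoneutrons (6 MV).
    """
    config = config or NeutronModelConfig()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    scalar = np.asarray(points).ndim == 1
    h = np.zeros(len(pts))
    if plan.nominal_energy in config.neutron_energies:
        lam = config.tissue_attenuation_length
        for f in plan.fields:
            src = SourcePoint.from_gantry_angle(f.gantry_angle, config.sad)
            r = np.linalg.norm(pts - src.position, axis=1)
            depth = radiological_depths(src, pts, phantom)
            mu_session = f.mu / plan.n_fractions
            h += mu_session * config.source_strength / r**2 * np.exp(-depth / lam)
    return float(h[0]) if scalar else h


def neutron_dose_grid(
    plan: TreatmentPlan,
    phantom: VoxelPhantom,
    config: NeutronModelConfig | None = None,
    infield_mask: np.ndarray | None = None,
) -> DoseGrid:
    """Per-session neutron dose-equivalent grid (Sv), zero outside the body
    and zero inside the in-field mask (the model is peripheral only)."""
    config = config or NeutronModelConfig()
    arr = np.zeros(phantom.shape)
    if plan.nominal_energy in config.neutron_energies:
        xs, ys, zs = phantom.voxel_centers()
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        mask = phantom.body_mask
        pts = np.column_stack([gx[mask], gy[mask], gz[mask]])
        arr[mask] = neutron_dose_equivalent(plan, phantom, pts, config)
        if infield_mask is not None:
            arr[infield_mask] = 0.0
    return phantom.grid_like(arr, unit="Sv")


class Tld600Result(NamedTuple):
    dose_equivalent_sv: float
    clamped: bool


def tld600_to_doseequiv(
    raw_signal: float,
    photon_dose: float,
    mean_energy: float,
    depth: float,
    config: NeutronModelConfig | None = None,
    response_curve=None,
) -> Tld600Result:
    """Convert a paired-TLD neutron reading to dose equivalent (Sv).

    The TLD600 chip registers photons and neutrons; the photon part is
    measured by the companion TLD700H chip (``photon_dose``, Gy).  The
    photon-equivalent signal — photon dose times the detector's relative
    response at the local mean photon energy — is subtracted from the raw
    TLD600 signal, and the residual neutron signal is multiplied by the
    depth-dependent conversion factor.  Negative residuals are clamped to
    zero with a warning flag.
    """
    if raw_signal < 0:
        raise ValueError("raw_signal must be non-negative")
    config = config or NeutronModelConfig()
    response = 1.0
    if response_curve is not None:
        response = response_curve.response(mean_energy)
    residual = raw_signal - photon_dose * response
    clamped = residual < 0
    if clamped:
        warnings.warn(
            "photon-equivalent signal exceeds raw TLD600 signal; "
            "neutron dose equivalent clamped to 0",
            stacklevel=2,
        )
        residual = 0.0
    return Tld600Result(residual * config.depth_factor(depth), bool(clamped))
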