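"""Mean out-of-field photon energy and detector energy-response correction.

The out-of-field photon field is a mixture of patient scatter,
collimator scatter and head leakage, each with a characteristic mean
energy measured once per nominal beam energy.  The local mean photon
energy is their dose-weighted average,

    E(l) = sum_i D_i(l) E_i / sum_i D_i(l),   i in {ps, cs, hl},

where D_i(l) are the model-calculated component doses at location l.
Because thermoluminescent dosimeters calibrated at the nominal beam
energy over- or under-respond toward the softer out-of-field spectrum,
the local mean energy is converted into a per-location correction
factor 1 / (relative response at E), applied to the detected dose.

The shipped component energies are the measured values for each nominal
energy, with the collimator-scatter energy taken at 35 cm from the field
edge (the region where collimator scatter matters most relative to the
other contributions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import DoseGrid, GridError
from .stray import ScatterComponents


class EnergyDomainError(ValueError):
    """All-zero dose weights or energy outside a curve's tabulated range."""


@dataclass
class ComponentEnergies:
    """Mean photon energies (MeV) of the three scatter contributions."""

    e_ps: float
    e_cs: float
    e_hl: float

    def __post_init__(self) -> None:
        if min(self.e_ps, self.e_cs, self.e_hl) <= 0:
            raise EnergyDomainError("component energies must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.e_ps, self.e_cs, self.e_hl])


# Measured mean component energies per nominal X-ray energy (MeV); the
# collimator-scatter value is the one determined 35 cm from the field edge.
TABLE_ENERGIES = {
    6: ComponentEnergies(e_ps=0.28, e_cs=0.62, e_hl=0.35),
    15: ComponentEnergies(e_ps=0.29, e_cs=0.53, e_hl=0.45),
}


def component_energies(energy_mv: int) -> ComponentEnergies:
    if energy_mv not in TABLE_ENERGIES:
        raise EnergyDomainError(f"no component energies for {energy_mv} MV")
    return TABLE_ENERGIES[energy_mv]


def mean_energy(
    components: ScatterComponents, energies: ComponentEnergies
) -> float | np.ndarray:
    """Dose-weighted mean photon energy (MeV) at one or many locations.

    Always lies within [min, max] of the three component energies.
    Raises for all-zero components (undefined weights).
    """
    ps = np.asarray(components.ps, dtype=float)
    cs = np.asarray(components.cs, dtype=float)
    hl = np.asarray(components.hl, dtype=float)
    total = ps + cs + hl
    if np.any(total <= 0):
        raise EnergyDomainError(
            "mean energy undefined where all component doses are zero"
        )
    e = (ps * energies.e_ps + cs * energies.e_cs + hl * energies.e_hl) / total
    return float(e) if e.ndim == 0 else e


@dataclass
class ResponseCurve:
    """Relative detector response vs mean photon energy.

    Normalized to 1 at the calibration energy; linear interpolation
    between tabulated points, error outside the tabulated range.
    """

    detector: str
    energy_mev: np.ndarray
    relative_response: np.ndarray
    calibration_energy: float

    def __post_init__(self) -> None:
        self.energy_mev = np.asarray(self.energy_mev, dtype=float)
        self.relative_response = np.asarray(self.relative_response, dtype=float)
        if np.any(self.relative_response <= 0):
            raise EnergyDomainError("relative response must be positive")
        if np.any(np.diff(self.energy_mev) <= 0):
            raise EnergyDomainError("energy grid must be strictly increasing")
        if abs(self.response(self.calibration_energy) - 1.0) > 1e-9:
            raise EnergyDomainError(
                f"{self.detector}: response({self.calibration_energy} MeV) must be 1"
            )

    def response(self, e: float) -> float:
        lo, hi = self.energy_mev[0], self.energy_mev[-1]
        if e < lo or e > hi:
            raise EnergyDomainError(
                f"energy {e} MeV outside tabulated range [{lo}, {hi}] MeV"
            )
        return float(np.interp(e, self.energy_mev, self.relative_response))

    # -- CSV interface -----------------------------------------------------

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"energy_mev": self.energy_mev, "relative_response": self.relative_response}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, detector: str, calibration_energy: float) -> "ResponseCurve":
        df = pd.read_csv(path)
        return cls(detector, df["energy_mev"].to_numpy(),
                   df["relative_response"].to_numpy(), calibration_energy)


def correction_factor(e: float, curve: ResponseCurve) -> float:
    """Energy-response correction: corrected dose = detected dose x factor."""
    return 1.0 / curve.response(e)


def mean_energy_grid(
    component_grids: dict[str, DoseGrid],
    energies: ComponentEnergies,
    probes: np.ndarray | None = None,
):
    """Voxelwise mean-energy grid plus a probe-population summary.

    ``component_grids`` maps {"ps", "cs", "hl"} to dose grids on one
    lattice.  Voxels with zero total dose get energy 0 (undefined).
    With ``probes`` (n, 3 room coordinates), returns ``(grid, mean, sd)``
    of the energies sampled at the probe sites (sample SD, 0 for a single
    probe); otherwise returns the grid alone.
    """
    ps, cs, hl = (component_grids[k] for k in ("ps", "cs", "hl"))
    ps.require_same_lattice(cs)
    ps.require_same_lattice(hl)
    total = ps.values + cs.values + hl.values
    num = (
        ps.values * energies.e_ps
        + cs.values * energies.e_cs
        + hl.values * energies.e_hl
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(total > 0, num / np.where(total > 0, total, 1.0), 0.0)
    grid = ps.copy_with(e, unit="MeV")
    if probes is None:
        return grid
    vals = grid.sample(np.atleast_2d(probes))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return grid, float(np.mean(vals)), sd
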