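"""End-to-end whole-body dose-equivalent assembly for one treatment.

Convenience driver tying the pieces together the way a study would run
them: stray-model photon dose fused with the (synthetic or imported)
planning-system grid at the fusion boundary, plus the peripheral neutron
dose equivalent for 15 MV plans and the per-scan CBCT dose, summed per
session and scaled to the full treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cbct import CbctProfile, cbct_dose_grid, default_pelvis_profile
from .fusion import DEVH, FusionSpec, SeamReport, devh, fuse, total_dose_equivalent
from .grids import DoseGrid
from .neutron import NeutronModelConfig, neutron_dose_grid
from .phantom import VoxelPhantom
from .plans import TreatmentPlan
from .stray import StrayModelConfig, default_config, stray_dose_grid
from .synthetic import synthetic_tps_grid


@dataclass
class TreatmentDose:
    """Per-treatment dose-equivalent grids and bookkeeping for one plan."""

    plan: TreatmentPlan
    total: DoseGrid                 # Sv per treatment
    photon_fused: DoseGrid          # Gy per session
    stray_components: dict[str, DoseGrid]   # Gy per session
    neutron: DoseGrid               # Sv per session
    cbct: DoseGrid                  # Gy per scan
    seam: SeamReport
    infield_region: np.ndarray      # voxels taking the planning-system dose

    def out_of_field_mask(self, body_mask: np.ndarray) -> np.ndarray:
        return body_mask & ~self.infield_region

    def therapy_total(self) -> DoseGrid:
        """Per-treatment dose equivalent of the treatment delivery alone
        (photon + neutron, imaging excluded).  Technique comparisons use
        this grid: the imaging dose is technique-independent, so including
        it would only dilute between-technique factors toward 1."""
        return total_dose_equivalent(
            self.photon_fused, self.neutron, None, self.plan.n_fractions
        )

    def devh(self, body_mask: np.ndarray, out_of_field: bool = False) -> DEVH:
        mask = self.out_of_field_mask(body_mask) if out_of_field else body_mask
        return devh(self.total, mask)


def treatment_dose_equivalent(
    plan: TreatmentPlan,
    phantom: VoxelPhantom,
    target: np.ndarray,
    stray_config: StrayModelConfig | None = None,
    neutron_config: NeutronModelConfig | None = None,
    cbct_profile: CbctProfile | None = None,
    boundary_distance: float = 4.0,
    tps_grid: DoseGrid | None = None,
) -> TreatmentDose:
    """Assemble the whole-body dose equivalent per treatment for one plan.

    Without an explicit ``tps_grid`` the synthetic planning-system grid
    is generated (consistent with the stray model at the seam).  A daily
    CBCT is assumed for every session.
    """
    stray_config = stray_config or default_config()
    neutron_config = neutron_config or NeutronModelConfig()
    cbct_profile = cbct_profile or default_pelvis_profile()

    stray_total, components = stray_dose_grid(
        plan, phantom, stray_config, return_components=True
    )
    if tps_grid is None:
        tps_grid = synthetic_tps_grid(plan, phantom, target, stray_config)
    spec = FusionSpec(target_mask=target, boundary_distance=boundary_distance)
    fused, seam = fuse(tps_grid, stray_total, spec,
                       body_mask=phantom.body_mask, return_seam=True)
    inner = spec.inner_region(tps_grid)
    neutron = neutron_dose_grid(plan, phantom, neutron_config,
                                infield_mask=target)
    cbct = cbct_dose_grid(cbct_profile, phantom)
    total = total_dose_equivalent(fused, neutron, cbct, plan.n_fractions)
    return TreatmentDose(
        plan=plan,
        total=total,
        photon_fused=fused,
        stray_components=components,
        neutron=neutron,
        cbct=cbct,
        seam=seam,
        infield_region=inner,
    )
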