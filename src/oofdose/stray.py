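"""Analytical out-of-field photon stray dose model.

The out-of-field photon dose is modelled as the sum of three
contributions, each with its own spatial behaviour and scaling law:

* **patient scatter (ps)** — photons Compton-scattered inside the patient
  from the primary beam.  Scales with the target dose delivered per
  session, grows with field area, and falls off steeply with distance
  from the field edge.
* **collimator scatter (cs)** — photons scattered off the jaws and MLC of
  the treatment head.  Scales linearly with monitor units and falls off
  more slowly with distance from the field edge.
* **head leakage (hl)** — radiation penetrating the treatment-head
  shielding (including the capture-gamma contribution, which is folded
  into the leakage calibration).  Scales linearly with monitor units and
  is nearly uniform, varying only through the inverse-square distance to
  the source and in-phantom attenuation.

Each component is ``amplitude x lateral falloff x exp(-depth /
attenuation length)``, where the lateral falloff is a mixture of an
exponential and an inverse-square term in the distance from the 50%
fluence field edge projected to the isocenter plane, and the depth is the
radiological (density-scaled) path length from the X-ray target to the
point.  Multi-field plans sum per-field contributions with MU weighting.

The shipped default configuration is calibrated per nominal energy so
that at the reference condition (10 x 10 cm^2 field on a 30 cm water
slab, 30 cm from the isocenter) patient scatter is twice as high for
6 MV as for 15 MV while collimator scatter per MU is 1.5 times lower,
and so that near the field edge patient scatter dominates while far from
the field head leakage dominates inside the body.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .phantom import SourcePoint, VoxelPhantom, radiological_depths
from .plans import BeamField, TreatmentPlan


class StrayConfigError(ValueError):
    """Unknown energy or invalid stray-model configuration."""


class CalibrationError(ValueError):
    """The calibration constraint set cannot be satisfied."""


@dataclass
class ComponentParams:
    """Parameters of one scatter component at one nominal energy.

    amplitude : Gy per delivered Gy (ps) or Gy per MU (cs, hl) at the
        reference geometry (field edge, zero depth).
    exp_weight / exp_length / invsq_length : the lateral falloff is
        ``w * exp(-d/L1) + (1 - w) * (L2 / (L2 + d))^2`` with d the
        distance (cm) from the projected field edge.
    attenuation_length : cm of soft-tissue-equivalent depth for the
        exponential in-phantom attenuation.
    area_exponent : exponent of the (field area / 100 cm^2) scaling
        (patient scatter only; 0 for the others).
    """

    amplitude: float
    exp_weight: float = 1.0
    exp_length: float = 1.0
    invsq_length: float = 1.0
    attenuation_length: float = 1.0
    area_exponent: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise StrayConfigError("amplitude must be non-negative")
        if not 0.0 <= self.exp_weight <= 1.0:
            raise StrayConfigError("exp_weight must lie in [0, 1]")
        if min(self.exp_length, self.invsq_length, self.attenuation_length) <= 0:
            raise StrayConfigError("falloff constants must be positive")

    def lateral(self, d_edge: np.ndarray) -> np.ndarray:
        d = np.maximum(np.asarray(d_edge, dtype=float), 0.0)
        w = self.exp_weight
        return w * np.exp(-d / self.exp_length) + (1.0 - w) * (
            self.invsq_length / (self.invsq_length + d)
        ) ** 2


@dataclass
class EnergyConfig:
    ps: ComponentParams
    cs: ComponentParams
    hl: ComponentParams


@dataclass
class StrayModelConfig:
    """Per-energy stray-model parameters plus machine geometry."""

    energies: dict[int, EnergyConfig]
    sad: float = 100.0          # source-axis distance, cm
    reference_area: float = 100.0  # cm^2 (10 x 10 field) for area scaling
    calibrated: bool = True

    def for_energy(self, energy_mv: int) -> EnergyConfig:
        if energy_mv not in self.energies:
            raise StrayConfigError(
                f"no stray-model parameters for {energy_mv} MV "
                f"(configured: {sorted(self.energies)})"
            )
        return self.energies[energy_mv]

    # -- serialization (structured text, explicit units) -------------------

    def to_yaml(self, path) -> None:
        def comp(p: ComponentParams) -> dict:
            return {
                "amplitude": p.amplitude,
                "exp_weight": p.exp_weight,
                "exp_length_cm": p.exp_length,
                "invsq_length_cm": p.invsq_length,
                "attenuation_length_cm": p.attenuation_length,
                "area_exponent": p.area_exponent,
            }

        doc = {
            "sad_cm": self.sad,
            "reference_area_cm2": self.reference_area,
            "calibrated": self.calibrated,
            "energies": {
                f"{e} MV": {
                    "patient_scatter_per_gy": comp(cfg.ps),
                    "collimator_scatter_per_mu": comp(cfg.cs),
                    "head_leakage_per_mu": comp(cfg.hl),
                }
                for e, cfg in self.energies.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StrayModelConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)

        def comp(d: dict) -> ComponentParams:
            return ComponentParams(
                amplitude=d["amplitude"],
                exp_weight=d["exp_weight"],
                exp_length=d["exp_length_cm"],
                invsq_length=d["invsq_length_cm"],
                attenuation_length=d["attenuation_length_cm"],
                area_exponent=d.get("area_exponent", 0.0),
            )

        energies = {}
        for key, val in doc["energies"].items():
            e = int(key.split()[0])
            energies[e] = EnergyConfig(
                ps=comp(val["patient_scatter_per_gy"]),
                cs=comp(val["collimator_scatter_per_mu"]),
                hl=comp(val["head_leakage_per_mu"]),
            )
        return cls(
            energies=energies,
            sad=float(doc.get("sad_cm", 100.0)),
            reference_area=float(doc.get("reference_area_cm2", 100.0)),
            calibrated=bool(doc.get("calibrated", True)),
        )


@dataclass
class ScatterComponents:
    """Patient-scatter / collimator-scatter / head-leakage dose triple.

    Scalar (one location) or arrays (per voxel / per location set);
    per session unless tagged otherwise by the caller.
    """

    ps: np.ndarray | float
    cs: np.ndarray | float
    hl: np.ndarray | float

    @property
    def total(self):
        return self.ps + self.cs + self.hl


def default_config() -> StrayModelConfig:
    """Shipped stray-model defaults, calibrated to the printed cross-energy
    constraints (ps 6/15 = 2.0, cs 15/6 = 1.5 at the reference condition)."""
    # lateral / depth shape constants shared between energies (the measured
    # mean energies of each component are nearly energy-independent, so the
    # spatial shapes are modelled as identical and only amplitudes differ)
    ps6 = ComponentParams(amplitude=0.040, exp_weight=0.7, exp_length=5.0,
                          invsq_length=8.0, attenuation_length=30.0,
                          area_exponent=0.5)
    ps15 = replace(ps6, amplitude=0.020)
    cs15 = ComponentParams(amplitude=3.0e-5, exp_weight=0.75, exp_length=25.0,
                           invsq_length=30.0, attenuation_length=16.0)
    cs6 = replace(cs15, amplitude=cs15.amplitude / 1.5)
    # head leakage is mildly lower for 15 MV (more forward-peaked target
    # emission); the ratio is chosen so that same-technique whole-body dose
    # stays close between the two energies, as observed
    hl6 = ComponentParams(amplitude=8.8e-6, exp_weight=1.0, exp_length=1e6,
                          invsq_length=1e6, attenuation_length=60.0)
    hl15 = replace(hl6, amplitude=hl6.amplitude / 1.1)
    return StrayModelConfig(
        energies={
            6: EnergyConfig(ps=ps6, cs=cs6, hl=hl6),
            15: EnergyConfig(ps=ps15, cs=cs15, hl=hl15),
        }
    )


# -- geometry helpers ------------------------------------------------------


def field_frame(field: BeamField) -> tuple[np.ndarray, np.ndarray]:
    """Cross-plane and longitudinal unit vectors of a field's aperture."""
    g = np.deg2rad(field.gantry_angle)
    e1 = np.array([np.cos(g), -np.sin(g), 0.0])  # cross-plane (IEC x)
    e2 = np.array([0.0, 0.0, 1.0])               # longitudinal
    return e1, e2


def distance_to_field_edge(field: BeamField, points: np.ndarray) -> np.ndarray:
    """Distance (cm) from each point to the projected 50%-fluence rectangle.

    The aperture rectangle at the isocenter plane is extruded along the
    beam axis; the distance is measured in the two aperture coordinates
    (0 inside the field).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    e1, e2 = field_frame(field)
    c1 = pts @ e1
    c2 = pts @ e2
    dx = np.maximum(np.abs(c1) - field.aperture[0] / 2.0, 0.0)
    dz = np.maximum(np.abs(c2) - field.aperture[1] / 2.0, 0.0)
    return np.hypot(dx, dz)


def _per_field_components(
    field: BeamField,
    dose_weight: float,
    cfg: EnergyConfig,
    points: np.ndarray,
    phantom: VoxelPhantom,
    sad: float,
    reference_area: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    src = SourcePoint.from_gantry_angle(field.gantry_angle, sad)
    depth = radiological_depths(src, pts, phantom)
    d_edge = distance_to_field_edge(field, pts)
    r = np.linalg.norm(pts - src.position, axis=1)
    area_scale = (field.area / reference_area) ** cfg.ps.area_exponent
    ps = (
        dose_weight
        * cfg.ps.amplitude
        * area_scale
        * cfg.ps.lateral(d_edge)
        * np.exp(-depth / cfg.ps.attenuation_length)
    )
    cs = (
        field.mu
        * cfg.cs.amplitude
        * cfg.cs.lateral(d_edge)
        * np.exp(-depth / cfg.cs.attenuation_length)
    )
    hl = (
        field.mu
        * cfg.hl.amplitude
        * (sad / r) ** 2
        * np.exp(-depth / cfg.hl.attenuation_length)
    )
    return ps, cs, hl


def component_doses(
    plan: TreatmentPlan,
    phantom: VoxelPhantom,
    points: np.ndarray,
    config: StrayModelConfig | None = None,
) -> ScatterComponents:
    """Per-session stray-dose components at out-of-field point(s).

    Patient scatter scales with the target dose delivered per session
    (apportioned over fields by MU share); collimator scatter and head
    leakage scale linearly with the MU delivered per session.
    """
    config = config or default_config()
    cfg = config.for_energy(plan.nominal_energy)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    scalar = np.asarray(points).ndim == 1
    ps = np.zeros(len(pts))
    cs = np.zeros(len(pts))
    hl = np.zeros(len(pts))
    total_mu = plan.total_mu
    n = len(plan.fields)
    for f in plan.fields:
        mu_share = f.mu / total_mu if total_mu > 0 else 1.0 / n
        session_field = BeamField(f.gantry_angle, f.aperture,
                                  f.mu / plan.n_fractions, f.collimator_angle)
        p, c, h = _per_field_components(
            session_field,
            plan.fraction_dose * mu_share,
            cfg, pts, phantom, config.sad, config.reference_area,
        )
        ps += p
        cs += c
        hl += h
    if scalar:
        return ScatterComponents(float(ps[0]), float(cs[0]), float(hl[0]))
    return ScatterComponents(ps, cs, hl)


def stray_dose_grid(
    plan: TreatmentPlan,
    phantom: VoxelPhantom,
    config: StrayModelConfig | None = None,
    return_components: bool = False,
):
    """Per-session out-of-field stray dose per voxel (Gy), zero outside the
    body.  With ``return_components`` the three component grids are returned
    as a dict alongside the total."""
    config = config or default_config()
    xs, ys, zs = phantom.voxel_centers()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    mask = phantom.body_mask
    pts = np.column_stack([gx[mask], gy[mask], gz[mask]])
    comp = component_doses(plan, phantom, pts, config)

    def as_grid(vals):
        arr = np.zeros(phantom.shape)
        arr[mask] = vals
        return phantom.grid_like(arr, unit="Gy")

    total = as_grid(np.asarray(comp.total))
    if not return_components:
        return total
    return total, {
        "ps": as_grid(np.asarray(comp.ps)),
        "cs": as_grid(np.asarray(comp.cs)),
        "hl": as_grid(np.asarray(comp.hl)),
    }


# -- calibration -----------------------------------------------------------


@dataclass
class CalibrationConstraints:
    """Cross-energy constraints at the reference condition plus shape checks.

    ps_ratio_6_over_15: patient scatter per delivered Gy, 6 MV / 15 MV.
    cs_ratio_15_over_6: collimator scatter per MU, 15 MV / 6 MV.
    """

    ps_ratio_6_over_15: float = 2.0
    cs_ratio_15_over_6: float = 1.5
    check_monotone: bool = True


def reference_phantom(spacing: float = 2.0) -> VoxelPhantom:
    """30 x 30 cm^2 cross-section water slab, 80 cm long, centred on the
    isocenter: the reference geometry for cross-energy calibration."""
    nx = ny = int(round(30.0 / spacing))
    nz = int(round(80.0 / spacing))
    density = np.ones((nx, ny, nz))
    mask = np.ones((nx, ny, nz), dtype=bool)
    material = np.ones((nx, ny, nz), dtype=np.int8)
    origin = (
        -(nx - 1) / 2.0 * spacing,
        -(ny - 1) / 2.0 * spacing,
        -(nz - 1) / 2.0 * spacing,
    )
    return VoxelPhantom(density, mask, material, (spacing, spacing, spacing), origin)


REFERENCE_POINT = np.array([0.0, 0.0, 30.0])  # 30 cm longitudinal, on axis


def _reference_plan(energy_mv: int) -> TreatmentPlan:
    """Single 10 x 10 anterior field, 100 MU, 1 Gy per session."""
    return TreatmentPlan(
        nominal_energy=energy_mv,
        technique="3DCRT",
        fields=[BeamField(0.0, (10.0, 10.0), 100.0)],
        fraction_dose=1.0,
        n_fractions=1,
    )


def reference_components(
    config: StrayModelConfig, energy_mv: int
) -> ScatterComponents:
    """ps per delivered Gy and cs/hl per MU at the reference condition."""
    phantom = reference_phantom()
    plan = _reference_plan(energy_mv)
    comp = component_doses(plan, phantom, REFERENCE_POINT, config)
    return ScatterComponents(comp.ps / plan.fraction_dose,
                             comp.cs / plan.total_mu,
                             comp.hl / plan.total_mu)


def check_constraints(
    config: StrayModelConfig,
    constraints: CalibrationConstraints | None = None,
    rtol: float = 1e-6,
) -> list[str]:
    """Evaluate every calibration constraint; return a list of violations."""
    constraints = constraints or CalibrationConstraints()
    failures: list[str] = []
    ref6 = reference_components(config, 6)
    ref15 = reference_components(config, 15)
    ps_ratio = ref6.ps / ref15.ps
    cs_ratio = ref15.cs / ref6.cs
    if abs(ps_ratio - constraints.ps_ratio_6_over_15) > rtol * constraints.ps_ratio_6_over_15:
        failures.append(
            f"ps 6 MV / 15 MV ratio {ps_ratio:.6g} != {constraints.ps_ratio_6_over_15}"
        )
    if abs(cs_ratio - constraints.cs_ratio_15_over_6) > rtol * constraints.cs_ratio_15_over_6:
        failures.append(
            f"cs 15 MV / 6 MV ratio {cs_ratio:.6g} != {constraints.cs_ratio_15_over_6}"
        )
    if constraints.check_monotone:
        phantom = reference_phantom()
        zs = np.arange(8.0, 39.0, 2.0)
        pts = np.column_stack([np.zeros_like(zs), np.zeros_like(zs), zs])
        for e in (6, 15):
            comp = component_doses(_reference_plan(e), phantom, pts, config)
            for name, vals in (("ps", comp.ps), ("cs", comp.cs), ("hl", comp.hl)):
                if np.any(np.diff(vals) > 1e-12 * np.max(vals)):
                    failures.append(
                        f"{name} at {e} MV is not monotonically non-increasing "
                        "with distance beyond the fusion boundary"
                    )
    return failures


def calibrate(
    config: StrayModelConfig | None = None,
    constraints: CalibrationConstraints | None = None,
    seed: int | None = None,
) -> StrayModelConfig:
    """Rescale the 6 MV amplitudes so the cross-energy ratios hold exactly.

    The 15 MV amplitudes are the anchor; the 6 MV patient-scatter and
    collimator-scatter amplitudes are rescaled so that the reference-
    condition ratios equal the requested constraints.  Deterministic
    (``seed`` is accepted for interface symmetry; the procedure involves
    no randomness).  Raises :class:`CalibrationError` with a report if
    the constraint set cannot be satisfied.
    """
    config = config or default_config()
    constraints = constraints or CalibrationConstraints()
    if constraints.ps_ratio_6_over_15 <= 0 or constraints.cs_ratio_15_over_6 <= 0:
        raise CalibrationError("cross-energy ratio constraints must be positive")
    ref6 = reference_components(config, 6)
    ref15 = reference_components(config, 15)
    if ref15.ps <= 0 or ref15.cs <= 0 or ref6.ps <= 0 or ref6.cs <= 0:
        raise CalibrationError(
            "reference components vanish; amplitudes cannot be rescaled"
        )
    cfg6 = config.energies[6]
    ps_scale = constraints.ps_ratio_6_over_15 / (ref6.ps / ref15.ps)
    cs_scale = (ref15.cs / ref6.cs) / constraints.cs_ratio_15_over_6
    new6 = EnergyConfig(
        ps=replace(cfg6.ps, amplitude=cfg6.ps.amplitude * ps_scale),
        cs=replace(cfg6.cs, amplitude=cfg6.cs.amplitude * cs_scale),
        hl=cfg6.hl,
    )
    new = StrayModelConfig(
        energies={6: new6, 15: config.energies[15]},
        sad=config.sad,
        reference_area=config.reference_area,
        calibrated=True,
    )
    failures = check_constraints(new, constraints)
    if failures:
        raise CalibrationError("calibration failed:\n" + "\n".join(failures))
    return new


# -- amplitude recovery from measurements ----------------------------------


def fit_amplitudes(
    measured: np.ndarray,
    points: np.ndarray,
    plans: TreatmentPlan | list[TreatmentPlan],
    phantom: VoxelPhantom,
    config: StrayModelConfig,
    energy_mv: int,
) -> dict[str, float]:
    """Refit the (ps, cs, hl) amplitudes from measured out-of-field doses.

    ``measured`` holds per-session doses at ``points``; with a list of
    plans, measured is concatenated plan-major.  The fit is linear least
    squares on the three unit-amplitude component shapes, weighted by
    1 / measurement so that the residuals are relative (doses span orders
    of magnitude).  Returns the recovered amplitudes.
    """
    if isinstance(plans, TreatmentPlan):
        plans = [plans]
    cfg = config.for_energy(energy_mv)
    unit = StrayModelConfig(
        energies={
            energy_mv: EnergyConfig(
                ps=replace(cfg.ps, amplitude=1.0),
                cs=replace(cfg.cs, amplitude=1.0),
                hl=replace(cfg.hl, amplitude=1.0),
            )
        },
        sad=config.sad,
        reference_area=config.reference_area,
    )
    shapes = []
    for plan in plans:
        if plan.nominal_energy != energy_mv:
            raise StrayConfigError("all plans must match the fitted energy")
        comp = component_doses(plan, phantom, points, unit)
        shapes.append(np.column_stack([comp.ps, comp.cs, comp.hl]))
    design = np.vstack(shapes)
    y = np.asarray(measured, dtype=float).ravel()
    if len(y) != len(design):
        raise ValueError("measured length does not match plans x points")
    w = 1.0 / np.maximum(y, 1e-300)
    sol, *_ = np.linalg.lstsq(design * w[:, None], y * w, rcond=None)
    return {"ps": float(sol[0]), "cs": float(sol[1]), "hl": float(sol[2])}
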