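"""Treatment plans, VMAT arc discretization, and monitor-unit accounting.

A plan is a nominal energy (6 or 15 MV), a delivery technique (3DCRT,
IMRT or VMAT), a list of static beam fields (gantry angle, equivalent
rectangular aperture at the isocenter, monitor units), and a
fractionation scheme.  A VMAT arc is approximated by grouping its control
points into a small number of static fields (six by default), each
carrying the MU sum of its angular bin at the MU-weighted mean gantry
angle — the standard discrete-field approximation for rotational
deliveries in out-of-field dose models.

The module ships the six pelvis plans used throughout the package as
fixtures: 3DCRT (four-field box), dynamic IMRT (five fields) and
single-arc VMAT, each at 6 and 15 MV, with the published fractionation
(2.0 Gy x 26 for 3DCRT, 2.2 Gy x 23 for the intensity-modulated plans)
and total monitor units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml


class PlanError(ValueError):
    """Invalid plan definition."""


@dataclass
class BeamField:
    gantry_angle: float            # deg, [0, 360)
    aperture: tuple[float, float]  # (x_width, y_width) cm at isocenter
    mu: float                      # monitor units >= 0
    collimator_angle: float = 0.0

    def __post_init__(self) -> None:
        self.gantry_angle = float(self.gantry_angle) % 360.0
        self.aperture = (float(self.aperture[0]), float(self.aperture[1]))
        if self.aperture[0] <= 0 or self.aperture[1] <= 0:
            raise PlanError(f"aperture widths must be positive, got {self.aperture}")
        if self.mu < 0:
            raise PlanError("mu must be non-negative")

    @property
    def area(self) -> float:
        """Aperture area at the isocenter plane, cm^2."""
        return self.aperture[0] * self.aperture[1]


@dataclass
class ArcControlPoint:
    gantry_angle: float
    mu: float                      # MU delivered in this control-point interval
    aperture: tuple[float, float]

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise PlanError("control-point mu must be non-negative")


@dataclass
class TreatmentPlan:
    nominal_energy: int            # MV: 6 or 15
    technique: str                 # 3DCRT | IMRT | VMAT
    fields: list[BeamField]
    fraction_dose: float           # Gy per session
    n_fractions: int

    def __post_init__(self) -> None:
        if self.nominal_energy not in (6, 15):
            raise PlanError(f"nominal_energy must be 6 or 15 MV, got {self.nominal_energy}")
        if self.technique not in ("3DCRT", "IMRT", "VMAT"):
            raise PlanError(f"unknown technique {self.technique!r}")
        if self.n_fractions < 1:
            raise PlanError("n_fractions must be a positive integer")
        if self.fraction_dose < 0:
            raise PlanError("fraction_dose must be non-negative")

    @property
    def total_mu(self) -> float:
        return sum(f.mu for f in self.fields)

    @property
    def mu_per_session(self) -> float:
        return self.total_mu / self.n_fractions

    @property
    def prescribed_dose(self) -> float:
        """Total treatment dose, Gy = fraction_dose x n_fractions."""
        return self.fraction_dose * self.n_fractions

    def scaled_mu(self, factor: float) -> "TreatmentPlan":
        """Same geometry, every field's MU multiplied by ``factor``."""
        return TreatmentPlan(
            self.nominal_energy,
            self.technique,
            [BeamField(f.gantry_angle, f.aperture, f.mu * factor, f.collimator_angle)
             for f in self.fields],
            self.fraction_dose,
            self.n_fractions,
        )

    # -- plan schema (structured text) ------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "energy_mv": self.nominal_energy,
            "technique": self.technique,
            "fraction_dose_gy": self.fraction_dose,
            "n_fractions": self.n_fractions,
            "fields": [
                {
                    "gantry_angle": f.gantry_angle,
                    "mu": f.mu,
                    "aperture_x": f.aperture[0],
                    "aperture_y": f.aperture[1],
                }
                for f in self.fields
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TreatmentPlan":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "arc" in doc:
            cps = [
                ArcControlPoint(c["gantry_angle"], c["mu"],
                                (c["aperture_x"], c["aperture_y"]))
                for c in doc["arc"]["control_points"]
            ]
            fields = discretize_arc(cps, int(doc["arc"].get("n_groups", 6)))
        else:
            fields = [
                BeamField(f["gantry_angle"], (f["aperture_x"], f["aperture_y"]), f["mu"])
                for f in doc["fields"]
            ]
        return cls(
            nominal_energy=int(doc["energy_mv"]),
            technique=doc["technique"],
            fields=fields,
            fraction_dose=float(doc["fraction_dose_gy"]),
            n_fractions=int(doc["n_fractions"]),
        )


def discretize_arc(
    control_points: list[ArcControlPoint], n_groups: int = 6
) -> list[BeamField]:
    """Group arc control points into ``n_groups`` static fields.

    The traversed gantry range is partitioned into equal closed-open
    angular bins anchored at the arc start angle.  Each output field
    carries the MU sum of its bin, the MU-weighted mean gantry angle and
    the MU-weighted mean aperture; total MU is conserved exactly.  Bins
    that receive no control points are dropped.
    """
    if n_groups < 1:
        raise PlanError("n_groups must be >= 1")
    if not control_points:
        raise PlanError("at least one control point is required")
    angles = [cp.gantry_angle for cp in control_points]
    a0, a1 = min(angles), max(angles)
    span = a1 - a0
    fields: list[BeamField] = []
    for k in range(n_groups):
        lo = a0 + span * k / n_groups
        hi = a0 + span * (k + 1) / n_groups
        if span == 0:
            members = control_points if k == 0 else []
        elif k == n_groups - 1:
            # last bin is closed above so the arc end is never dropped
            members = [cp for cp in control_points if lo <= cp.gantry_angle]
        else:
            members = [cp for cp in control_points if lo <= cp.gantry_angle < hi]
        if not members:
            continue
        mu = math.fsum(cp.mu for cp in members)
        if mu > 0:
            ang = math.fsum(cp.gantry_angle * cp.mu for cp in members) / mu
            ax = math.fsum(cp.aperture[0] * cp.mu for cp in members) / mu
            ay = math.fsum(cp.aperture[1] * cp.mu for cp in members) / mu
        else:  # zero-MU bin: unweighted means keep geometry defined
            ang = math.fsum(cp.gantry_angle for cp in members) / len(members)
            ax = math.fsum(cp.aperture[0] for cp in members) / len(members)
            ay = math.fsum(cp.aperture[1] for cp in members) / len(members)
        fields.append(BeamField(ang, (ax, ay), mu))
    return fields


def mu_per_gy(plan: TreatmentPlan) -> int:
    """Monitor units per treatment Gy, rounded half-up to an integer."""
    if plan.prescribed_dose <= 0:
        raise PlanError("prescribed dose must be positive")
    return int(math.floor(plan.total_mu / plan.prescribed_dose + 0.5))


# -- shipped pelvis plan fixtures ------------------------------------------

# (technique, energy MV) -> (fraction dose Gy, n fractions, total MU)
_PLAN_TABLE = {
    ("3DCRT", 6): (2.0, 26, 7326),
    ("3DCRT", 15): (2.0, 26, 5846),
    ("IMRT", 6): (2.2, 23, 22989),
    ("IMRT", 15): (2.2, 23, 21661),
    ("VMAT", 6): (2.2, 23, 13409),
    ("VMAT", 15): (2.2, 23, 11847),
}

# Gantry angles not published for these plans; conventional defaults.
_3DCRT_ANGLES = (0.0, 90.0, 180.0, 270.0)          # four-field box
_IMRT_ANGLES = (0.0, 72.0, 144.0, 216.0, 288.0)    # five equispaced fields

# Equivalent apertures (cm): 3DCRT fields open ~9 x 10, dynamic IMRT
# effective openings ~3 x 10, per the reported average field openings.
_APERTURE = {"3DCRT": (9.0, 10.0), "IMRT": (3.0, 10.0), "VMAT": (6.0, 10.0)}


def plan_fixture(technique: str, energy_mv: int) -> TreatmentPlan:
    """One of the six shipped pelvis plans, with exact published MU totals."""
    key = (technique, energy_mv)
    if key not in _PLAN_TABLE:
        raise PlanError(f"no fixture for {technique} at {energy_mv} MV")
    fraction_dose, n_fractions, total_mu = _PLAN_TABLE[key]
    aperture = _APERTURE[technique]
    if technique == "3DCRT":
        angles = _3DCRT_ANGLES
    elif technique == "IMRT":
        angles = _IMRT_ANGLES
    else:
        # single 360 deg arc, one control point per degree, equal MU,
        # grouped to six discrete fields
        n_cp = 360
        cps = [
            ArcControlPoint(a, total_mu / n_cp, aperture)
            for a in range(n_cp)
        ]
        fields = discretize_arc(cps, n_groups=6)
        return TreatmentPlan(energy_mv, technique, fields, fraction_dose, n_fractions)
    mu_each = total_mu / len(angles)   # per-field split not published: equal
    fields = [BeamField(a, aperture, mu_each) for a in angles]
    return TreatmentPlan(energy_mv, technique, fields, fraction_dose, n_fractions)


def plan_fixtures() -> list[TreatmentPlan]:
    """All six shipped plans: {3DCRT, IMRT, VMAT} x {6, 15} MV."""
    return [plan_fixture(t, e) for t, e in _PLAN_TABLE]
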