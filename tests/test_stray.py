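"""Photon stray-dose model: scaling laws, cross-energy calibration, shape."""

import numpy as np
import pytest

import oofdose as od
from oofdose.stray import (
    CalibrationConstraints,
    StrayConfigError,
    reference_components,
)

POINT = np.array([0.0, 0.0, 30.0])


@pytest.fixture(scope="module")
def plan6():
    return od.plan_fixture("IMRT", 6)


@pytest.fixture(scope="module")
def plan15():
    return od.plan_fixture("IMRT", 15)


class TestComponentDoses:
    def test_zero_plan_gives_zero_components(self, phantom, stray_config):
        plan = od.TreatmentPlan(
            6, "3DCRT", [od.BeamField(0.0, (10.0, 10.0), 0.0)], 0.0, 26
        )
        comp = od.component_doses(plan, phantom, POINT, stray_config)
        assert comp.ps == comp.cs == comp.hl == 0.0

    def test_all_components_non_negative(self, phantom, stray_config, plan6,
                                         oof_points):
        comp = od.component_doses(plan6, phantom, oof_points, stray_config)
        assert np.all(comp.ps >= 0) and np.all(comp.cs >= 0) and np.all(comp.hl >= 0)
        assert np.allclose(comp.total, comp.ps + comp.cs + comp.hl)

    def test_doubling_mu_doubles_cs_and_hl_exactly(self, phantom, stray_config,
                                                   plan6):
        base = od.component_doses(plan6, phantom, POINT, stray_config)
        doubled = od.component_doses(plan6.scaled_mu(2.0), phantom, POINT,
                                     stray_config)
        assert doubled.cs == 2.0 * base.cs
        assert doubled.hl == 2.0 * base.hl
        assert doubled.ps == base.ps  # ps scales with dose, not MU

    def test_ps_linear_in_fraction_dose(self, phantom, stray_config, plan6):
        base = od.component_doses(plan6, phantom, POINT, stray_config)
        bigger = od.TreatmentPlan(
            plan6.nominal_energy, plan6.technique, plan6.fields,
            plan6.fraction_dose * 2.0, plan6.n_fractions,
        )
        comp = od.component_doses(bigger, phantom, POINT, stray_config)
        assert comp.ps == pytest.approx(2.0 * base.ps, rel=1e-12)
        assert comp.cs == base.cs
        assert comp.hl == base.hl

    def test_unknown_energy_rejected(self, phantom, stray_config):
        cfg = od.StrayModelConfig(energies={6: stray_config.energies[6]})
        plan = od.plan_fixture("IMRT", 15)
        with pytest.raises(StrayConfigError):
            od.component_doses(plan, phantom, POINT, cfg)


class TestCrossEnergyCalibration:
    def test_reference_ratios_of_default_config(self, stray_config):
        ref6 = reference_components(stray_config, 6)
        ref15 = reference_components(stray_config, 15)
        assert ref6.ps / ref15.ps == pytest.approx(2.0, rel=1e-9)
        assert ref15.cs / ref6.cs == pytest.approx(1.5, rel=1e-9)

    def test_default_config_passes_all_constraints(self, stray_config):
        assert od.check_constraints(stray_config) == []

    def test_recalibration_recovers_constraints_after_perturbation(self,
                                                                   stray_config):
        from dataclasses import replace

        cfg6 = stray_config.energies[6]
        perturbed = od.StrayModelConfig(
            energies={
                6: od.stray.EnergyConfig(
                    ps=replace(cfg6.ps, amplitude=cfg6.ps.amplitude * 1.1),
                    cs=cfg6.cs,
                    hl=cfg6.hl,
                ),
                15: stray_config.energies[15],
            },
            calibrated=False,
        )
        assert od.check_constraints(perturbed) != []
        fixed = od.calibrate(perturbed)
        assert od.check_constraints(fixed) == []
        assert fixed.calibrated

    def test_infeasible_constraints_raise(self, stray_config):
        with pytest.raises(od.CalibrationError):
            od.calibrate(stray_config, CalibrationConstraints(
                ps_ratio_6_over_15=-1.0))


class TestSpatialShape:
    def test_components_decrease_along_mpax(self, stray_config, plan6):
        """Beyond the fusion boundary every component falls off with
        longitudinal distance from the field (uniform-thickness geometry;
        on a shaped body, thinning sections can locally raise the dose)."""
        from oofdose.stray import reference_phantom

        slab = reference_phantom()
        zs = np.arange(10.0, 39.0, 2.0)
        pts = np.column_stack([np.zeros_like(zs), np.zeros_like(zs), zs])
        comp = od.component_doses(plan6, slab, pts, stray_config)
        for vals in (comp.ps, comp.cs, comp.hl):
            assert np.all(np.diff(vals) <= 1e-12 * vals.max())

    def test_ps_dominates_near_field_edge_at_6mv(self, phantom, stray_config,
                                                 plan6):
        near = np.array([0.0, 0.0, 9.0])  # ~4 cm from the field edge
        comp = od.component_doses(plan6, phantom, near, stray_config)
        assert comp.ps > comp.cs
        assert comp.ps > comp.hl

    def test_hl_dominates_far_from_field_deep_in_body(self, phantom,
                                                      stray_config, plan6):
        far = np.array([0.0, 0.0, 75.0])  # head, ~65 cm from the field
        comp = od.component_doses(plan6, phantom, far, stray_config)
        assert comp.hl > comp.ps
        assert comp.hl > comp.cs

    def test_grid_value_matches_point_evaluation(self, phantom, stray_config,
                                                 plan6):
        grid = od.stray_dose_grid(plan6, phantom, stray_config)
        xs, ys, zs = phantom.voxel_centers()
        i, j, k = 22, 16, 80
        assert phantom.body_mask[i, j, k]
        probe = np.array([xs[i], ys[j], zs[k]])
        comp = od.component_doses(plan6, phantom, probe, stray_config)
        assert grid.values[i, j, k] == pytest.approx(float(comp.total), rel=1e-9)

    def test_zero_plan_gives_zero_grid(self, phantom, stray_config):
        plan = od.TreatmentPlan(
            6, "3DCRT", [od.BeamField(0.0, (10.0, 10.0), 0.0)], 0.0, 26
        )
        grid = od.stray_dose_grid(plan, phantom, stray_config)
        assert np.all(grid.values == 0)


class TestConfigIO:
    def test_yaml_round_trip(self, stray_config, tmp_path):
        path = tmp_path / "stray.yaml"
        stray_config.to_yaml(path)
        back = od.StrayModelConfig.from_yaml(path)
        for e in (6, 15):
            for comp in ("ps", "cs", "hl"):
                a = getattr(stray_config.energies[e], comp)
                b = getattr(back.energies[e], comp)
                assert a == b
        assert back.sad == stray_config.sad
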