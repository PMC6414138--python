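"""Dose fusion, whole-body summation, DEVHs and deviation statistics."""

import numpy as np
import pytest

import oofdose as od


@pytest.fixture
def lattice():
    """Small uniform lattice with a central target for fusion geometry."""
    shape = (8, 8, 40)
    spacing = (1.0, 1.0, 1.0)
    origin = (-3.5, -3.5, -19.5)
    tgt = np.zeros(shape, dtype=bool)
    tgt[2:6, 2:6, 17:23] = True  # target spans z in [-2.5, 2.5]
    return shape, spacing, origin, tgt


def grid_of(value, lattice, unit="Gy"):
    shape, spacing, origin, _ = lattice
    return od.DoseGrid(np.full(shape, float(value)), spacing, origin, unit)


class TestFuse:
    def test_identical_grids_fuse_to_either_with_zero_seam(self, lattice):
        *_, tgt = lattice
        g = grid_of(2.0, lattice)
        spec = od.FusionSpec(tgt, boundary_distance=4.0)
        fused, seam = od.fuse(g, g, spec, return_seam=True)
        assert np.array_equal(fused.values, g.values)
        assert seam.mean_relative_step == 0.0

    def test_zero_stray_gives_zero_beyond_boundary(self, lattice):
        shape, spacing, origin, tgt = lattice
        tps = grid_of(1.0, lattice)
        stray = grid_of(0.0, lattice)
        spec = od.FusionSpec(tgt, boundary_distance=4.0)
        fused = od.fuse(tps, stray, spec)
        zs = origin[2] + np.arange(shape[2]) * spacing[2]
        beyond = (zs <= -2.5 - 4.0) | (zs >= 2.5 + 4.0)  # dist >= 4: stray side
        assert np.all(fused.values[:, :, beyond] == 0)
        assert np.all(fused.values[:, :, ~beyond] == 1.0)

    def test_boundary_side_selection(self, lattice):
        """3.9 cm from the target takes the planning value, 4.1 cm the
        stray value (boundary at 4 cm)."""
        shape, spacing, origin, tgt = lattice
        tps = grid_of(1.0, lattice)
        stray = grid_of(5.0, lattice)
        spec = od.FusionSpec(tgt, boundary_distance=4.0)
        fused = od.fuse(tps, stray, spec)
        zs = origin[2] + np.arange(shape[2]) * spacing[2]
        # voxel centers at z = 5.5 (3 cm from target: inside boundary) and
        # z = 7.5 (5 cm from target: beyond it)
        assert fused.values[0, 0, int(np.argmin(np.abs(zs - 5.5)))] == 1.0
        assert fused.values[0, 0, int(np.argmin(np.abs(zs - 7.5)))] == 5.0

    def test_lattice_mismatch_rejected(self, lattice):
        *_, tgt = lattice
        g = grid_of(1.0, lattice)
        other = od.DoseGrid(np.ones(g.shape), g.spacing, (0.0, 0.0, 0.0))
        with pytest.raises(od.GridError):
            od.fuse(g, other, od.FusionSpec(tgt))


class TestTotalDoseEquivalent:
    def test_all_zero_inputs_give_zero(self, lattice):
        z = grid_of(0.0, lattice)
        total = od.total_dose_equivalent(z, z.copy_with(z.values, "Sv"), z, 23)
        assert np.all(total.values == 0)
        assert total.unit == "Sv"

    def test_unit_photon_grid_times_fractions(self, lattice):
        g = grid_of(1.0, lattice)
        total = od.total_dose_equivalent(g, None, None, 23)
        assert np.all(total.values == 23.0)

    def test_component_devhs_stack_below_total(self, lattice):
        rng = np.random.default_rng(5)
        shape, spacing, origin, tgt = lattice
        a = od.DoseGrid(rng.random(shape), spacing, origin)
        b = od.DoseGrid(rng.random(shape), spacing, origin)
        total = od.total_dose_equivalent(a, b.copy_with(b.values, "Sv"), None, 1)
        mask = np.ones(shape, dtype=bool)
        h_total = od.devh(total, mask)
        for part in (a, b):
            h_part = od.devh(part, mask)
            for d in np.linspace(0, 1.0, 7):
                assert h_total.fraction_at(d) >= h_part.fraction_at(d) - 1e-12


class TestDevh:
    def test_uniform_grid_step_function(self, lattice):
        g = grid_of(1.0, lattice, unit="Sv")
        mask = np.ones(g.shape, dtype=bool)
        h = od.devh(g, mask)
        assert h.fraction_at(0.0) == 1.0
        assert h.fraction_at(0.5) == 1.0
        assert h.fraction_at(1.5) == 0.0

    def test_half_volume_at_two_sv(self, lattice):
        shape, spacing, origin, _ = lattice
        vals = np.zeros(shape)
        vals[: shape[0] // 2] = 2.0
        g = od.DoseGrid(vals, spacing, origin, "Sv")
        h = od.devh(g, np.ones(shape, dtype=bool))
        assert h.fraction_at(1.0) == pytest.approx(0.5)

    def test_non_increasing_in_dose(self, lattice):
        rng = np.random.default_rng(11)
        shape, spacing, origin, _ = lattice
        g = od.DoseGrid(rng.random(shape), spacing, origin, "Sv")
        h = od.devh(g, np.ones(shape, dtype=bool))
        assert np.all(np.diff(h.volume_fraction) <= 1e-15)
        assert h.volume_fraction[0] == 1.0
        assert h.dose_edges[0] == 0.0

    def test_scaling_grid_shifts_devh_in_dose(self, lattice):
        rng = np.random.default_rng(12)
        shape, spacing, origin, _ = lattice
        g = od.DoseGrid(0.1 + rng.random(shape), spacing, origin, "Sv")
        h1 = od.devh(g, np.ones(shape, dtype=bool))
        h2 = od.devh(g.scaled(3.0), np.ones(shape, dtype=bool))
        for d in (0.2, 0.5, 0.9):
            assert h2.fraction_at(3.0 * d) == pytest.approx(
                h1.fraction_at(d), abs=0.02)

    def test_empty_mask_rejected(self, lattice):
        g = grid_of(1.0, lattice)
        with pytest.raises(ValueError):
            od.devh(g, np.zeros(g.shape, dtype=bool))


class TestDeviationStats:
    def test_perfect_agreement(self):
        s = od.deviation_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s.mean_percent == 0.0
        assert s.sd_percent == 0.0
        assert s.n == 3

    def test_uniform_ten_percent_overestimate(self):
        meas = np.array([1.0, 2.0, 5.0])
        s = od.deviation_stats(1.1 * meas, meas)
        assert s.mean_percent == pytest.approx(10.0)
        assert s.sd_percent == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_deviations_sample_sd(self):
        s = od.deviation_stats([1.1, 0.9], [1.0, 1.0])
        assert s.mean_percent == pytest.approx(0.0, abs=1e-12)
        assert s.sd_percent == pytest.approx(100.0 * 0.2 / np.sqrt(2), rel=1e-9)

    def test_zero_measurement_rejected(self):
        with pytest.raises(ValueError):
            od.deviation_stats([1.0], [0.0])


class TestBandRatio:
    def make_devh(self, values, lattice, unit="Sv"):
        shape, spacing, origin, _ = lattice
        g = od.DoseGrid(values, spacing, origin, unit)
        return od.devh(g, np.ones(shape, dtype=bool))

    def test_identical_devhs_give_unity(self, lattice):
        rng = np.random.default_rng(3)
        vals = 0.1 + rng.random(lattice[0])
        h = self.make_devh(vals, lattice)
        assert od.band_ratio(h, h, (0.2, 1.0)) == pytest.approx(1.0)

    def test_uniformly_doubled_grid_gives_two(self, lattice):
        rng = np.random.default_rng(4)
        vals = 0.2 + 0.3 * rng.random(lattice[0])
        h1 = self.make_devh(vals, lattice)
        h2 = self.make_devh(2.0 * vals, lattice)
        assert od.band_ratio(h2, h1, (0.05, 2.0)) == pytest.approx(2.0, rel=0.05)

    def test_empty_band_rejected(self, lattice):
        vals = np.full(lattice[0], 5.0)
        h = self.make_devh(vals, lattice)
        with pytest.raises(ValueError):
            od.band_ratio(h, h, (0.01, 0.02))
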