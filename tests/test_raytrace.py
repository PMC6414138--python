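"""Radiological-depth ray tracing against a fine-step numerical oracle."""

import numpy as np
import pytest

import oofdose as od
from oofdose.phantom import radiological_depth, radiological_depths
from oofdose.raytrace import OutsideGridError


def fine_step_depth(source, point, phantom, step=0.01):
    """Independent oracle: fixed-step numerical line integral of density."""
    src = np.asarray(source, dtype=float)
    pt = np.asarray(point, dtype=float)
    seg = pt - src
    length = np.linalg.norm(seg)
    n = max(int(np.ceil(length / step)), 1)
    # midpoint rule over n sub-segments
    t = (np.arange(n) + 0.5) / n
    samples = src + t[:, None] * seg
    idx = np.floor(
        (samples - (np.asarray(phantom.origin) - 0.5 * np.asarray(phantom.spacing)))
        / np.asarray(phantom.spacing)
    ).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(phantom.shape)), axis=1)
    dens = np.zeros(n)
    ii = idx[inside]
    dens[inside] = phantom.density[ii[:, 0], ii[:, 1], ii[:, 2]]
    return dens.sum() * length / n


def slab_phantom(layers, spacing=0.5):
    """Slab phantom stacked along y: layers = [(thickness_cm, density), ...]."""
    total = sum(t for t, _ in layers)
    ny = int(round(total / spacing))
    nx = nz = 20
    density = np.zeros((nx, ny, nz))
    y0 = 0.0
    for thickness, rho in layers:
        j0 = int(round(y0 / spacing))
        j1 = int(round((y0 + thickness) / spacing))
        density[:, j0:j1, :] = rho
        y0 += thickness
    mask = density > 0
    material = np.where(mask, 1, 0).astype(np.int8)
    origin = (
        -(nx - 1) / 2.0 * spacing,
        0.5 * spacing,  # front face of the slab at y = 0
        -(nz - 1) / 2.0 * spacing,
    )
    return od.VoxelPhantom(density, mask, material, (spacing, spacing, spacing), origin)


ANTERIOR = od.SourcePoint.from_gantry_angle(0.0)  # source at (0, 100, 0)


class TestKnownPaths:
    def test_uniform_soft_tissue_depth_equals_geometric_path(self):
        ph = slab_phantom([(10.0, 1.0)])
        # beam enters the slab at y = 10 and travels to y = 0: 10 cm of tissue
        d = radiological_depth(ANTERIOR, (0.0, 0.25, 0.0), ph)
        assert d == pytest.approx(10.0 - 0.25, abs=1e-9)

    def test_lung_layer_scales_by_quarter_density(self):
        # beam passes 4 cm of lung (0.25) then 6 cm of soft tissue:
        # radiological depth = 0.25 * 4 + 6 = 7 cm
        ph = slab_phantom([(6.0, 1.0), (4.0, 0.25)])
        d = radiological_depth(ANTERIOR, (0.0, 0.0 + 1e-6, 0.0), ph)
        assert d == pytest.approx(0.25 * 4 + 6, rel=1e-6)

    def test_entry_surface_point_has_zero_depth(self):
        ph = slab_phantom([(10.0, 1.0)])
        d = radiological_depth(ANTERIOR, (0.0, 10.0 - 1e-9, 0.0), ph)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_point_outside_grid_raises(self, water_slab):
        with pytest.raises(OutsideGridError):
            radiological_depth(ANTERIOR, (0.0, 0.0, 500.0), water_slab)


class TestProperties:
    def test_depth_monotone_along_ray(self, phantom):
        # points marching away from the source along one ray
        src = ANTERIOR
        t = np.linspace(0.55, 1.0, 40)
        far = np.array([3.0, -11.0, 20.0])
        pts = src.position + t[:, None] * (far - src.position)
        depths = radiological_depths(src, pts, phantom)
        assert np.all(np.diff(depths) >= -1e-12)

    def test_density_scaling_scales_depth_exactly(self, phantom):
        pts = np.array([[0.0, 0.0, 0.0], [2.0, -3.0, 40.0], [0.0, 0.0, 63.0]])
        base = radiological_depths(ANTERIOR, pts, phantom)
        scaled = od.VoxelPhantom(
            phantom.density * 1.7, phantom.body_mask, phantom.material,
            phantom.spacing, phantom.origin, mpax=phantom.mpax,
        )
        assert np.allclose(
            radiological_depths(ANTERIOR, pts, scaled), 1.7 * base, rtol=1e-12
        )

    def test_agrees_with_fine_step_oracle_on_random_phantoms(self):
        rng = np.random.default_rng(1234)
        for _ in range(4):
            density = rng.uniform(0.0, 1.5, size=(12, 14, 10))
            mask = density > 0.2
            density[~mask] = 0.0
            ph = od.VoxelPhantom(
                density, mask, mask.astype(np.int8),
                spacing=(0.9, 0.7, 1.1),
                origin=(-5.0, -4.5, -5.5),
            )
            src = rng.uniform(-80, 80, size=3)
            src[1] = 120.0
            for _ in range(5):
                pt = rng.uniform([-4, -4, -5], [4, 4, 4])
                exact = od.radiological_depth(od.SourcePoint(src), pt, ph)
                approx = fine_step_depth(src, pt, ph)
                assert exact == pytest.approx(approx, rel=0.01, abs=1e-3)


class TestMpaxProfile:
    def test_uniform_grid_gives_constant_profile(self, phantom):
        g = od.DoseGrid(np.ones(phantom.shape), phantom.spacing, phantom.origin)
        prof = od.mpax_profile(g, phantom)
        assert len(prof) == len(phantom.mpax)
        assert np.allclose(prof[:, 1], 1.0)
        assert np.all(np.diff(prof[:, 0]) > 0)  # inferior -> superior

    def test_linear_ramp_reproduced(self, phantom):
        _, _, zs = phantom.voxel_centers()
        vals = np.broadcast_to(5.0 + 0.1 * zs[None, None, :], phantom.shape)
        g = od.DoseGrid(vals, phantom.spacing, phantom.origin)
        prof = od.mpax_profile(g, phantom)
        assert np.allclose(prof[:, 1], 5.0 + 0.1 * prof[:, 0], rtol=1e-9)

    def test_empty_mpax_gives_empty_profile(self, water_slab):
        g = od.DoseGrid(np.ones(water_slab.shape), water_slab.spacing,
                        water_slab.origin)
        prof = od.mpax_profile(g, water_slab)
        assert prof.shape == (0, 2)

    def test_lattice_mismatch_rejected(self, phantom):
        g = od.DoseGrid(np.ones(phantom.shape), phantom.spacing,
                        origin=(0.0, 0.0, 0.0))
        with pytest.raises(od.GridError):
            od.mpax_profile(g, phantom)
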