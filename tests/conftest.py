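import numpy as np
import pytest

import oofdose as od


@pytest.fixture(scope="session")
def spec():
    return od.SyntheticSpec()


@pytest.fixture(scope="session")
def phantom(spec):
    return od.build_phantom(spec)


@pytest.fixture(scope="session")
def target(spec, phantom):
    return od.target_mask(spec, phantom)


@pytest.fixture(scope="session")
def probes(spec, phantom):
    return od.probe_locations(spec, phantom)


@pytest.fixture(scope="session")
def oof_points(probes):
    oof = probes[probes.out_of_field]
    return oof[["x", "y", "z"]].to_numpy()


@pytest.fixture(scope="session")
def stray_config():
    return od.default_config()


@pytest.fixture
def water_slab():
    """Uniform 20 x 20 x 40 cm^3 soft-tissue slab centred on the isocenter."""
    spacing = (1.0, 1.0, 1.0)
    shape = (20, 20, 40)
    density = np.ones(shape)
    mask = np.ones(shape, dtype=bool)
    material = np.ones(shape, dtype=np.int8)
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    return od.VoxelPhantom(density, mask, material, spacing, origin)
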