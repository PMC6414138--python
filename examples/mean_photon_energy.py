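"""Out-of-field mean photon energy and TLD energy-response correction.

Computes the dose-weighted mean photon energy at the out-of-field probe
sites of the synthetic phantom for the three 6 MV and the three 15 MV
plans, and converts one energy into a detector correction factor.  The
out-of-field spectrum is much softer (~0.4 MeV) than the nominal beam,
so detectors calibrated in-beam need per-location corrections.
"""

import numpy as np

import oofdose as od

spec = od.SyntheticSpec()
phantom = od.build_phantom(spec)
probes = od.probe_locations(spec, phantom)
points = probes[probes.out_of_field][["x", "y", "z"]].to_numpy()
config = od.default_config()

for energy in (6, 15):
    en = od.component_energies(energy)
    all_e = []
    for tech in ("3DCRT", "IMRT", "VMAT"):
        comp = od.component_doses(od.plan_fixture(tech, energy), phantom,
                                  points, config)
        all_e.append(od.mean_energy(comp, en))
    stacked = np.concatenate(all_e)
    print(
        f"{energy:>2} MV plans: mean photon energy over "
        f"{len(points)} out-of-field sites = "
        f"{stacked.mean():.2f} +- {stacked.std(ddof=1):.2f} MeV"
    )

# a TLD-like chip that over-responds toward softer spectra
curve = od.ResponseCurve(
    "TLD-like", [0.1, 0.3, 0.6, 1.25, 6.0], [1.30, 1.12, 1.05, 1.0, 1.0],
    calibration_energy=1.25,
)
factor = od.correction_factor(0.40, curve)
print(
    f"\nAt 0.40 MeV this detector over-responds by "
    f"{100 * (1 / factor - 1):.0f}%, so detected doses are multiplied by "
    f"{factor:.3f}."
)
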