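"""Whole-body dose equivalent and DEVH-based technique comparison.

Runs the full pipeline for the three 15 MV plans on the synthetic
phantom — stray model fused with the planning-system grid at the 4 cm
boundary, neutron dose equivalent, daily CBCT imaging dose — and
compares the techniques by the median out-of-field dose equivalent in
the low/intermediate band (0.05-5% of the prescribed dose).  The
between-technique factors track the ratio of total monitor units.
"""

import oofdose as od

spec = od.SyntheticSpec()
phantom = od.build_phantom(spec)
target = od.target_mask(spec, phantom)

devhs = {}
for tech in ("3DCRT", "IMRT", "VMAT"):
    plan = od.plan_fixture(tech, 15)
    td = od.treatment_dose_equivalent(plan, phantom, target)
    oof = td.out_of_field_mask(phantom.body_mask)
    devhs[tech] = od.devh(td.therapy_total(), oof)
    print(
        f"{tech:>6}: fusion seam mean step "
        f"{100 * td.seam.mean_relative_step:.0f}%, "
        f"out-of-field max {td.therapy_total().values[oof].max():.2f} Sv, "
        f"CBCT adds {td.plan.n_fractions * td.cbct.values.max():.2f} Sv in-FOV"
    )

presc = 50.6
band = (5e-4 * presc, 5e-2 * presc)
imrt = od.band_ratio(devhs["IMRT"], devhs["3DCRT"], band)
vmat = od.band_ratio(devhs["VMAT"], devhs["3DCRT"], band)
print(
    f"\nband-median out-of-field dose-equivalent ratios (band "
    f"{band[0]:.3f}-{band[1]:.2f} Sv):\n"
    f"  IMRT/3DCRT = {imrt:.2f} (~4: IMRT needs ~3.7x the MU)\n"
    f"  VMAT/3DCRT = {vmat:.2f} (~2: VMAT needs ~2x the MU)\n"
    "VMAT spares the rest of the body relative to IMRT at equal target dose."
)
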