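"""Peripheral neutron dose equivalent along the patient midline.

Computes the 15 MV neutron dose equivalent per session along the MPAX
for the three techniques.  The profile peaks where the least tissue
shields the midline — the neck — and, divided by the delivered MU, is
nearly identical for all techniques: neutrons scale with beam-on time,
not with field shaping.  Also shows the paired-TLD signal conversion.
"""

import numpy as np

import oofdose as od

spec = od.SyntheticSpec()
phantom = od.build_phantom(spec)
ncfg = od.NeutronModelConfig()

print("15 MV neutron dose equivalent per session along the MPAX:")
for tech in ("3DCRT", "IMRT", "VMAT"):
    plan = od.plan_fixture(tech, 15)
    h = od.neutron_dose_equivalent(plan, phantom, phantom.mpax, ncfg)
    z = phantom.mpax[:, 2]
    k = int(np.argmax(h))
    per_mu = h[k] / (plan.total_mu / plan.n_fractions)
    print(
        f"  {tech:>6}: peak {h[k] * 1e3:.2f} mSv/session at z = {z[k]:.0f} cm "
        f"(neck), {per_mu * 1e9:.2f} nSv/MU"
    )
print("(peak per MU is technique-independent: neutrons track monitor units)")

res = od.tld600_to_doseequiv(
    raw_signal=0.030, photon_dose=0.025, mean_energy=0.45, depth=8.0,
    config=ncfg,
)
print(
    "\npaired-TLD example: raw TLD600 signal 0.030, photon part 0.025 ->\n"
    f"residual neutron signal 0.005 x depth factor "
    f"{ncfg.depth_factor(8.0):.3f} = {res.dose_equivalent_sv * 1e3:.2f} mSv"
)
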