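# oofdose

Whole-body out-of-field dose-equivalent modelling for image-guided
radiotherapy (IGRT).

Treatment planning systems compute dose accurately around the target but
not in the rest of the body, where scattered and leakage radiation —
and, above the photoneutron threshold, neutrons — deposit the unwanted
"peripheral" dose that drives second-cancer risk and fetal-exposure
estimates.  `oofdose` assembles the whole-body dose equivalent of an
IGRT treatment from analytical models and lets you compare delivery
techniques (3DCRT, IMRT, VMAT) and nominal beam energies (6 vs 15 MV):

* **Photon stray dose** as the sum of patient scatter (`ps`), collimator
  scatter (`cs`) and head leakage (`hl`).  Each component is
  `amplitude × lateral falloff(distance to field edge) × exp(−depth/λ)`,
  where depth is the radiological (density-scaled) path length from the
  X-ray target, traced through the voxel phantom with an exact
  Siddon-style traversal.  `ps` scales with the delivered target dose,
  `cs` and `hl` scale linearly with monitor units (MU).
* **Peripheral neutron dose equivalent** for 15 MV: a point source at
  the X-ray target, inverse-square geometry and exponential attenuation
  with radiological depth (lungs at 0.25 × soft-tissue density), plus
  the paired-TLD (TLD600/TLD700H) signal conversion.
* **CBCT imaging dose**: per-slice mean doses interpolated along the
  patient midline (MPAX), constant within each transversal slice, with
  an exponential tail outside the field of view.
* **Fusion and comparison**: the planning-system grid is fused with the
  stray model 4 cm longitudinal from the treatment volume; per-session
  photon + neutron + imaging doses are scaled to the full treatment and
  compared through cumulative dose-equivalent volume histograms (DEVHs).
* **Mean photon energy**: per location,
  `Ē = (D_ps·E_ps + D_cs·E_cs + D_hl·E_hl) / (D_ps + D_cs + D_hl)`,
  used to correct TLD readings for their energy-dependent response.
* **Synthetic study inputs**: an anthropomorphic-phantom surrogate
  (stacked elliptical sections, lungs at 0.25 density), six pelvis plan
  fixtures with published MU totals, TLD-like probe sites and
  pseudo-measurements with 10% multiplicative noise.

## Worked example

```sh
python examples/whole_body_devh.py
```

```
 3DCRT: fusion seam mean step 8%, out-of-field max 0.53 Sv, CBCT adds 0.52 Sv in-FOV
  IMRT: fusion seam mean step 8%, out-of-field max 0.65 Sv, CBCT adds 0.46 Sv in-FOV
  VMAT: fusion seam mean step 8%, out-of-field max 0.55 Sv, CBCT adds 0.46 Sv in-FOV

band-median out-of-field dose-equivalent ratios (band 0.025-2.53 Sv):
  IMRT/3DCRT = 3.16 (~4: IMRT needs ~3.7x the MU)
  VMAT/3DCRT = 1.82 (~2: VMAT needs ~2x the MU)
VMAT spares the rest of the body relative to IMRT at equal target dose.
```

The seam step is the relative dose mismatch where the planning-system
grid hands over to the stray model; the band-median ratios compare the
median out-of-field dose equivalent between techniques in the
low/intermediate dose band (0.05–5% of the prescribed dose).  Because
collimator scatter, head leakage and neutrons are MU-linear, those
factors track the monitor units each technique needs for the same
prescription — the reason VMAT is preferable to dynamic IMRT for
radiation protection of the patient.

Other examples: `plan_accounting.py` (MU bookkeeping of the six plan
fixtures), `stray_components.py` (which component dominates where),
`mean_photon_energy.py` (out-of-field spectrum softening and detector
correction factors), `neutron_profile.py` (neutron peak in the neck,
per-MU technique independence).

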