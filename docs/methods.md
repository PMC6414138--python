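# Methods

## Scope and coordinate conventions

`oofdose` models the whole-body dose equivalent of a coplanar external
photon-beam treatment with daily cone-beam CT positioning.  Room
coordinates place the isocenter at the origin; `z` is the longitudinal
patient axis (inferior → superior), gantry angle 0° puts the source
anterior at the source–axis distance (default 100 cm, TrueBeam-like),
rotating about `z` (IEC convention, viewed from the couch foot).  Grids
put voxel centers on the lattice with half-open voxel extents; off-
lattice values are trilinear.  The reference grid spacing for clinical
use is 0.2 × 0.2 × 0.5 cm³; the synthetic study runs at 0.8 × 0.8 ×
1.0 cm³ (the generator default) so the full six-plan pipeline completes
in seconds — spacing is a parameter, not a model assumption.

## Radiological depth

All in-phantom attenuation uses the radiological depth: the line
integral of (density / soft-tissue density) from the X-ray target to
the point, traced with an exact Siddon-style voxel traversal (each
voxel contributes its density × intersected length; numba-compiled and
parallel for per-voxel grids).  Lungs carry 0.25 × soft-tissue density,
so a lung crossing contributes a quarter of its geometric length.  A
fixed-step numerical integrator exists only in the test suite as an
independent oracle (agreement within 1%).  Depth is exactly linear in a
global density rescaling and non-decreasing along a ray — both asserted
as properties.

## Photon stray dose

The out-of-field photon dose is the sum over beam fields of three
components, each of the form

    D_i = A_i · S_i · L_i(d_edge) · exp(−t / λ_i)

with `d_edge` the distance to the 50%-fluence aperture rectangle
projected to the isocenter plane, `t` the radiological depth, and the
lateral falloff `L(d) = w·exp(−d/ℓ₁) + (1−w)·(ℓ₂/(ℓ₂+d))²` — an
exponential near-field term with an inverse-square far tail.  The
scaling `S_i` differs per component: patient scatter scales with the
target dose delivered per session (apportioned over fields by MU share)
and with `(field area / 100 cm²)^0.5`; collimator scatter and head
leakage scale with the MU per session.  Head leakage has no lateral
falloff; it varies only through inverse-square distance to the source
and depth attenuation (its calibration absorbs the neutron-capture
gamma contribution, which is therefore not modelled separately).

Default parameters (per energy; lateral/depth shapes shared between
energies because the measured component mean energies barely differ):

| component | amplitude 6 MV | amplitude 15 MV | w | ℓ₁ (cm) | ℓ₂ (cm) | λ (cm) |
|---|---|---|---|---|---|---|
| ps (per Gy) | 0.040 | 0.020 | 0.70 | 5 | 8 | 30 |
| cs (per MU) | 2.0·10⁻⁵ | 3.0·10⁻⁵ | 0.75 | 25 | 30 | 16 |
| hl (per MU) | 8.8·10⁻⁶ | 8.0·10⁻⁶ | — | — | — | 60 |

The defaults were calibrated once, at design time, against the printed
behaviour of the measured components and then frozen:

* patient scatter per delivered Gy is exactly 2× higher at 6 MV, and
  collimator scatter per MU exactly 1.5× lower at 6 MV, at the
  reference condition (10 × 10 cm² field on a 30 cm water slab, point
  30 cm from the isocenter on the axis);
* near the field edge patient scatter is the largest component (6 MV);
  far from the field and deep in the body head leakage dominates;
* the probe-population mean photon energies land near 0.40 MeV (6 MV)
  and 0.47 MeV (15 MV) — see below;
* head leakage is mildly lower at 15 MV (ratio 1.1), chosen so that
  same-technique whole-body DEVHs stay close between the two energies,
  as observed for such treatments.

`calibrate()` re-imposes the cross-energy ratios exactly by rescaling
the 6 MV amplitudes against the 15 MV anchor and verifies monotone
falloff on the reference slab; it raises with a report if the
constraint set is infeasible.  Monotone falloff along the midline holds
exactly on uniform-thickness geometry; on a shaped body the depth
attenuation legitimately raises components where the body thins (the
neck), which is also why the neutron profile peaks there.

`fit_amplitudes()` recovers the three amplitudes from measured doses by
linear least squares on the unit-amplitude component shapes, weighted
by 1/measurement so residuals are relative (out-of-field doses span
orders of magnitude).  With 10% lognormal noise at ~150 probe sites and
three plans, amplitudes come back within a few percent.

## Neutron dose equivalent

For 15 MV beams (zero below the photoneutron threshold):

    H = MU_session · s / r² · exp(−t / λ_n)

summed over fields, with `s` the point-source strength at the X-ray
target (Sv·cm²/MU), `r` the distance to the per-field source position,
`t` the radiological depth (density-scaled through lung) and λ_n the
tissue attenuation length.  VMAT arcs are first discretized into six
static fields (MU-conserving angular binning).  In-field voxels are set
to zero — the model is peripheral only, as the neutron contribution is
negligible against the primary photon dose inside the beam.

The shipped constants (`s` = 0.03 Sv·cm²/MU, λ_n = 9 cm, synthetic
depth-conversion and fluence-to-dose-equivalent tables) are order-of-
magnitude placeholders and the config is flagged `calibrated=False`:
absolute neutron dose equivalents are indicative, while ratios and
shapes (MU linearity, exponential depth law, technique independence per
MU, the neck peak at minimum radiological depth) are parameter-robust
and are what the tests assert.  The paired-TLD conversion subtracts the
photon-equivalent signal (photon dose × detector response at the local
mean photon energy) from the raw TLD600 signal and multiplies the
residual by a depth-dependent factor; negative residuals clamp to zero
with a warning flag.

## CBCT imaging dose

A full-trajectory pelvis CBCT is assumed for every session.  Per-slice
mean doses are linearly interpolated along the MPAX and applied
uniformly within each transversal slice (a good approximation for a
full rotation); outside the sampled range the dose decays exponentially
with a 6 cm default tail length (the measured falloff shape; the
constant is configurable as it is protocol-dependent).  The shipped
profile is synthetic — a ~20 mGy/scan plateau across the ±8.75 cm field
of view — and a measured profile is a required input for real use.

## Mean photon energy and detector response

The local mean photon energy is the dose-weighted average of the
component mean energies, with defaults per nominal energy of
0.28/0.62/0.35 MeV (6 MV) and 0.29/0.53/0.45 MeV (15 MV) for ps/cs/hl;
the collimator-scatter value is the one measured 35 cm from the field
edge, the region where collimator scatter matters most relative to the
other components.  The result is convex in the component energies and
invariant under uniform rescaling of the dose triple.  Detector
response curves are editable tables normalized to 1 at the calibration
energy, linearly interpolated; the correction factor is the reciprocal
response at the local mean energy.

## Fusion, DEVHs and comparisons

Fusion is a hard switch at a longitudinal boundary 4 cm from the
treatment volume (≈3 cm from the field edge): planning-system dose
inside, stray model outside, justified by their agreement in the
overlap region.  The seam report quantifies the relative step on the
boundary-adjacent slices; on the synthetic study it averages ~8%
(max ~20%).  The per-treatment dose equivalent is
`(photon + neutron + CBCT) × n_sessions`, with photon Gy entering at
radiation weighting factor 1.

DEVHs are cumulative (fraction of the masked volume receiving at least
each dose) on 200 log-spaced bins from 10⁻⁴ Sv to the grid maximum,
preceded by a zero-dose edge at fraction 1.  Technique comparisons use
the band-median dose: the median dose received by the volume falling in
the low/intermediate band, default 0.05–5% of the prescribed dose.
These comparisons are computed on the treatment-delivery dose
equivalent (photon + neutron, `TreatmentDose.therapy_total()`): the
imaging dose is identical for every technique, so including it only
dilutes between-technique factors toward 1 without changing the
ranking.  A near-minimum-dose ratio (dose covering 98% of the volume)
is provided as an alternative statistic.

## Synthetic study inputs

The phantom surrogate stacks elliptical sections — pelvis (semi-axes
17 × 12 cm), abdomen (15 × 11), thorax (16 × 11) with two lung
ellipsoids flanking the midline, neck (5.5 × 6) and head (8.5 × 10.5) —
from z = −20 to +86 cm, soft tissue at 1.0 g/cm³ and lungs at 0.25.
The neck is the thinnest section, so the radiological depth to the
midline is smallest there.  The target is a 3 × 3 × 4 cm ellipsoid at
the isocenter (a pelvic-sarcoma surrogate).  The MPAX is a straight
longitudinal line through the isocenter's transverse position (the
body's curvature is not followed; configurable through the spec).

Plan fixtures carry the published totals — 3DCRT 2.0 Gy × 26 with
7326/5846 MU (6/15 MV), IMRT and VMAT 2.2 Gy × 23 with 22989/21661 and
13409/11847 MU — split equally over four (3DCRT) or five (IMRT) fields,
or over a 360° arc discretized to six fields (VMAT); gantry angles are
conventional defaults (0/90/180/270°, five equispaced, full arc), as
the per-field breakdown is not part of the published accounting and
only totals enter the MU-scaled components.

189 TLD-like probe sites sit on regular transversal slices, five per
slice at the midline and half the local cross-section, nudged to ≥1 cm
below the surface; ~160 lie beyond the fusion boundary (out-of-field).
Pseudo-measurements are model truth × lognormal multiplicative noise
(σ = 0.10, the agreement level of careful TLD dosimetry), seeded and
reproducible.  The synthetic planning-system grid is the prescription
in the target with a steep exponential penumbra (0.55 cm) plus the
stray-model dose scaled by 0.92 outside the target, so the fusion seam
is consistent by construction (planning systems slightly underestimate
the near-boundary out-of-field dose).

What passing on these inputs shows — and what it does not: the
synthetic body reproduces the geometric structure that drives the
models (thickness variation, lungs, a thin neck, realistic probe
coverage), and the noise model reproduces the measurement scatter.  It
does not contain real anatomy, CT-calibrated densities, skin/buildup
regions or organ contours, so absolute organ doses and skin doses are
out of reach by construction.

## Known limitations

* The stray model carries no surface-buildup term and underestimates
  skin dose (reportedly up to a factor of two for such algorithms);
  electron contamination is not modelled.
* The neutron constants are placeholders (`calibrated=False`); absolute
  neutron dose equivalents require commissioning against the machine.
  The simple density scaling through lung is known to overestimate the
  neutron dose there.
* Capture gammas are folded into head leakage rather than modelled
  separately; non-coplanar beams, wedges and flattening-filter-free
  modes are out of scope.
* The CBCT builder assumes transversal-slice homogeneity and an
  exponential tail; bowtie-filter in-slice structure and other imaging
  protocols are not modelled.
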