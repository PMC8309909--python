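# Methods

`torsoecg` quantifies how displacing ECG electrodes away from the
Einthoven/Mason–Likar reference placement distorts the recorded leads.
It couples three components: a voxel bidomain FitzHugh–Nagumo heart in
a passive torso volume conductor; a synthetic volunteer cohort
generator standing in for an unavailable 20-subject recording campaign;
and a signal-comparison stack (ensemble-average ECG, segment
coefficients, dynamic time warping, SNR, percentage
difference/similarity).

## Volume conductor and electrode geometry

The torso is an elliptic cylinder on a cell-centered voxel grid
(default 40×48×24 at 1 cm; x = subject's left, y = cranial,
z = anterior). From the skin inward: subcutaneous fat (2 cm), muscle
(2 cm), a rib-cage bone shell (1.5 cm over the thoracic band), then
homogeneous torso bulk with two ellipsoidal lungs and a two-chamber
heart. Passive conductivities (mS/m): torso and muscle 200, fat and
lungs 40, bone 6, blood 700, heart tissue 50 in the passive sense. All
regions are analytic shapes in physical units, so label volume
fractions converge under grid refinement; the node-scale conduction
clusters (SAN, AVN, His, bundle) are only 1–3 voxels at the default
resolution and are excluded from that statement.

The heart comprises an atrial shell stacked above a ventricular shell,
each with a blood cavity, separated by an insulating atrioventricular
gap. The conduction system is laid out for function rather than
anatomy-book fidelity: a sinoatrial (SAN) cap at the atrial roof apex
protruding into the passive surroundings (the real node is largely
insulated; an exposed node is phase-dispersed by the atrial load), an
AVN column descending through the atrial cavity and AV gap, a His
column crossing the ventricular roof, a bundle column running down the
cavity and fanning into a cap on the lower endocardium, and a Purkinje
layer lining the inner ventricular wall so activation spreads
endocardium-outward.

Electrodes follow the Mason–Likar torso placement: LA/RA in the
infraclavicular fossae separated by the inter-clavipectoral-triangle
distance `Wh` (cohort mean 28.8 cm), LL at the umbilical level a
vertical drop `Wv` (43.2 cm) below the sternal angle, RL mirrored on
the right as the reference (VGND = 0). Displaced configurations 1–6
contract the triangle toward its centroid in whole steps of
(f·Wh, f·Wv) with f = 0.125 — 3.6 cm horizontally and 5.4 cm
vertically at the cohort means — with step counts (1,0), (0,1), (1,1),
(2,1), (1,2), (2,2), so the displacement magnitude grows strictly with
the index (3.6 → 13.0 cm). The layout of the displaced positions
relative to anatomical landmarks is a documented convention of this
package: the source study shows the positions only pictorially.

## Cell model and its integration

Each heart subdomain carries a two-variable modified FitzHugh–Nagumo
model in the transmembrane potential `Vm` (SI volts internally;
parameter tables are stored and reported in their printed units):

    dVm/dt = k·c1·(Vm−B)·((Vm−B)/A − a)·(1 − (Vm−B)/A) − R + diffusion
    du/dt  = k·e·((Vm−B)/A − d·u − b)

with recovery current `R = k·c2·u` in the SAN and
`R = k·c2·u·(Vm−B)` elsewhere. The sign convention makes rest `Vm = B`
stable wherever `a > 0` and the SAN (`a = −0.6`) a relaxation
oscillator. With the tabulated values the SAN period is 0.840 s
(≈71 bpm), verified against an adaptive stiff (Radau) integration; its
steady peak-to-peak swing is 61.6 mV, a property of the printed
parameters' cubic branch geometry. Working-myocardium action
potentials peak near +52 mV with durations ordered by `e` (atria
~105 ms, ventricles ~207 ms), which is what produces a T wave.

The SAN reaction has rate constant `k·c1 = 10⁶ s⁻¹` and is stiff, so
every reaction step solves the backward-Euler update exactly: the
update polynomial is cubic in `Vm` for every subdomain, and the root is
computed in closed form (vectorized Cardano), selecting the real root
nearest the explicit-Euler prediction — which both continues gentle
suprathreshold growth correctly and lands the stiff SAN branch jumps on
the correct branch. The recovery variable uses its exact exponential
update. Diffusion is a semi-implicit solve with a prefactorized sparse
operator. Default time step 0.1 ms; outputs sampled at 250 Hz.

## Conduction on a coarse grid

Four engineering measures, all documented here as deliberate modeling
choices, are required before the printed parameters produce stable
sinus rhythm at desk scale:

1. **Refined heart subgrid.** FHN fronts at these parameters are
   narrower than 1 cm, so the active tissue is re-voxelized from the
   same analytic shapes at half the torso spacing (0.5 cm default,
   ~3 600 cells); the extracellular field is aggregated back to the
   coarse cells for the torso solve. The diffusivity scale (the
   conduction-velocity calibration) is fixed once at
   `8·10⁻³ m²·s⁻¹ per mS/m`.
2. **Graded interface conductivity.** Printed conductivities jump more
   than an order of magnitude between conduction-system subdomains. On
   a voxel grid an abrupt step makes the last cell before the step a
   fixed-ratio current divider that no global scaling can fire; two
   neighbor-averaging passes over σ (transitional tissue) turn each
   step into a climbable ramp.
3. **Rectified junctions.** The SAN→atrium and AVN→His couplings are
   one-way. Symmetric coarse junctions fail in both directions: every
   atrial action potential resets and accelerates the enlarged
   pacemaker (collapsing the sinus period), and the long-plateau
   His/bundle tissue re-excites the fast-recovering node retrogradely,
   sustaining an atrial echo loop. The real millimetre-scale structures
   are electrotonically protected/decremental; the rectifier is the
   coarse-grid expression of that. The AV junction additionally carries
   an explicit 80 ms nodal delay, giving a physiological PR segment.
4. **Space-clamped node.** The anatomical SAN is a millimetre structure
   that oscillates as one unit; the model's node is centimetre-scale
   for grid reasons, so its internal coupling is strengthened (×25) to
   keep it coherent, and it contributes no far-field source (see
   below).

With these in place the model runs indefinitely at a fixed 0.840 s
cycle: P wave, ~80 ms PR segment, ~35 ms QRS (≈0.7 mV in D2),
isoelectric ST, and a repolarization wave ~200 ms later.

## Torso coupling and lead formation

The printed heart conductivities satisfy σe = σi in every subdomain,
under which the bidomain pair reduces exactly to a monodomain with the
series conductivity. The body potential solves one global quasi-static
elliptic system: `∇·((σe+σi)∇Ve) = −∇·(σi∇Vm)` inside the heart,
`∇·(σ0∇V) = 0` in the passive tissues, zero normal current through the
torso surface, with the interface condition `V = Ve` holding by
construction (single continuous field). A uniformly depolarized
chamber is then electrically silent at the surface (closed double
layer), which a volume-Dirichlet shortcut would violate by several mV
of ST offset. The Neumann system is grounded at one fixed cell and the
leads re-referenced to the right-leg electrode, realizing VGND = 0; the
bipolar leads are D1 = VLA−VRA, D2 = VLL−VRA, D3 = VLL−VLA, so
D1 + D3 = D2 to rounding. SAN cells carry no source term: the real
node's far-field contribution is below measurement resolution, whereas
the grid-enlarged node would imprint its diastolic drift on every
lead. The factorized solve is reused at every output sample
(potentials are quasi-static).

Verification: the default-resolution solve agrees with a 1.33×-refined
solve within 5 % away from the source for a smooth dipolar blob in a
homogeneous conductor; at 1.5 cm spacing the thin-shell anatomy is no
longer resolved and deviations reach ~14 %, which bounds the useful
coarseness of the torso grid.

## Synthetic cohort

Each subject draws segment coefficients per lead and side
(truncated-normal around the reference cohort's means and SDs), a heart
rate (N(70, 8) bpm, the resting range of young adult males), a
normalization amplitude (N(1.5, 0.2) mV, matching the reported typical
signal amplitudes), and log-normal RR jitter with 3 % CV. Records
default to 300 s at 250 Hz, the original protocol's length; the
full-table analysis scripts state smaller sizes where they use them.

A beat is a sum of raised-cosine lobes (P, T) and an overlapping
triphasic QRS, constructed so the package's own delineation convention
— wave support at the 5 %-of-peak level, amplitudes normalized by the
subject amplitude, durations by the beat period — recovers the
configured coefficients from the clean template. The configured
coefficients and true R-peak times are emitted as record metadata, so
parameter-recovery tests are well defined. The subject normalization
amplitude is part of that metadata: a cross-lead-maximum normalizer
would force the largest lead's QRS coefficient to exactly 1000, which
contradicts the reference table (max 750.6), so the scale must be a
per-subject constant as it would be established once per volunteer.

Electrode displacement is modeled as a scalar distortion magnitude per
(lead, side, position) driving a fixed composition of amplitude gain,
wave-specific amplitude redistribution, QRS widening and timing shifts.
The magnitudes are calibrated at run time (bisection against the
reference cohort's mean DTW distances), reproducing the published
distance-by-position table within ~15 % and its orderings, including
the non-monotone D1 rows. A consequence worth knowing: under this
package's DTW scalar (mean absolute difference along the warp path),
reaching the published 300–490 µV distances requires displaced-position
amplitude gains of several-fold, which drives the walking-record SNR
between displaced and reference positions more negative than the
reference study reports at distant positions. The published scalar
reduction behind the distance tables is not fully specified, so this
is a limitation of the emulation, not of the metrics.

Walking records add three artifact components — baseline wander
(0.1–0.8 Hz sinusoids), EMG-like band-limited noise (20–60 Hz), and
sparse exponential electrode-motion transients — mixed 0.5/0.3/0.2 by
power and scaled so the clean-versus-contaminated SNR equals a
per-subject target (N(3, 3) dB, spanning the reference study's range).
Artifact level is a subject property, not a position property,
mirroring the original observation that artifacts vary between
subjects far more than between positions. Within a subject and
condition, all channels share one RR sequence (simultaneous
recording); everything descends deterministically from the master
seed.

What the generator does not emulate: baseline-morphology families
beyond one template shape per subject, respiratory modulation,
electrode-impedance physics, rhythm disturbances, and any female or
older-age morphology (the reference cohort was young males). Passing
tests on this cohort therefore demonstrate the correctness of the
processing chain under controlled truth, not clinical performance.

## Ensemble average and coefficients

R peaks are detected with a Pan–Tompkins-style chain (5–25 Hz
band-pass, squared derivative, 150 ms integration, adaptive threshold
at 25 % of the 90th feature percentile, 200 ms refractory, refinement
to the band-passed extremum). Baseline removal is a zero-phase
4th-order 0.67 Hz high-pass (≥20 dB on 0.3 Hz wander, <2 % QRS
attenuation). The ensemble average windows beats to the median RR
(40 % before / 60 % after the fiducial), drops beats whose RR deviates
>25 % from the median, and returns the mean with its SD envelope.
Delineation walks outward from each wave peak to the 5 %-of-peak
crossing with sub-sample interpolation; brief polarity-crossing notches
inside the QRS are jumped by requiring the level to stay low for ~3
samples. An undetectable P or T yields NaN coefficients, never zero.
Over a clean seeded 20-subject cohort the median relative error of
every coefficient is below 5 %.

## Comparison statistics

DTW follows the squared single-dimension Euclidean distance matrix and
the three-predecessor cumulative cost recurrence, with backtracking
from the far corner preferring diagonal then vertical steps on ties and
no global band. The scalar distance is the mean absolute difference of
the warped signals along the path — the only first-power (hence µV)
statistic available; the exact scalar behind the published tables is
not formulaic in the source and this is a documented convention, as is
the variation percentage (scalar distance over reference peak-to-peak).
One property worth noting: the optimal path can absorb part of a
constant offset by pairing steep samples, so an offset is an upper
bound on the scalar distance, exactly attained only on flat traces.
SNR is `10·log10(Σxr²/Σ(xp−xr)²)`; identical signals raise an error
rather than returning infinity. Percentage difference is
`|E1−E2|/((E1+E2)/2)·100`, similarity its complement.

The per-lead similarity of two coefficient tables averages the
coefficient-wise similarities (eight per column); the front/back
difference averages the percentage difference over the 24
(coefficient × lead) front/back pairs. Applied to the reference
volunteer table these reproduce the study's headline numbers: 4.94 %
front/back difference and 87.90 % mean similarity. Applied to this
package's model-versus-cohort tables they yield analogous but not
identical numbers — the voxel model is not the original FEM model, and
that comparison is reported as the package's own result.

## Problem sizes

Default analyses use: the 40×48×24 torso at 1 cm with the 0.5 cm heart
subgrid and 3.5 s of simulated time (four beats); a 20-subject cohort
at 60 s per record for parameter recovery; 8–10 subjects at 40–60 s for
the full distance/SNR table sweeps. These sizes were chosen once as
the package's desk-scale defaults; the generator's own defaults keep
the original 20-subject / 300 s protocol.

## Known limitations

* The forward model reproduces orderings and qualitative morphology,
  not the original study's printed model tables; its absolute lead
  amplitudes depend on the conduction-velocity calibration.
* The AV delay is imposed at the junction rather than emerging from
  nodal decrement; PR-interval physiology beyond a fixed delay is out
  of scope.
* The DTW scalar and variation definitions are conventions (see above);
  alternative reductions would change absolute distance values but not
  the orderings the analyses rest on.
* Bone, fat and muscle are isotropic averages; no torso deformation,
  respiration, or rib-by-rib anatomy.
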