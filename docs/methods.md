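# Methods

`mrl4d` simulates, at desk scale, a 4D treatment-planning comparison between
two respiratory-motion management strategies for centrally located lung
tumors treated with stereotactic ablative radiotherapy (SABR):

* **MLC tumor tracking** ("4D-MRL" arm): beam apertures conform to the
  planning target volume on the reference breathing phase and are shifted on
  every other phase by the tumor's centroid displacement via a *virtual couch
  shift* (VCS) — a software translation of the aperture in the isocenter
  plane with the isocenter itself fixed, as on an MRI-linac where the couch
  cannot move during delivery.
* **ITV** arm: one fixed aperture set conformed to the internal target
  volume (the union of the tumor over all breathing phases, plus the setup
  margin).

Both arms are pushed through identical 4D machinery: per-phase forward dose
on that phase's anatomy, weighting by the patient-specific 8-phase breathing
probability density function (PDF), deformation of each phase dose onto the
reference phase, accumulation into one summation plan, and prescription
normalization (target V99% = 100%). The "accumulated ITV" arm exists
precisely so the comparison is like for like: any artifact of the
weight/warp/accumulate chain hits both arms equally.

Commercial components that a clinical implementation would use are replaced
by controlled stand-ins: the Monte Carlo dose engine by a deterministic
analytic beam model, the deformable-image-registration engine by exact
("ground truth") deformation fields emitted by the phantom generator, and
patient 4D-CTs by a parametric synthetic phantom cohort. This isolates the
*geometric* benefit of tracking from registration and dosimetry error, at
the cost of realism documented under *Limitations*.

## Breathing model and phase PDF

The respiratory cycle is discretised into 8 amplitude-binned phases labelled
0, 12.5, …, 87.5 % with 0 % = maximum inhale (the reference phase) and
50 % = end exhale.

Synthetic bellows traces follow `a(t) = A_i · cos^{2n}(π t_i / T_i)` per
cycle *i* (default exponent n = 2), with per-cycle period and amplitude drawn
around their nominal values with relative standard deviation `variability`
(default 0.1 in the cohort). The form peaks at inhale and dwells near
exhale, as real abdominal-pressure traces do. Default nominal period 5 s
(cohort values 2.7–6.6 s), 60 s duration, 250 Hz sampling.

A trace becomes a PDF by: (1) a *decimating* moving average (block mean, one
output per 50 inputs — the smoothing convention of bellows processing);
(2) peak detection (local maxima at or above the trace mean, ≥ 1 s apart,
plateau ties to the first sample) giving peak-to-peak periods; (3) per
period, splitting the amplitude range into 5 equal levels — top level →
phase 0 %, bottom level → phase 50 %, each intermediate level mapping to two
phases by limb (descending = exhaling → 12.5/25/37.5 %, ascending →
62.5/75/87.5 %); weights are sample-count fractions; (4) averaging the
per-period PDFs and renormalising. Equal-amplitude levels (not equal-count
bins) are used, matching the amplitude-binned sorting convention of the
image sets. For a pure cosine this construction has the arcsine-law closed
form `(arcsin b − arcsin a)/π` per level, halved per limb — the main
analytic oracle of the breathing module.

## Synthetic 4D phantom

Geometry uses minimal primitives: tumor = sphere (radius from the requested
GTV volume), esophagus / trachea / spinal canal / great vessels = finite
z-aligned tubes, heart = ellipsoid, lungs = two lateral ellipsoids
(subtracting other structures), BODY = elliptic cylinder. Densities: lung
0.26 g/cc, soft tissue 1.0, spinal-canal channel 1.3, air 0.0012; absolute
dosimetry is not an evaluation surface, only paired differences are.

Motion is rigid per structure. The tumor moves along a configurable axis
(cranial–caudal by default) with phase fractions (0, ¼, ½, ¾, 1, ¾, ½, ¼) of
the full amplitude, reaching the amplitude at end exhale. An organ at risk
with relative organ motion `ROM > 0` drifts laterally toward the tumor so
its surface distance goes from `d_inh` at inhale to `d_inh − ROM` at exhale.
Placement solves the surface-distance equation exactly for tubes and for
ellipsoids along their principal axis; negative `d_inh` yields controlled
overlap. Requested amplitudes are reproduced within a voxel diagonal,
distances and ROM within 2 voxels (0.5 cm).

Masks are voxelized with anti-aliasing (majority vote over 2×2×2 sub-voxel
samples; 4×4 in-plane samples for tube cross-sections), which keeps volumes
stable under sub-voxel rigid motion. Irreducible limit: a translating disk
of ~12.6 cell areas legitimately covers 12–14 cells, so thin (2-voxel
radius) tubes can still swing ~7–10 % across phases; compact structures stay
within 5 %.

The generator is a pure function of its parameters and seed; identical
inputs give bit-identical phantoms.

## Ground-truth deformation fields

Fields use the pull-back convention: the field for phase *p* maps
reference-phase coordinates `x` to phase-*p* coordinates `x + v(x)`, so
sampling a phase-*p* image there represents it on the reference anatomy.

`v` blends the rigid per-structure displacements: a nearest-structure
softmax (length scale σ_sel = 0.4 cm, on distances to each structure's
*territory*) decides which structure a voxel follows, and a wider Gaussian
envelope (σ = 2 cm) fades displacements into the static background. The
tumor's territory is its motion envelope (union of the GTV over all phases)
and it wins contested voxels outright — inside the envelope the field *is*
the tumor's rigid displacement, exactly. An OAR's territory is its
reference-phase mask minus the tumor envelope. Where rigid bodies
interpenetrate, no single-valued field can satisfy both; the tumor-priority
rule makes the propagated GTV exact (the quantity the tracking comparison
rests on) and is the documented resolution of that ambiguity.

Consequences worth knowing: warping the end-exhale GTV to the reference
phase recovers the inhale GTV with Dice ≥ 0.95 for adequately resolved
tumors (the 15 cc, 1.74 cm amplitude cohort member); for sub-cc tumors at
0.25 cm voxels the indicator-resample-threshold semantics alone cap the
attainable Dice well below that — a voxelization limit, not a field error.
Cascading phase-to-phase fields agrees with the direct field to under one
voxel for smooth single-structure motion; steep transition zones between
adjacent structures moving differently locally exceed that.

## Planning

Beams are static, coplanar and isocentric, rotating about the
cranial–caudal axis; 7 equispaced gantry angles by default (no particular
clinical beam arrangement is assumed).
Machine presets: MRI-linac SAD 143.5 cm with 0.72 cm projected leaf width at
isocenter; conventional linac SAD 100 cm with 0.5 cm leaves. MLC leaf rows
stack along the in-plane cranial–caudal axis; leaves travel laterally.

Apertures are built in the beam's-eye view by true point-source ray
projection of every target voxel onto the isocenter plane; per leaf row the
opening is the [min, max] lateral extent of the projected points. The VCS
translates the aperture by the in-plane projection of the GTV centroid
displacement, re-quantizing rows to the leaf grid (round to nearest, ties
craniad — an arbitrary documented choice). Translation only: no rotation or
reshaping, so tracked aperture area is phase-invariant up to row
quantization.

Target volumes: tracked plans target the phase-0 PTV (GTV + 5 mm isotropic
margin); ITV plans target the phase-union GTV + the same margin. Margins are
Euclidean distance-transform dilations with a 0.29-voxel surface-depth
correction: EDT distances are measured to voxel centers, which sit on
average ~0.07 cm below the continuous surface, and the corrected threshold
makes dilated volumes agree with analytic sphere dilations to ~±4 % at
generic sub-voxel alignments (degenerate exactly-lattice-aligned
configurations can exceed this).

## Dose engine

Deterministic analytic primary-beam model, per beam:

```
dose(v) = fluence(u(v), w(v)) · exp(−μ · d_rad(v)) · (SAD / s_axial(v))²
```

* `fluence`: the aperture indicator rasterized in the isocenter plane with
  exact box-coverage anti-aliasing (0.05 cm pixels), convolved with a
  Gaussian penumbra σ = 0.3 cm, sampled at each voxel's point-source
  projection — divergence magnifies both field and penumbra. σ = 0.3 cm
  gives an ~5 mm 80–20 penumbra (the Gaussian-step closed form is
  1.683 σ_eff).
* `d_rad`: density-weighted radiological depth, computed by resampling the
  density into the beam frame, cumulatively summing along the axis, and
  resampling back; rays are parallel in the depth term only. μ = 0.045 /cm
  approximates megavoltage attenuation in water.
* inverse square on the axial source distance.

No magnetic field, electron-return effect, scatter kernels, MLC leakage or
MU calibration: the engine's role is a controlled, linear, geometry-faithful
dose surrogate. Linearity is exact; the central-axis depth ratio obeys
`exp(−μΔd) ×` inverse square to ~1e−4 (residual: field-edge tail at finite
field size).

Prescription normalization scales the accumulated dose by
`0.99·Rx / min(dose over target)` (plus one ulp so the minimum target voxel
is ≥ 0.99 Rx exactly despite float rounding): the target's V99 % becomes
exactly 100 %, and the rule is idempotent. Under this scaling,
volume-at-99 %-of-dose and dose-to-99 %-of-volume readings coincide.

## Accumulation and the cohort experiment

Accumulation is `Σ_p w_p · warp(D_p, field_p)` with the phase-0 term using
the zero field; with identity fields it reduces to the exact PDF-weighted
sum. Doses are total-course Gy; fraction counts are metadata. PDF weighting
multiplies dose (equivalent to weighting delivery time under a linear
engine).

The built-in cohort has five members spanning tumor amplitudes 0.12–1.74 cm,
GTV volumes 1.3–21.3 cc, prescriptions 50 Gy/5 and 52 Gy/4, and per-organ
(d_inh, ROM) pairs from −0.58 to 7.5 cm and 0 to 1.28 cm respectively, with
breathing periods 2.7–6.6 s — the clinical conditions the cohort emulates.
The cohort runs on a 96³ grid at the native 0.25 cm spacing (~2–3 min on one
CPU for both arms of all five members); the controlled amplitude family used
for the volume-reduction monotonicity check runs at 64³, where the property
is scale-free. Sparing per organ is
`(Dmean_ITV − Dmean_tracked)/prescription`; sparing is regressed on ROM by
OLS with a two-sided slope t-test (statsmodels), with no multiple-testing
correction (a single regression is reported, and raw p-values otherwise).
"Irradiated volume" is the BODY volume receiving at least a configurable
fraction (default 0.5) of the prescription; no standard operational
definition exists, so the threshold is exposed as a parameter.

Contours: the pipeline uses the generator's per-phase ground-truth masks; a
propagation mode (reference-phase contours pushed through the exact fields)
exists and is property-tested against it.

## Numerical choices and edge cases

* Warps are backward (pull-back) trilinear resamples; masks warp as float
  indicators thresholded at 0.5. A *exactly* axis-aligned half-voxel shift
  puts interpolated values of exactly 0.5 on whole planes, which the ≥ 0.5
  threshold dilates — a degenerate, measure-zero configuration.
* Out-of-grid dose lookups are 0 Gy; field composition extrapolates edge
  values (nearest-neighbour) so composing with the zero field is exact.
* Dmax is the single-voxel maximum (a D0.035cc reading is available but off
  by default). DVH bins are 0.1 Gy; cumulative queries round up to the next
  edge so a threshold just above a dose level excludes it.
* Signed GTV–OAR distance: positive = minimum surface gap between disjoint
  voxel sets; negative = deepest penetration (max over the intersection of
  the distance into either structure), chosen so organs moving into the
  target read as negative proximity. All distance tolerances are 2 voxels.
* Per-period PDFs error on flat (zero-range) segments; period detection
  errors below 2 peaks; empty or off-grid structures raise geometry errors
  naming the structure and phase.
* Determinism: every stochastic step (trace generation, cohort seeding) is
  driven by numpy `SeedSequence` spawning from a single seed; identical
  seeds give byte-identical cohort reports.

## Limitations

What the synthetic cohort does **not** emulate: CT texture and
heterogeneity beyond four density classes, hysteresis (inhale and exhale
limbs share geometry at equal amplitude), baseline drift and irregular
breathing beyond per-cycle period/amplitude jitter, deformation (motion is
rigid per structure with a smooth analytic blend), lung volume/density
change over the cycle, and delivery effects (tracking latency, interplay,
magnetic-field dosimetry). Passing tests therefore demonstrate the internal
consistency of the 4D machinery and the *direction and ordering* of the
tracking benefit under controlled conditions — not clinical dose accuracy.
Thresholded voxel masks at 0.25 cm limit volume and overlap fidelity for
structures only a few voxels across, as noted throughout.
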