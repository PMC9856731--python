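# Methods

This note documents the models, numerical choices and known limitations of
`tmsmap`. It is written for a reader who wants to understand what the
package computes, why the defaults are what they are, and what the passing
test suite does — and does not — establish about behavior on real data.

## The mapping method

Transcranial magnetic stimulation (TMS) motor mapping asks: which patch of
primary motor cortex drives a given hand muscle? The coil position alone
answers this poorly, because the induced electric field (EF) in the brain
is shaped by the conductive anatomy, not just by where the coil sits. The
method implemented here localizes a muscle representation from the fields
themselves:

1. compute the induced EF on the cortex for every coil placement of a
   stimulation session (a quasi-static volume-conductor solve per
   placement);
2. rank placements by the motor-evoked potential (MEP) they elicited and
   multiply, vertex by vertex, the cortical EF maps of the top *k*
   placements:  `EF_focal(v) = ∏ᵢ EFᵢ(v)`;
3. threshold the product at 10% of its maximum; the suprathreshold patch
   is the hotspot, summarized by its area and its intensity-weighted
   center of gravity (CoG);
4. relate the EF at the localized coordinate to the measured MEPs with a
   logistic recruitment curve `MEP(EF) = a / (1 + e^{-b(EF - c)})`, whose
   tangent-line activation threshold is the closed form `c − 2/b`.

The intuition for step 2: every high-MEP stimulus must have produced a
large field at the true representation; multiplying the maps retains only
the region that is large in *all* of them, and the relative threshold
makes the result invariant to positive rescaling of any input map (only
field *patterns* matter, which also makes the localization insensitive to
the conductivity assignment).

Two scalar EF metrics are carried throughout: the field strength `|EF|`
and the magnitude of the component along the outward cortical normal
`EF⊥ = |EF·n|`. On folded cortex they behave differently — `|EF|` peaks on
gyral crowns (closest to the coil), `EF⊥` on sulcal walls and lips (where
the surface normal aligns with the induced current) — and the package
reproduces this contrast on its synthetic fold.

## Synthetic study system

Real use of the method requires individual MRI-derived head models and EMG
recordings. The package replaces both with a fully synthetic, seeded study
system, so every quantity has a known ground truth.

**Head phantom** (`tmsmap.head`). Five nested quasi-spherical tissue
layers — skin, skull, cerebrospinal fluid (CSF), gray matter, white
matter — at anatomical scale: skin radius 78 mm (the sphere approximates
the superior cranial dome), scalp 6 mm, skull 6.5 mm, CSF 2.5 mm, cortex
3.0 mm. Anatomical scale matters because the figure-8 coil is a fixed-size
physical device: a scaled-down head would see an artificially broad field
relative to its cortex and misstate every mm² and V/m quantity downstream.
The cortical boundaries carry one sinusoidal invagination (raised-cosine
cross-section, default depth 15 mm, lip-to-lip wavelength 16 mm, length
40 mm with smooth tapers) — a central-sulcus/hand-knob analog, the minimal
geometry that distinguishes crown from wall from lip. The cortical ribbon
keeps constant *perpendicular* thickness: its radial extent on a slanted
wall is `t·√(1+|∇δ|²)`, which also keeps the gray-matter ribbon connected
at coarse voxelizations. Default conductivities (S/m): skin 0.465, skull
0.010, CSF 1.654, gray 0.275, white 0.126 — standard literature values,
config-exposed.

Two ground-truth muscle sites (an FDI and an ADM analog, the two intrinsic
hand muscles classically mapped together) are planted on the fold lip,
3 mm apart along the sulcus, FDI lateral.

**Sampling surface.** EF metrics are evaluated on a triangulated surface
0.8 mm inside the gray-matter outer boundary, extracted by marching cubes
on a signed distance transform of the gray+white compartment. Smoothing
scales are fixed in millimetres (1.2 mm for the level set, 2.8 mm for the
normal field) so that the extraction operator — and with it the sampled
fields — converges under grid refinement; normals are the normalized
gradient of the signed distance (outward). Vertex areas are barycentric
(one third of each incident triangle), so they sum exactly to the mesh
area.

**Coil** (`tmsmap.coil`). Thin-wire figure-8: two coplanar wings of nine
concentric loops each (diameters 55–92 mm), tangent at the placement
point, wound oppositely so the currents under the center are co-directed.
`dA/dt` is a Biot–Savart sum with midpoint quadrature over 72 straight
segments per loop (the field at a fixed point changes < 0.5% from 72 to
144 segments). Stimulator intensity scales the current time-derivative
linearly, 100% of maximum stimulator output (%MSO) = 174 A/µs. The
windings sit 2 mm above the scalp contact point — the coil casing; a
mathematically tangent thin wire would touch the voxelized scalp.
Placements carry a right-handed orthonormal triad (current direction,
handle, outward normal).

**Placement protocol.** Eight anchors at 5 mm intervals along the scalp
trace of the sulcus, each shifted −5/0/+5 mm along the induced-current
direction (perpendicular to the sulcus, tangent to the scalp): 24
placements at 4 stimuli/cm², stimulated at 35/45/55 %MSO with five trials
each (120 stimulations per intensity per muscle).

**MEP generator** (`tmsmap.dose_response`). Trial MEPs are
`sigmoid(EF at the truth vertex) · e^ε + floor·U`, with `ε ~ N(0, σ²)`,
σ = 0.3 by default (multiplicative lognormal noise is the dominant
variability of real MEP amplitudes) and a 0.02 mV uniform baseline floor.
The ground-truth sigmoid of each subject is anchored to the fields its own
head actually receives: the tangent threshold `c − 2/b` is placed at 49%
of the 100 %MSO field at the truth site, and the midpoint `c` sits a
factor 205/174 above the threshold — dimensionless ratios taken from the
shape of measured human recruitment curves. Together with the conventional
resting-motor-threshold (RMT) criterion (≥ 50 µV in at least half the
trials) this construction puts the subject's RMT near 42 %MSO, so the
three protocol intensities bracket it realistically (≈ 83/106/130% RMT).

**Cohorts.** Synthetic "participants" share the template head and surface
topology (so group-level maps use identity vertex correspondence in place
of nonlinear template registration) and differ in truth-site position
along the lip and in their MEP noise streams. Sharing the head also lets
one set of field solves serve the whole cohort.

## Numerical scheme

**Discretization.** The quasi-static scalar potential solves
`∇·σ∇φ = −∇·σ ∂A/∂t` with an insulating exterior. The solver uses a
cell-centered finite-volume / 7-point stencil on the voxel grid with
harmonic face-conductivity averaging; the right-hand side is the discrete
divergence of `σ·dA/dt` with face values averaged from the adjacent cell
centers. The scheme reproduces affine potentials exactly — a uniform
`dA/dt` in a homogeneous conductor yields E = 0 to solver tolerance — and
the assembled matrix is symmetric positive semi-definite with the constant
vector in its null space and exactly compatible right-hand sides (they sum
to zero in exact arithmetic).

**Solver.** Jacobi-preconditioned conjugate gradients to a relative
residual of 1e-6 (default), with the zero-mean gauge applied over
conducting nodes afterwards. An incomplete-LU option exists but diagonal
scaling wins in practice on these grids (a few hundred iterations; the ILU
setup cost dwarfs the iteration savings). Equivalence with the continuum
problem is established through oracles rather than through any particular
element type: a dense minimum-norm solve on ≤ 12³ systems (agreement to
1e-8), the uniform-field null case, and the spherical-conductor properties
(no radial field component; insensitivity to a radially varying
conductivity profile).

**Field reconstruction.** `E = −∇φ − ∂A/∂t` with central differences
inside tissue and one-sided differences at tissue boundaries, defined only
where σ > 0. All placements are solved at 100 %MSO; fields at other
intensities follow exactly by linearity (`×pct/100`), so a 24-placement,
3-intensity session costs 24 solves, not 72.

**Performance structure.** The system matrix depends only on the head, so
it is assembled and preconditioned once per head and reused across
placements. The `dA/dt` pattern of a rigid coil is invariant under rigid
motion, so it is evaluated once on a 1.5 mm coil-frame grid and
interpolated (with vector rotation) per placement; the interpolation error
at cortical depth is ~1e-3 relative, far below the discretization error.
On 1 mm grids each placement solve additionally warm-starts from a
prolonged 2 mm coarse solution. A full 24-placement session takes a few
minutes at 2 mm and ~10–15 minutes at 1 mm on one CPU.

**Surface sampling.** Trilinear interpolation of the field at the surface
vertices, with the interpolation support restricted to gray+white voxels
(weights of outside voxels dropped and renormalized): the normal field
component is discontinuous at the gray/CSF interface by current
conservation, and unmasked trilinear sampling at a staircase boundary
would dilute cortical values at coarse resolution. With these choices the
peak cortical field changes by < 5% between 2 mm and 1 mm grids.

**Hotspot arithmetic.** Each input map is normalized to unit maximum and
the product accumulated as a sum of logs (floor 1e-12); the result is
re-normalized to maximum 1 and thresholded at 0.1. A triangle contributes
its full area when the mean of its three vertex values is suprathreshold.
The CoG weights suprathreshold vertices by `ef_focal × vertex area`
(binary-mask weighting is available). The per-placement MEP used for
ranking is the median of the five trials (max and trial-level selection
are config options); ties break by placement id, so selection is
deterministic.

**Sigmoid fit.** Nonlinear least squares (`scipy` trust-region) from a
deterministic multi-start grid: slopes {0.01, 0.05, 0.1, 0.5} (V/m)⁻¹ ×
turning points at the EF quartiles, amplitude started at the maximum MEP;
the lowest final cost wins with grid-order tie-breaks. Degenerate outcomes
are returned flagged `divergent` rather than raised: non-positive slope, a
turning point more than 50% of the data span outside the observed EF
range, or any parameter standard error above 100%. `EF threshold = c − 2/b`
(the tangent-line x-intercept at the point of maximum slope, exact for the
logistic); `EF saturation = c + 2/b`, the symmetric tangent intercept with
the saturation plateau — one of several readings of "the maximum point of
the slope", documented here as interpretive. The RMT estimator fits the
best placement's trials as a sigmoid of %MSO (valid because EF scales
linearly with intensity) and line-searches the 50 µV crossing on a 1% grid.

**Evaluation studies** (`tmsmap.pipeline`). The sample-count sweep maps
hotspot area against k = 1..8 for both metrics. The random-sampling study
draws k = 5 records uniformly (without replacement, placements may repeat
and then enter the product repeatedly) from those exceeding 75/50/25/0% of
the maximum MEP, 100 repetitions per category by default, each compared to
the reference CoG from the k highest-MEP placements; categories with fewer
than k eligible records are skipped with a logged warning, and eligible
counts are reported so the skip rule is auditable. Random draws use a
dedicated stream per (seed, subject, category), so adding categories never
perturbs the others. The whole pipeline is a pure function of
(config, seed).

## Problem sizes used in the test suite

The shared test fixture is the default subject voxelized at 2 mm with all
24 placements solved (the package default is 1 mm; `scripts/acceptance.py`
runs at 1 mm). The cohort evaluation runs 10 template-sharing subjects at
50 repetitions per category and muscle; sigmoid recovery uses 20 noise
seeds at 72 EF–MEP pairs (24 placements × 3 intensities). Solver oracles
use purpose-built small models (≤ 12³ dense comparison, 20 mm spheres at
1 mm, 32³ homogeneous cubes); the grid-convergence check solves one
placement at 2 mm and 1 mm.

## What the synthetic system does and does not establish

The phantom reproduces the *mechanisms* the method relies on — realistic
coil-cortex distances and field magnitudes (peak cortical `|EF|` ≈ 350 V/m
at 100 %MSO, activation thresholds in the 150–200 V/m range), the
crown/wall dissociation of the two metrics, product sharpening with sample
count, better localization from higher-MEP samples — but not the full
field structure of real cortex:

* **One fold only.** Real cortex modulates `|EF|` strongly through
  neighboring gyri and sulci and variable CSF thickness. On the phantom's
  smooth cap the `|EF|` metric has little spatial contrast outside the
  fold, so strength-metric hotspots are substantially larger than on real
  anatomy (k = 5 areas of order 1200–2000 mm² rather than a few hundred).
  The normal-component metric derives its focality from the fold geometry,
  which the phantom does have; its k = 3 hotspot areas come out around
  600 mm² at the 1 mm default — the product mechanism trims the ~1200 mm²
  double-wall system by half, but an open synthetic groove lacks the
  lip-concentrated field structure of a nearly closed real sulcus that
  confines real-cortex hotspots below the ~400 mm² scale of a finger
  representation. Desk-scale area bounds inherited from real-cortex
  studies should be read with this in mind; localization (CoG) quantities
  are much less affected than areas.
* **Areas are resolution-sensitive.** At 2 mm the staircase representation
  of the thin sulcal walls inflates normal-metric areas by another ~40%
  and strength-metric areas by ~50% relative to 1 mm; CoG positions move
  by well under a voxel. Area comparisons should be made at the 1 mm
  default.
* **No EMG physics.** MEP latency, waveform and facilitation dynamics are
  out of scope; only peak-to-peak amplitudes are generated, with
  multiplicative noise.
* **Isotropic conductivity, no anisotropic white matter, one cortical
  fold, spherical outer layers** — all by design; the point of the phantom
  is a controlled ground truth, not anatomical realism.

## Degenerate inputs and edge behavior

Zero fold amplitude yields a smooth spherical cap (truth sites remain
distinct); non-nested layer specifications fail validation naming the
offending pair; a sampling depth exceeding the minimum cortical thickness
raises with the offending location; surface vertices outside the conductor
raise with their count and the worst offender; an empty hotspot mask
raises on CoG computation; constant MEP data produce a `divergent`-flagged
fit, not an exception; an RMT criterion of zero returns the lowest tested
intensity, and an unreachable criterion returns a flagged estimate.
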