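# Methods

This note documents the models behind `histoqa`, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical conventions that matter when interpreting results.

## Phantom model

The phantom is a voxelized agar-surrogate block (default 50 × 50 × 50 mm,
cube; a cylindrical option exists) of alternating layers normal to Z, the
ultrasound propagation axis: 4 mm low-attenuation and 1 mm high-attenuation
(barium-doped) layers, period 5 mm. A 28 mm sphere of the same layering is
embedded at the block centre with its layer stack offset by
`target_layer_phase_mm` (default half a period, 2.5 mm) relative to the
outer stack. That phase mismatch is what creates an intensity discontinuity
at the sphere surface — the visible edge used for planning — because within
any horizontal plane the inner and outer stacks generally show different
layer material.

Attenuation is in arbitrary units, linear in barium concentration:
`intensity_low = 20`, `intensity_high = 220`. These values were chosen so
that, with the default imaging noise, treatment-zone SDNRs land in the low
single digits, the regime this phantom class exhibits in practice. Voxel
spacing defaults to 0.5 mm isotropic (resolves the 1 mm layers with two
voxels); world coordinates are mm, voxel (i, j, k) is centred at
`origin + spacing · (i, j, k)`.

Hand-poured phantoms start their layer stack at an arbitrary height, so the
study pipeline randomizes the absolute stack phase per phantom
(`outer_layer_phase_mm ~ U(0, period)` from the phantom seed) while keeping
the target's relative mismatch fixed. This is the generator's only
phantom-to-phantom geometric variability; layer-thickness jitter from
manual pouring is *not* modelled, so replicate scatter in simulated studies
is smaller than in physical ones.

## Imaging surrogate

CBCT acquisition is modelled as an isotropic Gaussian blur
(`psf_sigma_mm = 0.8`) followed by additive white Gaussian noise
(`noise_sd = 8`). Noise is added after the blur, so the image noise SD
equals the parameter exactly. The blur uses periodic boundary handling,
which keeps the kernel exactly mean-preserving; the layer pattern is
z-periodic, so wrapping introduces no artificial boundary content.
Cone-beam reconstruction physics (scatter, beam hardening, ring/cone
artifacts, anisotropic resolution) is intentionally out of scope, so
visibility metrics on synthetic data characterize the metric
implementations, not a scanner.

## Treatment model

A spherical treatment is planned as a centre and diameter; mistargeting is
an explicit lateral shift of the plan, while a calibration error is a
hidden `true_offset_mm` displacing every delivered cloud position. The two
mechanisms are deliberately distinct, and analysis code never reads the
hidden offset.

The delivery path sweeps the ellipsoidal bubble cloud (semi-axes
1.5, 1.5, 3.0 mm; long axis along Z) along concentric helices of
decreasing radius (ring spacing 1.25 mm, in-plane step ≤ 1.0 mm, Z pitch
2.0 mm), each helix capped by closing circles at its top and bottom ends,
plus an axial column reaching the poles. The closing circles matter: a bare
helix leaves a full-pitch vertical gap at some angles on its last turn,
uncovering the sphere's shoulder. Ring heights equal the sphere's inscribed
height at that radius, so cloud tips touch but do not overrun the planned
surface. The prototype hardware's actual packing is proprietary; these
values were chosen so the voxelized ellipsoid union covers ≥ 99 % of the
planned sphere while its axis-aligned extents through the centroid equal
the planned diameter to within one voxel (verified in tests for 20 and
28 mm plans).

Treated voxels are homogenized. A single cloud pass is modelled as the mean
pre-treatment intensity over a Z window of one layer period
(`full_homogenization=False`), which equals the thickness-weighted layer
mean (4·20 + 1·220)/5 = 60 inside periodic layering. The study protocol
treats every phantom twice specifically to achieve *complete*
homogenization, and repeated window mixing converges to the mean over the
whole treated region; the default (`full_homogenization=True`) applies that
converged state directly. This choice also makes a second `apply_treatment`
pass exactly idempotent and avoids a single-pass artifact in which the
partial window straddling the target's phase boundary produces homogenate
that locally matches untreated material. Outside the treated region the
volume is bit-identical to the input; treated-zone noise comes from
re-imaging the post-treatment volume, not from the mixing step.

## Segmentation surrogates

The physical workflow contoured zones manually; `histoqa` substitutes
deterministic algorithms so every accuracy claim can be scored against the
simulator's ground-truth masks.

**Treatment zone** (pre/post pair, shared grid): the absolute difference
image is smoothed (σ = 2 mm, about half a layer period, blending the
alternating-layer difference into a solid blob) and thresholded by a
two-pass Otsu — a global pass finds the zone, a second pass restricted to
the zone's neighbourhood rebalances the foreground/background classes,
removing the size-dependent bias of global Otsu (which over-segments small
zones and under-segments large ones). The largest 6-connected component is
the detection. By default the mask is then regularized to a sphere
(`refine_shape="sphere"`), the automated counterpart of a human contouring
a planned spherical treatment as a smooth closed boundary:

* the **centre** comes from a weighted least-squares sphere fit to the
  difference image's boundary-gradient shell, restricted to a band
  −1.0/+2.5 mm around the component boundary and refined with progressive
  inlier trimming (3, 2, 1.5 mm);
* the **radius** is volume-matched to the detected component;
* the component itself is OR-ed back in (trimmed 0.75 mm past the fitted
  sphere) so real asymmetries of the difference signal are not erased.

The regularization exists because the difference image is genuinely blind
in one place: at the target surface the blurred phase-blend band already
resembles homogenate, so where that band lies just inside the zone
boundary (which happens asymmetrically when the delivered zone is shifted
relative to the target) the raw thresholded mask erodes and its centroid
acquires a systematic bias of up to ~0.4 mm. With regularization the
remaining bias is ≤ ~0.25 mm in the worst case (a 2.4 mm shifted
treatment) and ≲ 0.05 mm for centred, undertreated and mistargeted
scenarios — within the sub-voxel precision the QA procedure needs.
`refine_shape="none"` gives the plain thresholded-component behaviour.

An input pair with no treatment signal (identical images, or a difference
indistinguishable from noise) raises `NoTreatmentDetectedError`.

**Intact target** (pre-treatment volume, seeded by an approximate centre —
the operator-click surrogate): layer stacks are constant within any XY
plane, so the in-plane gradient magnitude is non-zero only on the target
boundary and from noise. Edge voxels (Otsu on that gradient within the
search box) are fitted with a weighted algebraic sphere, refined twice on
inliers (±2 mm). The fitted sphere is returned as the mask; on default
synthetic data its centroid is within ~0.02 mm of truth and its volume
within a few percent. A contrast-free phantom raises
`TargetNotFoundError` via an edge-support check (gradient on the fitted
shell must dominate the background gradient level).

## Geometry metrics and statistics

The location estimator is the centroid (first image moment) of a binary
mask in world coordinates; offsets are signed per-axis differences,
measured minus planned. Diameters are axis-aligned extents of the mask
along lines through its centroid — a caliper-style reading with no
sub-voxel interpolation, exact to one voxel. Reported values are rounded to
0.1 mm only at the reporting layer (`round_report`), never internally.

Group summaries keep both signed and magnitude statistics: the calibration
correction uses the *signed* mean per axis (applied only on axes whose mean
|offset| exceeds the 1 mm refinement threshold), while the before/after
comparison uses *magnitudes*, matching how such results are summarized in
prose (a signed mean of −0.38 ± 0.24 reads as 0.4 ± 0.2 in magnitude). The
group comparison is a two-sided unpaired Student's t-test per axis on
offset magnitudes (equal variances pooled; Welch available via
`equal_var=False`). A single-phantom group is allowed — its mean is usable
for refinement, its SD is undefined (NaN) — because one phantom already
pins the miscalibration well enough to correct it, a property the closed
loop tests verify.

## Visibility metrics

ROIs are circular disks, one voxel thick, radius 3 mm (placement planes are
standard; the size is this package's choice), placed in the axial, coronal
and sagittal planes through the treatment-zone centre and, for layers, in
the axial plane at the centre depth of three consecutive barium and three
consecutive non-barium layers near mid-depth, in a phantom corner clear of
target and treatment. ROI-set means pool all voxels; SDs combine per-ROI
SDs by root mean square so between-layer mean differences do not inflate
the noise estimate. SDNR is signed as (μ_t − μ_l)/√(σ_t² + σ_l²); take the
absolute value at the reporting layer if desired.

Edge strength: the target surface is extracted by marching cubes at
iso-level 0.5 on the mask; outward normals come from the gradient of a
1 mm-smoothed mask indicator; the volume is sampled by trilinear
interpolation at ±`normal_offset_mm` (default 1.5 mm, chosen larger than
the imaging blur sigma so a step edge is sampled at full height) along each
vertex normal; the result is the mean |outside − inside| divided by the
layer-measured noise SD. An ideal step edge of height h with noise s yields
h/s (within 5 % in tests); the default synthetic phantom yields ~3.4–3.8,
inside the 2.5–6.5 regime such targets show, though synthetic visibility
numbers characterize the metric, not a physical scanner.

## Study pipeline

`run_study` simulates one group end to end per seed: build phantom
(randomized layer phase) → pre CBCT → segment target → plan (centred on the
segmented target, plus any mistarget shift; 28 mm calibration groups, 20 mm
undertreatment, 28 mm + 7 mm Y mistarget) → helical path, executed with the
hidden offset minus any built-in correction → post CBCT → segment zone →
offsets, diameters, target-to-treatment distances, SDNRs, edge strength.
Stage seeds derive from the phantom seed via `SeedSequence`, so identical
configurations produce byte-identical reports; per-phantom failures are
recorded in the report and do not abort the study. `closed_loop_refinement`
runs a calibration study, derives the correction, and applies it in a test
study by shifting every delivered cloud position by −correction.

Problem sizes used throughout tests and the acceptance script: 100³ voxels
per phantom (50 mm at 0.5 mm spacing), 3–6 phantoms per group, 10 seeded
replicates for the segmentation-accuracy property — one phantom simulates
in roughly a second, a six-phantom closed loop in well under a minute.

## Known limitations

* The difference image carries no information exactly where the blurred
  target-edge band coincides with the zone boundary; after regularization
  a residual +0.25 mm Z bias remains for strongly shifted treatments
  (recovered 2.16 mm for an injected 2.40 mm). Centred and laterally
  shifted scenarios are unbiased to ~0.05 mm.
* Caliper diameters through the centroid are sensitive to single-voxel
  boundary bumps; per-phantom Z readings scatter by up to ~1 mm (group
  means are stable and are what the pipeline reports against).
* No cone-beam artifact model; no layer-thickness variability; acoustic
  aberration and robot/C-arm registration hardware are outside the
  simulation — the hidden offset subsumes all upstream error sources.
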