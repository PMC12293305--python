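# Methods

This note records the models, conventions and numerical choices behind
`canine_trace`, and what the synthetic validation does and does not show.

## Geometry and units

All coordinates are millimetres in a right-handed frame. No anatomical axis
convention is imposed: every reported quantity is a Euclidean distance
between corresponding points in a common frame, and distances are invariant
under any rigid change of frame (the test suite checks this invariance to
1e-9 mm). Internal arithmetic is float64 throughout, even though binary STL
stores float32 — rigid-fit residuals at the 1e-9 mm level are meaningless
in single precision. STL files are read in both binary and ASCII dialects;
duplicated facet corners are merged by an exact-match weld (tolerance 0),
which re-indexes but never moves geometry. STL itself is unitless;
coordinates are taken as mm because all clinical displacements are reported
in mm. Landmarks live in plain CSV (`name,x,y,z,role`) rather than inside
meshes: point picking is independent of mesh topology, and named points
keep every correspondence auditable.

## Rigid superimposition

Every overlay step solves the same orthogonal-Procrustes problem: paired
points `s_i → t_i`, minimise `Σ ‖R s_i + t − t_i‖²` over proper rotations
`R` and translations `t`. The closed-form solution uses the SVD of the
centred cross-covariance; when the naive product would have determinant −1
the axis of the smallest singular value is flipped (standard Kabsch
correction), so a reflection is never returned. No scale factor is fitted:
the two acquisitions image the same patient, scale is identically 1, and a
similarity fit would silently absorb calibration errors.

Correspondence is by landmark *name*, not nearest neighbour — the operator
picks matched points, and the implementation refuses sets whose name
sequences differ. Fewer than 3 landmarks, or a collinear configuration
(second singular value of the centred coordinates below 1e-8 of the
largest), is an error. A skull-point overlay with fewer than ten landmarks
triggers a warning rather than an error, reflecting the recommended minimum
for a cranial-base superimposition.

The crown overlay (STL-method step 4) has two modes. The landmark fit is
the default and the reference behaviour, because the clinical act — a
manual surface overlap in a GUI — has no published algorithm. Optional
refinement runs point-to-point trimmed ICP restricted to crown-region
vertices: matches trimmed at the 80th percentile of closest-point
distances, at most 50 iterations, convergence when the trimmed RMS improves
by under 1e-6 mm, initialised at the landmark fit; non-convergence returns
the last iterate with a warning. Refinement is the recommended mode when
landmark picks are noisy: the crown surface constrains the transform far
better than a handful of points, and the fit's rotational error matters
disproportionately because the root apex sits ~20 mm from the crown (a
0.03 rad error at the crown is 0.6 mm at the apex).

## The two measurement procedures

The CBCT method maps the final CBCT frame onto the initial one via skull
points and measures cusp-to-cusp and apex-to-apex distances directly. The
STL method composes three fits (tooth points: CBCT → initial scan; rugae:
initial → final scan; crown: initial canine → erupted crown) and measures
the same two distances between the carried initial pose and the
crown-aligned final pose. On rigidly consistent data with exact landmarks
the two procedures agree to floating-point error, and the tests assert
this at 1e-6 mm.

Two modelling decisions are inherent to the STL method. First, the final
apex is the initial apex carried rigidly under the crown-alignment
transform — intraoral scans contain no roots — which assumes the root does
not change shape during traction; every STL-method report carries this note.
Second, displacement is a plain point-to-point distance with no axis
decomposition, because the measurement defines no anatomical axes.
Rates are displacement divided by a per-case treatment duration in months;
what that duration denotes (traction time vs total treatment) is the
caller's definition.

## Difficulty index

The five component scores and their bands are integer arithmetic; the only
genuinely open choices were boundary closures. The angulation prose bands
("less than 30°", "between 30° and 45°", "more than 45°") leave the
endpoints unassigned; the middle band is taken closed, [30°, 45°] → 2, so
the bands partition [0°, 90°]. The deep-palatal class starts strictly
beyond 3 mm. Angulation can be computed from geometry as the angle between
the apex→cusp axis and the mid-sagittal plane (90° minus the angle to the
normal). Components may be supplied directly (the form clinical tables use)
or derived from raw features; both paths converge before totalling. An
exhaustive check over all 192 component combinations confirms totals stay
in [5, 15] and categories follow the 5 / 6–10 / 11–15 banding.

## Statistics

Method agreement is assessed on the overlap subset (cases measured by both
methods, paired by case id): Shapiro–Wilk on the paired differences, a
two-sided paired *t*-test (`t = mean(d)/(sd(d)/√n)`, df = n−1, sample SD
with the n−1 denominator), and Cohen's *d*. The *d* standardiser is the SD
of the paired differences — the natural choice for a paired design — with a
pooled-SD variant exposed because the convention is not universal. Effect
labels use the 0.20 / 0.50 / 0.80 anchors as half-open bands; |d| < 0.2 is
reported as small. Two sites (tip, apex) are tested without multiplicity
correction, and the report says so. When the two methods agree exactly on
every case the *t* statistic is undefined (zero-variance differences); the
report flags exact agreement instead of failing.

## Synthetic scenes

The generator builds a 14-tooth maxillary arch of parametric tooth solids
(elliptical-section cone-on-cone about a cervical plane; canines get a
pointier crown taper and a 16 mm root). Anatomical realism is deliberately
minimal: the pipelines are purely rigid-geometric, so only the *structure*
of the data matters — crowns-only scans, roots only in CBCT, an impacted
canine absent from the initial scan, stable cross-timepoint landmarks, and
four acquisitions each in its own random rigid frame (rotations up to 25°,
shifts up to 15 mm), so no overlay is trivial.

The impacted pose offsets the canine from its socket by a 25–45° tilt about
a mesiodistal axis plus a 3–6 mm palatal (or buccal) and 6–10 mm superior
shift; an explicit pose override is accepted. The ground-truth motion
undoes the tilt about the canine centroid and translates toward the socket,
with the translation magnitude solving a quadratic so the cusp tip moves by
exactly the requested target (machine precision). The apex displacement
follows from the motion and is recorded, typically smaller than the tip's —
as in traction, where the crown swings farther than the root.

Landmark geometry: ten skull points scattered in a cranial volume above the
arch; six rugae points on the anterior palatal vault, modelled as a dome
with ~10 mm of relief — a flat rugae patch would make the cross-arch
rotation of that fit ill-conditioned, which the real vault is not; tooth
correspondence points at the cusp tips of the erupted teeth; five crown
points (cusp tip plus four cervical-ring points) on the canine. Picking
error is isotropic Gaussian noise, independent per point and per
acquisition, applied to registration landmarks only (the cusp/apex
annotations are the measurands, not fit inputs); sigma is configurable,
0–0.5 mm being the plausible operator range, default 0 so the reference
configuration is exact. A deciduous canine crown can be placed in the
initial scan (present by default) to confirm that unlabelled extra geometry
cannot disturb landmark-driven registration.

Cohorts default to the study conditions this package emulates: 13 canines
of which 8 carry a final CBCT, cusp-path targets drawn uniformly from
11–19 mm and durations from 24–41 months (bracketing a severe-impaction
clinic population with ~0.5 mm/month tip rates), and a 9:13 palatal
proportion. One `numpy` generator seeded from the spec drives every draw;
the same seed reproduces a case bit-identically.

What passing tests show — and what they do not: recovery of known rigid
motions through the full pipeline, correct algebra, correct statistics, and
graceful degradation under picking noise. They do not validate segmentation
quality, scanner surface noise, soft-tissue change, rugae instability over
long treatments, or root-shape change — real-data effects outside this
package's scope.

## Problem sizes and determinism

Default tessellation gives ~190 faces per tooth (~3000 per scene), which
keeps a full two-method measurement under 10 ms and makes Monte-Carlo
studies cheap: the validation suite uses 200 replicates for the noise and
statistics studies and 100 random motions for registration exactness.
Everything — including ICP, which uses no subsampling — is deterministic
given the seed.

## Known limitations

* The rigid-root assumption of the STL method is untestable from scans
  alone; apex results inherit it.
* The difficulty index's horizontal-overlap and vertical-level criteria are
  accepted as categorical judgements; no 3D construction is attempted for
  them.
* Cohort-level means, p-values and effect sizes from synthetic cohorts
  characterise the generator's population, not any clinical population.
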