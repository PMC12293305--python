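# canine-trace

Tools for measuring the three-dimensional displacement of impacted
maxillary canines during orthodontic traction, by rigid superimposition of
segmented CBCT models and crown-only intraoral-scan (STL) meshes.

## The problem

An impacted canine is dragged over a centimetre or more through bone during
traction. Quantifying that movement in 3D normally requires a CBCT at both
timepoints, but a second CBCT means additional radiation — undesirable in
adolescent patients. Once the crown has erupted it is visible to an
intraoral scanner, so a *hybrid* measurement becomes possible: carry the
canine model segmented from the **initial** CBCT into the intraoral-scan
series, overlay its crown on the erupted crown in the final scan, and read
off how far the cusp tip and root apex travelled — no final CBCT needed.
This package implements both procedures so they can be compared:

* **CBCT–CBCT method** — the final CBCT is mapped onto the initial one by a
  least-squares rigid fit on ≥ 10 paired skull points; displacement is the
  distance between the superimposed cusp tips (and apices).
* **STL method** (five steps) — (1) teeth segmented from the initial CBCT;
  (2) rigid fit of corresponding tooth points carries the canine into the
  initial scan; (3) a rigid fit on stable palatal-rugae points carries it
  into the final scan; (4) the canine's crown is overlaid on its erupted
  crown (landmark fit, optionally refined by trimmed ICP on the crown
  surface); (5) cusp-tip and apex distances are measured. The apex is
  inferred by rigidly carrying the initial root — scans image no roots.

Every overlay is the closed-form Kabsch solution: given paired landmarks
`s_i → t_i`, find the proper rotation `R` and translation `t` minimising
`Σ ‖R s_i + t − t_i‖²` (SVD of the cross-covariance with the determinant
correction; no scale factor, since same-patient data are isometric).
Displacements divide by treatment duration to give rates in mm/month.

Also included:

* the five-component CBCT **impaction difficulty index** (angulation,
  vertical level, bucco-palatal position, horizontal overlap, rotation;
  totals 5–15 banded into minimum / moderate / maximum difficulty);
* **method-agreement statistics** on the cases both methods cover:
  Shapiro–Wilk on paired differences, two-sided paired *t*-test
  (`t = mean(d)/(sd(d)/√n)`), and Cohen's *d* standardised by the SD of the
  paired differences;
* a seeded **synthetic-case generator** producing complete scenes (tooth
  meshes, crown-only arches, cross-timepoint landmarks, acquisition frames)
  with an exactly known canine motion, so every stage is testable against
  ground truth.

## Worked example

```python
from canine_trace import SceneSpec, make_case, run_cbct_method, run_stl_method
from canine_trace.difficulty_index import score_case

sc = make_case(SceneSpec(seed=42, landmark_noise_sigma=0.2))
print(f"ground truth: tip {sc.truth.tip_displacement:.3f} mm, "
      f"apex {sc.truth.apex_displacement:.3f} mm")
for name, res in [("CBCT", run_cbct_method(sc.case)),
                  ("STL ", run_stl_method(sc.case, refine_crown=True))]:
    print(f"{name} method: tip {res.tip_displacement:.3f} mm "
          f"({res.tip_rate:.3f} mm/month), apex {res.apex_displacement:.3f} mm "
          f"({res.apex_rate:.3f} mm/month)")
s = score_case((3, 4, 1, 1, 2))
print(f"difficulty: components {s.components} -> total {s.total} ({s.category})")
```

prints

```
ground truth: tip 15.000 mm, apex 9.154 mm
CBCT method: tip 15.037 mm (0.501 mm/month), apex 9.098 mm (0.303 mm/month)
STL  method: tip 14.525 mm (0.484 mm/month), apex 9.363 mm (0.312 mm/month)
difficulty: components (3, 4, 1, 1, 2) -> total 11 (maximum)
```

The scene was generated with a known 15 mm cusp-tip path over 30 months and
0.2 mm Gaussian picking error on every registration landmark; both methods
recover the truth to a few tenths of a millimetre, and the difficulty row
(angulation > 45°, cusp above the apical third, palatal within 3 mm, overlap
below half a tooth width, rotated) totals 11 — maximum difficulty.

There is also a CLI:

```sh
canine-trace simulate --seed 3 --n-cases 13 --out cohort/
canine-trace run --case cohort/case_01/case.json --method both --out report.json
```

`simulate` writes STL meshes, per-acquisition landmark CSVs
(`name,x,y,z,role`), a `case.json` manifest, and a separate `truth.json`
(for testing only). `run` executes either or both methods and writes a
report with displacements, rates and full registration diagnostics.

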