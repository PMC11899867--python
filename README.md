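# asvasc

Quantification of ocular-surface microvasculature from anterior-segment
OCT-angiography (AS-OCTA) en-face images, with the clustered-eye cohort
statistics used to compare diseased and healthy eyes — for example in
thyroid eye disease (TED), where conjunctival and intrascleral vascular
changes track disease activity.

The package is aimed at ophthalmic imaging researchers who have en-face
AS-OCTA frames (3 × 3 mm fields sampled at 304 × 304) or depth volumes and
want reproducible vascular indices plus group-level inference, and at
methodologists who want every stage testable against synthetic ground
truth.

## What it computes

From a depth volume, two en-face slabs are projected: **superficial**
(conjunctival epithelium to 200 µm) and **deep** (200–1000 µm, the
intrascleral layer), each split into nasal and temporal quadrant ROIs.
Frames are enhanced with CLAHE and median filtering, and vessels are
segmented by Otsu's threshold computed over ROI pixels only. Four indices
are then measured on the binary vessel mask `V` inside ROI `R`, with
skeleton (centerline) `S`:

- vessel density `VD = |V| / |R|` (area fraction),
- vessel length density `VLD = len(S) / |R|` (px⁻¹), where `len(S)` sums
  1 per 4-adjacent and √2 per diagonal skeleton-pixel pair,
- vessel diameter index `VDI = |V| / len(S)` (mean caliber, px),
- fractal dimension `FD = −d log N(e) / d log e`, the box-counting slope
  over box sizes `e`.

By construction `VDI × VLD = VD`, which the pipeline enforces to machine
precision.

Cohort inference uses a Gaussian identity-link GEE clustered on subject
(both eyes of a participant are correlated), exchangeable working
correlation and robust sandwich errors, adjusting for age and gender; the
group coefficient is the adjusted mean difference (aMD). Families of
region × layer tests are Šidák-corrected, disease activity follows the
clinical activity score rule (CAS ≥ 3 = active), and CAS associations are
fit with the same clustered machinery.

Because no public AS-OCTA dataset accompanies this design, the
`synthetic_data` module generates vessel networks with known ground truth
(non-crossing curvature-bounded centerlines at controllable density,
caliber and noise), two-slab volumes, and study-structured cohorts
(29 + 21 subjects, two eyes each, realistic per-cell metric means/SDs).

## Worked example

```python
import numpy as np
from asvasc import (
    ROIMask, VesselSimParams, generate_vessel_image, segment_vessels,
    compute_metrics, CohortSimParams, generate_cohort, gee_compare,
)

# one synthetic en-face frame at the study's typical vessel density
img, truth = generate_vessel_image(VesselSimParams(seed=7, target_vd=0.34))
roi = ROIMask(np.ones(img.shape, dtype=bool))
mask = segment_vessels(img, roi)
m = compute_metrics(mask, roi)
print(f"VD  = {m.vd:.3f}")
print(f"VLD = {m.vld:.3f} px^-1")
print(f"VDI = {m.vdi:.2f} px")
print(f"FD  = {m.fd:.3f}")

# clustered-eye group comparison on a simulated cohort
cohort = generate_cohort(CohortSimParams(seed=7))
r = gee_compare(cohort, "vd", "temporal", "deep")
print(f"aMD = {r.amd:.3f}, 95% CI [{r.ci_low:.3f}, {r.ci_high:.3f}], p = {r.p:.4f}")
```

prints

```
VD  = 0.319
VLD = 0.114 px^-1
VDI = 2.79 px
FD  = 1.740
aMD = 0.041, 95% CI [0.000, 0.082], p = 0.0488
```

i.e. ~32% of the frame is vessel, mean caliber ≈ 2.8 px (~28 µm at
9.87 µm/px), a plane-filling-ish network (FD 1.74), and a temporal-deep
vessel-density difference of 0.041 between the simulated case and control
groups after adjusting for age and gender.

A command-line interface wraps the same functions:

```
asvasc simulate cohort --out cohort.csv --seed 7
asvasc quantify --config run.yaml
asvasc compare --config run.yaml --metrics out/metrics.csv --cohort cohort.csv
asvasc fixtures --out fixtures/
```

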