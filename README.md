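# bonefuse

Tools for 3D SPECT/CT fusion of skeletal imaging: the bone is segmented from
CT, volume-rendered as an opaque surface, and each visible surface point is
colored by the bone-SPECT value at the corresponding world location. Because
reconstructed bone SPECT has 4–10 mm voxels and poor spatial resolution,
volume-rendering SPECT itself produces blurred, swollen shapes that spill
activity into soft tissue; projecting the SPECT values onto the CT-derived
bone surface instead gives fused 3D images whose apparent resolution is that
of CT, with no extraosseous uptake displayed. The package also ships the
evaluation machinery used to compare such displays in reader studies of bone
metastasis, and a digital phantom so every stage is testable without patient
data.

Intended users: nuclear-medicine and medical-imaging researchers who want a
scriptable, reproducible implementation of the surface-projection display and
its reader-study statistics.

## Method

**Fusion display.** Bone is extracted from CT by thresholding at an HU level
chosen from the cortical density, followed by morphological closing, removal
of small components, and a close-holes step that re-fills marrow cavities
enclosed by the cortical shell. High tracer activity in the urinary tract and
bladder is suppressed by zeroing bright SPECT components that lie entirely
outside the dilated bone mask. Rendering uses orthographic rays marched in
steps of half the CT voxel spacing; at the first sample inside the bone mask
(refined by one bisection step) the pixel is

```
pixel = (1 − β·w(s)) · ct_shaded + β·w(s) · LUT(s)
```

where `s` is the window-normalized SPECT value trilinearly interpolated at
the hit point, `LUT` a hot-metal color scale, `ct_shaded` the
Lambertian-shaded CT transfer-function color, and `w(s) = s` so cold bone
renders as plain CT. A clip plane `n·x > d` removes a half-space; rays then
strike the cut face, which is colored with the fused CT/SPECT values to show
internal structure and metabolism in cross-section.

**Reader statistics.** Lesions scored on the four-point confidence scale
(1 definitely benign … 4 definitely malignant; score ≥ 3 = test-positive)
yield sensitivity/specificity/PPV/NPV, the tie-corrected rank AUC

```
AUC = [ Σ_{i>j} m_i b_j + ½ Σ_i m_i b_i ] / (M·B)
```

over score categories (equal to the trapezoidal area under the empirical ROC
curve), equivocal rates (scores 2–3), weighted kappa
`κ_w = 1 − Σ w_ij O_ij / Σ w_ij E_ij` with linear weights `|i−j|/3`, paired
t tests with Bonferroni adjustment, and AUC comparisons (normal test for
unpaired counts, seeded bootstrap for paired per-lesion scores).

## Worked example

The bundled reference table (`bonefuse.datasets.READER1_COUNTS`) holds one
reader's four-point confidence counts over 1746 skeletal lesions (744
metastatic, 1002 benign) under three displays: planar whole-body + SPECT,
2D SPECT/CT fusion, and 3D surface-projection fusion.

```python
from bonefuse import confusion_metrics, empirical_auc, equivocal_summary
from bonefuse.datasets import READER1_COUNTS

for name, c in READER1_COUNTS.items():
    print(name, round(empirical_auc(c).auc, 3),
          confusion_metrics(c).rounded(), equivocal_summary(c))
```

prints

```
wb_spect 0.8 {'sensitivity': 78, 'specificity': 77, 'ppv': 72, 'npv': 83} (1250, 72)
fusion_2d 0.983 {'sensitivity': 91, 'specificity': 99, 'ppv': 98, 'npv': 94} (336, 19)
fusion_3d 0.983 {'sensitivity': 91, 'specificity': 98, 'ppv': 97, 'npv': 94} (340, 19)
```

Reading across rows: planar + SPECT alone leaves 72 % of judgments equivocal
with AUC 0.800, while either fused display resolves most equivocal calls
(19 %) and raises the AUC to 0.983 — the anatomic context of CT, not the 2D
vs 3D presentation, carries the diagnostic gain.

The full imaging pipeline runs from the command line:

```
bonefuse phantom --seed 7 --out phantom_out
bonefuse segment --ct phantom_out/ct.nii.gz --out bone.nii.gz
bonefuse fuse3d --ct phantom_out/ct.nii.gz --spect phantom_out/spect.nii.gz \
    --out fusion_out --clip 0,1,0,158
bonefuse fuse2d --ct phantom_out/ct.nii.gz --spect phantom_out/spect.nii.gz
bonefuse stats --scores scores.csv --out metrics.json
```

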