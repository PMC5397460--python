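# Methods

## The display model

The package renders fused 3D bone SPECT/CT by *surface projection*: CT is
segmented into a binary bone mask, the mask is rendered as an opaque surface
by orthographic ray casting, and the SPECT value at each visible surface
point determines a color that is blended with the shaded CT color. The key
assumption is that bone-seeking-tracer uptake is only diagnostically
meaningful where there is bone: activity reconstructed outside the skeleton
(spill-over from the coarse SPECT grid, bladder content) is never displayed.
On a hybrid scanner the SPECT and CT volumes share a patient position, so the
SPECT→CT transform defaults to identity; a rigid transform is accepted but
never estimated.

Rays are marched in world space in steps of half the minimum CT voxel
spacing (default 1 mm on a 2 mm CT). Occupancy is tested against the nearest
voxel of the mask, so the rendered surface follows voxel-cell boundaries; one
bisection step between the last outside and first inside samples localizes
the surface to a quarter step. Surface color and shading are taken from the
first voxel *inside* the surface (the hit point itself sits on the air/bone
boundary, where trilinear HU is a meaningless mixture of air and cortex);
SPECT is interpolated trilinearly at the hit point, matching the idea that
the metabolic value belongs to the surface location. Shading is a headlight
Lambertian, `ambient + diffuse·max(0, n̂·l̂)` with ambient 0.3 and diffuse
0.7, normals from central differences of HU. In compositing mode each sample
along the ray is shaded the same way before front-to-back accumulation with
the transfer-function opacity; this makes a single fully-opaque sample
exactly reproduce the opaque-surface result, which the tests rely on as a
limit-case consistency check.

The blend is `pixel = (1 − β·w(s))·ct_shaded + β·w(s)·LUT(s)` with β = 0.5
by default and `w(s) = s`, the window-normalized uptake, so that cold bone
shows pure CT color and hot lesions approach the pure LUT color. A constant
blend (`w ≡ 1`) is available via `RenderSettings(uptake_modulated=False)`;
whether clinical workstations modulate by uptake is not standardized, so both
modes exist. The SPECT display window defaults to
[0, 99.5th percentile of in-bone SPECT], robust against the bladder dominating
the scale. The pixel color is a convex combination of two colors in [0,1]³,
so rendered values never leave gamut.

Clip-plane editing removes the half-space `n·x > d`. A first hit lying
within one marching step of the plane is classified as a *cut-face* hit: the
surface there is the plane itself, so it is shaded with the plane normal and
colored with the fused CT/SPECT value just behind the plane, exposing marrow,
lytic holes and internal uptake in cross-section. Commercial tools do not
document their cut-face shading; this definition is ours.

## Segmentation

Bone extraction is `HU ≥ threshold` (≥, so a voxel exactly at the threshold
is bone), morphological closing with a discrete ball (default radius 2 mm,
about one CT voxel), then removal of 26-connected components smaller than
`min_component_volume` (default 100 mm³, which deletes isolated noise specks
but keeps ribs). The default threshold is 150 HU for diagnostic CT and
100 HU is suggested for noisier low-dose CT; `suggest_threshold` offers half
the median HU at operator-placed cortical probe points as an advisory value,
since cortical density varies with osteoporosis and body habitus. Close-holes
fills every 6-connected background component not reachable from the volume
border — the marrow space enclosed by the cortical shell — and never removes
foreground, hence is extensive and idempotent. The 26/6 connectivity pairing
for foreground/background is the standard choice that avoids topological
paradoxes.

Urinary-tract and bladder suppression is defined here as: zero each
26-connected component of `SPECT ≥ urinary_percentile·max` (default 0.6)
whose voxels all lie farther than `urinary_margin` (default 10 mm) from the
bone mask. Voxels within the margin are never altered, so skeletal uptake is
conserved exactly. Clinical software calls this step "automatic" without
publishing an algorithm; ours is a reinterpretation with the stated contract.

## Reader-study statistics

Scores are 1–4 (definitely benign … definitely malignant); score ≥ 3 is
test-positive, giving sensitivity, specificity, PPV and NPV as exact
fractions plus half-up-rounded integer percentages (the convention of
clinical tables). The AUC is the tie-corrected two-sample rank statistic
over the four categories, identical to the trapezoidal area under the 5-point
empirical ROC; both routes are computed and compared in tests. Equivocal
judgments are scores 2–3 over both classes. Weighted kappa uses linear
disagreement weights `|i−j|/3` by default (quadratic available): linear is
the common choice for 4-point ordinal scales, and published κ values alone
cannot adjudicate the weighting since the underlying cross-tabs are rarely
printed. AUC comparison uses a placement-value (structural-component) normal
test for unpaired count data and a seeded lesion-bootstrap for paired
per-lesion scores; the method used is always reported alongside p, because
published reader studies often leave their ROC-comparison procedure unnamed.
Degenerate inputs (empty class, zero denominators, zero-variance differences,
one-category cross-tabs) return flagged NaN results rather than raising,
except where the statistic is undefined at the type level (empty class for
AUC).

## The digital phantom

The phantom emulates a skeletal SPECT/CT acquisition: cylindrical vertebrae
(800 HU cortex, 100 HU marrow), tubular ribs, an open pelvic ring, −50 HU
soft tissue and −1000 HU air, with Gaussian HU noise (default σ 15 HU, a
low-dose CT level). The activity map assigns relative tracer concentration
1.0 to cortex, 0.2 to marrow and 0.05 to soft tissue, adds lesions and a hot
bladder (default 15× cortical concentration) inside the pelvic ring, blurs
with an isotropic Gaussian PSF (default FWHM 12 mm, a typical reconstructed
bone-SPECT resolution), integrates onto the coarse SPECT grid (default 8 mm
voxels, inside the clinical 4–10 mm range) and Poisson-samples with means
scaled to a total count budget (default 5·10⁵). The PSF is applied on the
fine grid *before* downsampling; the order is fixed because the two
operations do not commute. All randomness comes from one seeded generator,
so a seed reproduces the volumes bitwise.

Lesion archetypes pair a CT change with an uptake change so that activity
alone discriminates malignancy poorly while CT morphology disambiguates —
the regime in which fused displays help: osteolytic metastasis −400 HU focus
with moderate uptake; osteoblastic metastasis +400 HU with high uptake;
fracture a one-voxel low-HU plane with a linear uptake band; degenerative
joint an osteophyte bump with rim uptake; plus the bladder artifact. The
magnitudes are fixture choices, not measured values. Metastasis archetypes
are malignant, the rest benign, and the truth object records per-lesion
masks and the true skeletal mask.

What the phantom does **not** model: attenuation, scatter and partial-volume
physics of SPECT reconstruction; anatomically realistic bone shapes and
trabecular texture; patient motion and rib misregistration; CT beam-hardening
and metal artifacts. Passing tests therefore demonstrate the correctness of
the pipeline's geometry, arithmetic and contracts under controlled
conditions, not clinical performance on real data.

The reader simulator draws, per lesion × reader × modality, a latent signal
`d·(±1) + N(0,1)` cut at fixed thresholds (−1, 0, 1) into scores 1–4, where
`d ≥ 0` is the modality's discrimination. It exists to exercise parameter
recovery (AUC monotone in `d`, AUC → 0.5 at `d = 0`) and the kappa pipeline
end to end; it does not model reader-specific bias or correlation beyond the
shared truth.

## Problem sizes and numerical choices

Tests and the acceptance script run the phantom at 128³ CT voxels (2 mm) and
32³ SPECT voxels (8 mm) with 64–96 px renders — sizes chosen so a full run
completes in seconds while every geometric effect (coarse-grid spill-over,
shell closure, clip-plane cuts) is still present. Resampling is trilinear
with zero fill outside the source (air/no counts) rather than clamping.
Probe points and surface lookups round to the nearest voxel. Percentages are
rounded half-up; AUC is reported to 3 decimals. Bootstrap p-values use the
add-one rule `(k+1)/(B+1)`.

## Known limitations

Perspective cameras, GPU acceleration, maximum-intensity projection,
deformable or estimated registration, attenuation/scatter correction and
SPECT reconstruction are out of scope. DICOM reading assumes a single
uniform-spacing series; gantry-tilted series are rejected by the spacing
check rather than resampled. The cut-face classification tolerance (one
marching step) can mislabel a true bone surface lying within a step of the
clip plane; reducing the step narrows the band.
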