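# Methods

This note records the models, parameter choices and numerical conventions
behind `retmodal`, and what the synthetic phantom does and does not
establish about real data.

## Coordinate and intensity conventions

All arrays are indexed `[ascan (x), bscan (y), axial (z)]` with 0-based
indices; the axial index grows with depth (vitreous → choroid). 2D images
(en-face, fundus, masks) are indexed `[x, y]`, and a point `(x, y)`
addresses `arr[x, y]`. Intensities are 8-bit (0–255). Voxel pitch is
`extent / grid` per axis; at the canonical acquisition geometry of
6 × 6 × 2 mm over 512 × 128 × 1024 voxels this is
(11.719, 46.875, 1.953) µm. Masks are stored on disk as 8-bit {0, 255}
and normalised to {0, 1} in memory; geometry metadata travels in a JSON
sidecar and is never silently defaulted.

## Phantom model

The OCT phantom is a five-surface slab model (ILM, NFL lower boundary,
OPL/ONL border, IS/OS, Bruch's membrane) at nominal depths
(200, 330, 650, 800, 880) µm, displaced by a shared low-frequency
sinusoidal undulation of ±20 µm plus ±0.5 voxel of per-surface jitter.
Slab mean reflectivities are 20 (vitreous), 120 (NFL), 45 (inner retina
between NFL-lower and IS/OS), 130 (IS/OS–BM complex) and 30 (choroid).
The whole inner band is deliberately kept at a single mean level: the
OPL/ONL border is retained as a geometric reference for focus placement
but carries no intensity step, so the only bright structures inside the
focus search band are the foci themselves. Speckle is multiplicative
Gamma noise with unit mean and relative standard deviation
`speckle_sigma = 0.1`, the standard first-order OCT speckle
approximation.

Foci are axis-aligned ellipsoids of intensity 95 centred near the OPL/ONL
border, on voxel centres (guaranteeing each focus owns at least one
voxel at coarse lateral pitch), with lateral semi-axis drawn from
50–90 µm. Hard-exudate-destined foci draw from the upper half of that
range and are elongated axially by a factor 1.6 (plain foci 1.0), so the
altitude feature separates the two lesion classes by construction.
Bounding boxes (plus a two-voxel margin) are kept disjoint along at least
one axis, so the truth mask always has exactly `n_foci` 26-connected
components and detection cannot merge distinct foci through background.
Configurations whose tallest focus cannot fit inside the narrow band are
rejected.

The paired fundus photograph is the transform preimage of the en-face
frame: exudate blobs are drawn exactly at the preimages of the selected
focus footprints, on a uniform retina background (RGB 185, 95, 45) with
Gaussian pixel noise (SD 1.5). Four straight low-contrast vessel lines
(RGB 165, 82, 42, two per orientation) provide four exactly known
intersection landmarks; the fundus→en-face mapping is a similarity
(default 3° rotation, auto-chosen scale so the fundus covers the en-face
frame, centred translation). Vessels are deliberately low-contrast: their
role here is geometric (landmarks), while the clinically important
pseudo-lesion problem (cotton-wool spots, bright vessel reflexes) is
exercised through the explicit correction-mask interface instead of
through photometric realism. Cohorts sample per-eye focus counts of 4–7
(NPDR) vs 9–14 (PDR) and exudate counts of 1–3 vs 4–7, reproducing the
direction of the clinical severity contrast; per-case seeds derive
reproducibly from the cohort seed.

**What the phantom does not emulate:** real speckle correlation and
shadowing under lesions, vascular tree geometry, photoreceptor-layer
texture, acquisition artefacts (motion, vignetting, defocus), foveal pit
geometry, and pseudo-lesions. Passing the recovery suites therefore
demonstrates algorithmic correctness under the stated noise model, not
clinical-grade performance on patient data.

## Layer segmentation

Each B-scan is denoised by a direct bilateral filter (5 × 5 window,
σ_spatial = 2 px, σ_range = 15 gray levels). The filter is implemented as
an explicit shift-and-weight sum: the centre pixel always carries weight
one, making the output a convex combination of inputs, which guarantees
the intensity-range-preservation invariant even where all neighbour
weights underflow.

A boundary is the minimum-cost left-to-right path through
`cost = ∓ ∂I/∂z` (sign selected by the requested polarity), with
per-step vertical jump ≤ 2 voxels, solved by dynamic programming;
ties break toward the smallest axial index, making runs deterministic.
Boundaries are traced top-down in stacked search bands — ILM over the
full range, NFL-lower within 15 % of the axial range below the ILM,
IS/OS below NFL-lower (stopping 3 % above the bottom), BM below IS/OS —
so each DP problem contains a single dominant transition of its
polarity. Surfaces are median-filtered over a 5 × 5 (ascan, bscan)
window and the ordering `nfl_lower < isos < bm` is enforced; a constant
volume is rejected for lack of gradient evidence. On phantom cohorts the
mean absolute surface error is ≈ 0.5 voxel, dominated by the half-voxel
ambiguity of a discrete step edge under central differences.

## HRF detection

The search band spans `nfl_lower + m ≤ z ≤ isos − m`. The band mask
itself uses margin m = 1 voxel (keeping residual NFL/OS brightness out);
the detection wrapper defaults to m = 2, the extra voxel guarding against
layer-surface estimation error, after bright-layer leakage was observed
at m = 1 during design.

Seeds are band pixels strictly brighter than `μ + k·σ` of the band pixels
of that B-scan (per-B-scan statistics make the threshold scale-free).
The library default is k = 2; the pipeline operating point is **k = 4**,
chosen from the phantom's noise model before the test suite was written:
with Gamma speckle at σ = 0.1 the background tail above μ + 2σ admits
~2 % of band pixels (hundreds of false seeds per volume), whereas at
μ + 4σ the expected number of false seed *pairs* per volume is ≪ 1.
Single-pixel seed components are discarded (`seed_min_px = 2`), since a
focus contributes a multi-pixel seed cluster while speckle excursions
are isolated. Region growing admits 8-connected band pixels within
δ = 10 gray levels of the seed-component mean; seed pixels stay in the
lesion unconditionally. Grown per-B-scan masks are linked by 26-connected
3D labelling and lesions below 3 voxels are dropped. A lesion is
classified as a hard exudate when ≥ 50 % of its en-face footprint lies
inside the registered fundus HE mask.

## HE segmentation on fundus images

Saliency at a scale h is the Euclidean distance between the mean CIELab
vector of the centred (2h+1)² square and that of the surrounding square
annulus of width h, with symmetric boundary padding; the final map sums
the per-scale maps. The default scale set is {2, 4, 8} px half-widths:
the outer window of a scale sets the width of the saliency halo around a
lesion, and with half-widths much larger than the lesion (e.g. 15 px for
a ~16 px blob) the halo survives thresholding and triples the mask area
(measured Dice 0.45 vs 0.95 on a single bright disc). Scales should track
the expected lesion diameter.

Thresholding defaults to Otsu on the summed map. Otsu is bistable when
exudates are rare — with one blob the inter-class variance optimum can
jump to the noise floor and flood the mask — so the end-to-end pipeline
uses a fixed threshold of 25 ΔE units, half the phantom's
exudate-to-retina Lab contrast (~50). Components under 5 px are removed.
The add/remove correction-mask interface replaces the human review step;
in the phantom pipeline the remove mask is the (dilated) vessel truth
mask, standing in for the clinician removing pseudo-exudates.

## Registration and projection

Transforms are fitted by least squares on landmark pairs (similarity by
default — rotation, isotropic scale, translation — affine by flag);
degenerate configurations (too few, coincident or collinear points) are
rejected, and the RMS residual is reported. The en-face image is the
mean intensity over the inclusive [IS/OS, BM] axial band. Fundus images
are resampled onto the en-face grid by inverse mapping with bilinear
interpolation (nearest-neighbour for masks), zero fill and an explicit
validity mask. The transform operates in pixel coordinates of the two
frames; it does not model the anisotropic physical pitch of the en-face
grid, matching how landmark registration is practised on these images.

## Features, statistics, classification

Per lesion: area = footprint pixel count × lateral pitches (mm²);
altitude = mean per-column axial voxel count × axial pitch (µm);
distance = *lateral* (en-face) Euclidean distance from lesion centroid to
the fovea — lesions sit at varying depths and the fovea is an en-face
reference, so the 2D reading was chosen over 3D; reflectivity = mean
intensity over lesion voxels. Eye-level features are means over lesions;
an eye with no lesions has undefined means (flagged), which the pipeline
maps to zero lesion load before normalisation. Features are min-max
normalised across the full cohort before leave-one-out evaluation; this
mirrors the stated analysis order but leaks the held-out eye's range
into training — a caveat for interpreting absolute accuracies.

Pearson r with a two-sided t-based p-value (n − 2 df) and OLS slope and
intercept quantify CFP-vs-OCT area agreement per severity group; groups
under three eyes are skipped with a warning. No multiple-testing
correction is applied.

The classifier is an RBF SVM under leave-one-out cross-validation, NPDR
positive. Per fold, (C, γ) are chosen by inner stratified 3-fold CV
accuracy over power-of-two grids (default 2⁻⁸…2⁸ in steps of 2² per
axis, a 9 × 9 grid — dense enough to bracket the scale of normalised
features while keeping the 24-fold evaluation of all combination/group
pairs tractable); ties break toward the smallest C then γ, making the
whole procedure deterministic. MCC with a zero denominator factor is
reported as 0 and flagged. The eight evaluated feature combinations are
{1,2}, {1,2,3}, {1,2,4}, {1,2,5}, {1,2,3,4}, {1,2,3,5}, {1,2,4,5},
{1,2,3,4,5} (1 = area, 2 = count, 3 = distance, 4 = altitude,
5 = reflectivity).

One caution on leave-one-out null distributions: under label permutation
the mean LOO accuracy of a *low-capacity* classifier is far below 50 %,
because removing one eye from a balanced cohort always leaves its class
in the training minority and a majority-rule predictor is then always
wrong. The permutation-null sanity check therefore uses a high-capacity
local configuration (C = 10⁴, γ = 4), whose null sits at ~47–49 %; this
is a property of LOO itself, not of the implementation.

## Problem sizes and determinism

Test and reproduction runs use cohorts at 128 × 32 × 256 voxels (same
6 × 6 × 2 mm extent, i.e. pitch (46.9, 187.5, 7.8) µm), the package's
standard reduced geometry for fast, deterministic end-to-end validation;
the canonical 512 × 128 × 1024 geometry is the config default for
single-case use. Every stochastic step is driven by
`numpy.random.default_rng` seeded from the case or run seed; reruns with
the same configuration are bit-identical, which the pipeline manifest
checksums verify.

## Known limitations

- The layer model segments exactly the three boundaries the analysis
  needs; it is not a general retinal layer segmenter and assumes the
  stacked-band ordering holds (pathologies that invert layer contrast
  would break the band heuristic).
- HRF detection assumes foci are brighter than the band background;
  hypo-reflective or shadow-dominated lesions are out of scope.
- The saliency segmenter has an intrinsic halo at the annulus scale; its
  masks are dilated relative to truth (Dice ≈ 0.5–0.6 on small blobs)
  even when lesion counts are exact. Downstream splitting uses overlap
  fractions and is insensitive to this dilation.
- Registration is planar and rigid-similar; no deformable component.
- Cohort-level classification accuracies on phantoms reflect the
  phantom's class separation, not clinical effect sizes.
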