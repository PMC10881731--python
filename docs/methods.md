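# Methods

## The measurement model

The package treats retinal vascular tortuosity assessment as a three-layer
measurement: per-segment geometry (how bent is each vessel), per-segment
anatomical context (how much should this vessel count), and an image-level
decision (is the retina clinically tortuous).

**Segment geometry.** A vessel segment's tortuosity follows the arc–chord
formulation: the centerline is split at inflection points into `n`
subsegments of constant convexity and scored
`τ_v = (n−1)/L_c · Σ (L_cs_i/L_xs_i − 1)`. The metric is zero exactly for
straight segments and single arcs (`n = 1`), grows with both the number of
convexity changes and their amplitude, and is invariant under rigid
motions. Its two inputs — inflection locations and subsegment lengths —
have different numerical sensitivities, which drives the smoothing design
below.

**Anatomical weighting.** Each segment's weight is
`f_i = L_ci·[ω_AV·f_AV + (1−ω_AV)(1−f_AV) + ω_Cal·f_Cal + ω_dOD·f_dOD +
ω_dFov·f_dFov]`. Factors are kept in raw pixel units; no normalization is
applied, so fitted coefficients are scale-bearing (distance coefficients
come out around 1e-3 because distances run to hundreds of pixels). The
artery/vein term is a convex combination (`0 ≤ ω_AV ≤ 1`); the remaining
coefficients are only constrained non-negative, keeping `τ_f ≥ 0`. The
bracket mixes a bounded term with unbounded pixel terms; this asymmetry is
deliberate and absorbed by the fitted coefficients. With every anatomical
factor disabled the weight reduces to the standard length weighting
`f_i = L_ci`. A reversed optic-disc distance `Rd_OD = k − d_OD` (k = 600 px,
slightly above the largest plausible distance; clamped at 0) is available
for ablations where near-disc vessels should count more.

**Decision and fitting.** An image is tortuous when `τ_f > φ_tort`
(strictly). The five parameters (ω's and φ_tort) are fitted by NSGA-II
against binary labels, maximizing (Sensitivity, Specificity) jointly; the
result is a Pareto front of operating points rather than a single model,
summarized by its ROC convex hull and AUC, with the balanced-accuracy
optimum exposed as the default predictor.

## Pipeline parameters

| parameter | default | units | rationale |
|---|---|---|---|
| binarization threshold | 0.5 | probability | maps are near-binary away from edges |
| optic-disc exclusion radius r | 60 | px | vessels curve naturally entering the disc; value matched to ~768×584 fundus geometry |
| min segment length | 10 | px | below the smoothing support, geometry is meaningless |
| rejoin direction tolerance | 30 | deg | end tangents (least-squares over the last ≤10 px) must be anti-parallel within this |
| rejoin caliber ratio tolerance | 0.25 | — | ratio within [0.75, 1.33] |
| Savitzky–Golay window / order | 7 / 2 | px | smallest meaningful order-2 window at the 10-px segment scale |
| Gaussian σ (smoothing) | 3 | px | with the SG stage, the detection low-pass |
| curvature significance ε_k | 1e-4 | — | cross-product of unit tangents; suppresses raster zero-crossings |
| inflection end guard | 12 | px | filter support; skeleton tips carry thinning artifacts |
| reversed-distance constant k | 600 | px | slightly above the largest optic-disc distance |
| NSGA-II | pop 100, SBX η_c=15 p_c=0.9, PM η_m=20 p_m=0.9 | — | standard operator settings; population scaled to desk-size datasets (500 is used at clinical scale) |
| stopping | 25 stalled generations, cap 200 | — | "until convergence" made operational: stop when the first front's objective set stops changing |
| gene uppers | ω_Cal ≤ 1, ω_dOD, ω_dFov, φ_tort ≤ 0.1 | — | lets each pixel-unit term span dominance to negligibility |

All tolerances and windows are keyword arguments; the defaults above are
what the tests and acceptance script use.

## Numerical choices in the tortuosity metric

The low-pass filter exists to make convexity-change detection robust to the
discrete pixel representation, but heavy smoothing also attenuates genuine
curve amplitude: a σ = 3 px Gaussian shrinks a 40-px-wavelength sinusoid by
roughly 8% in amplitude, which biases arc/chord ratios low by 10–25%. The
two roles are therefore separated:

- **Inflection detection** runs on the heavily smoothed curve
  (Savitzky–Golay order 2, window 7, then Gaussian σ = 3). The curvature
  sign is the z-component of the cross product of successive
  central-difference unit tangents; the zero crossing is interpolated to
  sub-sample precision before rounding. Crossings within 12 samples of
  either end are discarded (the filter support overlaps the boundary and
  skeleton tips carry thinning hooks).
- **Length measurement** runs on a Gaussian-weighted local quadratic fit
  (same σ). This filter reproduces second-order geometry exactly — circles
  and parabolas pass through unchanged — so subsegment arc and chord
  lengths are unbiased while pixel jitter still averages out.
- **Sub-pixel centerline refinement**: thinning quantizes the centerline to
  the grid and systematically loses up to half a pixel of amplitude at
  curve extrema — fatal at amplitude 5 px. When the soft class map is
  available, each skeleton pixel is moved to the midpoint of the two
  half-level crossings of the intensity profile along the local normal,
  recovering the boundary (and hence center) to sub-pixel precision.
  Pixels without a clean crossing pair, or needing a shift above 1.5 px,
  are left unchanged.

Endpoint handling throughout is odd (point) reflection, which continues
straight lines exactly: a straight path survives the whole smoothing stack
to machine precision, keeping the zero-tortuosity guarantee exact. Curve
endpoints always open and close subsegments, so the `n` subsegments
partition the segment; subsegments with numerically zero chords are
skipped with a warning. Two segment lengths are exposed deliberately: the
pixel count `L_ci` (used in the weighting factor) and the polyline arc
length of the measured curve (the `L_c` normalizer inside τ_v).

With these choices the pixel pipeline agrees with the continuous
quadrature oracle within 5% relative for sinusoids of amplitude ≥ 5 px and
wavelength ≥ 40 px, and varies under rotation by well under 2%. For
arbitrary short or low-amplitude vessels (amplitude < 5 px, or spans whose
terminal subsegments are heavily truncated) errors can be larger; the
weighting fit is robust to this because training and prediction use the
same measurement.

## Skeleton decomposition conventions

Connectivity is 8-connected throughout. Junction templates are all
45°-step rotations of the T pattern (three arms with ring gaps {2,2,4})
and the Y pattern (gaps {2,3,3}); background positions are don't-care, so
4-way crossings match, and matches within an 8-neighborhood are merged
into one junction (representative pixel nearest the cluster centroid).
Under the don't-care convention this template set is exactly "center plus
any three pairwise non-adjacent neighbors", which is what the test oracle
enumerates independently. The optic-disc region is masked before junction
detection. Components left with branch pixels that are not T/Y-shaped are
traced repeatedly so every pixel lands in some path. When segments are
rejoined through a junction, the junction pixels are inserted as a
connector and may be shared by both merged vessels — the same multi-label
convention the class maps use at artery/vein crossings. Merged calibers
are length-weighted means.

## The synthetic scene generator

The generator emulates what a well-trained segmentation network would
output for a retina, not the retina itself: per-class soft maps in [0, 1]
with near-1 interiors and soft edges, a whole-vessel map that is the
pixelwise maximum of the class maps, and exact landmark positions.
Vessels are straight or sinusoidal tubes with calibers of 4–8 px,
wavelengths 40–70 px, spans 100–220 px, placed radiating from the optic
disc on a 320×320 px canvas (584×768 for full-scale runs); arteries and
veins may cross freely (the trees are analyzed independently) but
same-class vessels keep clear of each other, and all centerlines keep
clear of the disc-masking radius so ground-truth segment counts are
unaffected by masking. T-junctions attach a half-caliber perpendicular
stem to a straight host vessel. Rasterization is anti-aliased
(`coverage = clip(r + 0.5 − d, 0, 1)`): the half-level contour sits
exactly on the true tube boundary, so the soft edge carries sub-pixel
boundary information the way a confident network output does; a 1-px
Gaussian (`edge_softness`) adds the final soft falloff. Scene generation
is bit-deterministic given the spec.

Per-vessel ground truth is analytic: curvature zeros of the parametric
sinusoid fall at every half wavelength, subsegment arc lengths come from
adaptive quadrature, and the same arc–chord formula gives τ*. Labeled
datasets apply the weighting rule with known coefficients (by default the
representative fitted configuration ω_AV = 0.223, ω_Cal = 8.83e-2,
ω_dOD = 1.32e-3, ω_dFov = 6.51e-4, φ_tort = 2.46e-3) to the ground-truth
factors — not pixel measurements — so optimizer correctness is isolated
from measurement noise. Half the scenes draw amplitudes from a low regime
(0–3 px) and half from a high one (6–14 px), and scenes whose rule-based
score falls within 25% (relative) of φ_tort are resampled: clinical
grading distinguishes none/mild from moderate/severe as categories, so
borderline images do not straddle the decision boundary, and labels stay
stable under the few-percent pixel-measurement noise.

What the generator does **not** model: background texture and illumination
artifacts, segmentation failures (gaps, false vessels), branching-tree
topology beyond single T-junctions, caliber tapering, pathology. Passing
tests therefore demonstrate correctness of the measurement and fitting
machinery on clean network-like inputs, not robustness to segmentation
errors on real fundus photographs — the clinical performance of the
approach cannot be established from synthetic scenes.

## Evaluation conventions

ROC hulls always include the trivial corners (0,0) and (1,1); AUC is the
exact trapezoid sum over hull vertices. Note the hull AUC of a finite
point set is generally larger than the rank (Mann–Whitney) AUC of the
underlying scores — both are exposed in the tests. Monte-Carlo
cross-validation uses stratified random splits (default 10 repetitions of
80/20) so Sensitivity and Specificity remain defined on small synthetic
sets, reports the mean ± sd of per-split hull AUCs, and also emits a
vertically averaged hull curve on a fixed 101-point FPR grid. Cohen's κ
returns 1 for identical lists even when chance agreement is 1.
Problem sizes in the shipped experiments (80 scenes, populations of 100,
≤ 100 generations) are desk-scale choices that keep the full acceptance
run at a few minutes on one CPU while leaving the optimizer's behaviour
qualitatively unchanged.

## Known limitations

- The rejoin step considers only pairwise merges per junction; a vessel
  crossing more than two others inside one junction cluster can stay split.
- Sub-pixel refinement assumes an approximately symmetric cross-vessel
  profile; near junctions and crossings the profile is contaminated and
  refinement falls back to the raw pixel.
- The weighting bracket's unit asymmetry means fitted coefficients are not
  comparable across image resolutions without refitting.
- `analytic_tortuosity` is exact only for the generator's sinusoidal
  family; for other parametric families the generator would need a new
  curvature-zero analysis.
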