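# Methods

## Problem and pipeline

`adpkdvol` measures kidney, liver and spleen volumes on axial
T2-weighted abdominal MRI of patients with autosomal dominant polycystic
kidney disease (ADPKD). Total kidney volume (TKV) and height-adjusted
TKV (ht-TKV = TKV / height) are the established prognostic biomarkers of
ADPKD progression; liver and spleen volumes track the extrarenal disease.

The pipeline is a 2D, per-organ design:

1. each axial slice is min–max normalized (slice minimum → 0.0, maximum
   → 1.0);
2. three independent *binary* U-Nets produce per-voxel probabilities for
   the kidney class (right + left merged — the merged class trains more
   reliably than a left/right distinction), the spleen, and the liver;
3. probabilities are thresholded at 0.5 (strictly greater than);
4. voxels claimed by more than one organ are adjudicated by a fixed
   priority, kidney > spleen > liver, which encodes the empirical
   observation that kidney/liver boundary conflicts belong to the kidney;
5. the merged kidney class is split into right (label 1) and left
   (label 2) at the mid-sagittal plane of the volume;
6. volumes are voxel counts × voxel volume; agreement statistics compare
   predictions to reference contours.

Label indices follow the ITK-SNAP annotation convention: 1 = right
kidney (red), 2 = left kidney (green), 3 = spleen (blue), 4 = liver
(yellow). A legacy diagnostic mode encodes an overlap voxel as the *sum*
of the claiming indices (right kidney 1 + liver 4 = pink 5). The sum
code is ambiguous — left kidney 2 + spleen 3 is also 5, and kidney 1 +
spleen 3 collides with the liver's own index 4 — so it is retained only
as a visual-audit output with an explicit ambiguity report, never for
volumetry.

## Canonical orientation and the midline

All volumes are reoriented at read time to canonical axes: axis 0 runs
patient right → left, axis 1 anterior → posterior, axis 2 inferior →
superior (nibabel axis codes `('L','P','S')`). The midline is the
mid-sagittal plane of the volume grid, `x index = (nx - 1) / 2`, not an
anatomical landmark; kidney voxels strictly patient-left of the plane
become left kidney, and voxels exactly on the plane stay right kidney.
This is the simplest reproducible rule; its known failure mode is a
kidney that genuinely crosses the midline, part of which will be
assigned to the wrong side.

## Asymmetric train/inference geometry

Training slices are mapped to 640×640 and center-cropped to 512×512,
focusing capacity on central anatomy. The 640 mapping preserves aspect
ratio (longer side scaled to 640, shorter side zero-padded) so organs
are never anisotropically stretched. At inference the crop is *removed*:
slices are resized directly to 512×512 with no cropping, because a
cropped inference path truncates organs near the image border (the liver
especially), and the probability map is resized back to the native grid
through an exact inverse descriptor. Intensities and probabilities are
resampled bilinearly; labels with nearest-neighbour.

Constant slices normalize to all zeros (they carry no contrast and would
otherwise divide by zero).

## Networks, loss, optimization

Each organ model is a U-Net: a double-convolution (3×3 conv → batch norm
→ ReLU, twice) encoder over six scales with 2×2 max pooling, and a
decoder with exactly five nearest-neighbour upsampling stages, each
followed by skip concatenation and a double-convolution block, ending in
a 1×1 convolution and sigmoid. Encoder size is a preset of channel
widths per scale — `tiny` (8…16 channels) for CPU/phantom work, wider
presets for larger studies; pretrained encoder weights can be loaded but
are not required, and all tests use random initialization. The network
core (layers, backpropagation, optimizers) is implemented in NumPy with
im2col convolutions; its gradients are verified against central finite
differences in float64.

The loss is soft dice plus binary cross-entropy with equal weights:

    L = w_d · (1 − (2Σpg + ε)/(Σp + Σg + ε)) + w_ce · BCE(p, g)

with smoothing ε = 1 in both numerator and denominator (stable on empty
masks; configurable). On binary predictions with ε → 0 the dice term
equals 1 − DSC, which the tests use as a cross-module consistency check.

Optimization is rectified Adam (RAdam) wrapped in Lookahead (k = 5,
α = 0.5), batch size 8, learning rate 5·10⁻³ (chosen once for reliable
convergence of the tiny preset on noise-free phantoms within 30 epochs).
After every epoch the *volume-wise* Dice on the validation subjects is
computed; the checkpoint keeps the weights of the best epoch, and
training stops early when validation Dice has not improved for
`patience` (default 10) epochs.

Multi-class softmax training and 3D models are deliberately out of
scope: the per-organ binary 2D design is the modelled protocol.

## Subject split

Train/validation assignment is per subject (all scans of a subject stay
together), stratified by TKV quartile crossed with pulse-sequence name,
at a 70/30 default. Within strata, train counts are set by
largest-remainder allocation against the global quota, so small strata
cannot systematically starve one partition; both partitions are
guaranteed non-empty.

## Agreement statistics

* **DSC** = 2|A∩B| / (|A|+|B|); two empty masks score 1.0 (an organ
  absent from both segmentations is perfect agreement).
* **Lin's concordance** uses population (1/n) moments:
  2s_xy / (s_x² + s_y² + (x̄ − ȳ)²); undefined (error) when both series
  are constant, reported as NaN for single-case runs.
* **RMSE** in mL; **average percent error** is the mean over cases of
  the *absolute* per-case error |y−x|/x × 100 (a signed mean would let
  over- and under-segmentation cancel); undefined when a truth volume is
  zero.
* **Zero-error count**: cases whose two volumes agree after rounding to
  the nearest 1 mL (volumes are reported in whole mL).
* **Bland–Altman** on the percent scale: per case (y−x)/mean(x,y)×100
  against the case mean; bias ± 1.96·SD limits; differences signed as
  prediction − truth.
* **Interobserver SD**: per-case sample SD across observers, averaged
  over cases.
* **ICC(2,1)**: two-way random effects, absolute agreement, single
  rater, from the ANOVA mean squares. This variant is the natural one
  for exchangeable human observers measuring the same cases; the tests
  cross-check it against an independent variance-components oracle and
  against `pingouin.intraclass_corr`.

## Synthetic phantom

The phantom generator is what makes every stage trainable and testable
without patient data. Each subject is four pairwise non-overlapping,
axis-aligned ellipsoids (right kidney, left kidney, spleen, liver) of
piecewise-constant intensity on a darker background, with spherical
hyperintense cysts rendered fully inside the kidneys and liver (ADPKD
spleens are enlarged but typically cyst-free, so the default spleen has
none), plus additive Gaussian noise. T2-like contrast ordering is
liver < kidney parenchyma < spleen ≪ cyst fluid. Voxel membership is by
center-point containment, which makes a brute-force point-in-ellipsoid
scan an *exact* oracle for the label maps and bounds the difference
between voxelized and analytic 4/3·π·abc volumes by one surface shell.

Defaults: a 64×64×20 grid at 5.5×5.5×9 mm spacing (an abdominal
352×352×180 mm field of view at phantom scale), organ positions and
sizes plausible for an enlarged ADPKD abdomen, 10 cysts per kidney and 5
in the liver with 3–12 mm radii, noise SD 8. Cohorts jitter organ sizes
log-normally (one shared factor for both kidneys so TKV varies smoothly)
and positions uniformly, drawing subject height ~N(1.70, 0.09) m and a
pulse-sequence tag; geometry that violates the non-overlap invariant is
redrawn. Default jitter gives a TKV spread wide enough to occupy the
quartile strata.

Observer variability is simulated by shifting each organ's signed
distance field (half-voxel-centered, in mm) by a smooth Gaussian random
field with pointwise SD equal to the boundary-noise scale and
re-extracting the positive set; zero noise returns the truth exactly,
and conflicts between perturbed organs resolve to the lowest label
index. Because the mechanism works in millimetres of boundary
displacement, noise well below the voxel size flips almost nothing —
observer-simulation tests therefore run on finer-spaced (3–4 mm)
phantoms.

What the phantom does *not* emulate: MRI physics (coil shading, T2
contrast detail, fat saturation), anatomical shape, and the confounders
seen clinically (fluid-filled stomach, gallbladder). Passing
phantom-scale tests demonstrates that the machinery — training loop,
adjudication, midline split, volumetry, statistics — is correct, not
that the tiny networks would segment patient MRI.

## Problem sizes used in the self-checks

The end-to-end self-check trains the three `tiny` networks on a
noise-free 8-subject cohort of 64×64×20 phantoms (70/30 split, ≤ 30
epochs) and evaluates on the held-out subjects; it completes on a single
CPU. Held-out per-label DSC ≥ 0.8 is the pass margin; the run reported
in the README reaches ≥ 0.997 for all four labels. Bland–Altman
coverage is exercised with 500 simulated cases at 5% proportional error,
and ICC parameter recovery with 200 cases × 3 observers.

## Numerical choices and edge cases

* Threshold ties: probability exactly 0.5 is negative (strict `>`).
* Midline ties: voxels exactly on the plane are right kidney.
* Adjudication is a single ordered scan (kidney, spleen, liver) —
  equivalent to the pairwise default rules and total; it never discards
  a claimed voxel, and is idempotent on its own output.
* DICOM series: slices sorted by projection of ImagePositionPatient on
  the slice normal; through-plane spacing is the median gap, with a
  warning when gaps deviate by more than 1% (clinical series jitter).
* NIfTI round trips preserve labels bit-exactly and spacing/orientation
  to float precision; the origin is not preserved (volumes are treated
  as position-relative).
* Label maps are stored as unsigned 8-bit (ITK-SNAP-compatible, exact).

## Known limitations

* The midline rule mislabels kidneys that cross the mid-sagittal plane.
* No connected-component cleanup or false-positive suppression; the
  clinical workflow assumes manual correction of model output.
* The sum-overlap encoding is ambiguous by construction and kept only
  as a flagged diagnostic.
* Phantom-scale training says nothing about clinical-scale accuracy;
  the wider encoder presets exist but are untested at clinical size.
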