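# Methods

## Problem setting

Routine aerobiological monitoring counts airborne pollen on Hirst-type
sampler tapes under a brightfield microscope. Within the nettle family
(Urticaceae) this is medically unsatisfying: *Urtica* pollen is barely
allergenic while several *Parietaria* species are severely so, yet their
grains — small (~11–20 µm), rounded, 3–4-porate, thin-walled — cannot be
told apart by eye. Only *Urtica membranacea* is distinguishable, by its
small size (~10–12 µm) and high pore count (usually more than six). The
morphological contrasts that do exist are subtle: a more pronounced
annulus (exine thickening around each pore) and slightly more angular
outline in *Urtica*, coarser (scabrate) surface ornamentation and
slightly smaller size in *Parietaria*.

`pollenstack` implements the image side of a monitoring workflow that
makes these contrasts machine-readable: Z-stacks (20 focal planes,
1.8 µm apart) of stained, unacetolysed grains are segmented, cleaned of
out-of-focus planes, collapsed into three complementary projections, and
classified by a convolutional network with an open-set "unknown"
category.

## Pipeline stages

### Grain detection

The detector binarises the minimum-intensity projection of the stack
(a stained grain is dark in at least one plane, so the projection is
robust to per-slice defocus; a per-slice union mode is available) with
Otsu's threshold, fills holes, applies one opening step, and labels
8-connected components. A candidate is kept only if it

* does not touch the frame edge (only complete grains are usable),
* has an equivalent circular diameter above 5 µm ("size" is read as
  equivalent diameter — the palynological convention for grain size;
  the area and bounding-box readings would pass smaller debris),
* has circularity 4πA/P² above 0.3, with P from the Freeman chain-code
  perimeter estimator (`skimage.measure.perimeter`). The estimator
  matters near the cut: for a digital square it reproduces the hand
  value π/4 within ~5 %, and it is named in the detection log,
* is separated from every other candidate by at least one background
  pixel, **and** contains only one grain-scale peak in its distance
  transform. The second condition catches pairs that have fused into a
  single component, which the pixel-separation rule cannot see: peaks
  must exceed 45 % of the component's deepest interior distance and be
  at least half a minimum grain diameter apart. Deeply fused pairs
  whose union is convex remain undetectable in principle; on rendered
  scenes the check resolves overlaps down to roughly 15 % engagement of
  the two discs.

Rejected candidates are logged with the first failed rule
(border / size / circularity / overlap) and the measured value, so every
exclusion is auditable. Accepted regions are returned sorted by
bounding-box origin for determinism.

### Focus filtering

An in-focus slice of a stained grain contains both deep shadows (the
exine wall) and a bright surround; defocus pulls both extremes toward
the mid-grey background. A slice is therefore kept when its minimum
intensity (within the grain mask dilated by the crop margin) is at or
below `min_pixel_threshold` **and** its maximum is at or above
`max_pixel_threshold`. The two thresholds bound different statistics,
so no ordering between them is enforced — `(+inf, 0)` is the vacuous
setting that keeps everything. Because absolute intensities depend on
bit depth and staining, the default thresholds are calibration-free
percentiles of the stack's own per-slice extrema (minimum ≤ P25 of the
slice minima, maximum ≥ P75 of the slice maxima); these defaults are a
package choice, not values from any reference instrument. If fewer
than `min_kept_slices` (default 3) slices survive — debris-occluded
grains on aerobiological tape — the highest-contrast slices are kept
instead and a warning is logged. Output is always a subsequence of the
input slices: no reordering, no resampling.

### Projections and framing

Three projections of the kept slices form the channels of the
classifier input, in the fixed order (stddev, min-intensity,
extended-focus):

* **standard deviation** — per-pixel sample standard deviation (n−1
  denominator; a flag selects the population variant). Bright wherever
  intensity changes with depth: walls, pores, ornamentation.
* **minimum intensity** — per-pixel minimum; the darkest rendition of
  every absorbing structure.
* **extended depth of field** — per pixel, the intensity from the slice
  where that pixel is sharpest. The focus score is squared Sobel
  gradient energy averaged over a 5 px window, with the score maps
  smoothed by a 2 px Gaussian before the arg-max to regularise the
  slice-index map. Selection is hard (no blending), so every output
  value exists somewhere in that pixel's slice column — an exactly
  testable invariant.

Each channel is min–max normalised to [0, 1] independently (the
channels have incommensurate ranges; the normalisation constants are
recorded in per-grain provenance) and placed **unscaled** into a
276 × 276 frame with the grain centroid at the centre (±1 px), padded
with the channel's border-median background. Grain size is a class
feature, so a grain larger than the frame is an error, never a resize.

### Classifier

The classification head is a softmax over the three classes; a grain
whose top score falls below the *identity threshold* (0.60 by default,
0.70 as the strict variant) is reported as `unknown` rather than forced
into a class. For a fixed prediction set the unknown fraction is
non-decreasing in the threshold.

Training uses stratified k-fold cross-validation — fivefold gives
80/20 train/validation splits, tenfold 90/10 — with 30 epochs per fold.
When plant/sample identifiers are available, folds additionally keep
all images from one plant together (`StratifiedGroupKFold`), which is
stricter than plain stratification and prevents leakage between images
of grains from the same plant; a flag restores plain stratification.
Augmentation is applied online to training batches only and is
deliberately morphology-preserving: random horizontal/vertical flips
plus one multiplicative brightness factor per image drawn uniformly
from [0.1, 2] and clipped to the input range. Rotation, zoom, shear and
translation are excluded because size and shape are class features.

Metrics follow the standard one-vs-rest decomposition per class:
precision TP/(TP+FP), recall TP/(TP+FN), F1 = 2PR/(P+R), and CCR
(correct classification rate) = trace/total. Averages are weighted by
class support; for a complete confusion matrix the weighted recall
equals the CCR, which is asserted as an identity test. Divisions by
zero yield 0 with a logged flag. Both fold-pooled (confusion matrices
summed, then scored) and fold-averaged metrics are reported, since
either convention is common.

The network engine is a small, self-contained numpy implementation
(im2col convolution, max/average pooling, dense layers, inverted
dropout, softmax cross-entropy with L2 weight decay, Adam); all
randomness flows through seeded generators, so builds, folds, dropout
and batch order are reproducible bit-for-bit. Four architectures are
registered. `tiny_test` is the desk-scale network used by the test
suite and the reproduction script: a parameter-free instance-norm input
layer (per-image, per-channel standardisation — this cancels the
multiplicative brightness augmentation by construction, so invariance
is architectural rather than learned), a 4× average-pool stem, three
conv(3×3)/ReLU/max-pool blocks of 12/24/48 channels, and a 64-unit dense
head with dropout. `light_v1`, `light_v2` and `deep_baseline` are
larger plain-conv variants of the same pattern. None of them is a
published backbone, and the published accuracies of GPU-scale
transfer-learning models on real reference libraries are not a target
of this package. `pretrained` mode loads an externally supplied weight
file and fails loudly when none is given — there is no silent fallback
to random initialisation.

Training defaults that the reference workflow leaves unspecified are
package choices, set once during development and documented in
`TrainConfig`: Adam with learning rate 3 × 10⁻³, batch size 32, dropout
0.25, L2 weight 10⁻⁴.

## Synthetic data

No public image set exists for this task (real reference images are
held by their authors), so the package ships a first-class phantom
generator that defines the study conditions for all tests.

A phantom grain is a dark disc on a bright background (stained
brightfield convention, background level 200 of 255) composed of: a
soft-edged cytoplasm disc; a dark exine rim ~0.45 µm wide drawn just
inside the outline; `n_pores` darker pore spots (~0.9 µm) evenly spaced
on the rim with small angular jitter; an annulus term — a wider,
shallower darkening around each pore whose amplitude is
`annulus_strength`; multiplicative ornamentation with 0.8 µm
correlation length (the scabrate scale; anything much finer would not
survive defocus, let alone the optics) scaled by `texture_amplitude`;
and a radial outline perturbation `r(θ) ∝ 1 + 0.16·angularity·cos(n_pores·θ)`
plus a slight ellipticity term. The rendered outline radius is drawn
1.2 px inside the nominal radius so that a thresholded mask of the
sharpest slice measures the nominal diameter within ±1 px — grain
diameter is conventionally read from the apparent boundary.

Depth is modelled by per-slice Gaussian defocus with
σ(z) = 0.8 px + 0.9 px/µm · |z − z_focus|, the simplest model that
reproduces the focus-dependent contrast the slice filter needs. Scenes
composite any number of grains additively in darkness (overlaps darken
further), add debris — random dark polygons of 1–3.5 µm at random
depths, kept below the 5 µm size cut so the detector's size rule is its
defence — and additive Gaussian detector noise. Scene ground truth
records each grain's centre, diameter, label, and overlap/border flags.

Class presets encode the direction of every reported contrast
(diameters: urtica 13–20, parietaria 11–16, membranacea 10–12 µm; pores
3–4 vs ≥6; annulus urtica ≫ parietaria; texture parietaria ≫ urtica;
angularity highest for membranacea). No quantitative ornamentation
measurements exist for these taxa, so the preset magnitudes are package
choices tuned for physical plausibility; by construction the classes
are separable, and the end-to-end accuracy bound in the acceptance
checks is a property of these presets, not an empirical claim about
real pollen. Datasets attribute grains to a small number of source
plants per class (default 4) with mild per-plant diameter/texture
offsets, so grouped cross-validation has real structure to respect.

What the phantoms deliberately do not model: realistic point-spread
optics (no PSF), colour, oncus bodies, non-Urticaceae confounders
(*Humulus*, *Morus* — in practice removed manually before
classification), grain clumping beyond pairwise overlap, and tape
background structure. Passing tests therefore demonstrate that the
pipeline's logic is correct under controlled contrasts, not that any
particular accuracy transfers to real aerobiological slides.

## Problem sizes and numerical choices

The test suite and the reproduction script run the full path at desk
scale: 100 grains per class (300 single-grain stacks of 208 × 208 × 20
voxels at 0.16 µm/px), five-fold grouped cross-validation of
`tiny_test` for 30 epochs per fold, and three synthetic monitoring
samples of 112, 63 and 26 grains for the open-set application. These
sizes were chosen so a complete run stays in the minutes range on one
CPU while keeping ≥ 90 % pooled CCR attainable by the separable
presets.

Degenerate inputs are defined, not special-cased: constant images
binarise to an empty mask; an all-background sub-stack falls back to
the highest-contrast slices with a warning; a single-slice stack is an
error for the standard-deviation projection (the caller is pointed at
the focus fallback) and the identity for min/EDoF; a constant channel
normalises to zeros. Ties in the EDoF arg-max resolve to the lowest
slice index; region ordering is fixed by bounding-box origin; metric
zero-divisions return 0 with a flag.

## Known limitations

* Grains must be located automatically in clean fields; heavily
  cluttered tape regions rely on the debris filters and the unknown
  category rather than on instance segmentation.
* Deeply fused grain pairs (near-convex union) are accepted as single
  grains — resolvable only by a shape prior the detector deliberately
  does not impose (splitting touching grains is out of scope).
* The numpy network engine is single-threaded BLAS-bound and intended
  for desk-scale experiments, not for training at reference-library
  scale.
* The synthetic-to-real gap is unquantified by design; the package's
  claims are about pipeline correctness, determinism and the behaviour
  of the open-set threshold, not about field accuracy.
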