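# Methods

## Pipeline

The annotation pipeline has three stages.

**Gaze → fixations → attention areas.** A gaze stream is a per-frame list of
`(frame, t_ms, x, y, valid)` samples. Fixations are detected by dispersion
grouping: valid samples are scanned in order, and a sample within
`dispersion_radius` (default 15 px, half the mean apple diameter) of the
running centroid extends the current run; otherwise the run closes. Runs of
at least f_i = ⌊fps · duration/1000⌋ samples (floored, minimum 1; 6 frames
at 25 fps and 275 ms) become fixations, shorter runs are discarded as
saccades or noise. "Same fixation position" has no standard hard definition;
dispersion grouping is the usual identification-by-dispersion-threshold
practice, scaled here to the object size. Around each fixation centroid a
square attention area of `side` px (default 180, six apple diameters) is
cut; when the centered square would overflow the frame it is **translated**
back inside rather than shrunk, so the area A — and with it the superpixel
scale — is identical for every area. Fixations revisiting the same object
are kept separate; their masks union downstream anyway.

**Segmentation inside an area.** The area is partitioned into
N = round(A/S) SLIC superpixels (clamped to ≥ 2; S = 900 px, the area of an
average 30 px-diameter apple). Blueish superpixels are excluded by a
relational rule on mean 8-bit color — B > R + margin and B > G + margin,
margin 10 — and additionally when at least half of a superpixel's
*individual pixels* satisfy the same rule; the second clause catches
superpixels straddling the sky/canopy boundary, whose mean can look green
while half the pixels are sky. Absolute color cutoffs would be
dataset-dependent; the relational rule is not. The remaining superpixels
are clustered by K-means (K = 2, squared Euclidean, k-means++
initialization, 10 restarts, fixed seed) on mean (R, G, B, H, S) features
scaled to [0, 1] (H, S from HSV). The cluster with the smaller **total
pixel area** — not superpixel count, since the assumption is that
background occupies most of the *area* — is selected as the object; area
ties go to the cluster with higher mean saturation (fruit is saturated,
foliage shadow is not). Raw hue is used by default to stay close to the
plain (R,G,B,H,S) feature space; hue wraps at red, and a config flag
(`hue_wrap`) switches to a cos/sin encoding if objects of hue ≈ 0 ever
split across the wrap. Selected superpixels are mapped back to frame
coordinates; overlapping areas combine by logical OR.

**Scoring.** Dice and Jaccard compare the assembled mask with ground truth
per frame (both-empty pairs score 1, exactly-one-empty pairs 0; the
identity Dc = 2J/(1+J) holds per image, never for averaged values).
Counting extracts 8-connected components of both masks; each predicted
component is paired with the ground-truth component of maximum intersection
and counts as a true positive when the overlap fraction reaches the
threshold (default 0.75). The denominator of the overlap fraction is
configurable (`pred` — fraction of the predicted object explained by ground
truth — is the default and is echoed in every report, with `gt`, `min` and
`iou` available). The shift error is the mean Euclidean centroid distance
over pairs above the same threshold; centroids are unweighted pixel-mean
coordinates in the frame. True negatives are not well defined for object
detection; here each attention area containing neither ground-truth nor
predicted pixels counts one TN, and every report carries this definition
explicitly. Ground-truth objects with under half their pixels inside the
union of attention areas were never "gazed"; they are excluded from FN and
reported separately (`excluded_gt`). Group (tree-level) aggregates are
means ± sd of per-image values; the overall row averages group means.
Pooled PD/TNR over summed counts are also reported — per-image ratios have
tiny denominators (≈ 5 objects) and average badly.

## Synthetic scenes and gaze

The simulator renders what the pipeline assumes about field conditions:

- **Foliage** is a green color field sampled on a 16 px grid and bilinearly
  blended, overlaid with several hundred leaf-scale ellipses — color
  variation lives at *leaf* scale, below the superpixel size, so
  superpixel means stay homogeneous the way real averaged foliage does.
- **Illumination** (sun/shade) is a smooth 2×2 bilinear gain field in
  [0.8, 1.2]: nearly constant within one 180 px attention area but strongly
  varying across the 960×544 frame. This is the structural reason the
  method works locally and fails globally — whole-frame K = 2 splits on
  illumination instead of object color.
- **Wood** (branches, trunk) is drawn as thin dark elongated strokes plus a
  5% share of dark clutter ellipses; being sub-superpixel, it shades
  superpixel means rather than forming its own color population.
- **Apples** are shaded disks (radial luminance 0.72–1.0 plus a specular
  highlight, per-apple color perturbation around red/orange tones, radius ~
  N(15, 2) px), placed with a center-biased truncated normal
  (sd = 0.22 · min(w, h)) at least one radius inside the frame and
  non-touching. The center bias emulates egocentric framing — the wearer
  aims the camera at the tree being inspected — and is the premise behind
  the center-prior baseline. An optional sky band and blue label patch
  exercise the blue-removal stage; optional foreground leaves occlude up to
  a bounded fraction of an apple, and ground truth contains visible pixels
  only.
- **Gaze** visits every apple once in random order: round(fps·duration/1000)
  consecutive samples at the apple centroid + a constant per-stream
  calibration shift + N(0, jitter²) per-sample noise (defaults: 275 ± 25 ms,
  jitter 2 px), separated by scattered saccade samples. Samples are clamped
  to the frame. The calibration shift is the defining nuisance of
  head-mounted trackers; streams store it exactly, so tests can verify the
  geometry bound ‖shift‖ + radius ≤ side/2 ⇒ the gazed apple lies wholly
  inside its area. A screen-based stream variant runs at 60 Hz with ≤ 5 px
  shift and 1 px jitter.

The frame "stream" is a repeated still scene: annotation quality is scored
on selected frames, and camera motion plays no part in any scored
computation. What the simulator does **not** model: photometric noise of
real sensors, motion blur, self-similar background fruit, green apple
varieties (the segmentation assumes red-on-green contrast), perspective
variation within a tree, and eye-tracker validity dropouts. Passing the
synthetic suite therefore shows the pipeline's logic and geometry are
right and that the method behaves as expected *in the regime it assumes*
(color-contrasting objects on locally simple backgrounds); it does not
certify field performance.

## Numerical and design choices

- SLIC runs on CIELab (native scale) with compactness 20 and
  `min_size_factor` 0.25. Compactness 20 gives regular superpixels that
  average out leaf speckle yet still follow the strong fruit/foliage color
  edge; at lower compactness superpixels chase background texture and
  bleed across object boundaries, which costs both Dice and the 75%-overlap
  detection count. The minimum segment size (0.25 · A/N ≈ 225 px) is set
  between typical clutter fragments and the smallest plausible apple so
  connectivity enforcement cannot silently absorb small objects into a
  background superpixel.
- N = A/S is rounded to nearest and clamped to ≥ 2 (K-means needs two
  items). A constant-color patch cannot be partitioned meaningfully; it is
  flagged degenerate and yields an empty selection.
- Saliency (for the tracker-free baseline) is frequency-tuned color
  saliency: Euclidean Lab distance between the Gaussian-blurred image and
  its global mean color, normalized to [0, 1]; a constant image maps to
  zero. The map is thresholded at 2× its mean, components under 100 px are
  dropped, and each surviving component yields one fixed-size area at its
  centroid. The detector is deliberately simple and pluggable; the point of
  the baseline is that bottom-up saliency is attracted by *any* contrast
  (labels, bright sky edges), not by the task.
- The center prior uses a square area for uniformity with every other
  strategy, though a disk would arguably be the purist reading; the
  difference is the four corners of a 180 px square, ~21% of its area.
- Determinism: every stochastic component (scene, gaze, K-means) takes an
  explicit seed; corpus builders derive child seeds from one master seed.

## Problem sizes

The default experiment harness uses 20-scene corpora (5 apples per scene,
960×544, calibration shift uniform up to 40 px) for strategy comparison and
8 scenes at a fixed 40 px shift for the area-size sweep; these sizes give
stable Dice means for the gaze strategy while keeping a full run in the
minutes range on one CPU. Mean Dice of the fixed-area baselines
(center prior, full frame) has intrinsically high variance across corpora —
it hinges on how many apples happen to fall inside the one area and on
whether whole-frame clustering happens to land on the fruit — so their
values should be read as qualitative levels, not precise constants; the
ranking gaze ≫ center prior > full frame is stable.

## Known limitations

- K = 2 presumes exactly two local color populations; a third salient
  population inside an area (dense dark wood, sky mixes that survive blue
  removal) can steal the "smaller cluster". Real deployments with green
  fruit or low contrast need a different feature space or K.
- Touching apples merge into one predicted component (no post-hoc instance
  splitting), which costs detection counts at the 75% overlap threshold.
- The TNR depends entirely on the adopted TN definition; comparisons across
  tools are only meaningful with the definition attached.
- Fixation detection assumes a stationary scene; smooth pursuit on a moving
  target would be split or discarded by the dispersion rule.
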