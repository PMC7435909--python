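# gazelabel

Joint acquisition–annotation of orchard imagery with egocentric gaze.

Pixel-wise annotation is the cost bottleneck of supervised fruit detection:
manually outlining every apple in field images takes close to a minute per
frame. `gazelabel` implements the alternative: while the wearer of
head-mounted eye-tracking glasses *looks for* apples, the recorded gaze
stream is converted into annotations automatically. Fixations (≥ f_i
consecutive gaze samples resting within a small dispersion radius, with
f_i = ⌊Fps · f_d⌋, e.g. 6 frames at 25 fps and f_d = 275 ms) become
fixed-size square **attention areas**; inside each area a non-supervised
segmentation extracts the gazed object:

1. SLIC superpixels, their number set by N = A / S where A is the area size
   in pixels and S ≈ 900 px the size of an average apple, so one superpixel
   stays about one apple regardless of the area size;
2. removal of blueish superpixels (sky, blue tree labels) by relational
   color thresholding;
3. K-means with K = 2 on per-superpixel mean (R, G, B, H, S) features; the
   cluster with the smaller total pixel area is taken as the apples, since
   background dominates the area.

Annotation quality is scored at three levels: segmentation via Dice
Dc = 2|X∩Y| / (|X|+|Y|) and Jaccard J = |X∩Y| / |X∪Y|; counting via
object-level matching at 75% overlap, giving the probability of good
detection PD = TP/(TP+FN) and the true-negative rate TNR = TN/(TN+FP);
and localization via the mean centroid distance d̄ between matched
predicted and ground-truth objects (the shift error).

The package also implements the tracker-free baselines under the same
contract — full frame, egocentric center prior, bottom-up color saliency —
and a synthetic orchard/gaze simulator that renders cluttered canopy scenes
with exact ground truth and eye-tracker-like gaze streams (constant
per-stream calibration shift plus per-sample jitter), so the whole pipeline
is testable without field recordings.

## Worked example

```python
from gazelabel import make_corpus, compare_strategies

corpus = make_corpus(n_scenes=20, seed=7, shift_max=40.0)   # 5 apples/scene
reports = compare_strategies(corpus, ("gaze", "center_prior", "full_frame"))
for name, rep in reports.items():
    print(f"{name:13s} dice={rep.overall['dice_mean']:.3f}"
          f"  PD={rep.pooled['pd']:.2f}"
          f"  shift={rep.pooled['shift_error_mean']:.2f} px")
```

prints

```
gaze          dice=0.928  PD=0.91  shift=0.34 px
center_prior  dice=0.462  PD=0.89  shift=1.02 px
full_frame    dice=0.271  PD=0.28  shift=0.07 px
```

Despite calibration shifts of up to 40 px, gaze-driven attention areas
recover the apples almost perfectly (Dice 0.93, 91% of apples detected,
sub-pixel localization of detected objects). The fixed center prior only
catches the apples that happen to sit centrally, and whole-frame
clustering collapses in the cluttered canopy — the segmentation works
*because* the attention area keeps the local scene simple. Note PD and the
shift error are conditioned on detection: the full-frame strategy localizes
the few objects it finds well while missing most of them.

The same pipeline is available from the shell:

```sh
gazelabel simulate --n-scenes 5 --seed 3 --out corpus/
gazelabel annotate --input corpus/ --strategy gaze --out pred/
gazelabel evaluate --pred pred/ --gt corpus/ --out report/
gazelabel sweep-radius --input corpus/ --sides 30,90,180,360,full --out sweep/
```

`annotate` writes one mask, contour overlay and fixation heatmap per scene;
`evaluate` writes JSON/CSV metric reports; `sweep-radius` traces mean Dice
against the attention-area side, which peaks at an intermediate size
(too small misses the object because of the calibration shift, too large
re-admits background complexity).

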