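# Methods

## Problem and model

A rapeseed seedling's unfolded-leaf count is a staged function of days
after planting (DAP), so a plot's plant count `y` is, at a fixed date,
approximately proportional to its canopy leaf count `x`:
`y = a·x + b` with `a ≈ 1 / (mean leaves per plant)`. The pipeline
therefore (i) detects individual canopy leaves in a high-resolution RGB
plot image with a patch classifier, (ii) corrects the detection count for
*overcounting* — one large leaf producing several detection points —
and (iii) converts the corrected leaf count into a stand count with a
per-date linear model fitted by leave-one-out cross-validation (LOOCV) on
training plots whose leaf outlines and plant counts are known.

Assumptions: leaves are the unit of detection (plants are never segmented
individually); every canopy leaf is outlined in the training annotation
even where leaves overlap; plant counts per plot are exact; the leaf/plant
ratio is stable within a date across plots of the same field.

## Patch classifier

Architecture (fixed): input `s×s×3` RGB in [0, 1] → 5×5 valid convolution,
12 feature maps, ReLU → 2×2 max-pool → 5×5 valid convolution, 12 maps,
ReLU → 2×2 max-pool → fully connected 64 units, ReLU → 3-way softmax
(leaf, weed, soil). Patch sizes 16, 24, 32, 40, 48 px. `s` must be a
multiple of 4 (and ≥ 16) so the two conv/pool stages tile exactly; all the
standard sizes qualify.

Choices the architecture description leaves open, fixed here:

- **FC width 64** — the smallest round width that trains stably at all
  five patch sizes.
- **Optimizer** — SGD with momentum 0.9 at learning rate 5e-4 is the
  library default; Adam (same rate) is selectable and is used by the
  desk-scale run profile, where the reduced sample counts make plain SGD
  needlessly slow to converge. A learning-rate sweep utility covers the
  grid 0.0001–0.0014 (step 0.0001).
- **Patch label = center-pixel class**; patches lie fully inside the
  image; per-class sampling is without replacement.
- **No mean subtraction / augmentation** — inputs are raw RGB scaled to
  [0, 1], keeping index-consistent colors interpretable.
- **Initialization** — He-normal weights from a seeded generator; training
  order reshuffled per epoch from the same seed, so loss trajectories are
  bit-reproducible.

Heat-map inference is *valid*-mode: value (i, j) is the leaf probability
of the patch with top-left corner (i, j), shape `(H−s+1, W−s+1)`, and the
stored offset `(s/2, s/2)` maps heat indices to plot coordinates of patch
centers. No border padding is used, so no probabilities are fabricated
outside the valid region. The dense implementation replaces patchwise
evaluation by full-image convolutions with stride-1 max-pooling and
dilated reads (dilation 2 after the first pool, 4 after the second): it is
numerically identical to the sliding window (tested to 1e-5; in practice
exact). An optional stride > 1 evaluates a subsampled grid and upsamples
nearest-neighbor.

## Leaf localization

Grayscale dilation with a 5×5 square window (reflected padding, so border
maxima remain detectable); a pixel is a detection candidate iff it keeps
its value under dilation and lies at or above the threshold. Thresholds
are swept over 0.50–1.00 in 0.01 steps; because the dilation-equality mask
is threshold-independent, detection counts are provably non-increasing in
the threshold. Tie/plateau handling: 8-connected components of retained
equal-valued pixels are merged to one point at the rounded centroid — a
flat plateau is one leaf candidate, not several. No distance-based merging
is applied beyond the dilation neighborhood: leaf boundaries are too
indistinct and leaf sizes too varied for a fixed merge tolerance.

## Matching and overcounting calibration

Detections are assigned to leaf-outline masks by point-in-polygon
containment (boundary counts as inside). A point inside several
overlapping masks is assigned to exactly one — the containing mask with
the nearest centroid — so the detection partition
`N = TP + FP + Σ(C_i − 1)` is exact. A mask with at least one point is a
TP; an empty mask is an FN; a point in no mask is an FP. The overcounting
rate `R_oc = Σ_{C_i>1}(C_i − 1)/N` is stored as a fraction and reported in
percent. Calibrated precision `TP/((1−R_oc)·N)`, recall `TP/M`, and their
harmonic mean F are the detection scores; the *uncalibrated* variant
counts every in-mask point (surplus included) as a true detection, which
is why it is systematically inflated. `R_oc` is undefined at `N = 0` and
raises rather than returning a sentinel. Best-threshold selection returns
the smallest threshold attaining the maximum F (ties go to the lower
threshold); by default the threshold is selected per test plot and scores
are averaged afterwards, with a pooled mode (one threshold maximizing the
mean F) selectable.

## LOOCV counting model

With `n` training plots (default 6), each fold fits a simple linear
regression on `n−1` plots and predicts the held-out plot. The final
coefficients are the **arithmetic mean of the fold coefficients**, not a
refit on all data — a deliberate departure from conventional LOOCV whose
diagnostics (RMSE, MAE, R²) are still computed purely from held-out
predictions. Fold slopes carry standard t-test p-values (reported, never
used for gating). Degenerate folds (zero leaf-count variance) raise. The
leaf count fed to a fitted model is the overcounting-calibrated count at
the best-F threshold, `(1−R_oc)·N`, measured from masks when available;
the fitted `R_oc`-vs-DAP trend can substitute when masks are absent.
Reported plant estimates are rounded half-away-from-zero; internal
arithmetic is unrounded. Aggregation mirrors the field-study table
layout: per-(date, patch-size) totals over the test plots, per-date means
of those totals, mean accuracy `100·mean/truth` computed from the
*unrounded* mean, RMSE over plots, and `rRMSE = 100·RMSE/ȳ` with `ȳ` the
mean per-plot truth.

## Synthetic scenes

The generator emulates the statistical structure the analysis relies on,
with exact ground truth:

- **Staging** — leaves per plant (1–3 before 40 DAP, 3–4 at 40–50, 4–6 at
  50–60, 7–9 after 60); leaf major axis grows roughly linearly in DAP
  (`0.14·DAP − 0.8` cm, ~6.6 cm at 53 DAP, late-stage blades of a few tens
  of cm²); overlap intensity rises with DAP and shortens the petiole
  offset, closing the canopy.
- **Geometry** — rosettes of slightly tear-dropped ellipses at
  golden-angle spacing with jitter; plants in rows (20 cm spacing
  default); per-plant layout state is persistent across dates so a
  time series has identical plant positions and non-decreasing leaf
  counts and sizes.
- **Color** — leaf and weed greens are drawn so ExG−ExR > 0 holds by
  construction; soil browns satisfy NGRDI < 0; weeds are yellower-green
  and at most ~40% of the stage's mean leaf area (a deliberate size/hue
  cue). Gaussian pixel noise (σ ≈ 2.5 DN) plus low-frequency soil texture.
- **Scale** — desk default 2 m × 1 m plots at 0.25 cm/px (800×400 px),
  ~21 plants/m², weed pressure 12 blobs/m²; the emulated field geometry
  (9.5 m × 2 m at 0.18 cm/px, 8 rows) is a config switch. The desk
  resolution is chosen so the smallest patch (16 px = 4 cm) is *smaller*
  than a 53-DAP leaf blade — the regime the method requires; at coarser
  resolution the heat map saturates over whole rosettes and per-leaf peaks
  vanish.

Not emulated: radiometric/atmospheric effects, perspective and mosaicking
artifacts, shadows, leaf venation/texture detail, wind blur. Passing tests
therefore demonstrate the pipeline's internal correctness and its behavior
under controlled overlap/noise — not performance on real UAV imagery.

## Problem sizes and determinism

The test suite trains patch-16 networks on a 1 m × 0.5 m fixture pair
(~1 s each) and the end-to-end check runs the default desk profile: eight
plots, 2000/1000/1000 patches (the 2:1:1 leaf:weed:soil ratio), 25 Adam
epochs, the full 51-threshold sweep — about 15 s on one CPU. Every random
draw flows from named `SeedSequence` children of the run seed (plot
layouts, patch sampling, weight init, shuffling), so reruns are
byte-identical including the summary JSON; wall-clock timings are reported
in a separate file for that reason.

## Known limitations

- Heavy canopy closure (≥ 7-leaf stage) merges heat-map peaks; recall
  drops and the calibrated count undercounts — the same failure mode the
  staging analysis attributes to late dates.
- The matcher's nearest-centroid rule for points in overlapping masks is a
  convention; alternative assignments change `C_i` bookkeeping only in
  heavily overlapped clusters.
- The numpy CNN is single-threaded BLAS-bound; field-scale images and
  20000/10000/10000 sample counts are supported but slow (minutes to tens
  of minutes per grid cell).
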