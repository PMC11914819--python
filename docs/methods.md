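# Methods

This note documents the models and procedures implemented in `wsifusion`,
the assumptions behind them, the parameters that matter, and the choices
made where the design was genuinely open.

## Pyramid geometry and aligned patch triples

A pyramidal slide is an ordered list of RGB rasters with strictly
increasing integer downsample factors, `downsamples[0] = 1`, and level
dimensions that divide the level-0 dimensions exactly. The default ladder
is (1, 4, 16), i.e. nominal magnifications 40×, 10×, 2.5×. A downsample
ratio of 4 between adjacent levels is used throughout, so an 8192-px
level-0 region corresponds to 2048 px at level 1 and 512 px at level 2.

Coordinate mapping between levels multiplies by the integer ratio when
moving to a finer level and floor-divides when coarsening; the fine →
coarse → fine round trip therefore moves a point by less than one ratio per
axis, which the tests check on random points for every level pair.

Patch-triple extraction is driven from the **coarsest** level: its raster
is tiled at a configurable stride, each tile centre is mapped up the
pyramid, and a window of the same pixel size is centred on the mapped point
at every finer level. Windows are 0-based, half-open, x rightward, y
downward. Triples whose centred windows would cross a raster boundary are
dropped rather than padded — padding would fabricate tissue at the edge.
Driving from the coarsest level guarantees that every emitted triple has
full three-level coverage. The default stride equals the patch size
(non-overlapping tiles); the desk-scale study profile uses stride =
patch/4 to enlarge the patch pool.

An adapter protocol (`SlideReader`) mirrors the geometry surface
(per-level dimensions, downsamples, region reads) so a real pyramidal
slide reader such as OpenSlide can stand behind the same routines;
bit-exactness across readers is not assumed anywhere.

## Patch filtering

There is no canonical formula for "contains histological content", so the
filter is deliberately simple and fully configurable:

* **tissue fraction** — Rec.601 luma, a global threshold (Otsu by default,
  patch-wise), and the fraction of pixels *darker* than the threshold.
  A contrast-free patch has no meaningful threshold and is defined to have
  fraction 0 (no contrast → no tissue). The keep cutoff is 0.25.
* **blood rule** — a patch with mean(R)/mean(G) ≥ 1.8 is dropped as
  blood; this is checked before the tissue rule because a saturated red
  pool can be nearly contrast-free and would otherwise be mislabelled
  "background". A zero green channel maps to an infinite ratio.
* **triple coupling** — the level-0 (finest) window carries the most
  reliable content signal, so its verdict decides for the whole triple.
* **circular mask** — pixels outside the inscribed circle (centre (s/2,
  s/2), radius s/2, pixel-centre convention) are set to the background
  fill (white). The mask is idempotent, commutes with 90° rotations, and
  removes the patch corners so that downstream features see a
  rotation-neutral field of view. It is applied after filtering and before
  feature extraction when enabled (the default).

## Per-level classification

The classifier contract is minimal: `predict_proba(patch) → ProbVector`
(two non-negative probabilities summing to 1). Fusion, regional decisions
and the statistics accept any object satisfying it; the tests exercise a
constant mock and a ground-truth oracle through the same code paths. Three
independent models are trained, one per pyramid level.

The built-in reference classifier uses a 26-dimensional descriptor:
a 16-bin normalised luma histogram, an 8-bin magnitude-weighted
gradient-orientation histogram over [0, π), and luma mean and standard
deviation scaled by 255. On top sits a two-class multinomial logistic
model (2 × 27 weights including bias) trained by full-batch gradient
descent from a zero initialisation: full-batch updates make the fit
independent of example order, zero epochs leave the uniform predictor, and
the default step size 1.0 stays below the 2/L smoothness bound for
features bounded in [0, 1], so the training loss is non-increasing — a
property the tests assert. Defaults are 5000 epochs; the per-epoch cost at
desk scale is microseconds, and shorter budgets visibly underfit the
orientation features. The reference classifier deliberately replaces
large fine-tuned transformer backbones: it keeps the framework desk-scale
while preserving every surrounding computation, and a heavyweight backend
can be attached through the contract without touching the pipeline.

## Weighted majority voting

The fused patch decision is `argmax_c Σ_i w_i · P_i(c | x)` with
non-negative per-level weights summing to one. Two derivations are
provided:

* **normalised accuracies** — `w_i = a_i / Σ_j a_j`; scale-invariant, so
  percentages and fractions give identical weights;
* **grid search** — exhaustive scan of the simplex grid: w0 and w1 range
  over 0…1 in steps of 0.001 (combinations with w0 + w1 > 1 skipped),
  w2 = 1 − w0 − w1. Accuracy is the selection criterion. Arithmetic is
  carried in integer grid units, so a step of 0.001 suffers no
  floating-point drift.

Tie rules are fixed and documented: exact argmax ties go to MEN
(configurable), and grid-score ties go to the first point encountered
scanning w0 ascending then w1 ascending. Because the simplex corners
(1,0,0), (0,1,0), (0,0,1) are grid points, the searched optimum can never
fall below any single level on the pool it was searched on. The pipeline
uses the grid search as the selection procedure; by default it searches
the validation pool, with an `all`-patches option matching the procedure
the normalised-accuracy weights are defined on (the desk-scale synthetic
profile uses `all`; in k-fold mode the pool is the pooled out-of-fold
predictions either way).

## Regional decisions, coloring and confidence

For visualisation, a slide is divided into square display regions
(8192 level-0 px by default). The level-local footprint of a region is
tiled into display tiles (256 px by default), every tile is classified by
that level's backend, probability pairs are averaged and renormalised per
level, and the three level pairs are combined with the fusion weights; the
region is coloured by the argmax (blue = MEN, green = SFT) at configurable
opacity. All tiles in a region are classified — no filtering — matching
the goal of colouring the entire slide. The per-slide confidence score is
the mean over regions of the fraction of tiles (pooled across levels
within a region) whose call matches the slide's ground-truth label,
expressed as a percentage.

## Slide-level beta model and threshold analysis

For each slide, the fraction of its fused patch decisions called MEN,
p(MEN), summarises the slide. Per ground-truth class these fractions are
modelled as a beta distribution. The fit is maximum likelihood: values
clamped to [1e-4, 1 − 1e-4], method-of-moments initialisation, then a
damped Newton iteration on the digamma score equations, stopping when the
parameter step falls below 1e-8. A sample that is constant after clamping
is rejected as degenerate. The tests check parameter recovery on
simulated data, symmetry on mirrored samples, dominance over the moment
initialiser, and agreement with an independent constrained fit.

The pipeline fits the group betas on **Jeffreys-smoothed** fractions,
(n_MEN + 0.5)/(n + 1), rather than raw ones: a classifier that is perfect
on some group produces raw fractions exactly 0 or 1, which carry no
likelihood under any beta density, while the half-count correction — the
same smoothing the slide bootstrap uses for its Beta(n_MEN + 0.5,
n_SFT + 0.5) draws — keeps the suite well-defined and is negligible when
patch counts are large.

From the two fitted distributions, theoretical curves over the decision
threshold t are SEN(t) = 1 − F_MEN(t), SPC(t) = F_SFT(t) (F the beta
CDFs), PRC(t) = SEN·π / (SEN·π + (1 − SPC)(1 − π)) with class prior π =
0.5 (balanced cohorts; configurable), and the Youden index J = SEN + SPC −
1. The operating point is the grid argmax of J over t = 0.001…0.999 in
steps of 0.001; slides are called MEN when their smoothed fraction meets
the threshold.

## Bootstrap and interval procedures

* **beta-parameter CIs** — each bootstrap sample resamples slides with
  replacement and draws p(MEN) ~ Beta(n_MEN + 0.5, n_SFT + 0.5) per
  selected slide (the Jeffreys posterior of that slide's patch counts),
  then refits the MLE. 95% limits are basic-bootstrap reflections
  (2θ̂ − q_{0.975}, 2θ̂ − q_{0.025}) from B = 1000 samples; degenerate
  refits are skipped and counted.
* **superiority test** — per bootstrap sample, one slide per class is
  drawn at random; its per-patch decision tuples (level-0 call, weighted
  aggregate call) are resampled with replacement at the original size; the
  false-positive rate on the SFT slide and the false-negative rate on the
  MEN slide are recorded for both deciders. The one-sided add-one p-value
  counts samples where the aggregate fails to be strictly better:
  p = (1 + #{aggregate ≥ level 0}) / (B + 1), so with B = 999 the
  attainable floor is exactly 1/1000. The add-one construction was chosen
  because it is the standard positively-biased resampling p-value; the
  floor behaviour is verified by direct simulation in the tests.
* **metric CIs** — SEN/SPC/PRC are treated as Bernoulli probabilities
  with exact Clopper–Pearson intervals via beta quantiles.

Reported percentages are rounded half away from zero to two decimals;
metrics with a zero denominator are flagged undefined rather than set
to 0. Sensitivity is TP/(TP+FN); "ROC approximated" is implemented
literally as (SEN+PRC)/2, its definition in the source framework, despite
the unconventional name.

## Synthetic slides: what they emulate, and what they do not

The generator renders a deliberate cartoon of an H&E slide scan:

* flat near-white background (≥ 240 per channel) — a blank scanner field
  has no contrast, so pure-background patches binarise as tissue-free and
  are filtered; the smooth tissue outline is a thresholded coarse Gaussian
  field covering a configurable fraction (default 0.6) of the slide;
* pink (eosin-like) tissue with dark (hematoxylin-like) marks covering
  ~30% of the tissue: isotropic blobs (Gaussian scale 3 px) for MEN,
  oriented streaks (scales 1.5 × 16 px, orientation drawn per slide) for
  SFT. The gradient-orientation resultant separates the two geometries
  without overlap, which the tests check on 50+ patches per class;
* class-dependent mark intensity: MEN marks are darker (luma ≈ 73) than
  the paler spindled SFT marks (luma ≈ 110). With the streak orientation
  random per slide, the orientation histogram alone is not *linearly*
  separable, so this intensity contrast is what makes the classes
  separable by the linear reference classifier at every pyramid level —
  a stated requirement of the generator;
* stain-intensity variability on the marks: a smooth within-slide field
  (SD 8 luma) plus a per-slide offset (SD 9 luma). The field makes patch
  errors cluster spatially; the offset moves whole slides toward or away
  from the class boundary, so the per-slide error rate itself varies —
  exactly the between-slide spread the beta model of p(MEN) is meant to
  capture. Together they hold per-level held-out accuracy around 95–99%
  while keeping the fraction distributions non-degenerate;
* blood-like artifacts: saturated-red ellipses clipped to the tissue
  region, exercising the blood rule;
* pyramids built by block mean-pooling with half-away-from-zero rounding,
  conserving mean intensity across levels to within 0.5 per channel
  (subsampling would not preserve the statistics the filter relies on);
* per-slide seeds derived from (cohort seed, slide index) through
  `SeedSequence`, so cohorts are reproducible and order-independent.

Not emulated: nuclear morphology, stain deconvolution behaviour,
scanner-specific compression, pen marks, folds, or cover-slip artifacts.
Passing tests therefore demonstrate that the *framework arithmetic* is
correct and that the pipeline behaves sensibly on separable-but-noisy
multi-resolution textures — not that any particular accuracy would
transfer to clinical slides.

## Study conditions and problem sizes

The desk-scale synthetic profile (`synthetic_study_config`) runs 2048-px
slides (pyramid 2048/512/128), 64-px patches at stride 16, 2048-px display
regions of 32-px tiles, and 40-slide cohorts (20 per class) — the full
geometry at 1/8 linear scale, chosen so a complete study (generation,
extraction, training, fusion, statistics) finishes in minutes on one CPU.
`ExperimentConfig` keeps the full-scale defaults (512-px patches, 8192-px
regions, 256-px tiles) for real pyramidal slides. Held-out evaluation
uses either a stratified train/val/test split (largest-remainder
apportioning per class) or stratified k-fold with pooled out-of-fold
predictions; the beta/bootstrap suite is most informative under k-fold,
where every patch prediction comes from a model that never saw the slide.

## Known limitations

* The reference classifier is linear on hand-crafted features; it is a
  stand-in for representation-learning backends, not a competitor.
* The grid search optimises plain accuracy; class-weighted criteria would
  need a different objective.
* The beta model treats patch decisions within a slide as exchangeable;
  spatial correlation of errors (which the synthetic stain field
  deliberately induces) makes the effective per-slide sample size smaller
  than the patch count, so the fitted concentrations are optimistic.
* Regional coloring classifies display tiles without filtering, so
  background-dominated regions dilute the confidence score of slides with
  sparse tissue.
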