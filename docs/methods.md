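# Methods

This note documents the models, parameter choices and numerical conventions
behind `stripscan`, and what the synthetic study conditions do and do not
show about real assay data.

## The texture operator

A patch is a 128-row × 32-column gray grid (rows = strip height, columns =
strip axis).  After optional RGB→gray conversion (ITU-R 601 luma weights
0.2989/0.5870/0.1140), the patch is quantised to `Ng = 64` levels.  The
default maps the patch's own `[gmin, gmax]` linearly onto levels 0…63 with
round-to-nearest; a `fixed_0_255` mode keeps absolute intensities
comparable across patches.  Per-image quantisation makes features largely
invariant to global gain/offset changes — the property that motivates a
texture readout in the first place — at the cost of discarding absolute
intensity.

Co-occurrence matrices are counted for ordered horizontal pairs
`(g[r,c], g[r,c+d])`, one matrix per offset `d = 1…25`.  The offset runs
along the 32-column strip axis, so `d = 25` still leaves 7 pairs per row.
Counts are *not* symmetrised by default (the symmetric variant is a flag).
Each offset's matrix is normalised to sum 1 **before** averaging, giving
every spatial scale equal weight; averaging raw counts instead (available
via `normalise_first=False`) would weight offset `d` by its pair count
`rows × (cols − d)`, overweighting short ranges.  The average is a proper
probability matrix: entries ≥ 0, total 1 (asserted to 1e-12).

## The 22 features

Gray-level indices run 1…Ng, so the sum distribution `pX+Y` lives on
k = 2…2Ng and the absolute-difference distribution `pX−Y` on k = 0…Ng−1.
All logarithms are base 2 with `eps = 2⁻⁵²` added inside each log to guard
empty cells; correlation returns 0 when a marginal standard deviation
vanishes.  With those two guards every feature is finite for any valid
input (property-tested).

Conventions worth recording, since the literature varies:

- `indnc` defaults to the plain form Σ p/(1+(i−j)²) (`strict_printed_formulas`);
  the Ng-normalised variant Σ p/(1+|i−j|/Ng) is a flag.  `idmnc` is always
  Σ p/(1+(i−j)²/Ng²).
- `svarh` (sum variance) uses the sum-entropy-centred form
  Σ (k − senth)² pX+Y(k), the convention of the classical feature-set
  implementations; `dvarh` is the variance of `pX−Y` about its own mean.
- `sosvh` is the variance about the row-marginal mean Σ (i − μx)² p(i,j).
- `savgh` is the sum average Σ k·pX+Y(k).
- Difference entropy is computed over the true support k = 0…Ng−1 of
  `pX−Y`.
- Cluster shade is the cubic moment of (i+j−μx−μy), cluster prominence the
  quartic.

Every feature is verified against an independent, deliberately
unvectorised double-loop implementation on random matrices to 1e-10.

## MRMR

Greedy forward selection with the MI-difference (MID) objective: the first
pick maximises I(f; y); each later pick maximises
I(f; y) − mean_{s∈selected} I(f; s).  Features are discretised into 16
equal-frequency bins via empirical quantiles, which makes the ranking
invariant to strictly monotone transforms; the class label is used as-is.
Ties break toward the earlier column, so rankings are bit-reproducible.
The quotient criterion (MIQ) is a config option.  Selection runs on the
training split only, to keep the held-out test samples out of every fitted
component; k = 9 features are kept by default.

## The tabular CNN

Each 22-feature row is treated as a 22×1 single-channel image.  The stack
is conv(3×3, same)–batchnorm–ReLU three times with filter counts
(8, 16, 32), max-pooling 2×2 stride 2 with asymmetric padding
(top, bottom, left, right) = (0, 1, 0, 1) after the first two blocks, then
a fully connected softmax layer with one unit per class (8).  The feature
axis evolves 22 → 11 → 6 under
`out = floor((size + pad_sum − window)/stride) + 1`; the singleton width
never changes, so the penultimate representation has 6 × 1 × 32 = 192
values.  Pooling is placed after blocks 1 and 2 (not 3) so exactly two
halvings occur between convolutions.

Training: cross-entropy with SGD momentum 0.9, learning rate 0.01, batch
size 32, 10 epochs, shuffling before each epoch, 15 % stratified
validation monitoring, z-scoring of inputs with training statistics
(for optimiser stability across feature scales).  The network is
implemented directly in numpy (vectorised batch forward/backward passes);
at this input size it trains in seconds on one CPU and is exactly
reproducible for a fixed seed.  After training it serves as a feature
extractor: `transform` returns the flattened activations feeding the
fully connected layer, the package's definition of "CNN features".

## Classifier battery and metrics

Eight classifiers, each behind a train-statistics `StandardScaler`,
hyperparameters fixed once: RBF SVM (C = 1, scale-gamma, one-vs-one);
MLPs with one hidden layer of 100 ("wide") or 25 ("medium") units,
max 1000 iterations; LDA with pooled covariance; bagging of 30 full
decision trees; k-NN with k = 10 (Euclidean); AdaBoost of 30 depth-3
trees; Gaussian naive Bayes.  All stochastic members are seeded.

The split is stratified 70/15/15 per class (train/val rounded, test takes
the remainder: 3200 balanced patches → 2240/480/480).  The validation
fraction is reserved for the CNN's epoch monitoring; classical members
train on the 70 % alone, so all rows of the summary are comparable on the
identical 15 % test set.

Metrics pool the per-class one-vs-rest TP/FP/FN/TN counts over all K
classes (micro averaging) before forming each ratio.  Two identities
follow and are property-tested: micro sensitivity ≡ accuracy (both equal
trace/total), and pooled specificity ≡ 1 − (1 − accuracy)/(K − 1), because
each error contributes one false positive against K − 1 true-negative
opportunities.  Macro averaging is not used.

## The synthetic study conditions

The generator emulates a reader frame (700×145 px, 8-bit, dark lines on a
light membrane) with:

- membrane grain: i.i.d. Gaussian noise, SD 6 gray levels;
- illumination: a linear ramp of amplitude 8 along the strip with random
  direction, plus per-image brightness jitter (SD 2);
- a test line (super-Gaussian band profile, width 24 px) whose darkness
  follows a strictly increasing depth map (18 → 74 gray levels over the
  eight labels);
- a control line (width 34 px — wider, as control lines are commonly
  printed, which also lets a patch betray which line it came from) whose
  darkness decays geometrically with concentration rank,
  72 × 0.80^rank, modelling first-order conjugate depletion: analyte
  captured at the test line consumes gold conjugate before it reaches the
  control zone;
- line texture from two components whose parameters follow *geometric*
  ladders in the concentration rank (ratio 1.5 per rank — the labels are
  log-spaced, and a constant adjacent-rank ratio keeps neighbouring classes
  equally distinguishable across the range): spatially correlated Gaussian
  speckle (correlation length 1.5 px) and discrete dark "aggregate" dots
  whose areal density and blob size grow with bound conjugate.  Test-line
  texture strengthens with rank; control-line texture weakens (depletion).
  Dot density and blob size survive per-image range normalisation, which is
  what lets texture features — not merely intensity — carry the class
  signal.

A `null_params()` configuration flattens the depth map, disables depletion
and removes all texture ladders; per-label image distributions are then
exchangeable and the whole pipeline must score at chance (1/8), which the
acceptance suite checks against the 95 % binomial band.

What passing on these conditions shows: that every stage is implemented
coherently end to end — segmentation finds the lines it should, patches
carry their labels, the texture operator and features transmit a
texture-coded signal, and the classifiers recover it at the accuracy level
the method targets.  What it does not show: performance on real reader
images, whose noise spectra, line morphologies and inter-assay variation
the generator does not claim to reproduce; no appearance statistics of the
original laboratory dataset were available to calibrate against.

## Problem sizes and numerical notes

- Default study scale: 8 labels × 100 images → 3200 patches; the full
  pipeline (generation to battery) runs in roughly a minute on one CPU.
  The package-level tests use smaller configurations (1–4 images per label)
  except the acceptance suite, which runs the full scale once.
- Resizing uses Pillow's box filter on float32 images: true area averaging
  on downscale, constants preserved to float precision; upscaling is
  refused unless explicitly allowed.
- Otsu thresholding operates per half; component ties break toward the
  leftmost bounding box.
- Patch placement is deterministic (centroid ± 8 columns, clamped to
  bounds) rather than manual, so expansion is exactly reproducible.
- A single master seed fans out to per-stage seeds through a seed sequence;
  changing the master seed changes realisations but never shapes or
  schemas.

## Known limitations

- The generator's realism is structural, not photometric; absolute feature
  values are not comparable to any real reader.
- The per-patch classification task treats the two control-line patches of
  an image as full-information samples; that holds here because depletion
  encodes concentration in the control line, and held on the original
  study's data, but would fail for assay chemistries whose control line is
  truly concentration-independent.
- Only horizontal co-occurrence is implemented (the strip axis); multi-
  direction GLCMs, run-length and LBP textures are out of scope.
- MRMR uses simple binned MI estimates; no bias correction for small
  samples.
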