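# Methods

## Model

The classifier is a four-stage bottleneck residual network with a
Convolutional Block Attention Module (CBAM) after each stage output.  Every
bottleneck block is 1×1 reduce → 3×3 → 1×1 expand, each convolution followed
by batch normalization and ReLU, with an identity shortcut (1×1 projection
when shape changes).  The `resnet50` variant uses blocks [3, 4, 6, 3] and
stage widths [256, 512, 1024, 2048] after a 7×7/stride-2 stem with 3×3/2
max-pooling; the `tiny` variant keeps identical wiring at widths
[16, 32, 64, 128] with one block per stage and an 8-channel stem.  At
224-pixel input the final stage map is 2048×7×7, so the flattened CBAM
feature is 100 352-dimensional and the pooled GAP⊕GMP descriptor is
4096-dimensional; at 64-pixel input the tiny variant ends at 128×2×2.

CBAM refines a map `F` sequentially: the channel mask is
`σ(MLP(GAP(F)) + MLP(GMP(F)))` with one shared hidden ReLU layer of width
C/r (no biases; r = 16 for `resnet50`, 4 for `tiny`), and the spatial mask is
`σ(conv7×7([mean_c; max_c]))` with padding 3 and a scalar bias.  Both masks
lie strictly in (0, 1) and can only attenuate.

The head concatenates global average and max pooling of the final refined
map, applies 1-D batch norm, dropout p = 0.5, an affine layer and softmax.
Prediction takes the argmax, breaking ties toward the lower class index.

## Training

Two stages under Adam (β₁ = 0.9, β₂ = 0.999), batch 16, loss
`L = mean CE + λ‖θ‖²` with λ = 1e-4 applied to the actively trained
parameters (implemented as a 2λθ gradient term; the reported loss adds the
penalty explicitly and is verified against an independent evaluation of the
formula to 1e-6).  Stage 1 freezes the backbone — its parameters are excluded
from the optimizer and remain bit-identical — and trains attention + head at
1e-3; stage 2 fine-tunes everything.  The stage-2 defaults (backbone 1e-5,
attention/head 1e-4) are the published fine-tuning rates and presume a
pretrained backbone that only needs gentle adaptation.  The desk-scale
end-to-end harness (`pipeline.run_end_to_end`) trains from random
initialization, where those rates cannot move the backbone meaningfully
within a few epochs; it therefore passes an explicit from-scratch profile of
1e-3 for all groups.  Both profiles run through the same `TrainConfig`
surface.  Splits are stratified 70/15/15, and all randomness (initialization,
shuffling, dropout) derives from one integer seed; training is bit-reproducible.

Three initialization choices matter for short schedules and are this
package's own conventions:

* **Neutral-start attention.**  CBAM output layers (the second MLP matrix and
  the 7×7 kernel) start at zero, so both masks begin at exactly 0.5 and
  attention is learned rather than imposed — the same idea as
  zero-initializing the last normalization layer of a residual branch.
  Randomly initialized masks scramble an untrained backbone's signal and
  measurably degrade downstream feature quality.
* **Near-zero classifier.**  The final affine weights are scaled by 0.05 at
  initialization so the initial loss starts at ≈ ln C.
* **Batch-norm momentum 0.3** (on the running-statistics update), so
  inference-mode statistics converge to training behavior within roughly two
  desk-scale epochs.

## Deep feature engineering

Features are extracted in inference mode (dropout off, batch norm on running
statistics) at six sites: flattened final CBAM map (channel-major), GAP, GMP,
their concatenation, the post-batch-norm "pre-final" descriptor, and the
pooled pre-CBAM final-stage output (`backbone`).  Extraction is deterministic
and idempotent.

Selection reduces D features to k = ⌈D/8⌉ (the 8:1 ratio used throughout):

* **PCA** — mean-centered projection onto the top-k covariance eigenvectors
  (full SVD solver, deterministic).
* **Chi-square** — features min-max scaled to [0, 1]; score_j =
  Σ_c (O_jc − E_jc)²/E_jc with O the class-wise feature sums and E the class
  prior times the feature total; terms with E = 0 contribute 0.  Min-max
  scaling plus class-sum contingency avoids choosing a bin count for
  continuous features.
* **Random forest** — mean impurity-decrease importances from a 200-tree
  seeded forest (unlimited depth).
* **Variance** — highest sample variance.

All rank ties break toward the lower feature index.  Intersections keep
indices in both parents' top-k; PCA's per-feature ranking (needed only for
intersections) is Σ_j evr_j·|V_kj| — explained-variance-weighted absolute
loadings, the least surprising scalarization of a projection into a
per-feature score.  An intersection smaller than two members is back-filled
from the union of the parent top-k sets by mean rank, so every selector
yields at least two columns (classifiers need at least one; SVMs benefit
from two).

Classifiers operate on per-fold standardized features (train-fold mean/sd,
constant columns mapped to 0): SVM with C = 1 and γ = 1/(D′·meanVar) under
one-vs-one multi-class voting (RBF and linear kernels), and kNN with k = 3,
Euclidean distance, majority vote — vote ties to the lower class index,
distance ties to the lower training-row index.  The `paper40` preset is
{GAP, GMP} × 10 selectors × {SVM-RBF, kNN} = 40 configurations; `full` adds
the CBAM and pre-final layers and the linear SVM (120), and `full+rf`
additionally allows a random-forest classifier.  Both extended presets exist
because published result tables list layers and classifiers beyond the
2×10×2 accounting.  Per fold the selector is fitted on training rows only,
both splits are transformed and standardized with training statistics, and
the classifier is fitted and scored; rankings sort by mean accuracy, then
mean F1, then configuration order.

## Metrics

Per-class one-vs-rest precision/recall/F1 in percent with 0/0 defined as 0
(warned); macro metrics are unweighted class means; accuracy is the diagonal
fraction of the confusion matrix.  Display values round half-up to two
decimals, matching printed tables, while full precision is kept internally.
The cross-validation summary reports mean, sample standard deviation
(n − 1), and two intervals: the mean ± std band that reproduces the
published table convention (94.50 and 1.18 give [93.32, 95.68]), and a
t-based 95 % confidence interval, separately labeled, because mean ± std is
not a 95 % CI.  McNemar's paired test uses the continuity-corrected statistic
(|b − c| − 1)²/(b + c) on the discordant counts with a χ²(1) p-value and the
degenerate b + c = 0 case defined as (0, 1).

## Synthetic data

The generator renders one bright cell per image on a Gaussian-noise
background (level 0.15, default σ 0.05) with a mild random illumination
gradient, as a stand-in for stained micrographs.  Heads are anti-aliased
soft ellipses/polygons at intensity 0.85; tails are quadratic Bézier tubes
at 0.45, dimmer so a threshold isolates the head.  Class geometry: 3-class
scheme — oval head + tail; eccentric doubled-ellipse head + tail; tail-less
debris blob.  4-class scheme — oval (axis ratio 1.5); elongated
(ratio 2 + 1.6·deform); pear (two fused unequal ellipses); random-walk
perturbed polygon.  `deform_strength` scales every deformation;
at the reference setting 0.5 the elongated class measures ratio ≥ 2.  The
head base radius is 0.16 of the frame so morphology stays legible at network
input resolution.  Datasets are balanced, shuffled and fully determined by
the `SyntheticSpec` (bit-identical under equal seeds).

What it does not emulate: staining variation and color, occlusions and
touching cells, debris heterogeneity, focus gradients, and the
inter-observer ambiguity of real morphology labels.  Passing tests on this
data demonstrate that the pipeline's machinery (training, extraction,
selection, evaluation) works and that its ranking behavior responds to real
class structure — not that the accuracies transfer to clinical images.

## Problem sizes

The test suite trains only the tiny variant (images 96 px rendered, 96 px
input for the end-to-end study; 64 px in unit fixtures); the end-to-end
study uses 60 images per class, two-stage 3 + 3 epochs, seeds 0–2, and the
40-configuration grid under stratified 5-fold CV.  The full-size
`resnet50` variant is exercised structurally — built and run forward at
224 px to confirm the printed dimensionalities — but never trained here.

## Numerical choices

Float64 throughout the network; convolutions via im2col with zero padding
(reflect padding is used in image preprocessing, where borders matter);
max-pool padding uses −∞ so zeros never win; gradient of max splits equally
among ties; softmax and cross-entropy are computed in log-space.  Histogram
stretching of a constant image returns zeros with a warning.  Unsharp
masking clips to [0, 1].  The Gaussian kernel is normalized to sum exactly 1.

## Known limitations

* Accuracies on the real SMIDS/HuSHeM collections are not reproduced here;
  that requires the external images and GPU-scale pretraining/fine-tuning.
* Pretrained backbone weights are supported as a configuration flag but no
  weight file is bundled; all shipped runs train from random initialization.
* The chi-square scores on continuous features depend on the min-max scaling
  convention; other discretizations would rank differently.
* McNemar's published χ² = 24.31 cannot be checked without the underlying
  discordant counts; only the formula's worked cases are verified.
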