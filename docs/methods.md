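# Methods

## Problem and pipeline

`histopatch` classifies high-resolution H&E breast-histology images into
four tissue classes — normal, benign, in situ carcinoma, invasive
carcinoma — and, at an intermediate stage, into cancerous (in situ +
invasive) versus non-cancerous (normal + benign). Because whole images
(reference geometry 1536×2048×3) are too large to train on directly, the
unit of learning is the 512×512 patch, and the scientific content of the
package is the machinery on either side of the patch classifier:

1. **Patch extraction with label propagation.** Each image is tiled with
   512×512 windows at stride 256 (50% overlap); a 1536×2048 image yields a
   5×7 grid of 35 patches. Every patch inherits its parent image's label,
   `l(i,j) = L(i)`. This is knowingly noisy — a cancerous image can contain
   predominantly healthy patches — and the aggregation stage exists to
   absorb that noise. Windows are half-open, coordinates 0-based, ordering
   row-major; images whose dimensions are not `patch + k·stride` simply
   drop the remainder margin (padding would fabricate tissue).
2. **Macenko stain normalization.** Stain contributions are additive in
   optical density, `OD = −log10(I/I₀) = M·C`, with `M` the 3×2 stain
   matrix (columns hematoxylin, eosin) and `C` the per-pixel
   concentrations. Tissue pixels (all-channel OD ≥ β) are projected onto
   the top-2 principal plane of their OD cloud; the stain vectors are the
   directions at the α-th and (100−α)-th percentile angles, sign-fixed to
   the nonnegative orthant and unit-normalized. Concentrations are solved
   by exact two-variable nonnegative least squares (closed form; a plain
   least-squares-with-clipping fast path is config-selectable), each
   patch's per-stain 99th-percentile concentrations are rescaled to the
   template's, and pixels are reconstructed through the template's stain
   matrix. Defaults follow standard Macenko practice: β = 0.15, α = 1,
   concentration percentile 99, I₀ = 1.0 in [0,1] pixel space. The
   template is the row-0/col-0 patch of the first training image, with a
   config override; the template model is persisted as JSON. Hematoxylin
   is assigned to the column with the larger red-to-blue OD ratio: a blue
   stain absorbs red/green, so its OD vector is red-dominant (the Ruifrok
   reference hematoxylin vector is ≈ (0.65, 0.70, 0.29) in RGB OD).
   Normalization is per patch; an image-level mode exists.
3. **Augmentation** (training stream only): Bernoulli horizontal and
   vertical flips (p = 0.5 each), rotation by a uniform angle in ±15°,
   translation by uniform fractions in ±0.1 of each dimension, in that
   order; bilinear interpolation, reflect fill. The bounds are
   conventional mild histology augmentation; none are stated by the
   architecture, all are configurable. The pipeline default is offline ×1
   expansion of the training patches (one augmented copy each); per-epoch
   on-the-fly augmentation is available through a callback in
   `train_head`, but re-embedding fresh patches every epoch dominates
   runtime at desk scale, so expansion is the default.
4. **Feature extraction.** A pluggable backbone maps a patch to a spatial
   feature map; the fine-tuning head — conv(512 kernels, 3×3, stride 1,
   ReLU, no padding) → max-pool(2×2, stride 2) → global average pooling →
   batch norm → dropout 0.4 → dense(64, sigmoid, He-uniform, L2) →
   dense(4) → softmax — is trained with Adam (β₁ = 0.8, β₂ = 0.99),
   cross-entropy (natural log), initial learning rate 0.008 decayed
   iteratively as `lr ← lr/(1 + decay)` after each epoch with
   `decay = lr0/max_epochs`, at most 60 epochs, early-stopped when
   validation categorical accuracy fails to improve by more than 1e−3 for
   5 consecutive epochs (best-epoch weights restored). Features are read
   at the GAP output — 512 dimensions for the standard head — and
   concatenated across backbones in configured order. The head's layer
   order after GAP (batch norm → dropout → dense) is one of the
   defensible readings of the architecture and is fixed here as a design
   choice; conv padding is "valid" (GAP makes the choice immaterial to
   feature length).
5. **Classifier ensemble.** The concatenated features are classified by
   five members: k-NN (k = 5, clamped to n), an RBF SVM with probability
   calibration, a random forest (200 trees), AdaBoost (200 estimators),
   and gradient-boosted trees (xgboost, 200 rounds). Hyperparameters are
   not prescribed by the architecture; these are conventional defaults,
   all seeded from the global seed. AdaBoost uses depth-2 base trees:
   four-class boosting with depth-1 stumps cannot separate classes
   arranged on a 2-D grid, since each axis-aligned stump only splits
   superclass pairs. Per-patch probability vectors are fused classwise by
   the arithmetic mean, the product, or the elementwise maximum (the mean
   rather than the raw sum — identical argmax, scores stay in [0,1]), and
   the fused scores pass through a softmax. Argmax ties break to the
   lowest class index everywhere.
6. **Two-stage aggregation.** For each image the predicted patch classes
   are counted into `Freq = [normal, benign, insitu, invasive]` (hard
   argmax counting; soft probability-sum counting is available behind a
   flag) and collapsed to `New_Freq = [cancerous, non-cancerous]`. Stage
   one — softmax over `New_Freq` → one L2-regularized affine unit →
   sigmoid — is trained with binary cross-entropy and Adam on the training
   images *plus the merged validation images* and yields the cancer
   probability `p`; an image is called cancerous when `p > 0.5`. The
   counts are then reweighted, `[normal·(1−p), benign·(1−p), insitu·p,
   invasive·p]` — an attention-like factor that suppresses
   cross-superclass confusion — and stage two — softmax over the weighted
   counts → dense(4, sigmoid) → dense(4, softmax) — is trained with
   cross-entropy under the same lr-decay schedule and yields the final
   class probabilities. A majority-vote baseline (modal patch class) is
   computed alongside and logged for comparison. Softmax over raw counts
   is scale-invariant only in count differences, so all balanced arrays
   (k, k) receive identical probabilities; this representational quirk is
   inherited from the architecture and surfaced in a test.

Metrics are one-vs-rest per class: precision TP/(TP+FP), recall
TP/(TP+FN), F1 their harmonic mean, and per-class accuracy the four-term
(TP+TN)/total — which is why per-class accuracy differs from recall.
Overall accuracy is trace/total. 0/0 ratios resolve to 0 with a warning.

The dataset partition is 65/15/20 train/validation/test, stratified by
class with largest-remainder rounding per class, deterministic given the
seed. The validation images merge into training before the image-level
stage. (One source passage suggests 20% validation; the 65/15/20 reading,
stated twice, is used.)

## The numpy neural-network core

No deep-learning runtime is a dependency. The three trainable components —
the fine-tuning head (~180k parameters at 32 input channels), the
two-class unit (3 parameters) and the four-class net (40 parameters) — are
implemented in `histopatch.nn`: valid 3×3 convolution, 2×2 max pooling,
GAP, batch norm, dropout, dense layers, softmax, Adam, the iterative
lr-decay schedule, and early stopping, all deterministic given a seed.

Two numerical choices matter on small datasets:

- **Batch-norm statistics are finalized exactly.** Exponential running
  averages lag the pre-normalization distribution while conv weights move
  quickly, and on a dataset of ~10² patches the mismatch between training
  (batch statistics) and inference (running statistics) can be
  catastrophic — observed as eval-mode accuracy 0.55 against 0.98 under
  batch statistics. After every epoch the running statistics are replaced
  by exact full-training-set moments, and early-stopping snapshots carry
  the statistics together with the weights.
- **Cross-entropy guards.** Probabilities are clamped at 1e−12 before the
  log; softmax subtracts the row max.

## Backbones

Backbones are an interface, not a dependency. The bundled `TinyBackbone`
block-averages the patch by 16× and applies two fixed random He-initialized
conv+pool blocks (3→16→32 channels), giving a 6×6×32 map for a 512×512
patch; it is deterministic given its seed and is never trained — the head
on top is the trained component. (The alternative of unfreezing the tiny
backbone was rejected: the head alone separates the synthetic classes, and
a frozen random projection keeps the training path small and exactly
reproducible.) Adapters for ImageNet-pretrained VGG-16, VGG-19 and
Inception-ResNet v2 activate only when a keras runtime with weights is
importable, defaulting to four unfrozen terminal layers; no weights are
shipped or downloaded, and nothing in the test suite requires them.

## The synthetic fixture generator

Fixtures emulate H&E microscopy through the same physics the stain
estimator assumes: per-pixel `OD = M·C` with a known unit-column 3×2 stain
matrix, pixels `I₀·10^(−OD)` plus optional Gaussian pixel noise, clipped
to [0,1]. The hematoxylin field is a sum of Gaussian blobs at sampled
nuclei centers (Poisson count, lognormal amplitude jitter around peak
concentration 2.5); the eosin field is a smooth low-frequency texture in
[0.2, 1.2], suppressed inside nuclei by `exp(−0.8·h)` — nuclei displace
cytoplasm — which also leaves near-pure hematoxylin pixels at blob cores.
Nuclei are sampled away from a stroma-only border margin (3 blob sigmas,
capped at 1/8 of each dimension), so even the densest class retains
near-pure eosin pixels; both choices keep the extreme-percentile angle
geometry of the Macenko estimator well posed for every class, mirroring
real sections, which carry stroma between and around cellular regions.

Class identity is carried by nuclei density (and mildly by blob radius),
strictly ordered normal < benign < insitu < invasive; the ordering is a
fixed convention. The default profile (80/160/320/640 nuclei per
megapixel, σ = 10–13 px, pixel noise 0.005) confines in situ nuclei to a
random sub-rectangle of 40% of the frame, so some patches of an in situ
image look normal — deliberately exercising the label noise that patch
label propagation accepts. The easy profile (60/160/380/850 per Mpx, no
noise, no confinement) is separable by construction and backs the
end-to-end benchmark.

**Benchmark geometry.** The easy profile renders 768×1280 images — a 2×4
grid of eight overlapping patches. Eight patches per image is the smallest
geometry at which the frequency-array stage is non-degenerate: with the
one-row 512×1024 profile (three patches) a single patch error flips the
array majority and the four-class net sees no mixed-count patterns during
training. The 512×1024 profile remains in use for unit tests of the stain
estimator, where only single images matter. The benchmark itself is
n_per_class = 6 (24 images: 16 train / 4 validation / 4 test after the
stratified 65/15/20 split), tiny backbone, full pipeline, and completes in
about one minute on one CPU.

**What the fixtures do not emulate:** real chromatin/gland morphology,
inter-image stain variability (each image uses the same generative stain
matrix unless composed explicitly), scanner noise correlations, and
realistic class overlap. Passing the benchmark therefore demonstrates that
the pipeline's stages compose correctly and that the aggregation recovers
image labels from imperfect patch labels — not that the defaults would
reach any particular accuracy on real histology.

## Degenerate inputs and tie-breaks

- Stain estimation requires ≥ 2 tissue pixels and a rank-2 OD cloud
  (second eigenvalue > 1e−3 of the first); violations raise a
  `DegenerateImageError` naming the condition. Patch normalization can be
  configured to pass such patches through unnormalized (the pipeline
  default) instead of failing the run.
- k for k-NN is clamped to the sample count; the SVM falls back to
  hard-label probabilities when a class has fewer than two samples
  (probability calibration needs folds).
- Argmax ties break to the lowest class index; the majority-vote baseline
  inherits the same rule.
- Metric 0/0 cases resolve to 0 with a warning; they do not occur in the
  benchmark.

## Reproducibility

Every stage seed derives deterministically from one global seed
(`SeedSequence([seed, stage_index])`, reduced mod 2³¹). Two runs with the
same config and seed write byte-identical prediction CSVs; this is
asserted in the test suite. Stage-wise CLI commands re-derive upstream
stages from the config and seed rather than deserializing fitted models,
so re-running any stage reproduces the full run's artifacts.
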