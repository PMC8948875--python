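# Methods

`nucstyle` implements a style-augmentation pipeline for nuclei instance
segmentation across heterogeneous microscopy modalities, together with the
evaluation stack used by the 2018 Data Science Bowl (DSB) style of
benchmark. This note records the models, the numerical choices, and what
the synthetic experiments do and do not demonstrate.

## Modality clustering

DSB-style collections carry no modality metadata, so domains for style
transfer are discovered from appearance. Each image is summarised by three
16-bin normalized histograms over the HSV channels (48 features). The
histogram feature is invariant to flips and right-angle rotations and
separates background/stain colour regimes cheaply; it deliberately ignores
geometry. K-means (k-means++ init, 10 restarts, 300-iteration cap, fixed
seed) clusters the features; the default is k = 6 clusters for exploration,
while the style model defaults to 5 domains. When a 6-cluster model must
drive a 5-domain style model, `merge_to_domains` merges the two nearest
centroids (repeatedly, weighted by group size) — a deterministic
reconciliation of the cluster/domain mismatch.

CLAHE contrast enhancement is provided for dark, low-contrast fluorescent
images. It is applied to the value channel only (hue and saturation are
untouched) with scikit-image's `equalize_adapthist`; the clip limit
defaults to 0.01 and the tile count to 8 per side. Clustering operates on
raw images by default: enhancement is an opt-in preprocessing step for
downstream stages, not part of the feature definition.

## Disentangled style transfer

The core model is a multi-domain image-to-image translation network with
disentangled representations, in the DRIT/MUNIT family:

* a **content encoder** E_c: two stride-2 convolution blocks and three
  residual blocks, producing a spatial code z_c with C_c channels at 1/4
  resolution (C_c = 64 at the full profile, 16 at the CPU test profile);
* a **variational attribute encoder** E_a: four stride-2 convolutions,
  global average pooling and two linear heads for (mu, logvar); the
  attribute vector z_a = mu + exp(logvar/2)·eps has 8 dimensions; logvar is
  clamped to [-10, 10] for numerical stability;
* a single shared **generator** G(z_c, z_a, d) conditioned on the one-hot
  domain code d. Style enters through **adaptive instance normalization**:
  a small MLP maps (z_a, d) to per-channel (gamma, beta) for every
  normalization site in the decoder. This is load-bearing: a plain
  instance norm subtracts exactly the constant per-channel shifts that
  carry global style (background colour, brightness), so injecting style
  only as concatenated channels at the bottleneck is erased by the
  following normalizations;
* a **domain-conditional discriminator** with two heads over a shared
  trunk: a patch-level least-squares (LSGAN) real/fake head whose input is
  conditioned on d, and an auxiliary per-image domain classifier. The
  auxiliary head gives the generator a direct, non-saturating gradient
  toward the target domain's appearance — without it, a discriminator that
  wins on texture realism alone never forces domain consistency;
* a **content discriminator**, a domain classifier on z_c trained with
  cross-entropy to the true domain while the encoder is pushed toward the
  uniform distribution over domains (cross-entropy to uniform equals ln D
  when the classifier is uninformative).

Training minimises the weighted sum of six terms: cross-cycle consistency
L_cc (swap content codes between two domains, translate, re-encode, swap
back, L1 to the originals), content-adversarial L_c, image-adversarial L_d,
self-reconstruction L_recon (L1), latent regression L_latent (a
prior-drawn z_a must be recoverable, via the posterior mean, from the image
generated with it), and the Gaussian KL L_KL on the attribute posterior,
0.5·Σ(mu² + e^logvar − 1 − logvar). Default weights are w_cc = 10,
w_recon = 10, w_latent = 10, w_KL = 0.01, w_d = 1, w_c = 1 — the
convention of the disentangled-translation literature; none are dictated by
the task and all are configurable. The latent branch is also passed
through the discriminator: generations from prior-sampled attributes are
exactly the regime used at augmentation time, so they must be
adversarially constrained or the generator learns to honour only encoded
attributes.

Optimisation is Adam with learning rate 1e-4, betas (0.5, 0.999) and
weight decay 1e-4 at the full profile, batch size two (one image from each
of two distinct domains per iteration), alternating discriminator and
generator/encoder updates. The CPU test profile shrinks channel widths
four-fold and raises the learning rate to 1e-3 so that a 500-iteration
smoke run converges visibly in about two minutes on one core. One master
seed derives the streams for weight initialisation, image sampling and
latent draws; seeded runs are bit-reproducible.

**Augmentation contract.** `sample_augmentation` keeps z_c fixed, draws
z_a from N(0, I) and the target domain uniformly (optionally excluding the
source domain or fixing a target), and attaches a bit-identical copy of
the source instance mask. Mask inheritance is structural — the mask is
never resampled — and is asserted bitwise in the tests. The translation
model assumes domains share content (nuclei on background); modalities
whose content differs (e.g. one shows cytoplasm, another only nuclei)
violate the assumption and produce unrealistic output. This failure mode
is inherent to the model family and is out of the package's scope.

## Augmentation pipeline and segmenter contract

`AugmentationPolicy` applies style augmentation with probability 0.5 by
default, before the standard ops (each of hflip/vflip/rot90 firing
independently, rescale in [0.8, 1.2], colour jitter with
brightness/contrast factors in [0.9, 1.1]). Style precedes geometry so the
style model sees axis-aligned content matching its training distribution.
Geometric ops act identically on pixels and mask (order-0 resampling for
masks); style acts on pixels only.

Heavy segmentation networks (Mask R-CNN and friends) are represented by a
contract — `train(dataset, seed)` / `predict(image)` — not an
implementation. The built-in reference segmenter is a per-pixel MLP (one
hidden layer of 16 units) on six features: RGB and the deviation from the
image's median colour; the context feature lets one model segment both
bright-on-dark and dark-on-bright modalities. Foreground components
smaller than 9 px are discarded. It is a deliberately small stand-in that
makes the with/without-augmentation comparison runnable in minutes, not a
claim about state-of-the-art segmentation.

## Evaluation

The per-image score is S = (1/|T|) Σ_t TP(t) / (TP(t) + FP(t) + FN(t))
over the threshold ladder T = {0.10, 0.15, …, 0.95} (18 values); the
10-value ladder starting at 0.50 used by the official Kaggle evaluator is
available behind a flag. A predicted instance is a true positive at t only
if matched one-to-one to a ground-truth instance with IoU **strictly**
greater than t (this decides the worked example: a single pair at IoU
exactly 0.6 scores 10/18). An image with neither predictions nor ground
truth scores 1.0.

Matching is solved as an exact assignment problem (maximum cardinality,
ties toward larger total IoU, via `linear_sum_assignment`). At t ≥ 0.5 the
matching is unique because instances within a set are disjoint; below 0.5
— and the 18-value ladder starts at 0.10 — greedy pairing by descending
IoU is demonstrably suboptimal on a fraction of random inputs, so the
exact solution is used. The test suite checks it against exhaustive
enumeration over injective assignments on 500 random small instance sets.

Test-time augmentation predicts on transformed views (flips, right-angle
rotations, rescaling with nearest-neighbour mask inversion, photometric
jitter), maps instances back through the inverse geometric transform, and
merges: pooled instances are grouped by single-linkage at pairwise
IoU ≥ 0.5, groups supported by more than half of the views survive, and
the merged mask keeps pixels voted by at least half the group's members
(ties kept). The merge rule is a design choice, fully configurable.

Run-length encoding follows the Kaggle submission convention bit-exactly:
column-major (down, then right), 1-based, maximal sorted runs; the
submission CSV has columns `ImageId,EncodedPixels`.

## Synthetic data

The generator emulates five visually distinct modalities with one colour
recipe each: dark-background fluorescence with small (radius 3–6 px) and
large (9–16 px) nuclei, H&E-like pink background with purple nuclei,
light-gray bright-field with dark nuclei, and purple-stained tissue with
background speckle. Nuclei are random ellipses (axis ratio in [0.6, 1],
uniform rotation) placed by rejection sampling with hard non-overlap,
matching the disjoint-mask convention of DSB data; rendering adds mild
per-instance brightness jitter and Gaussian pixel noise (sd 0.02–0.04).
Recipes for distinct domains must differ in background or nucleus colour
by L2 ≥ 0.2, which guarantees HSV separability. Defaults: 64 px side for
tests, 128 px for the folder-writing CLI.

What the synthetic domains do **not** capture: texture inside nuclei,
uneven illumination, touching/overlapping nuclei, cytoplasm channels, and
the long-tailed size distribution of real collections. Passing the
synthetic experiments therefore demonstrates that the pipeline's machinery
is correct (losses, disentanglement wiring, mask inheritance, metric,
imbalance handling) — not that the learned style transfer reaches
photorealistic quality on real microscopy.

## Scaled-down experiments and their sizes

The repository is sized for a single CPU. The smoke experiment trains the
2-domain test-profile model (dark fluorescent vs. light bright-field,
20 + 20 images, 64 px) for 500 iterations: self-reconstruction L1 over the
trailing 50 iterations falls to roughly a quarter of the leading-50 mean,
and translating a dark-domain image into the bright-field domain raises
its mean intensity by ≈ 0.4–0.65 (the source sits near 0.06, real
bright-field near 0.74). Domain fidelity at this scale is directional, not
exact: 500 iterations are enough to move styles decisively between
domains, not to match them pixel-perfectly.

The imbalance experiment trains the reference segmenter on a 90:10
two-domain set, with and without style augmentation under shared seeds
(3 each), and scores on 25 held-out minority-domain images. The style
model used for this comparison is trained to 1000 iterations (the
500-iteration smoke run continued): the smoke checks are about
convergence, while the comparison depends on augmentation quality, and
artifact-heavy styled images from an under-trained model can slightly
hurt rather than help. The per-pixel reference segmenter is strong
enough that ten minority images already anchor its performance near the
score ceiling, so the comparison verifies the direction (with ≥ without)
rather than reproducing the large gaps a deep detector shows on a real,
much harder benchmark.
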