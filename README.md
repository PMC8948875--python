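# nucstyle

Style augmentation for nuclei instance segmentation across microscopy
modalities — and the evaluation stack to measure whether it helps.

Collections such as the 2018 Data Science Bowl (BBBC038) mix imaging
modalities: most images are dark-background fluorescence, while bright-field
images of stained tissue form small minority classes on which segmentation
networks underperform. `nucstyle` counteracts that imbalance by *style
augmentation*: a multi-domain translation GAN with disentangled
representations decomposes an image into a spatial, domain-invariant
**content code** z_c (nuclei locations and shapes) and a low-dimensional
**attribute code** z_a (stain colour, background, contrast) plus a one-hot
domain label d. During augmentation only (z_a, d) are resampled while z_c
stays fixed, so the synthetic image keeps the original geometry and
**inherits its instance mask bit-for-bit** — annotation-free augmentation
into under-represented modalities.

The model is trained on unpaired images with the objective

    L_total = w_cc·L_cc + w_c·L_c + w_d·L_d + w_recon·L_recon
              + w_latent·L_latent + w_KL·L_KL

(cross-cycle consistency, content-adversarial, image-adversarial,
self-reconstruction, latent regression and Gaussian-prior KL; defaults
w = 10, 1, 1, 10, 10, 0.01). Segmentation quality is scored with the
competition metric

    S = (1/|T|) Σ_{t∈T} TP(t) / (TP(t) + FP(t) + FN(t)),
    T = {0.10, 0.15, …, 0.95},

with strict IoU > t matching, averaged over images. The package also
provides HSV-histogram K-means modality clustering with CLAHE enhancement
and a PCA embedding, DSB-layout folder I/O, Kaggle run-length-encoded
submissions, test-time augmentation with majority-vote instance merging, a
pluggable segmenter contract with a compact trainable reference segmenter,
and a five-modality synthetic nuclei generator so everything runs without
the benchmark download. The neural networks run on a small bundled
numpy autograd engine — one CPU is enough for every experiment in the
test suite.

## Worked example

```python
import dataclasses
import numpy as np
import nucstyle as ns

# two synthetic modalities: dark fluorescence and light bright-field
recipes = [ns.DEFAULT_RECIPES[0],
           dataclasses.replace(ns.DEFAULT_RECIPES[3], domain_id=1)]
imgs = ns.make_dataset([20, 20], recipes=recipes, side=64, seed=42)

model = ns.StyleModel(ns.StyleConfig.test_profile(n_domains=2, seed=0))
hist = model.train(imgs, iterations=500)
print(f"recon L1: first-50 mean {np.mean([h['recon'] for h in hist[:50]]):.3f}"
      f" -> last-50 mean {np.mean([h['recon'] for h in hist[-50:]]):.3f}")

dark = next(i for i in imgs if i.domain_id == 0)
aug = model.sample_augmentation(dark, np.random.default_rng(1), target_domain=1)
print(f"mean intensity {dark.pixels.mean():.3f} -> {aug.pixels.mean():.3f}")
print("mask inherited:", bool((aug.instance_mask == dark.instance_mask).all()))
```

prints

```
recon L1: first-50 mean 0.435 -> last-50 mean 0.111
mean intensity 0.063 -> 0.522
mask inherited: True
```

Self-reconstruction drops to about a quarter of its starting level within
500 CPU iterations; restyling a dark fluorescent image into the
bright-field domain raises its mean intensity toward the bright-field
level (~0.74 in this dataset) while the instance mask is untouched. The
metric's own worked example: a single predicted/true pair at IoU exactly
0.6 passes the 10 ladder thresholds below 0.6, so
`ns.image_score([pred], [gt])` returns 10/18 ≈ 0.556.

A command-line interface mirrors the library:

```bash
nucstyle generate --out data/ --counts 90,10 --side 128 --seed 1
nucstyle cluster fit --data data/ --k 2 --seed 0 --out model.json
nucstyle style train --data data/ --domains 2 --profile test --out ckpt/
nucstyle style augment --ckpt ckpt/ --in data/ --out styled/ --seed 1
nucstyle score --pred preds/ --gt data/ --thresholds paper
nucstyle submit --pred preds/ --out submission.csv
```

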