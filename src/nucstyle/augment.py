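"""Training-time augmentation policy and the pluggable segmenter contract.

Style augmentation is combined with standard geometric/photometric
augmentations: with probability ``style_prob`` (default 0.5) an image is
first re-styled by the trained style-transfer model — which leaves its
instance mask untouched — and geometric ops are then applied identically to
pixels and mask.

Heavy instance-segmentation networks are deliberately out of scope; any
segmenter exposing ``train(dataset, seed)`` and ``predict(image) ->
list-of-binary-masks`` plugs into the pipeline.  A compact reference
segmenter (a per-pixel MLP on colour-context features followed by connected
components) makes the full with/without-augmentation comparison runnable on
one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage import measure, transform as sktransform
from sklearn.neural_network import MLPClassifier

from .metrics import dataset_score, instances_from_mask
from .synthetic import LabeledImage

__all__ = [
    "AugmentationPolicy",
    "augment",
    "PixelSegmenter",
    "reference_segmenter",
    "run_experiment",
]

STANDARD_OPS = ("hflip", "vflip", "rot90", "rescale", "color_jitter")


@dataclass(frozen=True)
class AugmentationPolicy:
    """Which augmentations to draw, and how often.

    Each geometric/photometric op listed in `ops` fires independently with
    probability `op_prob`; the style op fires with probability `style_prob`
    and is applied first (the style model then sees unrotated content,
    matching its training distribution).
    """

    style_prob: float = 0.5
    ops: Tuple[str, ...] = ("hflip", "vflip", "rot90")
    op_prob: float = 0.5
    rescale_range: Tuple[float, float] = (0.8, 1.2)
    jitter_range: Tuple[float, float] = (0.9, 1.1)
    exclude_source_domain: bool = False

    def __post_init__(self):
        if not 0 <= self.style_prob <= 1:
            raise ValueError("style_prob must lie in [0, 1]")
        if self.rescale_range[0] <= 0:
            raise ValueError("rescale bounds must be positive")
        unknown = set(self.ops) - set(STANDARD_OPS)
        if unknown:
            raise ValueError(f"unknown ops: {sorted(unknown)}")


def augment(
    labeled: LabeledImage,
    policy: AugmentationPolicy,
    style_model=None,
    rng: Optional[np.random.Generator] = None,
) -> LabeledImage:
    """Draw one augmented copy of `labeled` under `policy`.

    Style (if drawn) alters pixels only; geometric ops are applied
    identically to pixels and mask (order-0 resampling for the mask), so
    with ``style_prob=0`` the output mask is the input mask under the drawn
    geometric transform alone.
    """
    rng = rng or np.random.default_rng()
    out = labeled
    if policy.style_prob > 0 and rng.random() < policy.style_prob:
        if style_model is None:
            raise ValueError("style_prob > 0 requires a trained style model")
        out = style_model.sample_augmentation(
            out, rng, exclude_source=policy.exclude_source_domain
        )
    pixels = out.pixels
    mask = out.instance_mask
    for op in policy.ops:
        if op == "hflip" and rng.random() < policy.op_prob:
            pixels, mask = pixels[:, ::-1], mask[:, ::-1]
        elif op == "vflip" and rng.random() < policy.op_prob:
            pixels, mask = pixels[::-1], mask[::-1]
        elif op == "rot90" and rng.random() < policy.op_prob:
            k = int(rng.integers(1, 4))
            pixels = np.rot90(pixels, k, axes=(0, 1))
            mask = np.rot90(mask, k, axes=(0, 1))
        elif op == "rescale" and rng.random() < policy.op_prob:
            f = rng.uniform(*policy.rescale_range)
            pixels = sktransform.rescale(
                pixels, f, channel_axis=2, order=1, anti_aliasing=False
            )
            mask = sktransform.resize(
                mask.astype(float), pixels.shape[:2], order=0,
                anti_aliasing=False,
            ).astype(mask.dtype)
        elif op == "color_jitter" and rng.random() < policy.op_prob:
            b = rng.uniform(*policy.jitter_range)
            c = rng.uniform(*policy.jitter_range)
            pixels = np.clip(((pixels - 0.5) * c + 0.5) * b, 0, 1)
    return LabeledImage(
        pixels=np.ascontiguousarray(pixels),
        instance_mask=np.ascontiguousarray(mask),
        domain_id=out.domain_id,
        image_id=out.image_id,
    )


# ---------------------------------------------------------------------------
# Reference segmenter: per-pixel MLP on colour + image-context features,
# then connected components with a minimum-area filter.
# ---------------------------------------------------------------------------


def _pixel_features(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel features: RGB plus deviation from the image median colour."""
    med = np.median(pixels.reshape(-1, 3), axis=0)
    diff = pixels - med
    return np.concatenate([pixels, diff], axis=2).reshape(-1, 6)


class PixelSegmenter:
    """Minimal trainable segmenter fulfilling the segmenter contract.

    A small MLP classifies each pixel as nucleus/background from its colour
    and its deviation from the image's median colour (so polarity — bright
    nuclei on dark background vs. dark on bright — is learnable from
    context).  Connected components of the foreground above `min_area`
    pixels become the predicted instances.
    """

    def __init__(self, min_area: int = 9, hidden: int = 16,
                 pixels_per_image: int = 1500):
        self.min_area = min_area
        self.hidden = hidden
        self.pixels_per_image = pixels_per_image
        self._clf = None

    def train(self, dataset: Sequence[LabeledImage], seed: int = 0) -> "PixelSegmenter":
        rng = np.random.default_rng(seed)
        xs, ys = [], []
        for lab in dataset:
            feats = _pixel_features(lab.pixels)
            labels = (lab.instance_mask > 0).ravel().astype(int)
            idx = rng.choice(len(feats), size=min(self.pixels_per_image, len(feats)),
                             replace=False)
            xs.append(feats[idx])
            ys.append(labels[idx])
        X = np.concatenate(xs)
        y = np.concatenate(ys)
        self._clf = MLPClassifier(
            hidden_layer_sizes=(self.hidden,), max_iter=300,
            random_state=seed, learning_rate_init=0.01,
        )
        self._clf.fit(X, y)
        return self

    def predict(self, image: np.ndarray) -> List[np.ndarray]:
        if self._clf is None:
            raise RuntimeError("segmenter is untrained; call train() first")
        image = np.asarray(image, dtype=float)
        probs = self._clf.predict_proba(_pixel_features(image))[:, 1]
        fg = probs.reshape(image.shape[:2]) > 0.5
        labeled = measure.label(fg, connectivity=1)
        out = []
        for m in instances_from_mask(labeled):
            if m.sum() >= self.min_area:
                out.append(m)
        return out


def reference_segmenter(min_area: int = 9) -> PixelSegmenter:
    """Factory for the built-in reference segmenter."""
    return PixelSegmenter(min_area=min_area)


def _augmented_training_set(
    train_set: Sequence[LabeledImage],
    policy: AugmentationPolicy,
    style_model,
    seed: int,
    copies: int = 1,
) -> List[LabeledImage]:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA26]))
    out = list(train_set)
    for _ in range(copies):
        for lab in train_set:
            out.append(augment(lab, policy, style_model, rng))
    return out


def run_experiment(
    train_set: Sequence[LabeledImage],
    test_set: Sequence[LabeledImage],
    style_model,
    policy: Optional[AugmentationPolicy] = None,
    seeds: Sequence[int] = (0, 1, 2),
    segmenter_factory=reference_segmenter,
    copies: int = 1,
) -> pd.DataFrame:
    """Train the plugged segmenter with and without style augmentation.

    Both arms see the originals plus `copies` augmented copies per image
    drawn under the same seeds; the only difference is ``style_prob`` (the
    policy's value vs. forced 0).  Returns one row per (arm, seed) with the
    dataset score on `test_set`.
    """
    policy = policy or AugmentationPolicy()
    control = AugmentationPolicy(
        style_prob=0.0, ops=policy.ops, op_prob=policy.op_prob,
        rescale_range=policy.rescale_range, jitter_range=policy.jitter_range,
    )
    gt = [instances_from_mask(lab.instance_mask) for lab in test_set]
    rows = []
    for arm, pol in (("with_style", policy), ("without_style", control)):
        for seed in seeds:
            aug_train = _augmented_training_set(
                train_set, pol, style_model if pol.style_prob > 0 else None,
                seed, copies,
            )
            seg = segmenter_factory().train(aug_train, seed=seed)
            pairs = [
                (seg.predict(lab.pixels), g) for lab, g in zip(test_set, gt)
            ]
            report = dataset_score(pairs)
            rows.append({"arm": arm, "seed": seed, "score": report.mean_score})
    return pd.DataFrame(rows)
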