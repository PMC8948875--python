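"""Instance-segmentation scoring and test-time augmentation.

The competition score for an image is the mean, over a ladder of IoU
thresholds, of TP / (TP + FP + FN), where a predicted instance counts as a
true positive at threshold t when it is one-to-one matched to a ground-truth
instance with IoU strictly greater than t.  The default ladder is
T = {0.10, 0.15, ..., 0.95} (18 values); the stricter 10-value ladder
starting at 0.50 used by the Kaggle evaluator is available as
``KAGGLE_THRESHOLDS``.  Dataset score is the unweighted mean over images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from skimage import transform as sktransform

__all__ = [
    "PAPER_THRESHOLDS",
    "KAGGLE_THRESHOLDS",
    "iou",
    "iou_matrix",
    "match_at_threshold",
    "image_score",
    "dataset_score",
    "instances_from_mask",
    "ScoreReport",
    "tta_predict",
    "Identity",
    "HFlip",
    "VFlip",
    "Rot90",
    "Rescale",
    "ColorJitter",
]

PAPER_THRESHOLDS = tuple(np.round(np.arange(10, 100, 5) / 100.0, 2))  # 0.10..0.95
KAGGLE_THRESHOLDS = tuple(np.round(np.arange(50, 100, 5) / 100.0, 2))  # 0.50..0.95


def instances_from_mask(instance_mask: np.ndarray) -> List[np.ndarray]:
    """Split an integer instance mask into per-instance binary masks."""
    instance_mask = np.asarray(instance_mask)
    return [
        instance_mask == k for k in range(1, int(instance_mask.max()) + 1)
    ]


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks."""
    mask_a, mask_b = np.asarray(mask_a), np.asarray(mask_b)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"shape mismatch: {mask_a.shape} vs {mask_b.shape}")
    a = mask_a.astype(bool)
    b = mask_b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def iou_matrix(preds: Sequence[np.ndarray], gts: Sequence[np.ndarray]) -> np.ndarray:
    """Pairwise IoU, predictions in rows, ground truths in columns."""
    m = np.zeros((len(preds), len(gts)))
    for i, p in enumerate(preds):
        for j, g in enumerate(gts):
            m[i, j] = iou(p, g)
    return m


def match_at_threshold(iou_mat: np.ndarray, t: float) -> Tuple[int, int, int]:
    """Optimal one-to-one matching at strict IoU threshold t.

    Returns (TP, FP, FN): matched pairs, unmatched predictions, unmatched
    ground truths.  A pair can only match when its IoU exceeds t strictly;
    among the admissible pairs a maximum-cardinality assignment is chosen
    (ties broken toward larger total IoU).  At thresholds >= 0.5 the
    matching is unique because instance masks within a set are disjoint;
    below 0.5 a simple greedy-by-IoU pairing can be suboptimal, so the
    assignment problem is solved exactly.
    """
    iou_mat = np.atleast_2d(np.asarray(iou_mat, dtype=float))
    n_pred, n_gt = iou_mat.shape
    if n_pred == 0 or n_gt == 0:
        return 0, n_pred, n_gt
    admissible = iou_mat > t
    # maximize match count first, then total IoU among max-cardinality matchings
    gain = admissible * (1.0 + iou_mat * 1e-6)
    rows, cols = linear_sum_assignment(-gain)
    tp = int(admissible[rows, cols].sum())
    return tp, n_pred - tp, n_gt - tp


@dataclass
class ScoreReport:
    """Per-image and per-threshold breakdown of the competition score."""

    thresholds: tuple
    per_image: pd.DataFrame  # columns: image, S
    per_threshold: pd.DataFrame  # columns: threshold, TP, FP, FN (summed)
    mean_score: float

    def summary(self) -> str:
        lines = [f"mean score S = {self.mean_score:.4f} "
                 f"over {len(self.per_image)} image(s), "
                 f"{len(self.thresholds)} IoU thresholds"]
        for _, row in self.per_threshold.iterrows():
            lines.append(
                f"  t={row['threshold']:.2f}  TP={int(row['TP'])} "
                f"FP={int(row['FP'])} FN={int(row['FN'])}"
            )
        return "\n".join(lines)


def image_score(
    preds: Sequence[np.ndarray],
    gts: Sequence[np.ndarray],
    thresholds: Sequence[float] = PAPER_THRESHOLDS,
    return_counts: bool = False,
):
    """Mean over thresholds of TP/(TP+FP+FN) for one image.

    An image with neither predictions nor ground truths scores 1.0
    (vacuously correct).
    """
    preds = [np.asarray(p) for p in preds]
    gts = [np.asarray(g) for g in gts]
    for m in (*preds, *gts):
        if m.shape != (preds + gts)[0].shape:
            raise ValueError("all masks must share one shape")
    if not preds and not gts:
        counts = [(t, 0, 0, 0) for t in thresholds]
        s = 1.0
    else:
        mat = iou_matrix(preds, gts)
        counts = []
        terms = []
        for t in thresholds:
            tp, fp, fn = match_at_threshold(mat, t)
            counts.append((t, tp, fp, fn))
            terms.append(tp / (tp + fp + fn) if (tp + fp + fn) else 1.0)
        s = float(np.mean(terms))
    if return_counts:
        return s, counts
    return s


def dataset_score(
    pairs: Sequence[Tuple[Sequence[np.ndarray], Sequence[np.ndarray]]],
    thresholds: Sequence[float] = PAPER_THRESHOLDS,
    image_ids: Optional[Sequence[str]] = None,
) -> ScoreReport:
    """Unweighted mean of per-image scores over a dataset."""
    if not len(pairs):
        raise ValueError("dataset_score requires at least one image")
    ids = image_ids or [f"image_{i:04d}" for i in range(len(pairs))]
    rows, agg = [], {t: [0, 0, 0] for t in thresholds}
    for image_id, (preds, gts) in zip(ids, pairs):
        s, counts = image_score(preds, gts, thresholds, return_counts=True)
        rows.append({"image": image_id, "S": s})
        for t, tp, fp, fn in counts:
            agg[t][0] += tp
            agg[t][1] += fp
            agg[t][2] += fn
    per_image = pd.DataFrame(rows)
    per_threshold = pd.DataFrame(
        [{"threshold": t, "TP": v[0], "FP": v[1], "FN": v[2]}
         for t, v in agg.items()]
    )
    return ScoreReport(
        thresholds=tuple(thresholds),
        per_image=per_image,
        per_threshold=per_threshold,
        mean_score=float(per_image["S"].mean()),
    )


# ---------------------------------------------------------------------------
# Test-time augmentation: predict on transformed copies, map instance masks
# back, and keep instances that a majority of views agree on.
# ---------------------------------------------------------------------------


class Transform:
    """An invertible test-time view of an image."""

    geometric = True

    def apply(self, image: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def invert_mask(self, mask: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Identity(Transform):
    def apply(self, image):
        return image

    def invert_mask(self, mask):
        return mask


class HFlip(Transform):
    def apply(self, image):
        return image[:, ::-1]

    def invert_mask(self, mask):
        return mask[:, ::-1]


class VFlip(Transform):
    def apply(self, image):
        return image[::-1]

    def invert_mask(self, mask):
        return mask[::-1]


class Rot90(Transform):
    def __init__(self, k: int = 1):
        self.k = k % 4

    def apply(self, image):
        return np.rot90(image, self.k, axes=(0, 1))

    def invert_mask(self, mask):
        return np.rot90(mask, -self.k, axes=(0, 1))


class Rescale(Transform):
    def __init__(self, factor: float):
        if factor <= 0:
            raise ValueError("rescale factor must be positive")
        self.factor = factor
        self._orig_shape = None

    def apply(self, image):
        self._orig_shape = image.shape[:2]
        return sktransform.rescale(
            image, self.factor, channel_axis=2, order=1, anti_aliasing=False
        )

    def invert_mask(self, mask):
        if self._orig_shape is None:
            raise RuntimeError("invert_mask before apply")
        return (
            sktransform.resize(
                mask.astype(float), self._orig_shape, order=0,
                anti_aliasing=False,
            )
            > 0.5
        )


class ColorJitter(Transform):
    """Photometric view; masks come back unchanged."""

    geometric = False

    def __init__(self, brightness: float = 1.0, contrast: float = 1.0):
        self.brightness = brightness
        self.contrast = contrast

    def apply(self, image):
        out = (image - 0.5) * self.contrast + 0.5
        return np.clip(out * self.brightness, 0, 1)

    def invert_mask(self, mask):
        return mask


def tta_predict(
    segmenter,
    image: np.ndarray,
    transforms: Sequence[Transform] = (Identity(),),
    group_iou: float = 0.5,
    min_support_frac: float = 0.5,
) -> List[np.ndarray]:
    """Aggregate a segmenter's predictions over transformed views.

    Each view is predicted, its instance masks are mapped back through the
    inverse geometric transform, and the pooled instances are grouped by
    single-linkage at pairwise IoU >= `group_iou`.  Groups supported by more
    than ``min_support_frac`` of the views survive; the merged mask keeps
    pixels voted for by at least half the group's members.
    """
    for tr in transforms:
        if not isinstance(tr, Transform):
            raise ValueError(f"not an invertible transform: {tr!r}")
    pooled, source = [], []
    for view_idx, tr in enumerate(transforms):
        pred = segmenter.predict(tr.apply(image))
        for m in pred:
            back = np.asarray(tr.invert_mask(np.asarray(m))).astype(bool)
            if back.any():
                pooled.append(back)
                source.append(view_idx)
    if not pooled:
        return []
    n = len(pooled)
    # single-linkage grouping at IoU >= group_iou (union-find)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if iou(pooled[i], pooled[j]) >= group_iou:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    needed = min_support_frac * len(transforms)
    merged = []
    for members in groups.values():
        support = len({source[i] for i in members})
        if support <= needed:
            continue
        votes = np.sum([pooled[i] for i in members], axis=0)
        mask = votes >= max(1, int(np.ceil(len(members) / 2)))
        if mask.any():
            merged.append(mask)
    return merged
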