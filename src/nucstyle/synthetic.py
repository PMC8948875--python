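"""Synthetic multi-domain nuclei images with ground-truth instance masks.

Real nuclei benchmarks (e.g. the 2018 Data Science Bowl collection) mix
imaging modalities: dark-background fluorescence with small or large nuclei,
H&E-like bright-field, grayscale bright-field and purple-stained tissue.
This module renders simple but visually distinct stand-ins for those
modalities: non-overlapping random ellipses on a flat (optionally speckled)
background, one colour recipe per modality.  Because the instance mask is
laid down first and rendering only paints pixels, the generator provides its
own ground truth for "style changes, content preserved".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DomainRecipe",
    "LabeledImage",
    "DEFAULT_RECIPES",
    "make_geometry",
    "render",
    "make_dataset",
]


@dataclass(frozen=True)
class DomainRecipe:
    """Rendering recipe for one imaging modality."""

    domain_id: int
    background_color: tuple  # RGB in [0, 1]
    nucleus_color: tuple  # RGB in [0, 1]
    nucleus_radius_range: tuple  # (min_px, max_px)
    noise_sd: float = 0.02
    texture_flag: bool = False

    def __post_init__(self):
        bg = np.asarray(self.background_color, dtype=float)
        nc = np.asarray(self.nucleus_color, dtype=float)
        if bg.shape != (3,) or nc.shape != (3,):
            raise ValueError("colors must be RGB 3-vectors")
        if bg.min() < 0 or bg.max() > 1 or nc.min() < 0 or nc.max() > 1:
            raise ValueError("colors must lie in [0, 1]")
        rmin, rmax = self.nucleus_radius_range
        if rmin < 2:
            raise ValueError("minimum nucleus radius must be >= 2 px")
        if not 0 <= self.noise_sd <= 1:
            raise ValueError("noise_sd must lie in [0, 1]")


@dataclass
class LabeledImage:
    """An RGB raster plus its integer instance mask.

    ``instance_mask`` uses 0 for background and contiguous labels 1..N for
    the N nuclei; no pixel belongs to two instances.
    """

    pixels: np.ndarray  # H x W x 3, float in [0, 1]
    instance_mask: np.ndarray  # H x W, int
    domain_id: Optional[int] = None
    image_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.instance_mask = np.asarray(self.instance_mask)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.pixels.shape[:2] != self.instance_mask.shape:
            raise ValueError("pixels and instance_mask disagree in H x W")

    @property
    def n_instances(self) -> int:
        return int(self.instance_mask.max())

    def instances(self) -> list:
        """Per-nucleus binary masks, label order."""
        return [self.instance_mask == k for k in range(1, self.n_instances + 1)]


# One recipe per emulated modality: (0) dark fluorescent small nuclei,
# (1) dark fluorescent large nuclei, (2) H&E-like pink/purple bright-field,
# (3) grayscale bright-field, (4) purple-stained tissue with speckle.
DEFAULT_RECIPES: tuple = (
    DomainRecipe(0, (0.02, 0.02, 0.06), (0.20, 0.50, 0.90), (3, 6), 0.02, False),
    DomainRecipe(1, (0.03, 0.05, 0.03), (0.30, 0.85, 0.45), (9, 16), 0.02, False),
    DomainRecipe(2, (0.95, 0.75, 0.85), (0.45, 0.20, 0.55), (4, 8), 0.03, False),
    DomainRecipe(3, (0.85, 0.85, 0.85), (0.25, 0.25, 0.25), (4, 8), 0.03, False),
    DomainRecipe(4, (0.75, 0.60, 0.80), (0.35, 0.15, 0.45), (4, 8), 0.04, True),
)


def _check_recipes(recipes: Sequence[DomainRecipe], side: int) -> None:
    for r in recipes:
        if r.nucleus_radius_range[1] > side / 4:
            raise ValueError(
                f"domain {r.domain_id}: max radius {r.nucleus_radius_range[1]} "
                f"exceeds side/4 = {side / 4}"
            )
    for a in recipes:
        for b in recipes:
            if a.domain_id >= b.domain_id:
                continue
            dbg = np.linalg.norm(
                np.subtract(a.background_color, b.background_color)
            )
            dnc = np.linalg.norm(np.subtract(a.nucleus_color, b.nucleus_color))
            if max(dbg, dnc) < 0.2:
                raise ValueError(
                    f"recipes {a.domain_id} and {b.domain_id} are not "
                    "separable: both colour distances < 0.2"
                )


def make_geometry(
    n_nuclei: int,
    side: int,
    radius_range: tuple,
    min_gap: int = 1,
    seed: int = 0,
    max_attempts: int = 1000,
) -> np.ndarray:
    """Place up to `n_nuclei` non-overlapping random ellipses on a side x side grid.

    Ellipses have major radius uniform in `radius_range`, axis ratio uniform
    in [0.6, 1] and uniform rotation; placement is rejection sampling with a
    `min_gap` pixel clearance, so fewer than `n_nuclei` may be placed if
    `max_attempts` proposals are exhausted.  Labels are contiguous from 1.
    """
    if side < 16:
        raise ValueError("side must be >= 16")
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    rmin, rmax = radius_range
    if rmin < 2 or rmax < rmin:
        raise ValueError("invalid radius_range")
    rng = np.random.default_rng(seed)
    mask = np.zeros((side, side), dtype=np.int32)
    yy, xx = np.mgrid[0:side, 0:side]
    placed = 0
    attempts = 0
    while placed < n_nuclei and attempts < max_attempts:
        attempts += 1
        a = rng.uniform(rmin, rmax)  # major radius
        b = a * rng.uniform(0.6, 1.0)  # minor radius
        theta = rng.uniform(0, np.pi)
        cy = rng.uniform(a, side - a)
        cx = rng.uniform(a, side - a)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        grown = (u / (a + min_gap)) ** 2 + (v / (b + min_gap)) ** 2 <= 1.0
        if not inside.any():
            continue
        if (mask[grown] != 0).any():
            continue
        placed += 1
        mask[inside] = placed
    return mask


def render(instance_mask: np.ndarray, recipe: DomainRecipe, seed: int = 0) -> LabeledImage:
    """Paint an instance mask according to a domain recipe.

    Background pixels take the background colour, nucleus pixels the nucleus
    colour with a mild per-instance brightness factor (uniform in
    [0.85, 1.15]), plus i.i.d. Gaussian noise of sd ``recipe.noise_sd`` and,
    if ``texture_flag``, a low-amplitude background speckle.  Output is
    clipped to [0, 1]; the instance mask is passed through untouched.
    """
    instance_mask = np.asarray(instance_mask)
    rng = np.random.default_rng(seed)
    h, w = instance_mask.shape
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(recipe.background_color)
    if recipe.texture_flag:
        speckle = rng.normal(0.0, 0.05, size=(h, w, 1))
        img = img + speckle
    n = int(instance_mask.max())
    nucleus_color = np.asarray(recipe.nucleus_color)
    for k in range(1, n + 1):
        brightness = rng.uniform(0.85, 1.15)
        img[instance_mask == k] = np.clip(nucleus_color * brightness, 0, 1)
    if recipe.noise_sd > 0:
        img = img + rng.normal(0.0, recipe.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return LabeledImage(
        pixels=img, instance_mask=instance_mask, domain_id=recipe.domain_id
    )


def make_dataset(
    counts_per_domain: Sequence[int],
    recipes: Optional[Sequence[DomainRecipe]] = None,
    side: int = 64,
    seed: int = 0,
    nuclei_range: tuple = (4, 12),
    min_gap: int = 1,
) -> list:
    """Generate a multi-domain dataset, ``counts_per_domain[d]`` images per domain.

    Imbalanced counts (e.g. ``(90, 10)``) are the intended use: the real
    benchmark's training set is dominated by one modality.  When `recipes`
    is omitted the first ``len(counts_per_domain)`` default recipes are used;
    an explicitly passed recipe list must match `counts_per_domain` in
    length.  Per-image seeds are spawned deterministically from the master
    seed.
    """
    if recipes is None:
        if len(counts_per_domain) > len(DEFAULT_RECIPES):
            raise ValueError("more domains requested than default recipes")
        recipes = DEFAULT_RECIPES[: len(counts_per_domain)]
    recipes = tuple(recipes)
    if len(counts_per_domain) != len(recipes):
        raise ValueError(
            f"{len(counts_per_domain)} counts but {len(recipes)} recipes"
        )
    _check_recipes(recipes, side)
    ss = np.random.SeedSequence(seed)
    total = int(np.sum(counts_per_domain))
    child_seeds = [s.generate_state(1)[0] % (2**31) for s in ss.spawn(2 * total)]
    master = np.random.default_rng(child_seeds[0])
    images = []
    i = 0
    for count, recipe in zip(counts_per_domain, recipes):
        # large-nuclei domains get fewer nuclei per frame so placement succeeds
        big = recipe.nucleus_radius_range[1] > side / 8
        lo, hi = (2, max(3, nuclei_range[1] // 3)) if big else nuclei_range
        for j in range(count):
            n_nuclei = int(master.integers(lo, hi + 1))
            gseed = child_seeds[2 * i] if 2 * i < len(child_seeds) else i
            rseed = child_seeds[2 * i + 1] if 2 * i + 1 < len(child_seeds) else i + 1
            geom = make_geometry(
                n_nuclei, side, recipe.nucleus_radius_range, min_gap, int(gseed)
            )
            lab = render(geom, recipe, int(rseed))
            lab.image_id = f"synth_d{recipe.domain_id}_{j:04d}"
            images.append(lab)
            i += 1
    return images
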