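"""DSB-layout folder I/O and Kaggle run-length encoding.

The 2018 Data Science Bowl distributes each sample as a folder

    <image_id>/
        images/<image_id>.png
        masks/<uuid>.png      (one binary raster per nucleus)

and scores submissions as a CSV of run-length encoded masks in column-major
(down-then-right), 1-based pixel order.  Readers and writers here round-trip
both layouts bit-exactly so the same code path serves real downloads and the
synthetic generator.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image
import tifffile

from .synthetic import LabeledImage

__all__ = [
    "read_dsb_folder",
    "write_dsb_folder",
    "read_dsb_root",
    "rle_encode",
    "rle_decode",
    "write_submission",
]


class MaskOverlapError(ValueError):
    """Two per-nucleus mask files claim the same pixel."""


def _load_raster(path: Path) -> np.ndarray:
    """Load a PNG/TIFF raster as float in [0,1], H x W x 3."""
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 65535.0
    elif np.issubdtype(arr.dtype, np.integer):
        # Pillow loads 16-bit grayscale PNG as int32 mode "I"
        denom = 65535.0 if arr.max() <= 65535 else np.iinfo(arr.dtype).max
        arr = arr.astype(np.float64) / denom
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return arr


def read_dsb_folder(path, force: bool = False) -> LabeledImage:
    """Read one DSB sample folder into a :class:`LabeledImage`.

    Per-nucleus binary masks are merged into a single integer instance mask
    with labels assigned in sorted-filename order.  Overlapping mask files
    raise :class:`MaskOverlapError` unless ``force=True``, in which case
    contested pixels go to the smaller-area nucleus (with a warning).
    """
    path = Path(path)
    image_files = sorted((path / "images").glob("*"))
    if not image_files:
        raise FileNotFoundError(f"no image file under {path}/images")
    pixels = _load_raster(image_files[0])
    h, w = pixels.shape[:2]
    instance_mask = np.zeros((h, w), dtype=np.int32)
    mask_dir = path / "masks"
    mask_files = sorted(mask_dir.glob("*")) if mask_dir.is_dir() else []
    areas = {}
    owner_file = {}
    for label, mf in enumerate(mask_files, start=1):
        m = np.asarray(Image.open(mf))
        if m.ndim == 3:
            m = m[..., 0]
        if m.shape != (h, w):
            raise ValueError(
                f"mask {mf.name} has shape {m.shape}, image is {(h, w)}"
            )
        binary = m > 0
        clash = binary & (instance_mask > 0)
        if clash.any():
            other = int(instance_mask[clash][0])
            if not force:
                raise MaskOverlapError(
                    f"masks {owner_file[other]} and {mf.name} overlap in "
                    f"{int(clash.sum())} pixel(s)"
                )
            # keep contested pixels on the smaller nucleus
            keep_new = binary.sum() < areas[other]
            warnings.warn(
                f"overlap between {owner_file[other]} and {mf.name}: "
                f"assigning contested pixels to the smaller nucleus"
            )
            if not keep_new:
                binary = binary & ~clash
        instance_mask[binary] = label
        areas[label] = int(binary.sum())
        owner_file[label] = mf.name
    # relabel contiguously in case a forced merge emptied a nucleus
    labels = [l for l in sorted(areas) if (instance_mask == l).any()]
    out = np.zeros_like(instance_mask)
    for new, old in enumerate(labels, start=1):
        out[instance_mask == old] = new
    return LabeledImage(pixels=pixels, instance_mask=out, image_id=path.name)


def write_dsb_folder(root, labeled: LabeledImage) -> Path:
    """Write a :class:`LabeledImage` as a DSB sample folder under `root`."""
    root = Path(root)
    folder = root / labeled.image_id
    (folder / "images").mkdir(parents=True, exist_ok=True)
    (folder / "masks").mkdir(parents=True, exist_ok=True)
    img8 = np.clip(np.round(labeled.pixels * 255), 0, 255).astype(np.uint8)
    Image.fromarray(img8).save(folder / "images" / f"{labeled.image_id}.png")
    for k in range(1, labeled.n_instances + 1):
        m = ((labeled.instance_mask == k) * 255).astype(np.uint8)
        Image.fromarray(m).save(folder / "masks" / f"{k:04d}.png")
    return folder


def read_dsb_root(root, force: bool = False) -> List[LabeledImage]:
    """Read every sample folder under a DSB-layout root, sorted by id."""
    root = Path(root)
    folders = sorted(p for p in root.iterdir() if (p / "images").is_dir())
    return [read_dsb_folder(p, force=force) for p in folders]


# ---------------------------------------------------------------------------
# Run-length encoding: column-major (down, then right), 1-based, maximal runs.
# ---------------------------------------------------------------------------


def rle_encode(binary_mask: np.ndarray) -> List[Tuple[int, int]]:
    """Encode a binary mask as sorted, maximal (start, length) runs."""
    binary_mask = np.asarray(binary_mask)
    if binary_mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    vals = np.unique(binary_mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mask values must be in {0, 1}")
    flat = binary_mask.flatten(order="F").astype(np.int8)
    padded = np.concatenate([[0], flat, [0]])
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1) + 1  # 1-based
    ends = np.flatnonzero(diff == -1) + 1
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def rle_decode(pairs: Sequence[Tuple[int, int]], shape: Tuple[int, int]) -> np.ndarray:
    """Decode (start, length) runs back into a binary mask of `shape`."""
    h, w = shape
    flat = np.zeros(h * w, dtype=np.uint8)
    for start, length in pairs:
        if length < 1 or start < 1 or start + length - 1 > h * w:
            raise ValueError(f"run ({start}, {length}) out of range for {shape}")
        flat[start - 1 : start - 1 + length] = 1
    return flat.reshape((h, w), order="F")


def write_submission(predictions: dict, out_csv) -> pd.DataFrame:
    """Write a Kaggle submission CSV (`ImageId,EncodedPixels`).

    `predictions` maps image_id -> list of binary instance masks.  Each
    instance becomes one row with space-separated start/length pairs; an
    image with no instances gets a single empty row so it is still listed.
    """
    rows = []
    for image_id in sorted(predictions):
        masks = predictions[image_id]
        if not len(masks):
            rows.append({"ImageId": image_id, "EncodedPixels": ""})
            continue
        for m in masks:
            pairs = rle_encode(np.asarray(m).astype(np.uint8))
            enc = " ".join(f"{s} {l}" for s, l in pairs)
            rows.append({"ImageId": image_id, "EncodedPixels": enc})
    df = pd.DataFrame(rows, columns=["ImageId", "EncodedPixels"])
    df.to_csv(out_csv, index=False)
    return df
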