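"""Dataset folder I/O.

Layout written by ``segmatch generate`` and read back by ``segmatch train``:

    DIR/images/NNNN.png   8-bit RGB
    DIR/masks/NNNN.png    8-bit single channel, pixel value = class id
    DIR/split.json        {"labelled": [...], "unlabelled": [...], "n_classes": L}

Masks are raw class-id PNGs (not palettized) so round-trips are bit-exact.
Images pair with masks by filename stem; an image without a mask is
unlabelled.
"""

from __future__ import annotations

import json
import os
from typing import List, Optional, Tuple

import numpy as np
from PIL import Image

from segmatch.errors import DataError
from segmatch.synthetic import SegDataset


def image_to_uint8(image: np.ndarray) -> np.ndarray:
    return np.clip(np.round(np.asarray(image, dtype=np.float64) * 255.0),
                   0, 255).astype(np.uint8)


def uint8_to_image(raw: np.ndarray) -> np.ndarray:
    return (raw.astype(np.float32) / 255.0)


def write_dataset(dataset: SegDataset, out_dir: str) -> None:
    """Write images, labelled masks, and the split manifest."""
    images_dir = os.path.join(out_dir, "images")
    masks_dir = os.path.join(out_dir, "masks")
    os.makedirs(images_dir, exist_ok=True)
    os.makedirs(masks_dir, exist_ok=True)
    for idx, (image, mask) in zip(dataset.labelled_indices, dataset.labelled):
        Image.fromarray(image_to_uint8(image)).save(
            os.path.join(images_dir, f"{idx:04d}.png"))
        Image.fromarray(mask.astype(np.uint8), mode="L").save(
            os.path.join(masks_dir, f"{idx:04d}.png"))
    for idx, image in zip(dataset.unlabelled_indices, dataset.unlabelled):
        Image.fromarray(image_to_uint8(image)).save(
            os.path.join(images_dir, f"{idx:04d}.png"))
    with open(os.path.join(out_dir, "split.json"), "w") as fh:
        json.dump({"labelled": dataset.labelled_indices,
                   "unlabelled": dataset.unlabelled_indices,
                   "n_classes": dataset.n_classes}, fh, indent=2)


def read_mask_folder(directory: str,
                     ) -> List[Tuple[np.ndarray, Optional[np.ndarray]]]:
    """Read (image, mask-or-None) pairs in stable lexicographic stem order."""
    images_dir = os.path.join(directory, "images")
    masks_dir = os.path.join(directory, "masks")
    if not os.path.isdir(images_dir):
        raise DataError(f"missing images/ directory under {directory}")
    items: List[Tuple[np.ndarray, Optional[np.ndarray]]] = []
    for name in sorted(os.listdir(images_dir)):
        stem, ext = os.path.splitext(name)
        if ext.lower() != ".png":
            continue
        image = uint8_to_image(np.asarray(Image.open(os.path.join(images_dir, name)).convert("RGB")))
        mask_path = os.path.join(masks_dir, f"{stem}.png")
        mask: Optional[np.ndarray] = None
        if os.path.isfile(mask_path):
            mask = np.asarray(Image.open(mask_path)).astype(np.int64)
            if mask.ndim != 2:
                raise DataError(f"mask {mask_path} is not single-channel")
            if mask.shape != image.shape[:2]:
                raise DataError(
                    f"mask/image size mismatch for stem {stem!r}: "
                    f"{mask.shape} vs {image.shape[:2]}")
        items.append((image, mask))
    return items


def read_dataset(directory: str) -> SegDataset:
    """Rebuild a :class:`SegDataset` from a folder written by ``write_dataset``."""
    with open(os.path.join(directory, "split.json")) as fh:
        split = json.load(fh)
    items = read_mask_folder(directory)
    stems = sorted(os.path.splitext(n)[0]
                   for n in os.listdir(os.path.join(directory, "images"))
                   if n.lower().endswith(".png"))
    by_index = {int(stem): item for stem, item in zip(stems, items)}
    labelled = []
    for idx in split["labelled"]:
        image, mask = by_index[idx]
        if mask is None:
            raise DataError(f"index {idx} listed as labelled but has no mask")
        labelled.append((image, mask))
    unlabelled = [by_index[idx][0] for idx in split["unlabelled"]]
    return SegDataset(labelled=labelled, unlabelled=unlabelled,
                      n_classes=int(split["n_classes"]),
                      labelled_indices=list(split["labelled"]),
                      unlabelled_indices=list(split["unlabelled"]))


def read_mask_dir_plain(directory: str) -> List[np.ndarray]:
    """Read all single-channel class-id PNGs of a flat directory."""
    out = []
    for name in sorted(os.listdir(directory)):
        if not name.lower().endswith(".png"):
            continue
        out.append(np.asarray(Image.open(os.path.join(directory, name))).astype(np.int64))
    return out
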