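"""Invertible weak spatial augmentations.

A weak transform is applied to an unlabelled image before the pseudo-label
forward pass; the exact inverse is then applied to the resulting logit map
so it can be compared, pixel by pixel, with the strong branch's output on
the original frame. Dihedral transforms (flips and 90-degree rotations)
invert bit-exactly on the full image; ``crop_resize`` inverts only on the
observed crop rectangle, which the validity mask records.

Coordinates are 0-based and rectangles are half-open, matching numpy
slicing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize, rotate

from segmatch.errors import ConfigurationError, GeometryError

DIHEDRAL_KINDS = ("identity", "hflip", "vflip", "rot90", "rot180", "rot270")
DEFAULT_WEAK_KINDS = DIHEDRAL_KINDS + ("crop_resize",)
ValidityMask = np.ndarray  # (H, W) bool


@dataclass(frozen=True)
class InvertibleTransform:
    """A weak spatial transform packaged with enough geometry to invert it."""

    kind: str
    params: Dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "params": self.params}, sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "InvertibleTransform":
        record = json.loads(payload)
        return cls(kind=record["kind"], params=record["params"])


def sample_weak_transform(rng: np.random.Generator,
                          image_shape: Tuple[int, int],
                          enabled: Optional[Sequence[str]] = None,
                          ) -> InvertibleTransform:
    """Draw one transform uniformly from the enabled kind set.

    Crop rectangles always cover at least half of each image dimension.
    """
    h, w = int(image_shape[0]), int(image_shape[1])
    if h < 16 or w < 16:
        raise GeometryError(f"image dims must be >= 16, got {h}x{w}")
    kinds = tuple(enabled) if enabled is not None else DEFAULT_WEAK_KINDS
    if not kinds:
        raise ConfigurationError("enabled transform set is empty")
    unknown = set(kinds) - set(DEFAULT_WEAK_KINDS) - {"rotate_free"}
    if unknown:
        raise ConfigurationError(f"unknown weak transform kinds: {sorted(unknown)}")

    kind = kinds[int(rng.integers(len(kinds)))]
    if kind == "crop_resize":
        ch = int(rng.integers((h + 1) // 2, h + 1))
        cw = int(rng.integers((w + 1) // 2, w + 1))
        r0 = int(rng.integers(0, h - ch + 1))
        c0 = int(rng.integers(0, w - cw + 1))
        return InvertibleTransform(
            "crop_resize", {"rect": [r0, r0 + ch, c0, c0 + cw], "shape": [h, w]})
    if kind == "rotate_free":
        # Opt-in only: bilinear resampling means inversion is approximate and
        # the validity mask shrinks to pixels observed by both rotations.
        angle = float(rng.uniform(0.0, 360.0))
        return InvertibleTransform("rotate_free", {"angle": angle, "shape": [h, w]})
    return InvertibleTransform(kind, {})


def _check_rect(rect: Sequence[int], shape: Tuple[int, int]) -> Tuple[int, int, int, int]:
    r0, r1, c0, c1 = (int(v) for v in rect)
    h, w = shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise GeometryError(f"crop rect {rect} outside image {h}x{w}")
    return r0, r1, c0, c1


def apply_weak(t: InvertibleTransform, x: np.ndarray) -> np.ndarray:
    """Apply the spatial transform to an (H, W[, C]) array."""
    if t.kind == "identity":
        return x.copy()
    if t.kind == "hflip":
        return x[:, ::-1].copy()
    if t.kind == "vflip":
        return x[::-1].copy()
    if t.kind == "rot90":
        return np.rot90(x, k=1, axes=(0, 1)).copy()
    if t.kind == "rot180":
        return np.rot90(x, k=2, axes=(0, 1)).copy()
    if t.kind == "rot270":
        return np.rot90(x, k=3, axes=(0, 1)).copy()
    if t.kind == "crop_resize":
        r0, r1, c0, c1 = _check_rect(t.params["rect"], x.shape[:2])
        crop = x[r0:r1, c0:c1]
        out = resize(crop.astype(np.float64), x.shape[:2] + crop.shape[2:],
                     order=1, mode="edge", anti_aliasing=False, preserve_range=True)
        return out.astype(x.dtype) if np.issubdtype(x.dtype, np.floating) else out
    if t.kind == "rotate_free":
        out = rotate(x.astype(np.float64), t.params["angle"], order=1,
                     mode="constant", cval=0.0, preserve_range=True)
        return out.astype(x.dtype) if np.issubdtype(x.dtype, np.floating) else out
    raise ConfigurationError(f"unknown transform kind {t.kind!r}")


def invert_on_logits(t: InvertibleTransform,
                     logits: np.ndarray) -> Tuple[np.ndarray, ValidityMask]:
    """Map logits computed on the transformed frame back to the original.

    Returns the re-mapped logit map and a boolean validity mask: all-true
    for dihedral kinds, true exactly on the crop rectangle for
    ``crop_resize``. Invalid pixels must be excluded from the confident set
    downstream.
    """
    if t.kind in DIHEDRAL_KINDS:
        inverse = {"identity": "identity", "hflip": "hflip", "vflip": "vflip",
                   "rot90": "rot270", "rot180": "rot180", "rot270": "rot90"}[t.kind]
        out = apply_weak(InvertibleTransform(inverse, {}), logits)
        return out, np.ones(out.shape[:2], dtype=bool)
    if t.kind == "crop_resize":
        h, w = (int(v) for v in t.params["shape"])
        if logits.shape[:2] != (h, w):
            raise GeometryError(
                f"logits shape {logits.shape[:2]} does not match transform frame {(h, w)}")
        r0, r1, c0, c1 = _check_rect(t.params["rect"], (h, w))
        back = resize(logits.astype(np.float64), (r1 - r0, c1 - c0) + logits.shape[2:],
                      order=1, mode="edge", anti_aliasing=False, preserve_range=True)
        out = np.zeros((h, w) + logits.shape[2:], dtype=np.float64)
        out[r0:r1, c0:c1] = back
        validity = np.zeros((h, w), dtype=bool)
        validity[r0:r1, c0:c1] = True
        return out, validity
    if t.kind == "rotate_free":
        h, w = (int(v) for v in t.params["shape"])
        if logits.shape[:2] != (h, w):
            raise GeometryError(
                f"logits shape {logits.shape[:2]} does not match transform frame {(h, w)}")
        angle = float(t.params["angle"])
        out = rotate(logits.astype(np.float64), -angle, order=1,
                     mode="constant", cval=0.0, preserve_range=True)
        ones = np.ones((h, w), dtype=np.float64)
        fwd = rotate(ones, angle, order=1, mode="constant", cval=0.0)
        covered = rotate(fwd, -angle, order=1, mode="constant", cval=0.0)
        return out, covered >= 0.999
    raise ConfigurationError(f"unknown transform kind {t.kind!r}")
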