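"""Seeded synthetic scenes with the structure of instrument images.

Scenes are elongated bright capsules (rotated rectangle + semicircular end
caps, optionally overlaid with a brighter specular streak) over a smooth
low-frequency textured background plus i.i.d. noise. They are not meant to
be photo-realistic — only to exercise every training and evaluation code
path without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from skimage.transform import resize

from segmatch.errors import ConfigurationError
from segmatch.rng import STREAM_SCENE, STREAM_SPLIT, substream

ImageTensor = np.ndarray  # (H, W, 3) float32 in [0, 1]
LabelMask = np.ndarray  # (H, W) int64 in {0..L-1}


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic scene distribution."""

    height: int = 64
    width: int = 64
    n_classes: int = 2
    n_objects_range: Tuple[int, int] = (1, 3)
    object_width_range: Tuple[float, float] = (4.0, 8.0)
    highlight_probability: float = 0.5
    background_texture_scale: float = 16.0
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> "SceneConfig":
        if self.height < 16 or self.width < 16:
            raise ConfigurationError(
                f"scene dimensions must be >= 16, got {self.height}x{self.width}")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2 (class 0 is background)")
        lo, hi = self.n_objects_range
        if lo < 0 or hi < lo:
            raise ConfigurationError(f"invalid n_objects_range {self.n_objects_range}")
        wlo, whi = self.object_width_range
        if wlo <= 0 or whi < wlo:
            raise ConfigurationError(f"invalid object_width_range {self.object_width_range}")
        if not 0.0 <= self.highlight_probability <= 1.0:
            raise ConfigurationError("highlight_probability must be in [0, 1]")
        if self.background_texture_scale <= 0:
            raise ConfigurationError("background_texture_scale must be > 0")
        if not 0.0 <= self.noise_sd <= 1.0:
            raise ConfigurationError("noise_sd must be in [0, 1]")
        return self


@dataclass
class SegDataset:
    """A labelled/unlabelled split of image–mask pairs.

    The labelled and unlabelled index sets are disjoint by construction;
    unlabelled masks are discarded at generation time.
    """

    labelled: List[Tuple[ImageTensor, LabelMask]]
    unlabelled: List[ImageTensor]
    n_classes: int
    labelled_indices: List[int] = field(default_factory=list)
    unlabelled_indices: List[int] = field(default_factory=list)


def _capsule_mask(height: int, width: int,
                  p0: np.ndarray, p1: np.ndarray, radius: float) -> np.ndarray:
    """Boolean mask of pixel centres within ``radius`` of segment p0–p1."""
    rr, cc = np.mgrid[0:height, 0:width]
    pts = np.stack([rr, cc], axis=-1).astype(np.float64)
    d = p1 - p0
    seg_len2 = float(d @ d)
    if seg_len2 == 0.0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / seg_len2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    return dist <= radius


def generate_scene(config: SceneConfig, index: int) -> Tuple[ImageTensor, LabelMask]:
    """Generate scene ``index`` of the distribution described by ``config``.

    Deterministic: identical (config, index) pairs give bit-identical output
    regardless of generation order.
    """
    config.validate()
    rng = substream(config.seed, STREAM_SCENE, index)
    h, w = config.height, config.width

    # Low-frequency background: coarse random grid upsampled bilinearly.
    grid = max(2, int(round(max(h, w) / config.background_texture_scale)) + 1)
    coarse = rng.uniform(-1.0, 1.0, size=(grid, grid))
    texture = resize(coarse, (h, w), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    base = rng.uniform(0.15, 0.45, size=3)
    amplitude = rng.uniform(0.05, 0.15)
    image = np.clip(base[None, None, :] + amplitude * texture[:, :, None], 0.0, 1.0)
    mask = np.zeros((h, w), dtype=np.int64)

    n_lo, n_hi = config.n_objects_range
    n_objects = int(rng.integers(n_lo, n_hi + 1))
    diag = 0.7 * max(h, w)
    for _ in range(n_objects):
        cls = int(rng.integers(1, config.n_classes))
        width_px = rng.uniform(*config.object_width_range)
        length = rng.uniform(3.0 * width_px, max(3.0 * width_px + 1.0, diag))
        centre = np.array([rng.uniform(0, h - 1), rng.uniform(0, w - 1)])
        angle = rng.uniform(0.0, np.pi)
        direction = np.array([np.sin(angle), np.cos(angle)])
        p0 = centre - 0.5 * length * direction
        p1 = centre + 0.5 * length * direction
        body = _capsule_mask(h, w, p0, p1, width_px / 2.0)

        # Metallic grey with a slight per-channel tint and axial shading.
        value = rng.uniform(0.55, 0.9)
        tint = rng.uniform(-0.05, 0.05, size=3)
        shade = rng.uniform(0.85, 1.0)
        colour = np.clip(value * shade + tint, 0.0, 1.0)
        image[body] = colour
        mask[body] = cls

        if rng.uniform() < config.highlight_probability:
            # Specular streak: thinner, brighter capsule along the same axis.
            # It alters only the image, never the mask.
            offset = rng.uniform(-width_px / 4.0, width_px / 4.0)
            normal = np.array([-direction[1], direction[0]])
            shrink = rng.uniform(0.3, 0.7)
            q0 = p0 + (1 - shrink) * 0.5 * length * direction + offset * normal
            q1 = p1 - (1 - shrink) * 0.5 * length * direction + offset * normal
            streak = _capsule_mask(h, w, q0, q1, max(0.5, width_px / 6.0)) & body
            glow = rng.uniform(0.92, 1.0)
            image[streak] = glow

    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return image, mask


def generate_dataset(config: SceneConfig, n_total: int,
                     labelled_fraction: float) -> SegDataset:
    """Generate ``n_total`` scenes and split them into labelled/unlabelled.

    ``floor(labelled_fraction * n_total)`` scenes keep their masks; the rest
    have their masks discarded. The split is a seeded permutation, so the
    labelled and unlabelled index sets are disjoint and deterministic.
    """
    config.validate()
    if n_total < 1:
        raise ConfigurationError(f"n_total must be >= 1, got {n_total}")
    if not 0.0 < labelled_fraction <= 1.0:
        raise ConfigurationError(
            f"labelled_fraction must be in (0, 1], got {labelled_fraction}")

    n_labelled = int(np.floor(labelled_fraction * n_total))
    split_rng = substream(config.seed, STREAM_SPLIT)
    order = split_rng.permutation(n_total)
    labelled_idx = sorted(int(i) for i in order[:n_labelled])
    unlabelled_idx = sorted(int(i) for i in order[n_labelled:])

    labelled = [generate_scene(config, i) for i in labelled_idx]
    unlabelled = [generate_scene(config, i)[0] for i in unlabelled_idx]
    return SegDataset(labelled=labelled, unlabelled=unlabelled,
                      n_classes=config.n_classes,
                      labelled_indices=labelled_idx,
                      unlabelled_indices=unlabelled_idx)
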