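"""Hand-crafted photometric strong augmentations.

These initialize the strong branch before adversarial refinement. Every op
is a pure intensity change (per-pixel, per-channel, or small-kernel), so
the ground-truth mask of the underlying scene is untouched by construction
— the invariance contract of the strong branch.

Op semantics follow the common photometric family on the continuous [0, 1]
domain: factor-style ops (contrast, brightness, colour, sharpness) are
identity at factor 1; posterize quantizes each channel to ``bits`` bits
(identity at 8); solarize inverts pixels strictly above the threshold
(identity at threshold 1); random noise is Gaussian with a seed fixed at
sample time so application is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy.ndimage import uniform_filter

from segmatch.errors import ConfigurationError

OP_NAMES = ("contrast", "brightness", "colour", "sharpness",
            "random_noise", "posterize", "solarize")

#: Default magnitude ranges, mild enough to stay visually plausible.
DEFAULT_MAGNITUDE_RANGES: Dict[str, Tuple[float, float]] = {
    "contrast": (0.6, 1.4),
    "brightness": (0.6, 1.4),
    "colour": (0.6, 1.4),
    "sharpness": (0.6, 1.4),
    "random_noise": (0.0, 0.05),   # Gaussian sd
    "posterize": (3, 8),           # bits, integer
    "solarize": (0.7, 1.0),        # threshold
}

N_OPS_PER_COMPOSITION = 3


@dataclass(frozen=True)
class PhotometricOp:
    name: str
    magnitude: float
    noise_seed: int = 0  # used by random_noise only

    def __post_init__(self):
        if self.name not in OP_NAMES:
            raise ConfigurationError(f"unknown photometric op {self.name!r}")


@dataclass(frozen=True)
class StrongAugmentation:
    """An ordered composition of exactly three photometric ops."""

    ops: Tuple[PhotometricOp, ...]

    def __post_init__(self):
        if len(self.ops) != N_OPS_PER_COMPOSITION:
            raise ConfigurationError(
                f"strong augmentation must compose exactly {N_OPS_PER_COMPOSITION} ops")

    def to_json(self) -> str:
        return json.dumps([
            {"name": o.name, "magnitude": o.magnitude, "noise_seed": o.noise_seed}
            for o in self.ops])

    @classmethod
    def from_json(cls, payload: str) -> "StrongAugmentation":
        return cls(tuple(PhotometricOp(**rec) for rec in json.loads(payload)))


def sample_strong_augmentation(rng: np.random.Generator,
                               magnitude_ranges: Dict[str, Tuple[float, float]] | None = None,
                               pool: Tuple[str, ...] = OP_NAMES,
                               ) -> StrongAugmentation:
    """Draw three distinct ops from the pool with uniform magnitudes."""
    ranges = dict(DEFAULT_MAGNITUDE_RANGES)
    if magnitude_ranges:
        ranges.update(magnitude_ranges)
    if len(pool) < N_OPS_PER_COMPOSITION:
        raise ConfigurationError(
            f"op pool must contain at least {N_OPS_PER_COMPOSITION} ops")
    chosen = rng.choice(len(pool), size=N_OPS_PER_COMPOSITION, replace=False)
    ops: List[PhotometricOp] = []
    for idx in chosen:
        name = pool[int(idx)]
        lo, hi = ranges[name]
        if name == "posterize":
            magnitude = float(rng.integers(int(lo), int(hi) + 1))
        else:
            magnitude = float(rng.uniform(lo, hi))
        seed = int(rng.integers(0, 2**31 - 1)) if name == "random_noise" else 0
        ops.append(PhotometricOp(name, magnitude, seed))
    return StrongAugmentation(tuple(ops))


def _apply_op(op: PhotometricOp, x: np.ndarray) -> np.ndarray:
    m = op.magnitude
    if m == 1.0 and op.name in ("brightness", "contrast", "colour", "sharpness"):
        return x
    if op.name == "brightness":
        return x * m
    if op.name == "contrast":
        mean = x.mean()
        return mean + m * (x - mean)
    if op.name == "colour":
        grey = x.mean(axis=2, keepdims=True)
        return grey + m * (x - grey)
    if op.name == "sharpness":
        blurred = uniform_filter(x, size=(3, 3, 1), mode="nearest")
        return blurred + m * (x - blurred)
    if op.name == "random_noise":
        if m == 0.0:
            return x
        noise_rng = np.random.default_rng(op.noise_seed)
        return x + noise_rng.normal(0.0, m, size=x.shape)
    if op.name == "posterize":
        bits = int(round(m))
        if bits >= 8:
            return x
        levels = 2 ** bits
        q = np.minimum(np.floor(x * levels), levels - 1)
        return q / (levels - 1)
    if op.name == "solarize":
        return np.where(x > m, 1.0 - x, x)
    raise ConfigurationError(f"unknown photometric op {op.name!r}")


def apply_strong_init(a: StrongAugmentation, x: np.ndarray) -> np.ndarray:
    """Apply the composition in order, clamping to [0, 1] after each op."""
    out = np.asarray(x, dtype=np.float64)
    if out.min() < 0.0 or out.max() > 1.0:
        raise ConfigurationError("input image must lie in [0, 1]")
    for op in a.ops:
        out = np.clip(_apply_op(op, out), 0.0, 1.0)
    return out.astype(np.float32)
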