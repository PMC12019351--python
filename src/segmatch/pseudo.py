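"""Sharpened soft pseudo-labels and the confident pixel set.

The weak branch's inverted logits are softmaxed per pixel; the confident
set keeps pixels whose *unsharpened* softmax maximum reaches the threshold
``t`` (and which are valid under the weak transform's inverse); the target
distribution is the temperature-sharpened softmax. Targets are plain
arrays, so no gradient can flow back into the weak branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from segmatch.errors import ConfigurationError, DataError

DEFAULT_TEMPERATURE = 0.5
DEFAULT_THRESHOLD = 0.8


@dataclass
class PseudoLabel:
    """Per-pixel sharpened targets plus the boolean confident set."""

    targets: np.ndarray  # (H, W, L) sharpened distributions
    confident: np.ndarray  # (H, W) bool
    threshold: float
    temperature: float


def sharpen(d: np.ndarray, T: float) -> np.ndarray:
    """Raise a distribution to the power 1/T and renormalize.

    Works on any array whose last axis is the class axis. T < 1 concentrates
    mass on the argmax; T = 1 is the identity.
    """
    if T <= 0:
        raise ConfigurationError(f"temperature must be > 0, got {T}")
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise DataError("distribution entries must be non-negative")
    total = d.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise DataError("cannot sharpen a zero vector")
    if T == 1.0:
        return d.copy()
    # Scale by the max first so tiny probabilities cannot underflow to an
    # all-zero row at small T.
    peak = d.max(axis=-1, keepdims=True)
    powered = np.where(peak > 0, (d / peak) ** (1.0 / T), 0.0)
    return powered / powered.sum(axis=-1, keepdims=True)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def make_pseudo_label(logits_w: np.ndarray,
                      validity: np.ndarray | None = None,
                      T: float = DEFAULT_TEMPERATURE,
                      t: float = DEFAULT_THRESHOLD) -> PseudoLabel:
    """Turn inverted weak-branch logits into a pseudo-label.

    Confidence is evaluated on the pre-sharpening softmax maximum; the
    stored target is the sharpened distribution. Invalid pixels (outside a
    crop rectangle, for example) are never confident.
    """
    logits_w = np.asarray(logits_w)
    if not np.all(np.isfinite(logits_w)):
        raise DataError("logits must be finite")
    if not 0.0 <= t <= 1.0:
        raise ConfigurationError(f"threshold must be in [0, 1], got {t}")
    probs = softmax(logits_w)
    confident = probs.max(axis=-1) >= t
    if validity is not None:
        confident = confident & np.asarray(validity, dtype=bool)
    targets = sharpen(probs, T)
    return PseudoLabel(targets=targets, confident=confident,
                       threshold=float(t), temperature=float(T))
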