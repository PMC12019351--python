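"""Gradient-sign refinement of the strongly-augmented images.

The attack maximizes the confidence-masked consistency loss with respect to
the input image only: the model is run in evaluation mode, its parameters
receive no gradient and are bit-identical before and after, and the
pseudo-labels are constants. Each of the K iterations takes a step of size
epsilon/K along the sign of the input gradient and re-projects into the
intersection of the epsilon-ball around the initial image and [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from segmatch.errors import ConfigurationError, GeometryError
from segmatch.losses import unsupervised_loss_grad
from segmatch.pseudo import PseudoLabel


@dataclass(frozen=True)
class AdversarialConfig:
    epsilon: float = 0.08
    steps: int = 25
    enabled: bool = True
    #: normalization statistics for the attack forward passes: "eval" uses
    #: the running averages, "batch" uses frozen batch statistics
    #: (consistent with how the pseudo-labels were produced).
    stats: str = "eval"

    def validate(self) -> "AdversarialConfig":
        if self.epsilon < 0:
            raise ConfigurationError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.steps < 1:
            raise ConfigurationError(f"steps must be >= 1, got {self.steps}")
        if self.stats not in ("batch", "eval"):
            raise ConfigurationError(f"stats must be 'batch' or 'eval', got {self.stats}")
        return self


def clip_neighbourhood(x: np.ndarray, x0: np.ndarray,
                       epsilon: float) -> np.ndarray:
    """Project ``x`` into the L-inf epsilon-ball around ``x0``, then [0, 1].

    Pixels already satisfying both constraints pass through unchanged.
    """
    x = np.asarray(x, dtype=np.float64)
    x0 = np.asarray(x0, dtype=np.float64)
    if x.shape != x0.shape:
        raise GeometryError(f"shape mismatch {x.shape} vs {x0.shape}")
    out = np.clip(x, x0 - epsilon, x0 + epsilon)
    return np.clip(out, 0.0, 1.0)


def _as_pseudo_list(pseudo) -> List[PseudoLabel]:
    return [pseudo] if isinstance(pseudo, PseudoLabel) else list(pseudo)


def ifgsm_attack(model, x0: np.ndarray,
                 pseudo: PseudoLabel | Sequence[PseudoLabel],
                 cfg: AdversarialConfig) -> np.ndarray:
    """Iterated gradient-sign attack on a batch of images.

    ``x0`` is ``(H, W, 3)`` or ``(N, H, W, 3)`` in [0, 1]; ``pseudo`` one
    pseudo-label per image. Returns the attacked batch with
    ``max |x_K - x0| <= epsilon`` guaranteed per pixel. ``sign(0) = 0`` so
    pixels with exactly zero gradient never drift.
    """
    cfg.validate()
    pseudos = _as_pseudo_list(pseudo)
    single = np.asarray(x0).ndim == 3
    x0 = np.asarray(x0, dtype=np.float64)
    if single:
        x0 = x0[None]
    if len(pseudos) != x0.shape[0]:
        raise GeometryError("one pseudo-label per image is required")

    if cfg.epsilon == 0.0 or not any(p.confident.any() for p in pseudos):
        out = clip_neighbourhood(x0, x0, 0.0)
        return out[0] if single else out

    use_batch_stats = cfg.stats == "batch" and hasattr(model, "set_freeze_stats")
    if use_batch_stats:
        model.set_freeze_stats(True)
    try:
        step = cfg.epsilon / cfg.steps
        x = x0.copy()
        for _ in range(cfg.steps):
            logits = model.forward(x.astype(np.float32), train=use_batch_stats)
            _, dlogits = unsupervised_loss_grad(pseudos, logits)
            dx = model.backward(dlogits, want_param_grads=False)
            x = clip_neighbourhood(x + step * np.sign(dx), x0, cfg.epsilon)
    finally:
        if use_batch_stats:
            model.set_freeze_stats(False)
    return x[0] if single else x


def fgsm_attack(model, x0: np.ndarray,
                pseudo: PseudoLabel | Sequence[PseudoLabel],
                epsilon: float) -> np.ndarray:
    """Single-step gradient-sign attack (the K = 1 special case)."""
    return ifgsm_attack(model, x0, pseudo,
                        AdversarialConfig(epsilon=epsilon, steps=1))
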