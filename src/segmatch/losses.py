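"""Training objectives: supervised Dice + CE, masked consistency CE, ramp-up.

Because the network stack is pure numpy, every loss comes in two flavours:
a value function matching the documented contract, and a ``*_grad`` variant
that additionally returns the analytic gradient with respect to the logits
(softmax Jacobian folded in), which the trainer and the adversarial attack
backpropagate through the network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from segmatch.errors import ConfigurationError, DataError
from segmatch.pseudo import PseudoLabel, softmax


@dataclass(frozen=True)
class LossConfig:
    rampup_epochs: int = 10
    w_max: float = 1.0
    smooth: float = 1e-6

    def validate(self) -> "LossConfig":
        if self.rampup_epochs < 1:
            raise ConfigurationError("rampup_epochs must be >= 1")
        if self.w_max <= 0:
            raise ConfigurationError("w_max must be > 0")
        if self.smooth <= 0:
            raise ConfigurationError("smooth must be > 0")
        return self


def _as_batch(logits: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    logits = np.asarray(logits, dtype=np.float64)
    y = np.asarray(y)
    if logits.ndim == 3:
        logits = logits[None]
        y = y[None]
    if logits.shape[:3] != y.shape:
        raise DataError(f"logits {logits.shape} and labels {y.shape} disagree")
    if y.min() < 0 or y.max() >= logits.shape[-1]:
        raise DataError("label values must lie in [0, n_classes)")
    return logits, y


def _soft_dice_terms(p: np.ndarray, onehot: np.ndarray, y: np.ndarray,
                     smooth: float):
    """Per-image soft Dice pieces for the foreground classes considered.

    Considered classes are the non-background classes present in the ground
    truth or in the hard prediction; classes absent from both are skipped.
    """
    L = p.shape[-1]
    pred_hard = p.argmax(axis=-1)
    classes = [c for c in range(1, L)
               if np.any(y == c) or np.any(pred_hard == c)]
    if not classes:
        return 0.0, None, classes
    num = {}
    den = {}
    for c in classes:
        g = onehot[..., c]
        pc = p[..., c]
        num[c] = 2.0 * float((pc * g).sum()) + smooth
        den[c] = float(pc.sum() + g.sum()) + smooth
    dsc = np.mean([num[c] / den[c] for c in classes])
    return 1.0 - dsc, (num, den), classes


def supervised_loss(logits: np.ndarray, y: np.ndarray,
                    smooth: float = 1e-6) -> float:
    """Soft Dice loss plus mean pixel-wise cross-entropy.

    Accepts one image ``(H, W, L)`` or a batch ``(N, H, W, L)``; the batch
    version averages the per-image loss over images.
    """
    return supervised_loss_grad(logits, y, smooth)[0]


def supervised_loss_grad(logits: np.ndarray, y: np.ndarray,
                         smooth: float = 1e-6) -> Tuple[float, np.ndarray]:
    """Value and gradient w.r.t. logits of the supervised loss."""
    logits, y = _as_batch(logits, y)
    n, h, w, L = logits.shape
    p = softmax(logits)
    onehot = np.eye(L)[y]
    npix = h * w

    total = 0.0
    grad = np.zeros_like(logits)
    for i in range(n):
        pi, gi, yi = p[i], onehot[i], y[i]
        # Cross-entropy term, mean over pixels.
        logp = np.log(np.maximum(pi, 1e-300))
        ce = -float((gi * logp).sum()) / npix
        dce_dz = (pi - gi) / npix
        # Soft Dice term over considered foreground classes.
        dice_loss, pieces, classes = _soft_dice_terms(pi, gi, yi, smooth)
        dz_dice = np.zeros_like(pi)
        if classes:
            num, den = pieces
            dl_dp = np.zeros_like(pi)
            inv = 1.0 / len(classes)
            for c in classes:
                gc = gi[..., c]
                dl_dp[..., c] = -inv * (2.0 * gc * den[c] - num[c]) / (den[c] ** 2)
            # Chain through per-pixel softmax.
            inner = (dl_dp * pi).sum(axis=-1, keepdims=True)
            dz_dice = pi * (dl_dp - inner)
        total += dice_loss + ce
        grad[i] = (dz_dice + dce_dz) / n
    return total / n, grad


def unsupervised_loss(pseudo: PseudoLabel | Sequence[PseudoLabel],
                      probs_strong: np.ndarray) -> float:
    """Confidence-masked soft cross-entropy between pseudo-labels and the
    strong branch's probabilities; exactly 0 when the confident set is empty.
    """
    pseudos = [pseudo] if isinstance(pseudo, PseudoLabel) else list(pseudo)
    probs = np.asarray(probs_strong, dtype=np.float64)
    if probs.ndim == 3:
        probs = probs[None]
    if len(pseudos) != probs.shape[0]:
        raise DataError("pseudo-label count and probability batch disagree")
    total = 0.0
    for pl, p in zip(pseudos, probs):
        mask = pl.confident
        if not mask.any():
            continue
        logp = np.log(np.maximum(p[mask], 1e-300))
        total += float(-(pl.targets[mask] * logp).sum(axis=-1).mean())
    return total / len(pseudos)


def unsupervised_loss_grad(pseudos: List[PseudoLabel],
                           logits_strong: np.ndarray,
                           ) -> Tuple[float, np.ndarray]:
    """Value and gradient w.r.t. the strong-branch logits.

    Pseudo-label targets are constants: no gradient flows into them.
    """
    logits = np.asarray(logits_strong, dtype=np.float64)
    if logits.ndim == 3:
        logits = logits[None]
    if len(pseudos) != logits.shape[0]:
        raise DataError("pseudo-label count and logit batch disagree")
    p = softmax(logits)
    n = len(pseudos)
    total = 0.0
    grad = np.zeros_like(logits)
    for i, pl in enumerate(pseudos):
        mask = pl.confident
        n_conf = int(mask.sum())
        if n_conf == 0:
            continue
        targets = pl.targets[mask]
        logp = np.log(np.maximum(p[i][mask], 1e-300))
        total += float(-(targets * logp).sum(axis=-1).mean())
        # d/dz of -sum_c t_c log softmax(z)_c is p*sum(t) - t; targets sum
        # to 1 so this is p - t, averaged over the confident set.
        grad[i][mask] = (p[i][mask] * targets.sum(axis=-1, keepdims=True)
                         - targets) / (n_conf * n)
    return total / n, grad


def rampup_weight(epoch: int, cfg: LossConfig) -> float:
    """Gaussian ramp-up of the consistency weight.

    Exactly 0 at epoch 0, ``w_max * exp(-5 (1 - epoch/rampup_epochs)^2)``
    during the ramp, and ``w_max`` from ``rampup_epochs`` onward.
    """
    if epoch < 0:
        raise ConfigurationError("epoch must be >= 0")
    if epoch == 0:
        return 0.0
    if epoch >= cfg.rampup_epochs:
        return float(cfg.w_max)
    frac = epoch / cfg.rampup_epochs
    return float(cfg.w_max * np.exp(-5.0 * (1.0 - frac) ** 2))


def total_loss(L_s: float, L_u: float, epoch: int, cfg: LossConfig) -> float:
    """Supervised loss plus ramped consistency loss."""
    return float(L_s + rampup_weight(epoch, cfg) * L_u)
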