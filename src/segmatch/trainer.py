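"""The two-pathway semi-supervised training loop.

Each step draws a mixed batch (equal numbers of labelled and unlabelled
images) and, on one shared-parameter model: computes the supervised Dice+CE
loss on the labelled half; runs the weak branch (spatial transform, forward
pass, exact inverse, sharpened pseudo-labels — no gradient); initializes the
strong branch photometrically and refines it with the gradient-sign attack
against the frozen parameters; computes the confidence-masked consistency
loss on the attacked images; and applies a single SGD update on
``L_s + w(epoch) * L_u``. There is no teacher copy: pseudo-labels and the
attack both use the current parameters.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from segmatch.adversarial import AdversarialConfig, ifgsm_attack
from segmatch.backbone import ModelConfig, SegmentationModel, build_model
from segmatch.errors import ConfigurationError, TrainingError
from segmatch.losses import (LossConfig, rampup_weight, supervised_loss_grad,
                             unsupervised_loss_grad)
from segmatch.metrics import evaluate
from segmatch.nn.optim import SGD
from segmatch.pseudo import (DEFAULT_TEMPERATURE, DEFAULT_THRESHOLD,
                             PseudoLabel, make_pseudo_label)
from segmatch.rng import STREAM_AUGMENT, STREAM_BATCH, substream
from segmatch.strong import apply_strong_init, sample_strong_augmentation
from segmatch.synthetic import SegDataset
from segmatch.weak import (DEFAULT_WEAK_KINDS, InvertibleTransform, apply_weak,
                           invert_on_logits, sample_weak_transform)

logger = logging.getLogger("segmatch")


@dataclass(frozen=True)
class PseudoConfig:
    temperature: float = DEFAULT_TEMPERATURE
    threshold: float = DEFAULT_THRESHOLD


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    lr_ini: float = 0.01
    eta: float = 0.7
    momentum: float = 0.95
    seed: int = 0
    pseudo: PseudoConfig = field(default_factory=PseudoConfig)
    adversarial: AdversarialConfig = field(default_factory=AdversarialConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    weak_enabled: bool = True
    strong_enabled: bool = True
    use_unlabelled: bool = True
    weak_kinds: Tuple[str, ...] = DEFAULT_WEAK_KINDS
    #: optional per-op overrides of the photometric magnitude ranges
    strong_augmentation: Optional[Dict[str, Tuple[float, float]]] = None

    def validate(self) -> "TrainConfig":
        if self.epochs < 0:
            raise ConfigurationError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if not 0.0 < self.eta <= 1.0:
            raise ConfigurationError("eta must be in (0, 1]")
        if not 0.0 <= self.momentum < 1.0:
            raise ConfigurationError("momentum must be in [0, 1)")
        self.adversarial.validate()
        self.loss.validate()
        return self


@dataclass
class StepReport:
    L_s: float
    L_u: float
    w: float
    attack_norm: float
    confident_fraction: float = 0.0


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Linearly decayed learning rate: ``lr_ini * (1 - epoch/epochs) * eta``."""
    if cfg.epochs == 0:
        return 0.0
    return cfg.lr_ini * (1.0 - epoch / cfg.epochs) * cfg.eta


class _CyclingSampler:
    """Draw fixed-size index batches, reshuffling each time a pool runs out."""

    def __init__(self, n: int, rng: np.random.Generator) -> None:
        self.n = n
        self.rng = rng
        self._queue: List[int] = []

    def draw(self, k: int) -> List[int]:
        out: List[int] = []
        while len(out) < k:
            if not self._queue:
                self._queue = list(self.rng.permutation(self.n))
            out.append(int(self._queue.pop()))
        return out


def make_mixed_batch(dataset: SegDataset, batch_size: int,
                     rng: np.random.Generator,
                     ) -> Tuple[List[Tuple[np.ndarray, np.ndarray]], List[np.ndarray]]:
    """One mixed batch: ``batch_size`` labelled pairs plus ``batch_size``
    unlabelled images (empty when the unlabelled pool is empty)."""
    if not dataset.labelled:
        raise ConfigurationError("labelled set must not be empty")
    lab_idx = rng.choice(len(dataset.labelled),
                         size=min(batch_size, len(dataset.labelled)),
                         replace=False)
    lab_idx = list(lab_idx) * (batch_size // len(lab_idx) + 1)
    labelled = [dataset.labelled[int(i)] for i in lab_idx[:batch_size]]
    if not dataset.unlabelled:
        return labelled, []
    unl_idx = rng.choice(len(dataset.unlabelled),
                         size=min(batch_size, len(dataset.unlabelled)),
                         replace=False)
    unl_idx = list(unl_idx) * (batch_size // len(unl_idx) + 1)
    unlabelled = [dataset.unlabelled[int(i)] for i in unl_idx[:batch_size]]
    return labelled, unlabelled


def _weak_branch(model: SegmentationModel, images: Sequence[np.ndarray],
                 cfg: TrainConfig, rng: np.random.Generator,
                 ) -> List[PseudoLabel]:
    """Pseudo-labels from the invertible weak branch (no gradient)."""
    transforms: List[InvertibleTransform] = []
    weak_images: List[np.ndarray] = []
    for img in images:
        if cfg.weak_enabled:
            t = sample_weak_transform(rng, img.shape[:2], enabled=cfg.weak_kinds)
        else:
            t = InvertibleTransform("identity", {})
        transforms.append(t)
        weak_images.append(apply_weak(t, img).astype(np.float32))

    # Group by shape so rot90 on non-square frames still batches. Batch
    # statistics (frozen: no running-stat update) are used rather than the
    # still-converging running averages, matching the supervised pathway's
    # view of the data.
    logits: List[Optional[np.ndarray]] = [None] * len(images)
    by_shape: Dict[Tuple[int, int], List[int]] = {}
    for j, img in enumerate(weak_images):
        by_shape.setdefault(img.shape[:2], []).append(j)
    model.set_freeze_stats(True)
    try:
        for idxs in by_shape.values():
            batch_logits = model.forward(
                np.stack([weak_images[j] for j in idxs]), train=True)
            for j, lg in zip(idxs, batch_logits):
                logits[j] = lg
    finally:
        model.set_freeze_stats(False)

    pseudos: List[PseudoLabel] = []
    for t, lg in zip(transforms, logits):
        inverted, validity = invert_on_logits(t, lg)
        pseudos.append(make_pseudo_label(inverted, validity,
                                         T=cfg.pseudo.temperature,
                                         t=cfg.pseudo.threshold))
    return pseudos


def train_step(model: SegmentationModel, optimizer: SGD,
               batches: Tuple[Sequence[Tuple[np.ndarray, np.ndarray]],
                              Sequence[np.ndarray]],
               cfg: TrainConfig, epoch: int,
               rng: np.random.Generator) -> StepReport:
    """One optimizer update on a mixed batch."""
    labelled, unlabelled = batches
    lr = lr_schedule(epoch, cfg)
    w = rampup_weight(epoch, cfg.loss)

    model.zero_grad()
    x_l = np.stack([img for img, _ in labelled])
    y_l = np.stack([mask for _, mask in labelled])
    logits_l = model.forward(x_l, train=True)
    L_s, dlogits_l = supervised_loss_grad(logits_l, y_l, smooth=cfg.loss.smooth)
    model.backward(dlogits_l, want_param_grads=True)

    L_u = 0.0
    attack_norm = 0.0
    confident_fraction = 0.0
    if unlabelled:
        pseudos = _weak_branch(model, unlabelled, cfg, rng)
        confident_fraction = float(np.mean([p.confident.mean() for p in pseudos]))

        if cfg.strong_enabled:
            x_s0 = np.stack([
                apply_strong_init(
                    sample_strong_augmentation(
                        rng, magnitude_ranges=cfg.strong_augmentation),
                    img)
                for img in unlabelled])
        else:
            x_s0 = np.stack(unlabelled).astype(np.float32)

        if cfg.adversarial.enabled and cfg.adversarial.epsilon > 0:
            x_s = ifgsm_attack(model, x_s0.astype(np.float64), pseudos,
                               cfg.adversarial)
            attack_norm = float(np.max(np.abs(x_s - x_s0)))
        else:
            x_s = x_s0

        logits_s = model.forward(x_s.astype(np.float32), train=True)
        L_u, dlogits_u = unsupervised_loss_grad(pseudos, logits_s)
        if w > 0.0:
            model.backward(w * dlogits_u, want_param_grads=True)

    total = L_s + w * L_u
    if not np.isfinite(total):
        raise TrainingError(
            f"non-finite loss at epoch {epoch}: L_s={L_s}, L_u={L_u}, w={w}")

    optimizer.step(model.grads(), lr)
    model.zero_grad()
    return StepReport(L_s=float(L_s), L_u=float(L_u), w=float(w),
                      attack_norm=attack_norm,
                      confident_fraction=confident_fraction)


def steps_per_epoch(dataset: SegDataset, cfg: TrainConfig) -> int:
    """Steps are set by the larger (unlabelled) pool so a supervised-only
    baseline on the same dataset gets an identical update budget."""
    pool = len(dataset.unlabelled) if dataset.unlabelled else len(dataset.labelled)
    return max(1, int(np.ceil(pool / cfg.batch_size)))


def train(dataset: SegDataset, cfg: TrainConfig,
          model_cfg: Optional[ModelConfig] = None,
          val_set: Optional[Sequence[Tuple[np.ndarray, np.ndarray]]] = None,
          out_dir: Optional[str] = None,
          ) -> Tuple[SegmentationModel, List[Dict]]:
    """Run the full training loop; fully reproducible under ``cfg.seed``.

    Returns the trained model and the per-epoch history (also written as
    ``history.csv`` inside ``out_dir`` when given).
    """
    cfg.validate()
    if not dataset.labelled:
        raise ConfigurationError("labelled set must not be empty")
    if model_cfg is None:
        model_cfg = ModelConfig(n_classes=dataset.n_classes, seed=cfg.seed)
    model = build_model(model_cfg)
    optimizer = SGD(model.parameters(), momentum=cfg.momentum)

    batch_rng = substream(cfg.seed, STREAM_BATCH)
    augment_rng = substream(cfg.seed, STREAM_AUGMENT)
    lab_sampler = _CyclingSampler(len(dataset.labelled), batch_rng)
    unl_sampler = (_CyclingSampler(len(dataset.unlabelled), batch_rng)
                   if dataset.unlabelled and cfg.use_unlabelled else None)

    n_steps = steps_per_epoch(dataset, cfg)
    history: List[Dict] = []
    for epoch in range(cfg.epochs):
        sums = np.zeros(4)
        for _ in range(n_steps):
            labelled = [dataset.labelled[i]
                        for i in lab_sampler.draw(cfg.batch_size)]
            unlabelled = ([dataset.unlabelled[i]
                           for i in unl_sampler.draw(cfg.batch_size)]
                          if unl_sampler else [])
            report = train_step(model, optimizer, (labelled, unlabelled),
                                cfg, epoch, augment_rng)
            sums += (report.L_s, report.L_u, report.attack_norm,
                     report.confident_fraction)
        row = {"epoch": epoch,
               "lr": lr_schedule(epoch, cfg),
               "L_s": sums[0] / n_steps,
               "L_u": sums[1] / n_steps,
               "w": rampup_weight(epoch, cfg.loss),
               "attack_linf": sums[2] / n_steps,
               "confident_fraction": sums[3] / n_steps,
               "val_dice": None}
        if val_set is not None:
            row["val_dice"] = evaluate(model, val_set).dice
        history.append(row)
        logger.info(
            "epoch %d lr %.5f L_s %.4f L_u %.4f w %.3f attack_linf %.4f "
            "conf %.3f val_dice %s", epoch, row["lr"], row["L_s"], row["L_u"],
            row["w"], row["attack_linf"], row["confident_fraction"],
            "-" if row["val_dice"] is None else f"{row['val_dice']:.4f}")

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        path = os.path.join(out_dir, "history.csv")
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=[
                "epoch", "lr", "L_s", "L_u", "w", "attack_linf",
                "confident_fraction", "val_dice"])
            writer.writeheader()
            writer.writerows({k: repr(v) if isinstance(v, float) else v
                              for k, v in row.items()} for row in history)
    return model, history


def supervised_config(cfg: TrainConfig) -> TrainConfig:
    """The matched supervised-only baseline: same budget, unlabelled unused."""
    return replace(cfg, use_unlabelled=False)
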