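"""Augmentation-removal ablation grid and paired baseline runs."""

from __future__ import annotations

import dataclasses
from typing import Dict, Sequence, Tuple

import numpy as np

from segmatch.config import RunConfig
from segmatch.metrics import evaluate
from segmatch.synthetic import SceneConfig, generate_dataset, generate_scene
from segmatch.trainer import TrainConfig, supervised_config, train

VARIANTS = ("full", "no_adversarial", "no_strong", "no_weak", "supervised")


def variant_config(train_cfg: TrainConfig, variant: str) -> TrainConfig:
    if variant == "full":
        return train_cfg
    if variant == "no_adversarial":
        return dataclasses.replace(
            train_cfg,
            adversarial=dataclasses.replace(train_cfg.adversarial, enabled=False))
    if variant == "no_strong":
        return dataclasses.replace(train_cfg, strong_enabled=False)
    if variant == "no_weak":
        return dataclasses.replace(train_cfg, weak_enabled=False)
    if variant == "supervised":
        return supervised_config(train_cfg)
    raise ValueError(f"unknown ablation variant {variant!r}")


def shifted_condition(scene: SceneConfig) -> SceneConfig:
    """A degraded imaging condition never seen during training.

    Mirrors the evaluation protocol of surgical-segmentation challenges whose
    combined test sets include procedures absent from training: stronger
    noise and finer background texture at unchanged object geometry. Robust
    methods (adversarially refined augmentation in particular) should
    degrade less here.
    """
    return dataclasses.replace(scene, noise_sd=min(1.0, scene.noise_sd + 0.07),
                               background_texture_scale=scene.background_texture_scale / 2,
                               seed=scene.seed + 1000)


def make_test_set(scene: SceneConfig, n_train: int, n_test: int):
    """Held-out scenes: half from the training distribution (indices beyond
    the training range), half from the shifted unseen condition."""
    seen = [generate_scene(scene, n_train + i) for i in range(n_test)]
    unseen_scene = shifted_condition(scene)
    unseen = [generate_scene(unseen_scene, i) for i in range(n_test)]
    return seen + unseen


def run_variant(cfg: RunConfig, variant: str, seed: int) -> float:
    """Train one variant at one seed; returns Dice on the mixed held-out set."""
    scene = dataclasses.replace(cfg.scene, seed=seed)
    dataset = generate_dataset(scene, cfg.data.n_total, cfg.data.labelled_fraction)
    test_set = make_test_set(scene, cfg.data.n_total, cfg.data.n_test)
    train_cfg = variant_config(dataclasses.replace(cfg.train, seed=seed), variant)
    model_cfg = dataclasses.replace(cfg.model, seed=seed,
                                    n_classes=cfg.scene.n_classes)
    model, _ = train(dataset, train_cfg, model_cfg=model_cfg)
    return evaluate(model, test_set).dice


def run_ablation(cfg: RunConfig, n_seeds: int = 3,
                 variants: Sequence[str] = VARIANTS,
                 base_seed: int = 0) -> Dict:
    """Mean held-out Dice per variant over ``n_seeds`` paired seeds."""
    per_seed: Dict[str, Dict[int, float]] = {v: {} for v in variants}
    for variant in variants:
        for s in range(n_seeds):
            seed = base_seed + s
            per_seed[variant][seed] = run_variant(cfg, variant, seed)
    mean_dice = {v: float(np.mean(list(scores.values())))
                 for v, scores in per_seed.items()}
    return {"per_seed": {v: {str(k): val for k, val in scores.items()}
                         for v, scores in per_seed.items()},
            "mean_dice": mean_dice,
            "n_seeds": n_seeds}
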