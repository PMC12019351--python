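import dataclasses

import numpy as np
import pytest

from segmatch.adversarial import AdversarialConfig
from segmatch.backbone import ModelConfig, build_model
from segmatch.losses import LossConfig
from segmatch.synthetic import SceneConfig, generate_dataset, generate_scene
from segmatch.trainer import TrainConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_scene_config():
    return SceneConfig(height=32, width=32, n_classes=2, seed=7)


@pytest.fixture
def tiny_model():
    return build_model(ModelConfig(depth=2, base_channels=4, n_classes=2, seed=0))


# ---------------------------------------------------------------------------
# Shared behavioural-run grid (semi-supervised gain + ablation ordering).
# One training run per (variant, seed); cached for the whole session because
# these runs dominate suite wall time.
# ---------------------------------------------------------------------------

BEHAVE_SEEDS = (0, 1, 2)
BEHAVE_SCALE = dict(height=32, width=32, n_total=80, labelled_fraction=0.10,
                    n_test=30, epochs=20)


def behavioural_run(variant: str, seed: int) -> float:
    """Train one variant at desk-test scale; returns held-out Dice."""
    from segmatch.ablation import run_variant
    from segmatch.config import DataConfig, RunConfig

    scene = SceneConfig(height=BEHAVE_SCALE["height"],
                        width=BEHAVE_SCALE["width"], n_classes=2, seed=seed)
    cfg = RunConfig(
        scene=scene,
        data=DataConfig(n_total=BEHAVE_SCALE["n_total"],
                        labelled_fraction=BEHAVE_SCALE["labelled_fraction"],
                        n_test=BEHAVE_SCALE["n_test"]),
        model=ModelConfig(depth=2, base_channels=8, n_classes=2, seed=seed),
        train=TrainConfig(
            epochs=BEHAVE_SCALE["epochs"], batch_size=8, seed=seed,
            adversarial=AdversarialConfig(epsilon=0.08, steps=3),
            loss=LossConfig(rampup_epochs=10, w_max=1.0)))
    return run_variant(cfg, variant, seed)


@pytest.fixture(scope="session")
def behavioural_grid():
    """Held-out Dice for each (variant, seed) of the behavioural twin runs."""
    results = {}
    for variant in ("supervised", "full", "no_adversarial", "no_strong"):
        for seed in BEHAVE_SEEDS:
            results[(variant, seed)] = behavioural_run(variant, seed)
    return results
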