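import dataclasses

import numpy as np
import pytest

from segmatch.adversarial import AdversarialConfig
from segmatch.backbone import ModelConfig, build_model
from segmatch.errors import ConfigurationError
from segmatch.losses import LossConfig, unsupervised_loss
from segmatch.nn.optim import SGD
from segmatch.pseudo import make_pseudo_label, softmax
from segmatch.rng import STREAM_AUGMENT, substream
from segmatch.synthetic import SceneConfig, generate_dataset
from segmatch.trainer import (PseudoConfig, TrainConfig, lr_schedule,
                              make_mixed_batch, steps_per_epoch,
                              supervised_config, train, train_step)

FAST = dict(epochs=3, batch_size=4,
            adversarial=AdversarialConfig(epsilon=0.05, steps=2),
            loss=LossConfig(rampup_epochs=2))


def tiny_dataset(seed=0, n_total=12, frac=0.5, size=16):
    scene = SceneConfig(height=size, width=size, seed=seed)
    return generate_dataset(scene, n_total, frac)


class TestLrSchedule:
    def test_printed_policy_constants(self):
        cfg = TrainConfig(epochs=1000, lr_ini=0.01, eta=0.7)
        assert lr_schedule(0, cfg) == pytest.approx(0.007)

    def test_final_epoch_is_zero(self):
        cfg = TrainConfig(epochs=40)
        assert lr_schedule(40, cfg) == 0.0

    def test_midpoint(self):
        cfg = TrainConfig(epochs=100, lr_ini=0.01, eta=0.7)
        assert lr_schedule(50, cfg) == pytest.approx(0.0035)


class TestMakeMixedBatch:
    def test_equal_halves_with_cycling(self, rng):
        ds = tiny_dataset(n_total=100, frac=0.1)
        labelled, unlabelled = make_mixed_batch(ds, 8, rng)
        assert len(labelled) == 8
        assert len(unlabelled) == 8

    def test_empty_unlabelled_pool(self, rng):
        ds = tiny_dataset(n_total=6, frac=1.0)
        labelled, unlabelled = make_mixed_batch(ds, 4, rng)
        assert len(labelled) == 4
        assert unlabelled == []

    def test_seeded_batches_reproducible(self):
        ds = tiny_dataset()
        a = make_mixed_batch(ds, 4, np.random.default_rng(9))
        b = make_mixed_batch(ds, 4, np.random.default_rng(9))
        for (ia, _), (ib, _) in zip(a[0], b[0]):
            assert np.array_equal(ia, ib)

    def test_empty_labelled_rejected(self, rng):
        ds = tiny_dataset()
        ds.labelled = []
        with pytest.raises(ConfigurationError):
            make_mixed_batch(ds, 4, rng)


class TestTrainStep:
    def _setup(self, seed=0, **overrides):
        ds = tiny_dataset(seed=seed)
        cfg = TrainConfig(seed=seed, **{**FAST, **overrides})
        model = build_model(ModelConfig(depth=2, base_channels=4,
                                        n_classes=2, seed=seed))
        opt = SGD(model.parameters(), momentum=cfg.momentum)
        return ds, cfg, model, opt

    def test_epoch_zero_update_is_supervised_direction(self):
        """With w(0)=0 the unlabelled branch must not move parameters."""
        ds, cfg, model, opt = self._setup()
        labelled, unlabelled = make_mixed_batch(ds, 4, np.random.default_rng(0))

        twin = build_model(ModelConfig(depth=2, base_channels=4,
                                       n_classes=2, seed=0))
        twin_opt = SGD(twin.parameters(), momentum=cfg.momentum)
        train_step(twin, twin_opt, (labelled, []), cfg, epoch=0,
                   rng=substream(0, STREAM_AUGMENT))

        train_step(model, opt, (labelled, unlabelled), cfg, epoch=0,
                   rng=substream(0, STREAM_AUGMENT))
        for (_, a), (_, b) in zip(model.parameters(), twin.parameters()):
            np.testing.assert_allclose(a, b, rtol=0, atol=1e-6)

    def test_report_fields(self):
        ds, cfg, model, opt = self._setup()
        batches = make_mixed_batch(ds, 4, np.random.default_rng(1))
        report = train_step(model, opt, batches, cfg, epoch=1,
                            rng=np.random.default_rng(2))
        assert report.L_s >= 0 and report.L_u >= 0
        assert 0 <= report.attack_norm <= cfg.adversarial.epsilon + 1e-9
        assert report.w == pytest.approx(np.exp(-5 * 0.25))

    def test_disabled_attack_reports_zero_norm(self):
        ds, cfg, model, opt = self._setup(
            adversarial=AdversarialConfig(enabled=False))
        batches = make_mixed_batch(ds, 4, np.random.default_rng(1))
        report = train_step(model, opt, batches, cfg, epoch=1,
                            rng=np.random.default_rng(2))
        assert report.attack_norm == 0.0

    def test_all_disabled_lu_is_self_consistency(self):
        """With identity branches and t=0, L_u equals the soft CE between the
        model's sharpened eval prediction and its train-mode prediction."""
        ds, cfg, model, opt = self._setup(
            weak_enabled=False, strong_enabled=False,
            adversarial=AdversarialConfig(enabled=False),
            pseudo=PseudoConfig(threshold=0.0, temperature=0.5))
        labelled, unlabelled = make_mixed_batch(ds, 4, np.random.default_rng(1))

        x_u = np.stack(unlabelled)
        report = train_step(model, opt, (labelled, unlabelled), cfg, epoch=1,
                            rng=np.random.default_rng(2))
        # replay the step's forward passes on an identically-seeded twin:
        # supervised train-mode pass first (it moves BN running statistics),
        # then the weak eval-mode pass, then the strong train-mode pass on
        # the raw unlabelled images
        twin = build_model(ModelConfig(depth=2, base_channels=4,
                                       n_classes=2, seed=0))
        x_l = np.stack([img for img, _ in labelled])
        twin.forward(x_l, train=True)
        twin.set_freeze_stats(True)
        logits_weak = twin.forward(x_u, train=True)
        twin.set_freeze_stats(False)
        pseudos = [make_pseudo_label(lg, None, T=0.5, t=0.0)
                   for lg in logits_weak]
        logits_train = twin.forward(x_u.astype(np.float32), train=True)
        expected = unsupervised_loss(pseudos, softmax(logits_train))
        assert report.L_u == pytest.approx(expected, rel=1e-5)


class TestTrain:
    def test_zero_epochs_returns_initial_model(self):
        ds = tiny_dataset()
        cfg = TrainConfig(epochs=0)
        model, history = train(ds, cfg,
                               model_cfg=ModelConfig(depth=1, base_channels=4,
                                                     n_classes=2, seed=3))
        assert history == []
        assert model.state_hash() == build_model(
            ModelConfig(depth=1, base_channels=4, n_classes=2, seed=3)).state_hash()

    def test_same_seed_identical_history(self):
        ds = tiny_dataset()
        cfg = TrainConfig(seed=5, **FAST)
        mc = ModelConfig(depth=1, base_channels=4, n_classes=2, seed=5)
        model1, h1 = train(ds, cfg, model_cfg=mc)
        model2, h2 = train(ds, cfg, model_cfg=mc)
        assert h1 == h2
        assert model1.state_hash() == model2.state_hash()

    def test_history_csv_written(self, tmp_path):
        ds = tiny_dataset()
        cfg = TrainConfig(seed=5, **{**FAST, "epochs": 2})
        train(ds, cfg, model_cfg=ModelConfig(depth=1, base_channels=4,
                                             n_classes=2, seed=5),
              out_dir=str(tmp_path))
        lines = (tmp_path / "history.csv").read_text().strip().splitlines()
        assert lines[0].startswith("epoch,lr,L_s,L_u,w,attack_linf")
        assert len(lines) == 3

    def test_supervised_only_degeneration(self):
        """With no unlabelled data the loop is bit-identical to training on
        the same config with unlabelled use disabled."""
        scene = SceneConfig(height=16, width=16, seed=2)
        full = generate_dataset(scene, 8, 1.0)
        cfg = TrainConfig(seed=2, **FAST)
        mc = ModelConfig(depth=1, base_channels=4, n_classes=2, seed=2)
        m1, h1 = train(full, cfg, model_cfg=mc)
        m2, h2 = train(full, supervised_config(cfg), model_cfg=mc)
        assert m1.state_hash() == m2.state_hash()
        assert h1 == h2

    def test_one_optimizer_step_per_train_step(self):
        """Parameters move once per step regardless of attack iterations."""
        ds = tiny_dataset()
        cfg = TrainConfig(seed=1, **FAST)
        model = build_model(ModelConfig(depth=1, base_channels=4,
                                        n_classes=2, seed=1))
        opt = SGD(model.parameters(), momentum=0.0)
        batches = make_mixed_batch(ds, 4, np.random.default_rng(0))
        before = {n: p.copy() for n, p in model.parameters()}
        train_step(model, opt, batches, cfg, epoch=1,
                   rng=np.random.default_rng(3))
        # velocity equals -lr * grad exactly after a single step from rest
        moved = 0.0
        for name, p in model.parameters():
            np.testing.assert_allclose(p - before[name],
                                       opt.velocity[name], rtol=0, atol=1e-7)
            moved += np.abs(p - before[name]).sum()
        assert moved > 0.0

    def test_steps_per_epoch_uses_larger_pool(self):
        ds = tiny_dataset(n_total=100, frac=0.1)
        cfg = TrainConfig(batch_size=8)
        assert steps_per_epoch(ds, cfg) == int(np.ceil(90 / 8))
        assert steps_per_epoch(ds, supervised_config(cfg)) == int(np.ceil(90 / 8))

    def test_shared_parameters_no_teacher_copy(self):
        """The same arrays are updated by the optimizer and used by every
        branch: there is no EMA/teacher parameter set anywhere."""
        ds = tiny_dataset()
        cfg = TrainConfig(seed=1, **FAST)
        model = build_model(ModelConfig(depth=1, base_channels=4,
                                        n_classes=2, seed=1))
        opt = SGD(model.parameters(), momentum=cfg.momentum)
        ids_before = {n: id(p) for n, p in model.parameters()}
        batches = make_mixed_batch(ds, 4, np.random.default_rng(0))
        train_step(model, opt, batches, cfg, epoch=1,
                   rng=np.random.default_rng(3))
        assert {n: id(p) for n, p in model.parameters()} == ids_before
        assert {n: id(p) for n, p in opt.parameters} == ids_before
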