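import numpy as np
import pytest

from oracles import oracle_boundary, oracle_nsd
from segmatch.backbone import ModelConfig, build_model
from segmatch.errors import DataError
from segmatch.metrics import (MetricReport, boundary_pixels, dice_score,
                              evaluate, multiclass_iou_report, nsd_score,
                              scaled_tolerance)
from segmatch.synthetic import SceneConfig, generate_scene


def oracle_dice(pred, gt):
    inter = sum(1 for i in range(pred.shape[0]) for j in range(pred.shape[1])
                if pred[i, j] and gt[i, j])
    total = int(np.sum(pred)) + int(np.sum(gt))
    return 1.0 if total == 0 else 2.0 * inter / total


class TestDice:
    def test_perfect_overlap(self):
        m = np.array([[1, 0], [1, 1]])
        assert dice_score(m, m, cls=1) == 1.0

    def test_disjoint_masks(self):
        a = np.array([[1, 0], [0, 0]])
        b = np.array([[0, 0], [0, 1]])
        assert dice_score(a, b, cls=1) == 0.0

    def test_hand_counted_toy(self):
        pred = np.zeros((4, 4), dtype=int)
        gt = np.zeros((4, 4), dtype=int)
        pred[0, 0:4] = 1          # |P| = 4
        gt[0, 2:4] = 1
        gt[1, 2:4] = 1            # |G| = 4, |P∩G| = 2
        assert dice_score(pred, gt, cls=1) == 0.5

    def test_both_empty_is_one(self):
        z = np.zeros((3, 3), dtype=int)
        assert dice_score(z, z, cls=1) == 1.0

    def test_matches_oracle_on_random_masks(self, rng):
        for _ in range(50):
            a = rng.integers(0, 2, size=(5, 5))
            b = rng.integers(0, 2, size=(5, 5))
            assert dice_score(a, b, cls=1) == pytest.approx(oracle_dice(a, b))


class TestNsd:
    def test_identical_masks(self, rng):
        m = rng.integers(0, 2, size=(8, 8))
        for tau in (0.0, 1.0, 5.0):
            assert nsd_score(m, m, tau) == 1.0

    def test_huge_tolerance(self, rng):
        a = np.zeros((8, 8), dtype=int)
        b = np.zeros((8, 8), dtype=int)
        a[0, 0] = 1
        b[7, 7] = 1
        assert nsd_score(a, b, tau=20.0) == 1.0

    def test_empty_conventions(self):
        z = np.zeros((4, 4), dtype=int)
        m = np.eye(4, dtype=int)
        assert nsd_score(z, z, 1.0) == 1.0
        assert nsd_score(m, z, 1.0) == 0.0
        assert nsd_score(z, m, 1.0) == 0.0

    def test_boundary_definition_matches_oracle(self, rng):
        for _ in range(30):
            m = rng.integers(0, 2, size=(6, 6)).astype(bool)
            ours = {tuple(p) for p in np.argwhere(boundary_pixels(m))}
            assert ours == set(oracle_boundary(m))

    def test_random_3x3_pairs_against_bruteforce(self, rng):
        # the exhaustive 2^9 x 2^9 sweep lives in the acceptance suite;
        # here a random sample keeps the unit tests fast
        for _ in range(300):
            a = rng.integers(0, 2, size=(3, 3))
            b = rng.integers(0, 2, size=(3, 3))
            for tau in (0.0, 1.0, 2.0):
                assert nsd_score(a, b, tau) == pytest.approx(
                    oracle_nsd(a, b, tau), abs=1e-12)


class TestMulticlassIou:
    def test_perfect_predictions(self, rng):
        gts = [rng.integers(0, 3, size=(4, 4)) for _ in range(3)]
        ch, isi, mc, per = multiclass_iou_report(gts, gts, 3)
        assert ch == isi == mc == 1.0

    def test_spurious_class_lowers_isi_only(self):
        gt = np.zeros((4, 4), dtype=int)
        gt[:2] = 1
        pred = gt.copy()
        pred[3, 3] = 2  # spurious class absent from GT
        ch, isi, mc, per = multiclass_iou_report([pred], [gt], 3)
        assert ch == 1.0  # class 1 only, predicted perfectly... almost
        assert isi < ch
        assert per[2] == 0.0

    def test_two_image_hand_computed_fixture(self):
        # image 1: gt has class 1 (4 px), pred covers 2 of them plus 2 extra
        gt1 = np.zeros((4, 4), dtype=int)
        gt1[0, :] = 1
        pred1 = np.zeros((4, 4), dtype=int)
        pred1[0, :2] = 1
        pred1[1, :2] = 1
        iou1_c1 = 2 / 6  # inter 2, union 6
        # image 2: gt has classes 1 and 2; pred nails class 2, misses class 1,
        # and hallucinates class 3
        gt2 = np.zeros((4, 4), dtype=int)
        gt2[0, :2] = 1
        gt2[3, :] = 2
        pred2 = np.zeros((4, 4), dtype=int)
        pred2[3, :] = 2
        pred2[1, 2] = 3
        iou2_c1, iou2_c2, iou2_c3 = 0.0, 1.0, 0.0

        ch, isi, mc, per = multiclass_iou_report([pred1, pred2], [gt1, gt2], 4)
        expected_ch = np.mean([iou1_c1, np.mean([iou2_c1, iou2_c2])])
        expected_isi = np.mean([iou1_c1, np.mean([iou2_c1, iou2_c2, iou2_c3])])
        assert ch == pytest.approx(expected_ch, abs=1e-12)
        assert isi == pytest.approx(expected_isi, abs=1e-12)
        # mc: class 1 appears in both images, classes 2, 3 in image 2 only
        expected_per = {1: np.mean([iou1_c1, iou2_c1]), 2: iou2_c2, 3: iou2_c3}
        assert per == pytest.approx(expected_per, abs=1e-12)
        assert mc == pytest.approx(np.mean(list(expected_per.values())), abs=1e-12)

    def test_ch_at_least_isi_under_spurious_additions(self, rng):
        for _ in range(20):
            gt = rng.integers(0, 3, size=(6, 6))
            pred = gt.copy()
            # corrupt some background pixels into a class absent from gt
            pred[gt == 0] = rng.choice([0, 3], size=(pred[gt == 0]).shape)
            ch, isi, _, _ = multiclass_iou_report([pred], [gt], 4)
            assert ch >= isi - 1e-12

    def test_relabelling_symmetry(self, rng):
        gt = rng.integers(0, 3, size=(6, 6))
        pred = rng.integers(0, 3, size=(6, 6))
        swap = {0: 0, 1: 2, 2: 1}
        gt2 = np.vectorize(swap.get)(gt)
        pred2 = np.vectorize(swap.get)(pred)
        a = multiclass_iou_report([pred], [gt], 3)
        b = multiclass_iou_report([pred2], [gt2], 3)
        assert a[0] == pytest.approx(b[0])
        assert a[1] == pytest.approx(b[1])
        assert a[2] == pytest.approx(b[2])

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            multiclass_iou_report([np.zeros((2, 2))], [], 2)


class _FixedPredictionModel:
    """Stand-in model emitting one-hot logits for a fixed mask per image."""

    def __init__(self, masks, n_classes):
        from segmatch.backbone import ModelConfig
        self.cfg = ModelConfig(n_classes=n_classes)
        self._masks = list(masks)
        self._cursor = 0

    def forward(self, x, train=False):
        out = []
        for _ in range(x.shape[0]):
            mask = self._masks[self._cursor % len(self._masks)]
            self._cursor += 1
            out.append(np.eye(self.cfg.n_classes)[mask] * 10.0)
        return np.stack(out)


class TestEvaluate:
    def test_perfect_model_scores_one(self):
        rng = np.random.default_rng(0)
        gts = []
        for _ in range(3):
            m = np.zeros((16, 16), dtype=int)
            r, c = rng.integers(2, 10, size=2)
            m[r:r + 4, c:c + 4] = 1
            gts.append(m)
        images = [np.zeros((16, 16, 3), dtype=np.float32) for _ in gts]
        model = _FixedPredictionModel(gts, n_classes=2)
        report = evaluate(model, list(zip(images, gts)), tolerance=1.0)
        assert report.dice == 1.0
        assert report.nsd == 1.0
        assert report.ch_iou == 1.0

    def test_constant_background_model_scores_zero(self):
        gt = np.zeros((16, 16), dtype=int)
        gt[4:10, 4:10] = 1
        model = _FixedPredictionModel([np.zeros((16, 16), dtype=int)], 2)
        image = np.zeros((16, 16, 3), dtype=np.float32)
        report = evaluate(model, [(image, gt)], tolerance=1.0)
        assert report.dice == 0.0
        assert report.nsd == 0.0

    def test_report_fields_bounded(self, rng, tiny_model):
        scenes = [generate_scene(SceneConfig(height=32, width=32, seed=s), 0)
                  for s in range(10)]
        report = evaluate(tiny_model, scenes)
        assert isinstance(report, MetricReport)
        for value in (report.dice, report.nsd, report.ch_iou,
                      report.isi_iou, report.mc_iou):
            assert 0.0 <= value <= 1.0

    def test_tolerance_scales_with_width(self):
        assert scaled_tolerance(512) == 13.0
        assert scaled_tolerance(256) == pytest.approx(6.0)
        assert scaled_tolerance(32) == 1.0
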