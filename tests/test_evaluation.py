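"""Matching, cluster credit, precision/recall and color statistics."""

import itertools

import numpy as np
import pytest

from fnfpepper import (
    EvalCounts,
    EvalParams,
    GroundTruthObject,
    MaturityClass,
    RGBImage,
    cluster_credit_counts,
    evaluate_dataset,
    iou,
    labeled_pixel_stats,
    match_detections,
    precision_recall,
    sweep_thresholds,
    DetectorParams,
    GeneratorConfig,
    simulate_scenes,
)
from fnfpepper.detector import Detection
from fnfpepper.imaging import HSVImage, hsv_to_rgb

CANVAS = (60, 80)


def det_from_box(x0, y0, x1, y1):
    mask = np.zeros(CANVAS, bool)
    mask[y0:y1, x0:x1] = True
    return Detection(blob_mask=mask, area=int(mask.sum()), bbox=(x0, y0, x1, y1))


def truth_from_box(x0, y0, x1, y1, maturity=MaturityClass.MATURE):
    mask = np.zeros(CANVAS, bool)
    mask[y0:y1, x0:x1] = True
    return GroundTruthObject(mask=mask, bbox=(x0, y0, x1, y1), maturity=maturity)


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 10, 10), (20, 20, 30, 30)) == 0.0

    def test_half_shifted_boxes(self):
        assert iou((0, 0, 10, 10), (5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_degenerate_box_errors(self):
        with pytest.raises(ValueError):
            iou((0, 0, 0, 10), (0, 0, 10, 10))


class TestMatching:
    def test_overlap_above_threshold_is_tp(self):
        # boxes 20x10 shifted by 5 in x: IoU = 150/250 = 0.6
        c = match_detections([det_from_box(0, 0, 20, 10)], [truth_from_box(5, 0, 25, 10)])
        assert (c.n_tp, c.n_fp, c.n_fn) == (1, 0, 0)

    def test_overlap_below_threshold_is_fp_plus_fn(self):
        # shifted by 8: IoU = 120/280 ~ 0.43
        c = match_detections([det_from_box(0, 0, 20, 10)], [truth_from_box(8, 0, 28, 10)])
        assert (c.n_tp, c.n_fp, c.n_fn) == (0, 1, 1)

    def test_partially_mature_scheme_split(self):
        det = [det_from_box(0, 0, 20, 10)]
        truth = [truth_from_box(0, 0, 20, 10, MaturityClass.PARTIALLY_MATURE)]
        strict = match_detections(det, truth, "strict")
        flexible = match_detections(det, truth, "flexible")
        assert (strict.n_fp2, strict.n_tp, strict.n_fn) == (1, 0, 0)
        assert (flexible.n_tp, flexible.n_fp2, flexible.n_fn) == (1, 0, 0)

    def test_immature_match_is_fp1_and_never_fn(self):
        truth = [truth_from_box(0, 0, 20, 10, MaturityClass.IMMATURE)]
        matched = match_detections([det_from_box(0, 0, 20, 10)], truth)
        missed = match_detections([], truth)
        assert matched.n_fp1 == 1
        assert (missed.n_fn, missed.n_fp) == (0, 0)

    def test_distant_truth_never_changes_precision_or_recall(self):
        dets = [det_from_box(0, 0, 20, 10), det_from_box(40, 20, 60, 30)]
        truths = [truth_from_box(0, 0, 20, 10)]
        with_dc = truths + [truth_from_box(40, 20, 60, 30, MaturityClass.DISTANT)]
        a = precision_recall(match_detections(dets, truths))
        b = precision_recall(match_detections(dets, with_dc))
        # the DC match removes an FP from the denominator is NOT allowed:
        # DC is ignored entirely, so precision must not improve via FP ->
        # DC reclassification of a detection matching nothing countable.
        c1 = match_detections(dets, with_dc)
        assert c1.n_dc == 1 and c1.n_tp == 1
        assert a[1] == b[1] == 1.0

    def test_greedy_matching_is_one_to_one(self):
        dets = [det_from_box(0, 0, 20, 10), det_from_box(2, 0, 22, 10)]
        truths = [truth_from_box(1, 0, 21, 10)]
        c = match_detections(dets, truths)
        assert c.n_tp == 1 and c.n_fp == 1  # second detection cannot reuse truth
        c2 = match_detections([dets[0]], [truths[0], truth_from_box(3, 0, 23, 10)])
        assert c2.n_tp == 1 and c2.n_fn == 1

    def test_tp_plus_fn_equals_countable_truths(self):
        rng = np.random.default_rng(5)
        classes = list(MaturityClass)
        for _ in range(30):
            dets, truths = [], []
            for _ in range(rng.integers(0, 5)):
                x0, y0 = rng.integers(0, 50), rng.integers(0, 40)
                dets.append(det_from_box(x0, y0, x0 + 12, y0 + 10))
            for _ in range(rng.integers(0, 5)):
                x0, y0 = rng.integers(0, 50), rng.integers(0, 40)
                truths.append(
                    truth_from_box(x0, y0, x0 + 12, y0 + 10, classes[rng.integers(0, 4)])
                )
            for scheme in ("strict", "flexible"):
                c = match_detections(dets, truths, scheme)
                countable = sum(
                    t.maturity is MaturityClass.MATURE
                    or (scheme == "flexible" and t.maturity is MaturityClass.PARTIALLY_MATURE)
                    for t in truths
                )
                assert c.n_tp + c.n_fn == countable


class TestClusterCredit:
    def test_merged_blob_credits_every_covered_fruit(self):
        # one detection spanning two touching mature fruit (the cluster case)
        blob = det_from_box(0, 0, 40, 10)
        truths = [truth_from_box(0, 0, 18, 10), truth_from_box(20, 0, 40, 10)]
        per_object = match_detections([blob], truths)
        cluster = cluster_credit_counts([blob], truths)
        assert (per_object.n_tp, per_object.n_fn) == (1, 1)
        assert (cluster.n_tp, cluster.n_fn, cluster.n_fp) == (2, 0, 0)

    def test_detection_covering_nothing_is_fp(self):
        c = cluster_credit_counts([det_from_box(50, 40, 70, 50)], [truth_from_box(0, 0, 10, 10)])
        assert c.n_fp == 1 and c.n_fn == 1

    def test_forty_percent_containment_is_not_covered(self):
        truth = truth_from_box(0, 0, 20, 10)  # 200 px
        det = det_from_box(12, 0, 40, 10)     # covers 80 px = 40%
        c = cluster_credit_counts([det], [truth])
        assert c.n_fn == 1 and c.n_tp == 0

    def test_cluster_credit_dominates_per_object(self, default_scenes_50):
        from fnfpepper import compose_images, detect

        for scene in default_scenes_50[:10]:
            dets = detect(compose_images(scene.flash, scene.noflash))
            for scheme in ("strict", "flexible"):
                po = match_detections(dets, scene.truth.objects, scheme)
                cc = cluster_credit_counts(dets, scene.truth.objects, scheme)
                assert cc.n_tp >= po.n_tp
                assert cc.n_fn <= po.n_fn


class TestPrecisionRecall:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (EvalCounts(n_tp=3, n_fp=1, n_fn=1), (0.75, 0.75)),
            (EvalCounts(n_tp=0, n_fp=0, n_fn=2), (None, 0.0)),
            (EvalCounts(n_tp=5), (1.0, 1.0)),
        ],
    )
    def test_examples(self, counts, expected):
        assert precision_recall(counts) == expected

    def test_fp1_fp2_fold_into_precision_but_not_recall(self):
        p, r = precision_recall(EvalCounts(n_tp=2, n_fp=1, n_fp1=1, n_fp2=2, n_fn=2))
        assert p == pytest.approx(2 / 6)
        assert r == pytest.approx(0.5)

    def test_exhaustive_small_counts_match_direct_formulas(self):
        for tp, fp, fn, fp1, fp2 in itertools.product(range(4), repeat=5):
            p, r = precision_recall(EvalCounts(tp, fp, fn, fp1, fp2, n_dc=1))
            nfp = fp + fp1 + fp2
            assert p == (tp / (tp + nfp) if tp + nfp else None)
            assert r == (tp / (tp + fn) if tp + fn else None)


class TestPixelStats:
    def _image_with_hue(self, hues):
        h = np.asarray(hues, dtype=float)
        return hsv_to_rgb(
            HSVImage(hue=h, saturation=np.full(h.shape, 255.0), value=np.full(h.shape, 255.0))
        )

    def test_constant_hue_has_zero_std(self):
        img = self._image_with_hue(np.full((10, 10), 60.0))
        truth = [GroundTruthObject(np.ones((10, 10), bool), (0, 0, 10, 10), MaturityClass.MATURE)]
        stats = labeled_pixel_stats([img], [truth])
        assert stats["hue_std"] == pytest.approx(0.0, abs=1e-9)

    def test_two_point_distribution_std(self):
        hues = np.full((10, 10), 72.0)  # normalized 0.2
        hues[5:] = 144.0                # normalized 0.4
        img = self._image_with_hue(hues)
        truth = [GroundTruthObject(np.ones((10, 10), bool), (0, 0, 10, 10), MaturityClass.MATURE)]
        stats = labeled_pixel_stats([img], [truth])
        assert stats["hue_std"] == pytest.approx(0.1, abs=1e-3)
        assert stats["n_pixels"] == 100
        assert stats["hue_hist"].sum() == 100

    def test_no_pixels_of_class_errors(self):
        img = self._image_with_hue(np.full((5, 5), 60.0))
        truth = [GroundTruthObject(np.ones((5, 5), bool), (0, 0, 5, 5), MaturityClass.IMMATURE)]
        with pytest.raises(ValueError):
            labeled_pixel_stats([img], [truth], MaturityClass.MATURE)


class TestDatasetEvaluation:
    def test_aggregate_equals_hand_counts_on_toy_scene(self):
        from fnfpepper.simulator import Scene, SceneTruth

        # one synthetic image holding one detectable fruit-colored disk and
        # one labeled fruit that the detector cannot see
        from conftest import disk_image

        img, mask = disk_image(radius=25, hue=35, sat=200)
        visible = GroundTruthObject(mask, detected_bbox(mask), MaturityClass.MATURE)
        hidden_mask = np.zeros(img.shape, bool)
        hidden_mask[5:30, 250:300] = True
        hidden = GroundTruthObject(hidden_mask, (250, 5, 300, 30), MaturityClass.MATURE)
        black = RGBImage(np.zeros((img.height, img.width, 3), dtype=np.uint8))
        scene = Scene(
            "toy", img, black,
            truth=SceneTruth(np.zeros(img.shape, np.uint8), [visible, hidden]),
            composite=img,
        )
        result, per_scene, dist = evaluate_dataset([scene], modality="fnf")
        assert result.counts.n_tp == 1 and result.counts.n_fn == 1
        assert result.precision == 1.0 and result.recall == 0.5
        assert dist["TP"] == 1 and dist["FN"] == 1
        assert len(per_scene) == 1

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError):
            evaluate_dataset([])

    def test_missing_labels_error_names_scene(self):
        from fnfpepper.simulator import Scene

        from conftest import disk_image

        img, _ = disk_image(radius=25, hue=35, sat=200)
        scene = Scene("unlabeled", img, img)
        with pytest.raises(ValueError, match="unlabeled"):
            evaluate_dataset([scene])


@pytest.fixture(scope="module")
def small_scenes():
    return simulate_scenes(GeneratorConfig(), 8, master_seed=3)


class TestSweep:
    def test_single_point_grid_matches_evaluate_dataset(self, small_scenes):
        params = DetectorParams()
        table = sweep_thresholds(small_scenes, [params], scheme="flexible")
        result, _, _ = evaluate_dataset(small_scenes, params, scheme="flexible")
        assert table.loc[0, "precision"] == result.precision
        assert table.loc[0, "recall"] == result.recall

    def test_recall_non_increasing_in_sat_min(self, small_scenes):
        grid = [DetectorParams(sat_min=s) for s in (60, 90, 120)]
        table = sweep_thresholds(
            grid=grid, scenes=small_scenes, scheme="flexible", cluster_mode="cluster_credit"
        )
        recalls = table["recall"].tolist()
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))


def detected_bbox(mask):
    ys, xs = np.nonzero(mask)
    return (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
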