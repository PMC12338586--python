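import numpy as np
import pytest
from shapely.geometry import Polygon

import ftuscope as ft
from ftuscope.annotation_io import AnnotationType, FTUAnnotation, new_uuid
from ftuscope.errors import GeometryError


def _ann(vocab, geometry, cid=1, rng=None):
    return FTUAnnotation(
        uuid=new_uuid(rng or np.random.default_rng(0)),
        class_id=cid,
        class_name=vocab.id_to_name(cid),
        annotation_type=AnnotationType.MANUAL,
        geometry=geometry,
    )


class TestDice:
    def test_identical_and_disjoint(self):
        a = np.zeros((8, 8), np.uint16)
        a[:4] = 1
        assert ft.dice_binary(a, a.copy()) == 1.0
        b = np.zeros_like(a)
        b[6:] = 1
        assert ft.dice_binary(a, b) == 0.0

    def test_counted_toy_pair(self):
        # |A|=6, |B|=4, |A n B|=3 -> 2*3/10 = 0.6 on a 4x4 grid.
        a = np.zeros((4, 4), np.uint16)
        b = np.zeros((4, 4), np.uint16)
        a[0, :4] = 1
        a[1, :2] = 1
        b[0, 1:4] = 1
        b[3, 3] = 1
        assert int((a != 0).sum()) == 6
        assert int((b != 0).sum()) == 4
        assert int(((a != 0) & (b != 0)).sum()) == 3
        assert ft.dice_binary(a, b) == pytest.approx(0.6)

    def test_symmetry_and_relabel_invariance(self, rng):
        a = rng.integers(0, 4, (16, 16)).astype(np.uint16)
        b = rng.integers(0, 4, (16, 16)).astype(np.uint16)
        assert ft.dice_binary(a, b) == ft.dice_binary(b, a)
        relabeled = np.where(b != 0, b + 7, 0).astype(np.uint16)
        assert ft.dice_multiclass_collapsed(a, b) == ft.dice_multiclass_collapsed(a, relabeled)

    def test_collapsed_ignores_class(self):
        a = np.full((5, 5), 3, np.uint16)
        b = np.full((5, 5), 5, np.uint16)
        assert ft.dice_multiclass_collapsed(a, b) == 1.0
        assert ft.dice_binary(np.zeros((5, 5)), b) == 0.0

    def test_empty_vs_empty_is_one(self):
        z = np.zeros((4, 4), np.uint16)
        assert ft.dice_binary(z, z) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            ft.dice_binary(np.zeros((3, 3)), np.zeros((4, 4)))


class TestCenterPixel:
    def test_square_centroid_pixel(self, prostate):
        a = _ann(prostate, Polygon([(0, 0), (10, 0), (10, 10), (0, 10)]))
        assert ft.center_pixel(a) == (5, 5)

    def test_convex_polygon_rounded_centroid_inside(self, prostate):
        a = _ann(prostate, Polygon([(2, 1), (14, 3), (12, 12), (3, 10)]))
        px, py = ft.center_pixel(a)
        from ftuscope.postprocess import annotation_footprint

        foot = annotation_footprint(a, (16, 16))
        assert foot[py, px]

    def test_c_shape_falls_back_to_interior_point(self, prostate):
        # C-shape whose centroid lands in the gap.
        ring = [(0, 0), (12, 0), (12, 3), (3, 3), (3, 9), (12, 9), (12, 12), (0, 12)]
        a = _ann(prostate, Polygon(ring))
        px, py = ft.center_pixel(a)
        from ftuscope.postprocess import annotation_footprint

        foot = annotation_footprint(a, (14, 14))
        assert foot[py, px]

    def test_zero_raster_area_polygon_raises(self, prostate):
        with pytest.raises(GeometryError):
            ft.center_pixel(
                _ann(prostate, Polygon([(0, 0), (0.2, 0), (0.2, 0.2), (0, 0.2)]))
            )


class TestClassificationAccuracy:
    def test_self_prediction_is_perfect(self, scene, prostate):
        acc, cm = ft.classification_accuracy(scene["aset"], scene["mask"], prostate)
        assert acc == 1.0
        off_diag = cm.counts.sum() - np.trace(cm.counts)
        assert off_diag == 0

    def test_all_background_prediction(self, scene, prostate):
        acc, cm = ft.classification_accuracy(
            scene["aset"], np.zeros_like(scene["mask"]), prostate
        )
        assert acc == 0.0
        assert cm.counts[:, 0].sum() == len(scene["aset"])  # all in Background column

    def test_partial_hits_brute_force(self, prostate, rng):
        # Four 6x6 squares; three predicted correctly, one misclassified.
        squares, preds = [], np.zeros((40, 40), np.uint16)
        for i, (cid, pred_cid) in enumerate([(1, 1), (2, 2), (4, 4), (5, 1)]):
            x0 = 2 + i * 9
            squares.append(_ann(
                prostate, Polygon([(x0, 2), (x0 + 6, 2), (x0 + 6, 8), (x0, 8)]),
                cid=cid, rng=rng))
            preds[2:8, x0 : x0 + 6] = pred_cid
        aset = ft.AnnotationSet("img", squares)
        acc, cm = ft.classification_accuracy(aset, preds, prostate)
        assert acc == pytest.approx(0.75)
        assert cm.total == 4

    def test_confusion_total_conserved(self, scene, prostate):
        from ftuscope.synthetic import DropInstance

        degraded = ft.degrade(scene["mask"], [DropInstance(0.5)], seed=1)
        _, cm = ft.classification_accuracy(scene["aset"], degraded, prostate)
        assert cm.total == len(scene["aset"])

    def test_monte_carlo_random_labels_approach_one_over_k(self, prostate):
        # Uniform random labels over K classes: accuracy -> 1/K.
        rng = np.random.default_rng(7)
        k = 17
        n = 10_000
        gt = rng.integers(1, k + 1, n)
        pred = rng.integers(1, k + 1, n)
        acc = float((gt == pred).mean())
        p = 1.0 / k
        se = np.sqrt(p * (1 - p) / n)
        assert abs(acc - p) < 3 * se


class TestRandomBaseline:
    def test_seventeen_classes_is_5_9_percent(self):
        assert ft.random_baseline_accuracy(17) == pytest.approx(0.0588, abs=5e-4)

    @pytest.mark.parametrize("k,expected", [(1, 1.0), (2, 0.5)])
    def test_small_k(self, k, expected):
        assert ft.random_baseline_accuracy(k) == expected

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            ft.random_baseline_accuracy(0)


class TestGradeStrata:
    @pytest.mark.parametrize(
        "score,stratum",
        [(0, "no_tumor"), (6, "low"), (7, "medium"), (8, "high"), (9, "high"), (10, "high")],
    )
    def test_mapping(self, score, stratum):
        assert ft.stratify_by_grade(score) == stratum

    @pytest.mark.parametrize("score", [-1, 3, 5, 11])
    def test_out_of_range(self, score):
        with pytest.raises(ValueError):
            ft.stratify_by_grade(score)

    def test_dice_report_mean_and_strata(self):
        rep = ft.dice_report(
            {"a": 0.9, "b": 0.8, "c": 0.7},
            gleason={"a": 6, "b": 7, "c": 9},
        )
        assert rep.mean == pytest.approx(0.8)
        assert rep.grade == {"a": "low", "b": "medium", "c": "high"}


class TestCompareDiceDistributions:
    def test_identical_groups_not_significant(self):
        g = {"m1": [0.5] * 5 + [0.6] * 6, "m2": [0.5] * 5 + [0.6] * 6,
             "m3": [0.5] * 5 + [0.6] * 6}
        res = ft.compare_dice_distributions(g)
        assert res.omnibus_p > 0.05
        assert (res.pairwise["p_adjusted"] > 0.05).all()

    def test_separated_groups_significant(self, rng):
        lo = (0.1 + 0.1 * rng.random(11)).tolist()
        hi = (0.85 + 0.1 * rng.random(11)).tolist()
        res = ft.compare_dice_distributions({"zero_shot": lo, "fine_tuned": hi})
        assert res.omnibus_p < 0.05
        assert (res.pairwise["p_adjusted"] < 0.05).all()

    def test_bonferroni_clamped_at_one(self):
        g = {f"g{i}": [0.5, 0.6, 0.55] for i in range(4)}
        res = ft.compare_dice_distributions(g)
        assert (res.pairwise["p_adjusted"] <= 1.0).all()

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            ft.compare_dice_distributions({"a": [0.5], "b": [0.6, 0.7]})
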