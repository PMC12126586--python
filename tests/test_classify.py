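import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from wetlandscape.classify import (
    ControlPointSet,
    accuracy_report,
    predict_map,
    predict_points,
    select_variables,
    split_control_points,
    train_classifier,
    variable_importance,
)
from wetlandscape.indices import FeatureStack
from wetlandscape.synthetic_data import default_scene_model, generate_control_points, generate_truth_map

from conftest import make_layer


def points_table(n_per_class, classes=("marsh", "swamp"), zone="TW", seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for cls in classes:
        for _ in range(n_per_class):
            rows.append({"x": rng.uniform(0, 100), "y": rng.uniform(0, 100), "cls": cls, "zone": zone})
    return ControlPointSet(pd.DataFrame(rows))


def separable_fixture(seed=0, n_noise=3, shape=(40, 40)):
    """One feature perfectly separates marsh from swamp; the rest is noise."""
    rng = np.random.default_rng(seed)
    truth = np.zeros(shape, dtype=np.int16)
    truth[: shape[0] // 2] = 1   # marsh
    truth[shape[0] // 2:] = 3    # swamp
    informative = np.where(truth == 1, 1.0, -1.0) + 0.01 * rng.standard_normal(shape)
    layers = [("signal", make_layer(informative))]
    for i in range(n_noise):
        layers.append((f"noise{i}", make_layer(rng.standard_normal(shape))))
    stack = FeatureStack(layers, zone="TW")
    truth_layer = make_layer(truth)
    points = generate_control_points(truth_layer, 30, seed=seed + 1, include_background=False)
    return stack, points, truth_layer


class TestSplit:
    def test_half_split_counts(self):
        pts = split_control_points(points_table(10), 0.5, seed=1)
        counts = pts.frame.groupby(["cls", "split"]).size()
        for cls in ("marsh", "swamp"):
            assert counts[cls, "train"] == 5
            assert counts[cls, "test"] == 5

    def test_same_seed_identical(self):
        a = split_control_points(points_table(11), 0.5, seed=9)
        b = split_control_points(points_table(11), 0.5, seed=9)
        assert (a.frame["split"] == b.frame["split"]).all()

    def test_rounded_share(self):
        pts = split_control_points(points_table(7), 0.5, seed=2)
        assert (pts.frame[pts.frame["cls"] == "marsh"]["split"] == "train").sum() == 4  # round(3.5)

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2])
    def test_degenerate_fraction_rejected(self, fraction):
        with pytest.raises(ValueError):
            split_control_points(points_table(4), fraction, seed=0)

    def test_tiny_class_rejected(self):
        pts = ControlPointSet(pd.DataFrame([{"x": 1, "y": 1, "cls": "marsh", "zone": "TW"}]))
        with pytest.raises(ValueError, match="fewer than 2"):
            split_control_points(pts, 0.5, seed=0)


class TestVariableImportance:
    def test_informative_feature_ranked_first_every_run(self):
        stack, points, _ = separable_fixture()
        report = variable_importance(stack, points, n_runs=5, ntree=50, seed=3)
        for _, row in report.runs.iterrows():
            assert row.idxmax() == "signal"
        assert report.ranking()[0] == "signal"

    def test_per_run_scores_sum_to_one(self):
        stack, points, _ = separable_fixture()
        report = variable_importance(stack, points, n_runs=3, ntree=30, seed=0)
        np.testing.assert_allclose(report.runs.sum(axis=1), 1.0, rtol=1e-9)

    def test_pure_noise_features_statistically_even(self):
        rng = np.random.default_rng(12)
        shape = (30, 30)
        truth = make_layer(rng.integers(1, 3, size=shape).astype(np.int16) * 2 - 1)  # classes 1, 3
        layers = [(f"n{i}", make_layer(rng.standard_normal(shape))) for i in range(4)]
        stack = FeatureStack(layers, zone="TW")
        points = generate_control_points(truth, 50, seed=4, include_background=False)
        report = variable_importance(stack, points, n_runs=6, ntree=60, seed=5)
        means = report.mean_scores
        assert means.max() <= 2 * means.min()

    def test_select_top_k_and_ties(self):
        runs = pd.DataFrame([{"a": 0.25, "b": 0.5, "c": 0.25}])
        from wetlandscape.classify import ImportanceReport

        report = ImportanceReport(runs)
        assert select_variables(report, 3) == ["b", "a", "c"]  # tie a/c → declared order
        assert select_variables(report, 1) == ["b"]
        with pytest.raises(ValueError):
            select_variables(report, 0)


class TestTrainPredict:
    def test_seeded_training_is_deterministic(self):
        stack, points, _ = separable_fixture()
        m1 = train_classifier(stack, points, ntree=25, seed=8)
        m2 = train_classifier(stack, points, ntree=25, seed=8)
        p1 = predict_map(m1, stack)
        p2 = predict_map(m2, stack)
        np.testing.assert_array_equal(p1.values, p2.values)

    @pytest.mark.parametrize("ntree", [1, 100])
    def test_separable_fixture_recovered(self, ntree):
        stack, points, truth = separable_fixture()
        model = train_classifier(stack, points, ntree=ntree, seed=0)
        predicted = predict_map(model, stack)
        agree = (predicted.values == truth.values).mean()
        assert agree >= 0.95

    def test_single_class_training_rejected(self):
        stack, points, _ = separable_fixture()
        marsh_only = ControlPointSet(points.frame[points.frame["cls"] == "marsh"].reset_index(drop=True))
        with pytest.raises(ValueError, match="single class"):
            train_classifier(stack, marsh_only, ntree=5, seed=0)

    def test_feature_contract_is_strict(self):
        stack, points, _ = separable_fixture()
        model = train_classifier(stack, points, ntree=5, seed=0)
        permuted = FeatureStack(list(reversed(stack.features)), zone="TW")
        with pytest.raises(ValueError, match="contract"):
            predict_map(model, permuted)

    def test_all_nodata_stack_predicts_all_nodata(self):
        stack, points, _ = separable_fixture()
        model = train_classifier(stack, points, ntree=5, seed=0)
        blank = FeatureStack(
            [(n, make_layer(np.full(l.shape, np.nan), nodata=np.nan)) for n, l in stack.features],
            zone="TW",
        )
        out = predict_map(model, blank)
        assert (out.values == out.nodata).all()


class TestAccuracyReport:
    def test_hand_computed_confusion(self):
        # confusion [[45, 5], [15, 35]]: OA 0.80, p_e 0.5 → kappa 0.60,
        # PA(class1) 0.90, UA(class1) 0.75
        reference = ["a"] * 50 + ["b"] * 50
        predicted = ["a"] * 45 + ["b"] * 5 + ["a"] * 15 + ["b"] * 35
        rep = accuracy_report(predicted, reference)
        assert rep.overall_accuracy == pytest.approx(0.80)
        assert rep.kappa == pytest.approx(0.60)
        assert rep.producers_accuracy["a"] == pytest.approx(0.90)
        assert rep.users_accuracy["a"] == pytest.approx(0.75)

    def test_kappa_matches_independent_implementation(self):
        rng = np.random.default_rng(6)
        ref = rng.integers(0, 4, 300)
        pred = np.where(rng.random(300) < 0.7, ref, rng.integers(0, 4, 300))
        rep = accuracy_report(pred, ref)
        assert rep.kappa == pytest.approx(cohen_kappa_score(ref, pred), abs=1e-12)

    def test_perfect_agreement(self):
        rep = accuracy_report(["x", "y", "x"], ["x", "y", "x"])
        assert rep.overall_accuracy == 1.0 and rep.kappa == 1.0

    def test_kappa_never_exceeds_oa(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            ref = rng.integers(0, 3, 100)
            pred = rng.integers(0, 3, 100)
            rep = accuracy_report(pred, ref)
            assert rep.kappa <= rep.overall_accuracy + 1e-12

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(8)
        ref = rng.integers(0, 3, 200)
        pred = rng.integers(0, 3, 200)
        rep = accuracy_report(pred, ref)
        perm = {0: 2, 1: 0, 2: 1}
        rep_p = accuracy_report([perm[p] for p in pred], [perm[r] for r in ref])
        assert rep.overall_accuracy == rep_p.overall_accuracy
        assert rep.kappa == pytest.approx(rep_p.kappa)

    def test_absent_class_reported_missing_not_zero(self):
        rep = accuracy_report(["a", "a", "c"], ["a", "a", "a"], labels=["a", "b", "c"])
        assert np.isnan(rep.producers_accuracy["b"])
        assert np.isnan(rep.users_accuracy["b"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            accuracy_report([], [])

    def test_label_outside_legend_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            accuracy_report(["z"], ["a"], labels=["a", "b"])


class TestEndToEndPoints:
    def test_predict_points_recovers_test_labels(self):
        model = default_scene_model(cell_size=50.0)
        truth, _ = generate_truth_map(model, (60, 60), seed=2)
        from wetlandscape.indices import build_feature_stack
        from wetlandscape.synthetic_data import generate_scene

        scene = generate_scene(truth, model, season="wet", seed=3)
        stack = build_feature_stack({"wet": scene}, ["NDVI_wet", "NDWI_wet", "Ndiff_wet", "B8_wet"])
        points = generate_control_points(truth, 40, seed=4)
        points = split_control_points(points, 0.5, seed=5)
        fitted = train_classifier(stack, points.subset("train"), ntree=100, seed=6)
        pred, ref = predict_points(fitted, stack, points.subset("test"))
        assert (pred == ref).mean() >= 0.9
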