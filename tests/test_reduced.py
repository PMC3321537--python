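"""Reduced model: gain weights, weighted distances, classification, metric."""

import logging

import numpy as np
import pytest
from sklearn.metrics import balanced_accuracy_score

from mmts import (CohortTable, GainTable, MMTSError, build_reduced_model,
                  classify, evaluate, macro_average, mahalanobis_distance,
                  weighted_md)
from mmts.screening import GainTable as GT
from .conftest import gaussian_cohort


def make_gain_table(features, gains, selected=None):
    gains = np.asarray(gains, dtype=float)
    if selected is None:
        selected = gains > 0
    return GT(list(features), gains + 1.0, np.ones_like(gains),
              gains, np.asarray(selected, dtype=bool), [])


def fitted_model(seed=0, d=3, gains=(3.0, 1.0, 2.0), n=40, separation=3.0):
    cohort = gaussian_cohort(seed, n_per_class=n, d=d, separation=separation)
    table = make_gain_table(cohort.feature_names, gains)
    return cohort, build_reduced_model(cohort, table)


class TestWeights:
    def test_single_selected_feature_gets_unit_weight(self):
        cohort = gaussian_cohort(0, n_per_class=30, d=2, separation=2.0)
        table = make_gain_table(cohort.feature_names, [4.0, -1.0])
        model = build_reduced_model(cohort, table)
        assert model.selected_features == ["f0"]
        assert model.weights.tolist() == [1.0]

    def test_equal_gains_split_evenly(self):
        cohort = gaussian_cohort(1, n_per_class=30, d=2, separation=2.0)
        model = build_reduced_model(cohort, make_gain_table(cohort.feature_names,
                                                            [2.0, 2.0]))
        assert np.allclose(model.weights, [0.5, 0.5])

    def test_three_to_one_gains(self):
        cohort = gaussian_cohort(2, n_per_class=30, d=2, separation=2.0)
        model = build_reduced_model(cohort, make_gain_table(cohort.feature_names,
                                                            [3.0, 1.0]))
        assert np.allclose(model.weights, [0.75, 0.25])

    def test_weights_sum_to_one_and_ignore_gain_rescaling(self):
        cohort, model = fitted_model()
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-12)
        table = make_gain_table(cohort.feature_names, 7.3 * model.gains)
        rescaled = build_reduced_model(cohort, table)
        assert np.allclose(rescaled.weights, model.weights)

    def test_nonpositive_multifeature_selection_rejected(self):
        cohort = gaussian_cohort(3, n_per_class=30, d=2, separation=2.0)
        table = make_gain_table(cohort.feature_names, [2.0, -1.0],
                                selected=[True, True])
        with pytest.raises(MMTSError):
            build_reduced_model(cohort, table)

    def test_singleton_nonpositive_fallback_is_degraded_but_usable(self):
        cohort = gaussian_cohort(4, n_per_class=30, d=2, separation=2.0)
        table = make_gain_table(cohort.feature_names, [-0.5, -2.0],
                                selected=[True, False])
        model = build_reduced_model(cohort, table)
        assert model.weights.tolist() == [1.0]
        assert any("degraded" in w for w in model.warnings)


class TestWeightedDistance:
    def test_zero_at_class_mean(self):
        _, model = fitted_model()
        space = model.spaces[0]
        assert weighted_md(model, space.class_id, space.mu) == pytest.approx(0.0,
                                                                             abs=1e-20)

    def test_hand_computed_weighted_distance(self):
        # w = (0.75, 0.25): recompute (1/δ)·Σ w_l u_l²/ζ_l² by direct arithmetic
        cohort = gaussian_cohort(5, n_per_class=30, d=2, separation=2.0)
        model = build_reduced_model(cohort, make_gain_table(cohort.feature_names,
                                                            [3.0, 1.0]))
        space = model.spaces[1]
        x = np.array([1.7, -0.4])
        z = (x - space.mu) / space.sigma
        u1 = z[0]
        u2 = z[1] - space.gs_coeffs[1, 0] * u1
        by_hand = (0.75 * u1 ** 2 / space.zeta[0] ** 2
                   + 0.25 * u2 ** 2 / space.zeta[1] ** 2) / 2
        assert weighted_md(model, space.class_id, x) == pytest.approx(by_hand,
                                                                      rel=1e-12)

    def test_uniform_weights_reduce_to_plain_distance_over_delta(self):
        cohort = gaussian_cohort(6, n_per_class=30, d=3, separation=2.0)
        model = build_reduced_model(cohort, make_gain_table(cohort.feature_names,
                                                            [1.0, 1.0, 1.0]))
        x = np.array([0.3, 1.1, -0.8])
        for space in model.spaces:
            plain = mahalanobis_distance(space, x)
            assert weighted_md(model, space.class_id, x) == pytest.approx(
                plain / model.delta, rel=1e-12)

    def test_uniform_weights_classify_like_unweighted_argmin(self):
        cohort = gaussian_cohort(7, n_per_class=40, d=3, separation=1.0)
        model = build_reduced_model(cohort, make_gain_table(cohort.feature_names,
                                                            [1.0, 1.0, 1.0]))
        X = np.random.default_rng(7).normal(0.5, 1.5, size=(30, 3))
        pred = classify(model, X, feature_names=cohort.feature_names)
        for row, p in zip(X, pred):
            dists = [mahalanobis_distance(s, row) for s in model.spaces]
            assert p == model.spaces[int(np.argmin(dists))].class_id

    def test_upweighting_the_dominant_component_increases_distance(self):
        cohort = gaussian_cohort(8, n_per_class=30, d=2, separation=2.0)
        mild = build_reduced_model(cohort, make_gain_table(cohort.feature_names,
                                                           [1.0, 1.0]))
        heavy = build_reduced_model(cohort, make_gain_table(cohort.feature_names,
                                                            [3.0, 1.0]))
        space = mild.spaces[0]
        # a point displaced along the first feature only: u1² dominates
        x = space.mu + np.array([5.0 * space.sigma[0], 0.0])
        assert weighted_md(heavy, space.class_id, x) > weighted_md(
            mild, space.class_id, x)

    def test_unselected_features_in_input_are_ignored(self):
        cohort = gaussian_cohort(9, n_per_class=30, d=2, separation=2.0)
        model = build_reduced_model(cohort, make_gain_table(cohort.feature_names,
                                                            [4.0, -1.0]))
        with_extra = {"f0": 1.3, "f1": 99.0, "other": -5.0}
        only_selected = {"f0": 1.3}
        assert weighted_md(model, "c0", with_extra) == pytest.approx(
            weighted_md(model, "c0", only_selected), rel=1e-12)

    def test_missing_selected_feature_rejected(self):
        _, model = fitted_model()
        with pytest.raises(MMTSError):
            weighted_md(model, model.spaces[0].class_id, {"f0": 1.0})


class TestClassify:
    def test_class_means_classify_to_their_classes(self):
        cohort = gaussian_cohort(10, n_per_class=40, d=3, separation=6.0, k=4)
        model = build_reduced_model(cohort, make_gain_table(cohort.feature_names,
                                                            [1.0, 2.0, 1.5]))
        X = np.vstack([s.mu for s in model.spaces])
        pred = classify(model, X, feature_names=model.selected_features)
        assert list(pred) == [s.class_id for s in model.spaces]

    def test_exact_tie_goes_to_first_class_and_is_logged(self, caplog):
        # classes mirrored around zero: the midpoint ties exactly
        rng = np.random.default_rng(11)
        block = rng.normal(3.0, 1.0, size=(25, 2))
        values = np.vstack([block, -block])
        labels = np.repeat(["a", "b"], 25)
        cohort = CohortTable(["f0", "f1"], values, labels, ("a", "b"))
        model = build_reduced_model(cohort, make_gain_table(["f0", "f1"],
                                                            [1.0, 1.0]))
        with caplog.at_level(logging.WARNING, logger="mmts.reduced"):
            pred = classify(model, np.zeros((1, 2)),
                            feature_names=["f0", "f1"])
        assert pred[0] == "a"
        assert any("tie" in rec.message for rec in caplog.records)


class TestEvaluate:
    ORDER = ["normal", "mild", "moderate", "severe"]

    def test_perfect_predictions(self):
        y = ["normal"] * 3 + ["mild"] * 2 + ["moderate"] * 2 + ["severe"] * 2
        rep = evaluate(y, y, self.ORDER)
        assert rep.macro_accuracy == 1.0
        assert all(v == 1.0 for v in rep.per_class_accuracy.values())

    def test_published_comparison_row_reconstruction(self):
        # per-class rates 7/8, 4/6, 9/9, 5/6 -> macro 84.375%, printed 84.38
        y_true = (["normal"] * 8 + ["mild"] * 6 + ["moderate"] * 9
                  + ["severe"] * 6)
        y_pred = (["normal"] * 7 + ["mild"]
                  + ["mild"] * 4 + ["normal"] * 2
                  + ["moderate"] * 9
                  + ["severe"] * 5 + ["moderate"])
        rep = evaluate(y_true, y_pred, self.ORDER)
        assert rep.per_class_accuracy["normal"] == pytest.approx(0.875)
        assert rep.per_class_accuracy["mild"] == pytest.approx(2 / 3)
        assert rep.per_class_accuracy["moderate"] == pytest.approx(1.0)
        assert rep.per_class_accuracy["severe"] == pytest.approx(5 / 6)
        assert rep.macro_accuracy == pytest.approx(0.84375)
        assert rep.confusion.sum(axis=1).tolist() == [8, 6, 9, 6]
        # independent implementation of the same metric
        assert rep.macro_accuracy == pytest.approx(
            balanced_accuracy_score(y_true, y_pred))

    def test_constant_predictor_on_balanced_classes(self):
        y_true = np.repeat(self.ORDER, 5)
        y_pred = ["normal"] * 20
        assert evaluate(y_true, y_pred, self.ORDER).macro_accuracy == 0.25

    def test_macro_accuracy_ignores_prevalence(self):
        rep1 = evaluate(["a"] * 10 + ["b"] * 10,
                        ["a"] * 5 + ["b"] * 5 + ["b"] * 10, ["a", "b"])
        rep2 = evaluate(["a"] * 2 + ["b"] * 50,
                        ["a"] + ["b"] + ["b"] * 50, ["a", "b"])
        assert rep1.macro_accuracy == rep2.macro_accuracy == 0.75

    def test_absent_true_class_rejected(self):
        with pytest.raises(MMTSError):
            evaluate(["normal", "mild"], ["normal", "mild"], self.ORDER)

    def test_macro_average_helper(self):
        assert macro_average([0.875, 2 / 3, 1.0, 5 / 6]) == pytest.approx(0.84375)
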