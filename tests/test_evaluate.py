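import numpy as np
import pytest

import stagedfs as s
from stagedfs.errors import ConfigError, PipelineError
from stagedfs.evaluate import ConfusionCounts


class TestSplits:
    def test_sets_are_disjoint_and_stratified(self):
        y = np.r_[np.ones(80, int), np.zeros(20, int)]
        plan = s.make_splits(y, n_rep=10, seed=1)
        for rep in plan.repetitions:
            assert not set(rep.test) & set(rep.learning)
            assert not set(rep.train) & set(rep.validation)
            assert len(rep.test) == 20
            assert (y[rep.test] == 1).sum() == 16
            assert (y[rep.test] == 0).sum() == 4

    def test_same_seed_same_plan(self):
        y = np.r_[np.ones(40, int), np.zeros(15, int)]
        a = s.make_splits(y, seed=9)
        b = s.make_splits(y, seed=9)
        for ra, rb in zip(a.repetitions, b.repetitions):
            assert (ra.test == rb.test).all() and (ra.train == rb.train).all()

    def test_zero_test_frac_rejected(self):
        with pytest.raises(ConfigError):
            s.make_splits(np.r_[np.ones(10), np.zeros(10)], test_frac=0.0)

    def test_tiny_class_raises_stratification_error(self):
        y = np.r_[np.ones(50, int), np.zeros(1, int)]
        with pytest.raises(PipelineError):
            s.make_splits(y, seed=0)

    def test_partition_mode_parts_are_disjoint(self):
        y = np.r_[np.ones(160, int), np.zeros(80, int)]
        plan = s.make_splits(y, n_rep=4, seed=2, mode="partition")
        pools = [set(r.learning) | set(r.test) for r in plan.repetitions]
        for i in range(len(pools)):
            for j in range(i + 1, len(pools)):
                assert not pools[i] & pools[j]


class TestConfusion:
    def test_all_correct(self):
        c = s.confusion([1] * 5 + [0] * 3, [1] * 5 + [0] * 3)
        assert (c.TP, c.TN, c.FP, c.FN) == (5, 3, 0, 0)

    def test_all_predicted_tumor(self):
        c = s.confusion([1] * 5 + [0] * 3, [1] * 8)
        assert (c.TP, c.FP, c.TN, c.FN) == (5, 3, 0, 0)

    def test_prediction_flip_transposes_counts(self):
        y = [1, 1, 0, 0, 1]
        pred = [1, 0, 0, 1, 1]
        a = s.confusion(y, pred)
        b = s.confusion(y, [1 - p for p in pred])
        assert (a.TP, a.TN) == (b.FN, b.FP)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            s.confusion([0, 1, 2], [0, 1, 1])


class TestBasicMetrics:
    def test_perfect_prediction(self):
        m = s.basic_metrics(ConfusionCounts(TP=5, FP=0, TN=3, FN=0))
        for k in ("ACC", "SES", "SPC", "PRC", "F1"):
            assert m[k] == 1.0

    def test_hand_computed_mixture(self):
        m = s.basic_metrics(ConfusionCounts(TP=3, FP=1, TN=2, FN=2))
        assert m["ACC"] == pytest.approx(0.625)
        assert m["SES"] == pytest.approx(0.6)
        assert m["SPC"] == pytest.approx(2 / 3)
        assert m["PRC"] == pytest.approx(0.75)
        assert m["F1"] == pytest.approx(2 * 3 / (6 + 1 + 2))

    def test_auc_rank_extremes(self):
        y = [0, 0, 1, 1]
        perfect = s.basic_metrics(
            ConfusionCounts(2, 0, 2, 0), scores=[0.1, 0.2, 0.8, 0.9], y_true=y
        )
        inverted = s.basic_metrics(
            ConfusionCounts(2, 0, 2, 0), scores=[0.9, 0.8, 0.2, 0.1], y_true=y
        )
        assert perfect["AUC"] == 1.0 and inverted["AUC"] == 0.0

    def test_zero_denominator_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="PRC"):
            m = s.basic_metrics(ConfusionCounts(TP=0, FP=0, TN=5, FN=2))
        assert np.isnan(m["PRC"])


class TestWeights:
    def test_equal_raws_normalize_to_half(self):
        w = s.class_weights([1.0], [1.0])
        assert w.w_normal == w.w_tumor == 0.5

    def test_hand_normalization(self):
        w = s.class_weights([0.8], [1.0])
        assert w.w_normal == pytest.approx(0.8 / 1.8)
        assert w.w_tumor == pytest.approx(1.0 / 1.8)

    def test_boundary_zero_weight(self):
        w = s.class_weights([0.0], [1.0])
        assert (w.w_normal, w.w_tumor) == (0.0, 1.0)

    def test_all_zero_raws_rejected(self):
        with pytest.raises(ValueError):
            s.class_weights([0.0], [0.0])

    def test_weights_average_over_repetitions(self):
        w = s.class_weights([0.5, 1.0], [1.0, 1.0])
        assert w.w_normal_raw == pytest.approx(0.75)


class TestBalancedAccuracy:
    def test_perfect_inputs_give_one(self):
        w = s.class_weights([0.7], [0.9])
        assert s.balanced_accuracy(1.0, 1.0, w) == pytest.approx(1.0)

    def test_weighted_sum_by_hand(self):
        w = s.class_weights([0.8], [1.0])
        got = s.balanced_accuracy(0.9, 1.0, w)
        assert got == pytest.approx(0.9 * (0.8 / 1.8) + 1.0 / 1.8)

    def test_equal_weights_reduce_to_macro_recall(self):
        w = s.class_weights([0.9], [0.9])
        ses, spc = 0.73, 0.91
        assert s.balanced_accuracy(spc, ses, w) == pytest.approx((ses + spc) / 2)

    def test_raw_mode_uses_unnormalized_weights(self):
        w = s.class_weights([1.0], [1.0])
        assert s.balanced_accuracy(1.0, 1.0, w, mode="raw") == pytest.approx(2.0)


@pytest.fixture(scope="module")
def small_config():
    return s.PipelineConfig(case=3, n_rep=3, seed=21)


class TestPipeline:

    def test_case1_uses_all_genes(self, dataset):
        cfg = s.PipelineConfig(case=1, n_rep=2, seed=5)
        report = s.evaluate_pipeline(dataset, cfg)
        assert (report.per_repetition["n_features"] == len(dataset.genes)).all()

    def test_case3_report_structure(self, dataset, small_config):
        report = s.evaluate_pipeline(dataset, small_config)
        assert len(report.per_repetition) == 3
        assert set(s.evaluate.METRIC_NAMES) <= set(report.per_repetition.columns)
        agg = report.aggregate
        assert (agg["mean"] == report.per_repetition[agg.index].mean()).all()

    def test_aggregate_mean_matches_hand_recomputation(self, dataset, small_config):
        report = s.evaluate_pipeline(dataset, small_config)
        assert report.aggregate.loc["ACC", "mean"] == pytest.approx(
            report.per_repetition["ACC"].mean()
        )

    def test_same_seed_reproduces_report(self, dataset, small_config):
        a = s.evaluate_pipeline(dataset, small_config)
        b = s.evaluate_pipeline(dataset, small_config)
        assert a.per_repetition.equals(b.per_repetition)
        assert a.manifest["repetitions"] == b.manifest["repetitions"]

    def test_panel_mode_restricts_features(self, dataset):
        panel = dataset.genes[:4]
        cfg = s.PipelineConfig(case=3, n_rep=2, seed=5, panel=panel)
        report = s.evaluate_pipeline(dataset, cfg)
        assert (report.per_repetition["n_features"] == 4).all()

    def test_baseline_classifier_path(self, dataset):
        cfg = s.PipelineConfig(case=3, n_rep=2, seed=5, classifier="KNN")
        report = s.evaluate_pipeline(dataset, cfg)
        assert report.per_repetition["ACC"].between(0, 1).all()

    def test_report_files_round_trip(self, dataset, small_config, tmp_path):
        report = s.evaluate_pipeline(dataset, small_config)
        paths = report.to_files(tmp_path)
        assert paths["per_repetition"].exists()
        assert paths["aggregate"].exists()
        assert paths["manifest"].exists()
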