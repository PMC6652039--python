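"""Laplacian-corrected naive Bayes: booleanization, hand-computed weight
anchors, EstPGood mapping, and out-of-fold stacking behavior."""

import math

import numpy as np
import pytest
from scipy.special import expit

from phenostack.stacked_nb import (
    BayesModel,
    NaiveBayesClassifier,
    best_mcc_threshold,
    booleanize,
    fit_nb,
    fit_stacked,
)
from phenostack.descriptor_engine import DescriptorMatrix


class TestBooleanize:
    def test_binary_column_passes_through(self):
        vals = np.array([[0.0], [1.0], [1.0], [0.0]])
        feats, names, edges = booleanize(vals, ["lab"], [False])
        assert names == ["lab"]
        assert feats[:, 0].tolist() == [0, 1, 1, 0]
        assert edges == {}

    def test_median_split_indicator_pair(self):
        vals = np.array([[0.1], [0.4], [0.6], [0.9]])
        feats, names, _ = booleanize(vals, ["p"], [True], n_bins=2)
        assert names == ["p__bin0", "p__bin1"]
        assert feats[:, 0].tolist() == [1, 1, 0, 0]
        assert feats[:, 1].tolist() == [0, 0, 1, 1]

    def test_out_of_range_value_clamps_to_edge_bin(self):
        train = np.linspace(0, 1, 20).reshape(-1, 1)
        _, _, edges = booleanize(train, ["p"], [True], n_bins=4)
        feats, _, _ = booleanize(np.array([[-5.0], [99.0]]), ["p"], [True],
                                 n_bins=4, edges=edges)
        # interval-membership oracle: which bin does each value fall in?
        e = edges["p"]
        for row, v in zip(feats, [-5.0, 99.0]):
            oracle = sum(v > cut for cut in e)
            assert row.tolist() == [int(b == oracle) for b in range(len(e) + 1)]

    def test_exactly_one_indicator_per_group_fires(self, rng):
        vals = rng.normal(size=(50, 3))
        feats, names, _ = booleanize(vals, ["a", "b", "c"],
                                     [True, True, True], n_bins=5)
        for g in ("a", "b", "c"):
            cols = [i for i, n in enumerate(names) if n.startswith(g + "__")]
            assert np.array_equal(feats[:, cols].sum(axis=1),
                                  np.ones(50))

    def test_constant_feature_collapses_to_single_bin(self):
        vals = np.full((10, 1), 3.3)
        feats, names, _ = booleanize(vals, ["p"], [True], n_bins=5)
        assert names == ["p__bin0"]
        assert feats.all()

    def test_rejects_single_bin(self):
        with pytest.raises(ValueError):
            booleanize(np.zeros((3, 1)), ["p"], [True], n_bins=1)


class TestFitNb:
    def test_unseen_feature_relaxes_to_prior_with_zero_weight(self):
        feats = np.array([[1, 0], [1, 0], [0, 0], [0, 0], [0, 0]])
        model = fit_nb(feats, [1, 0, 0, 0, 0])
        assert model.n_f[1] == 0
        assert model.weights[1] == 0.0

    def test_hand_computed_weight_pure_active_feature(self):
        # P_base = 0.2 so K = 5; feature in 10 compounds, all active
        labels = np.r_[np.ones(10, int), np.zeros(40, int)]
        feats = np.zeros((50, 1), dtype=int)
        feats[:10, 0] = 1
        model = fit_nb(feats, labels)
        assert model.p_base == pytest.approx(0.2)
        p_f = (10 + 1) / (10 + 5)
        assert p_f == pytest.approx(11 / 15)
        assert model.weights[0] == pytest.approx(math.log(p_f / 0.2))
        assert model.weights[0] == pytest.approx(1.2993, abs=1e-4)

    def test_hand_computed_weight_pure_inactive_feature(self):
        labels = np.r_[np.ones(10, int), np.zeros(40, int)]
        feats = np.zeros((50, 1), dtype=int)
        feats[10:20, 0] = 1   # present only among inactives
        model = fit_nb(feats, labels)
        assert model.weights[0] == pytest.approx(math.log((1 / 15) / 0.2))
        assert model.weights[0] == pytest.approx(-1.0986, abs=1e-4)

    def test_always_present_feature_carries_no_information(self):
        labels = np.r_[np.ones(10, int), np.zeros(40, int)]
        model = fit_nb(np.ones((50, 1), dtype=int), labels)
        assert model.weights[0] == pytest.approx(0.0, abs=1e-12)

    def test_weight_strictly_increases_with_active_count(self):
        labels = np.r_[np.ones(20, int), np.zeros(80, int)]
        weights = []
        for a in range(0, 11):
            feats = np.zeros((100, 1), dtype=int)
            feats[:a, 0] = 1            # a actives
            feats[20:30, 0] = 1         # 10 inactives
            weights.append(fit_nb(feats, labels).weights[0])
        assert np.all(np.diff(weights) > 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_nb(np.ones((3, 1)), [1, 1, 1])


class TestScoring:
    @pytest.fixture()
    def model(self):
        return BayesModel(p_base=0.2, feature_names=["f0"],
                          a_f=np.array([10.0]), n_f=np.array([10.0]),
                          weights=np.array([math.log((11 / 15) / 0.2)]))

    def test_empty_row_scores_the_prior(self, model):
        row = np.zeros((1, 1))
        assert model.score(row)[0] == 0.0
        assert model.est_p_good(row)[0] == pytest.approx(0.2)

    def test_single_feature_est_p_good_hand_value(self, model):
        row = np.ones((1, 1))
        expected = expit(math.log(0.25) + 1.2993)
        assert model.est_p_good(row)[0] == pytest.approx(expected, abs=1e-3)
        assert model.est_p_good(row)[0] == pytest.approx(0.478, abs=5e-3)

    def test_adding_positive_weight_feature_never_decreases_est(self):
        m = BayesModel(p_base=0.3, feature_names=["a", "b"],
                       a_f=np.array([5.0, 5.0]), n_f=np.array([6.0, 6.0]),
                       weights=np.array([0.9, 0.4]))
        base = m.est_p_good(np.array([[1, 0]]))[0]
        more = m.est_p_good(np.array([[1, 1]]))[0]
        assert more >= base

    def test_est_p_good_always_in_unit_interval(self, rng):
        w = rng.normal(0, 5, 30)
        m = BayesModel(p_base=0.2, feature_names=[f"f{i}" for i in range(30)],
                       a_f=np.zeros(30), n_f=np.zeros(30), weights=w)
        feats = (rng.random((100, 30)) < 0.5).astype(int)
        est = m.est_p_good(feats)
        assert np.all((est >= 0) & (est <= 1))

    def test_best_mcc_threshold_separates_separable_scores(self):
        labels = np.array([0, 0, 0, 1, 1])
        scores = np.array([-2.0, -1.0, 0.0, 3.0, 4.0])
        t = best_mcc_threshold(labels, scores)
        assert 0.0 < t < 3.0


class TestUninformativeBases:
    def test_constant_probability_features_predict_majority_everywhere(self):
        # all meta-features constant (p=0.5 oracles), no fingerprints:
        # every weight is 0 and the model falls back to the prior < 0.5
        labels = np.r_[np.ones(10, int), np.zeros(40, int)]
        meta = np.full((50, 8), 0.5)
        feats, names, _ = booleanize(meta, [f"m{i}" for i in range(8)],
                                     [True] * 8, n_bins=4)
        model = fit_nb(feats, labels, names)
        preds = model.predict(feats, threshold=0.5)
        assert not preds.any()
        np.testing.assert_allclose(model.est_p_good(feats), 0.2, atol=1e-12)


class TestNaiveBayesClassifier:
    def test_learns_an_informative_descriptor(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(2, 0.5, 30), rng.normal(-2, 0.5, 90)].reshape(-1, 1)
        y = np.r_[np.ones(30, int), np.zeros(90, int)]
        m = DescriptorMatrix([f"c{i}" for i in range(120)], ["d0"], x, y)
        clf = NaiveBayesClassifier(n_bins=5).fit(m)
        out = clf.predict(m)
        acc = (out.predicted_label == y).mean()
        assert acc >= 0.9


class TestFitStacked:
    def test_stacked_model_is_self_contained(self, default_dataset,
                                             stacked_model):
        test = default_dataset.subset("test")
        out1 = stacked_model.predict(test)
        out2 = stacked_model.predict(list(reversed(test)))
        lookup = dict(zip(out2.compound_ids, out2.est_p_good))
        for cid, est in zip(out1.compound_ids, out1.est_p_good):
            assert est == lookup[cid]

    def test_requires_one_spec_per_algorithm(self, default_dataset):
        from phenostack.base_classifiers import ClassifierSpec
        with pytest.raises(ValueError, match="one spec per algorithm"):
            fit_stacked(default_dataset,
                        base_specs=[ClassifierSpec("RF")] * 4)

    def test_feature_table_includes_fingerprints_only_when_asked(
            self, stacked_model, stacked_model_no_fp):
        n_fp = 256
        with_fp = len(stacked_model.nb.feature_names)
        without = len(stacked_model_no_fp.nb.feature_names)
        assert with_fp - without == n_fp

    def test_probability_pair_features_complementary(self, stacked_model,
                                                     default_dataset):
        # p_pos and p_neg bins both exist for every base algorithm
        names = stacked_model.nb.feature_names
        for algo in ("AB", "kNN", "CT", "RF"):
            assert any(n.startswith(f"{algo}_p_pos__") for n in names)
            assert any(n.startswith(f"{algo}_p_neg__") for n in names)
            assert f"{algo}_label" in names
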