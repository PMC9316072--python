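import itertools
import math

import numpy as np
import pytest

from ecshock.errors import ConfigurationError, EvaluationError
from ecshock.naive_bayes import KernelNaiveBayes
from ecshock.nested_cv import (ModelSpec, compare_auc, default_model_specs,
                               entropy_filters, expand_grid_if_edge,
                               forward_wrapper_select, grid_search,
                               make_ltocv_splits, run_nested_cv,
                               select_features)


class TestSplits:
    def test_ltocv_sizes(self):
        ids = [f"S{i}" for i in range(29)]
        splits = make_ltocv_splits(ids, n_rep=29, seed=1)
        assert len(splits) == 29
        for sp in splits:
            assert len(sp.test_subjects) == 2
            assert len(sp.train_subjects) == 27
            assert not set(sp.test_subjects) & set(sp.train_subjects)

    def test_four_subjects_six_reps_cover_all_pairs(self):
        splits = make_ltocv_splits(["a", "b", "c", "d"], n_rep=6, seed=2)
        pairs = {tuple(sorted(sp.test_subjects)) for sp in splits}
        assert pairs == set(itertools.combinations(["a", "b", "c", "d"], 2))

    def test_no_duplicate_pairs_while_possible(self):
        splits = make_ltocv_splits([f"S{i}" for i in range(10)], n_rep=29, seed=3)
        pairs = [tuple(sorted(sp.test_subjects)) for sp in splits]
        assert len(set(pairs)) == len(pairs)  # 29 <= C(10,2) = 45

    def test_too_few_subjects(self):
        with pytest.raises(ConfigurationError):
            make_ltocv_splits(["a", "b", "c"])


class TestEntropyFilters:
    def test_perfect_predictor_gain_equals_label_entropy(self):
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        X = y.reshape(-1, 1).astype(float)
        scores = entropy_filters(X, y)
        assert scores.loc[0, "info_gain"] == pytest.approx(1.0)  # H(y) = 1 bit
        assert scores.loc[0, "sym_uncert"] == pytest.approx(1.0)

    def test_constant_feature_scores_zero(self):
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        scores = entropy_filters(np.ones((40, 1)), y)
        assert (scores.iloc[0] == 0.0).all()

    def test_hand_computed_discrete_table(self):
        # X splits {0,0,1,1}; Y = {0,1,1,1}: H(Y)=0.8113, H(Y|X)=0.5
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 1, 1, 1])
        h_y = -(0.25 * math.log2(0.25) + 0.75 * math.log2(0.75))
        ig = h_y - 0.5
        scores = entropy_filters(X, y)
        assert scores.loc[0, "info_gain"] == pytest.approx(ig)
        assert scores.loc[0, "gain_ratio"] == pytest.approx(ig / 1.0)  # H(X)=1
        assert scores.loc[0, "sym_uncert"] == pytest.approx(2 * ig / (1.0 + h_y))

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            entropy_filters(np.ones((10, 1)), np.ones(10, dtype=int))


class TestSelection:
    def test_knn_uses_all_features(self, rng):
        X = rng.normal(0, 1, (40, 6))
        y = rng.integers(0, 2, 40)
        spec = default_model_specs(6)[0]
        assert spec.algorithm == "knn" and spec.selection == "all"
        assert select_features(spec, X, y) == list(range(6))

    def test_forward_wrapper_picks_informative_first(self, rng):
        y = rng.integers(0, 2, 120)
        X = np.c_[2.0 * y + rng.normal(0, 0.5, 120), rng.normal(0, 1, (120, 9))]
        spec = ModelSpec("knn", {"k": [5]}, "forward-wrapper")
        sel = forward_wrapper_select(spec, X, y, seed=4)
        assert sel[0] == 0

    def test_wrapper_keeps_best_single_feature_when_nothing_helps(self, rng):
        X = rng.normal(0, 1, (40, 4))
        y = rng.integers(0, 2, 40)
        spec = ModelSpec("knn", {"k": [5]}, "forward-wrapper")
        sel = forward_wrapper_select(spec, X, y, seed=5)
        assert len(sel) >= 1

    def test_union_filter_never_empty(self, rng):
        X = rng.normal(0, 1, (60, 5))
        y = rng.integers(0, 2, 60)
        spec = ModelSpec("rf", {"mtry": [2]}, "entropy-filter-union")
        assert len(select_features(spec, X, y)) >= 1


class TestGridSearch:
    def test_single_point_grid(self, rng):
        X = rng.normal(0, 1, (60, 3))
        y = (X[:, 0] > 0).astype(int)
        spec = ModelSpec("rf", {"mtry": [2]})
        chosen, auc = grid_search(spec, X, y, seed=6)
        assert chosen == {"mtry": 2} and 0 <= auc <= 1

    def test_tie_breaks_toward_smaller_value(self, rng):
        # perfectly separable: every k achieves AUC 1, smallest k wins
        X = np.r_[rng.normal(-5, 0.1, (30, 2)), rng.normal(5, 0.1, (30, 2))]
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        spec = ModelSpec("knn", {"k": [3, 5, 7]})
        chosen, auc = grid_search(spec, X, y, seed=7)
        assert auc == 1.0 and chosen == {"k": 3}


class TestGridExpansion:
    def test_interior_choice_no_rerun(self):
        spec = ModelSpec("rf", {"mtry": [2, 5, 8]})
        grid, rerun, _ = expand_grid_if_edge(spec, {"mtry": 5})
        assert not rerun and grid["mtry"] == [2, 5, 8]

    def test_arithmetic_extension_upward(self):
        spec = ModelSpec("rf", {"mtry": [2, 5, 8]})
        grid, rerun, log = expand_grid_if_edge(spec, {"mtry": 8})
        assert rerun and grid["mtry"] == [2, 5, 8, 11]

    def test_geometric_extension_downward(self):
        spec = ModelSpec("svmrad", {"sigma": [0.25, 0.5, 1.0], "cost": [1, 2]})
        grid, rerun, _ = expand_grid_if_edge(spec, {"sigma": 0.25, "cost": 2})
        assert rerun
        assert min(grid["sigma"]) == pytest.approx(0.125)

    def test_positive_axis_never_extended_below_zero(self):
        spec = ModelSpec("rf", {"mtry": [2, 5, 8]})
        grid, rerun, _ = expand_grid_if_edge(spec, {"mtry": 2})
        assert min(grid["mtry"]) > 0

    def test_expansion_capped(self):
        spec = ModelSpec("rf", {"mtry": [2, 5, 8]})
        log = {("mtry", "high"): 2}
        grid, rerun, _ = expand_grid_if_edge(spec, {"mtry": 8}, log)
        assert not rerun


class TestKernelNaiveBayes:
    def test_separates_shifted_gaussians(self, rng):
        X = np.r_[rng.normal(0, 1, (80, 2)), rng.normal(3, 1, (80, 2))]
        y = np.r_[np.zeros(80), np.ones(80)].astype(int)
        for kernel in (False, True):
            nb = KernelNaiveBayes(kernel=kernel).fit(X, y)
            assert (nb.predict(X) == y).mean() > 0.9
            proba = nb.predict_proba(X)
            assert np.allclose(proba.sum(axis=1), 1.0)

    def test_invalid_bandwidth_rejected(self):
        with pytest.raises(ConfigurationError):
            KernelNaiveBayes(kernel=True, adjust=-1.0).fit(
                np.zeros((4, 1)), np.array([0, 0, 1, 1]))


class TestModelSpec:
    def test_grid_axes_must_match_algorithm(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("rf", {"k": [1]})

    def test_default_specs_cover_all_families(self):
        specs = default_model_specs(119)
        assert [s.algorithm for s in specs] == ["knn", "nb", "svmrad", "svmlin", "rf"]
        nb = specs[1]
        assert all(a > 0 for a in nb.grid["adjust"])  # clamped to valid bandwidths
        assert all(f >= 0 for f in nb.grid["fL"])


class TestCompareAuc:
    def test_identical_distributions_large_p(self, rng):
        a = rng.uniform(0.7, 0.9, 29)
        assert compare_auc(a, a) > 0.5

    def test_identical_constant_samples(self):
        assert compare_auc([0.8] * 5, [0.8] * 5) == 1.0

    def test_shifted_distributions_tiny_p(self, rng):
        a = rng.normal(0.9, 0.02, 29)
        b = rng.normal(0.5, 0.02, 29)
        assert compare_auc(a, b) < 1e-3

    def test_insufficient_samples(self):
        with pytest.raises(EvaluationError):
            compare_auc([0.9], [0.5])


@pytest.fixture(scope="module")
def cv_output(feature_table):
    spec = ModelSpec("rf", {"mtry": [3, 6]}, "entropy-filter-union")
    return spec, run_nested_cv([spec], feature_table, n_rep=3, seed=21)


class TestRunNestedCv:
    def test_outputs_shape(self, cv_output):
        _, (results, markers) = cv_output
        res = results["rf"]
        assert len(res.aucs) == 3
        assert all(np.isnan(a) or 0 <= a <= 1 for a in res.aucs)
        assert set(markers["marker"]) == {"hr", "sbp", "dbp", "map"}
        assert len(res.selected_features[0]) >= 1
        assert set(res.chosen_params[0]) == {"mtry"}

    def test_deterministic_given_seed(self, feature_table, cv_output):
        spec, (results, _) = cv_output
        again, _ = run_nested_cv([spec], feature_table, n_rep=3, seed=21)
        assert results["rf"].aucs == again["rf"].aucs
        assert results["rf"].chosen_params == again["rf"].chosen_params

    def test_train_test_subject_disjointness(self, feature_table):
        splits = make_ltocv_splits(feature_table["subject_id"].unique(),
                                   n_rep=10, seed=9)
        for sp in splits:
            assert not set(sp.test_subjects) & set(sp.train_subjects)
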