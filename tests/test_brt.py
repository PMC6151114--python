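"""BRT engine: deviance, tree growth, boosting, influence, dependence."""

import numpy as np
import pandas as pd
import pytest

from brtsdm import (
    BRTModel,
    BRTParams,
    RegressionTree,
    bernoulli_deviance,
    fit_brt,
    fit_regression_tree,
    partial_dependence,
    predict_brt,
    relative_influence,
)
from brtsdm.brt import _Node, _logistic

from conftest import make_binary_dataset


def brute_force_stump(x: np.ndarray, z: np.ndarray, min_obs: int = 1):
    """Exhaustive best split of one variable by SSE reduction of z."""
    order = np.argsort(x)
    xs, zs = x[order], z[order]
    total = zs.sum()
    n = len(zs)
    base = total**2 / n
    best = None
    for i in range(1, n):
        if xs[i] == xs[i - 1] or i < min_obs or n - i < min_obs:
            continue
        gain = zs[:i].sum() ** 2 / i + zs[i:].sum() ** 2 / (n - i) - base
        thr = (xs[i - 1] + xs[i]) / 2.0
        if best is None or gain > best[0] + 1e-12:
            best = (gain, thr)
    return best


def leaf(value):
    return _Node(value=value)


def split(feature, threshold, left, right, improvement=0.0):
    return _Node(feature=feature, threshold=threshold, left=left, right=right,
                 improvement=improvement)


class TestDeviance:
    def test_known_value(self):
        d = bernoulli_deviance([1, 0], [0.5, 0.5])
        assert d == pytest.approx(-2 * np.log(0.5), abs=1e-12)

    def test_perfect_fit_limit(self):
        y = np.array([1.0, 0.0, 1.0])
        assert bernoulli_deviance(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 20).astype(float)
        p = rng.random(20)
        perm = rng.permutation(20)
        assert bernoulli_deviance(y, p) == pytest.approx(
            bernoulli_deviance(y[perm], p[perm]), abs=1e-14)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bernoulli_deviance([1, 0], [0.5])


class TestRegressionTree:
    def test_split_matches_exhaustive_search(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(6, 21))
            x = np.round(rng.normal(size=n), 2)
            z = rng.normal(size=n)
            p = np.full(n, 0.5)
            tree = fit_regression_tree(x[:, None], z, z, p * (1 - p),
                                       tc=1, min_obs_per_node=1)
            expected = brute_force_stump(x, z)
            if expected is None or expected[0] <= 0:
                assert tree.n_splits == 0
                continue
            assert tree.n_splits == 1
            assert tree.root.threshold == pytest.approx(expected[1])
            assert tree.root.improvement == pytest.approx(expected[0], rel=1e-9)

    def test_tc_one_gives_exactly_two_leaves(self):
        x = np.arange(10.0)
        z = np.array([0.0] * 5 + [1.0] * 5)
        p = np.full(10, 0.5)
        tree = fit_regression_tree(x[:, None], z, z, p * (1 - p), tc=1,
                                   min_obs_per_node=1)
        assert tree.n_splits == 1
        assert tree.root.left.is_leaf and tree.root.right.is_leaf

    def test_constant_response_single_leaf(self):
        x = np.arange(8.0)
        z = np.zeros(8)
        y_minus_p = np.full(8, 0.3)
        den = np.full(8, 0.25)
        tree = fit_regression_tree(x[:, None], z, y_minus_p, den, tc=3,
                                   min_obs_per_node=1)
        assert tree.n_splits == 0
        # pooled Newton step: sum(y-p)/sum(p(1-p)) = 2.4/2.0
        assert tree.root.value == pytest.approx(1.2)

    def test_min_obs_respected(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        z = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 10.0])
        p = np.full(6, 0.5)
        tree = fit_regression_tree(x[:, None], z, z, p * (1 - p), tc=1,
                                   min_obs_per_node=2)
        if tree.n_splits:  # isolating the outlier alone is inadmissible
            assert tree.root.threshold < 4.5


class TestFitPredict:
    def test_empty_ensemble_predicts_prevalence(self, binary_data):
        params = BRTParams(max_trees=0)
        model = fit_brt(binary_data, params)
        probs = predict_brt(model, binary_data)
        np.testing.assert_allclose(probs, binary_data["label"].mean())

    def test_full_bag_training_deviance_nonincreasing(self, binary_data):
        params = BRTParams(bf=1.0, lr=0.1, tc=2, ss=10, max_trees=60,
                           n_folds=5, seed=3)
        model = fit_brt(binary_data, params)
        X = binary_data[model.variables]
        y = binary_data["label"].to_numpy(dtype=float)
        F = np.full(len(y), model.intercept)
        devs = [bernoulli_deviance(y, _logistic(F))]
        for tree in model.trees:
            F += tree.predict(X.to_numpy(dtype=float))
            devs.append(bernoulli_deviance(y, _logistic(F)))
        assert (np.diff(devs) <= 1e-12).all()

    def test_separable_data_recovers_threshold(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-1, 1, 200)
        y = (x > 0.1).astype(int)
        data = pd.DataFrame({"x": x, "label": y})
        params = BRTParams(bf=1.0, lr=0.5, tc=1, ss=5, max_trees=50,
                           n_folds=5, min_obs_per_node=5, seed=5)
        model = fit_brt(data, params)
        first = model.trees[0].root
        gap = np.sort(x)
        lo = gap[y[np.argsort(x)] == 0].max()
        hi = x[y == 1].min()
        assert lo < first.threshold < hi
        from brtsdm import auc

        assert auc(y, predict_brt(model, data)) == pytest.approx(1.0)

    def test_seeded_bit_reproducibility(self, binary_data):
        params = BRTParams(bf=0.6, lr=0.1, tc=2, ss=10, max_trees=40,
                           n_folds=4, seed=11)
        m1 = fit_brt(binary_data, params)
        m2 = fit_brt(binary_data, params)
        assert m1.to_json() == m2.to_json()
        np.testing.assert_array_equal(predict_brt(m1, binary_data),
                                      predict_brt(m2, binary_data))

    def test_json_round_trip_prediction_exact(self, binary_data):
        params = BRTParams(bf=0.6, lr=0.1, tc=3, ss=10, max_trees=40,
                           n_folds=4, seed=12)
        model = fit_brt(binary_data, params)
        clone = BRTModel.from_json(model.to_json())
        np.testing.assert_array_equal(predict_brt(model, binary_data),
                                      predict_brt(clone, binary_data))
        assert clone.nt == model.nt

    def test_halved_learning_rate_needs_no_fewer_trees(self):
        wins = 0
        for seed in range(5):
            data = make_binary_dataset(n=300, seed=100 + seed)
            base = dict(bf=1.0, tc=2, ss=10, max_trees=300, n_folds=5,
                        patience=3, seed=seed)
            nt_fast = fit_brt(data, BRTParams(lr=0.1, **base)).nt
            nt_slow = fit_brt(data, BRTParams(lr=0.05, **base)).nt
            if nt_slow >= nt_fast:
                wins += 1
        assert wins >= 4

    def test_probabilities_bounded_logits_finite(self, binary_data):
        params = BRTParams(bf=0.75, lr=0.2, tc=3, ss=10, max_trees=60,
                           n_folds=4, seed=13)
        model = fit_brt(binary_data, params)
        probs = predict_brt(model, binary_data)
        logits = predict_brt(model, binary_data, scale="logit")
        assert ((probs > 0) & (probs < 1)).all()
        assert np.isfinite(logits).all()

    def test_single_class_rejected(self):
        data = pd.DataFrame({"x": [1.0, 2.0, 3.0], "label": [1, 1, 1]})
        with pytest.raises(ValueError):
            fit_brt(data, BRTParams(n_folds=2))

    def test_zero_trees_probability_is_logistic_intercept(self):
        model = BRTModel(intercept=0.0, trees=[], nt=0, params=BRTParams(),
                         variables=["x"])
        p = predict_brt(model, pd.DataFrame({"x": [1.0, -5.0]}))
        np.testing.assert_allclose(p, 0.5)

    def test_two_constant_trees_analytic_logistic(self):
        trees = [RegressionTree(leaf(0.3), 0), RegressionTree(leaf(-0.1), 0)]
        model = BRTModel(intercept=0.0, trees=trees, nt=2, params=BRTParams(),
                         variables=["x"])
        p = predict_brt(model, pd.DataFrame({"x": [7.0]}))
        assert p[0] == pytest.approx(1 / (1 + np.exp(-0.2)), abs=1e-10)

    def test_vector_prediction_matches_manual_traversal(self):
        # one split on x at 0, left leaf +1, right split never reached from
        # the left; hand-traverse each row
        tree = RegressionTree(
            split(0, 0.0, leaf(1.0), split(1, 2.0, leaf(-0.5), leaf(0.25))),
            n_splits=2,
        )
        model = BRTModel(intercept=0.1, trees=[tree], nt=1, params=BRTParams(),
                         variables=["x", "w"])
        rows = pd.DataFrame({"x": [-1.0, 0.0, 1.0, 1.0],
                             "w": [9.0, 9.0, 1.0, 3.0]})
        expected = 0.1 + np.array([1.0, 1.0, -0.5, 0.25])
        np.testing.assert_allclose(
            predict_brt(model, rows, scale="logit"), expected)


class TestInfluence:
    def test_sums_to_hundred(self, binary_data):
        params = BRTParams(bf=0.75, lr=0.1, tc=2, ss=10, max_trees=50,
                           n_folds=4, seed=21)
        model = fit_brt(binary_data, params)
        inf = relative_influence(model)
        assert inf.sum() == pytest.approx(100.0, abs=1e-6)
        assert (inf >= 0).all()

    def test_hand_built_accumulation(self):
        # improvements A: {8, 2}, B: {10} -> 50% / 50%
        t1 = RegressionTree(split(0, 0.0, leaf(0.1), leaf(-0.1), improvement=8.0),
                            n_splits=1)
        t2 = RegressionTree(
            split(0, 1.0,
                  split(1, 0.0, leaf(0.0), leaf(0.1), improvement=10.0),
                  leaf(0.2), improvement=2.0),
            n_splits=2,
        )
        model = BRTModel(intercept=0.0, trees=[t1, t2], nt=2,
                         params=BRTParams(), variables=["A", "B"])
        inf = relative_influence(model)
        assert inf["A"] == pytest.approx(50.0)
        assert inf["B"] == pytest.approx(50.0)

    def test_single_variable_model_gets_all(self):
        t = RegressionTree(split(0, 0.0, leaf(0.1), leaf(-0.1), improvement=3.0),
                           n_splits=1)
        model = BRTModel(intercept=0.0, trees=[t], nt=1, params=BRTParams(),
                         variables=["A", "B"])
        inf = relative_influence(model)
        assert inf["A"] == pytest.approx(100.0) and inf["B"] == 0.0

    def test_true_drivers_rank_first(self):
        hits = 0
        for seed in range(5):
            data = make_binary_dataset(n=400, seed=200 + seed, n_noise=6)
            params = BRTParams(bf=0.75, lr=0.1, tc=2, ss=10, max_trees=150,
                               n_folds=4, seed=seed)
            inf = relative_influence(fit_brt(data, params))
            if set(inf.index[:2]) == {"x1", "x2"}:
                hits += 1
        assert hits >= 4


class TestPartialDependence:
    def test_unused_variable_constant_curve(self, binary_data):
        t = RegressionTree(split(0, 0.0, leaf(0.5), leaf(-0.5), improvement=1.0),
                           n_splits=1)
        model = BRTModel(intercept=0.2, trees=[t], nt=1, params=BRTParams(),
                         variables=["x1", "x2"])
        curve = partial_dependence(model, "x2", np.linspace(-2, 2, 7),
                                   binary_data[["x1", "x2"]])
        assert curve["mean_logit"].std() == pytest.approx(0.0, abs=1e-14)

    def test_single_split_step_function(self, binary_data):
        t = RegressionTree(split(0, 0.3, leaf(1.0), leaf(-1.0), improvement=1.0),
                           n_splits=1)
        model = BRTModel(intercept=0.0, trees=[t], nt=1, params=BRTParams(),
                         variables=["x1", "x2"])
        curve = partial_dependence(model, "x1", np.array([-1.0, 0.0, 1.0, 2.0]),
                                   binary_data[["x1", "x2"]])
        vals = curve["mean_logit"].to_numpy()
        np.testing.assert_allclose(vals, [1.0, 1.0, -1.0, -1.0])

    def test_matches_brute_force_overwrite(self, binary_data):
        params = BRTParams(bf=0.75, lr=0.1, tc=2, ss=10, max_trees=30,
                           n_folds=4, seed=31)
        model = fit_brt(binary_data, params)
        background = binary_data[model.variables].head(50)
        grid = np.linspace(-2, 2, 11)
        curve = partial_dependence(model, "x1", grid, background)
        for v, got in zip(grid, curve["mean_logit"]):
            acc = 0.0
            for _, row in background.iterrows():
                r = row.copy()
                r["x1"] = v
                acc += predict_brt(model, r.to_frame().T, scale="logit")[0]
            assert got == pytest.approx(acc / len(background), abs=1e-10)

    def test_empty_grid_rejected(self, binary_data):
        model = fit_brt(binary_data, BRTParams(max_trees=0))
        with pytest.raises(ValueError):
            partial_dependence(model, "x1", np.array([]), binary_data)


class TestStagewiseSelection:
    def test_profile_evaluated_every_step_size(self, binary_data):
        params = BRTParams(bf=0.75, lr=0.1, tc=2, ss=15, max_trees=90,
                           n_folds=4, patience=100, seed=41)
        model = fit_brt(binary_data, params)
        nts = [nt for nt, _ in model.cv_deviance_profile]
        assert nts == list(range(15, 91, 15))
        assert model.nt in nts

    def test_selected_nt_minimizes_profile(self, binary_data):
        params = BRTParams(bf=0.75, lr=0.2, tc=2, ss=10, max_trees=120,
                           n_folds=4, seed=42)
        model = fit_brt(binary_data, params)
        devs = dict(model.cv_deviance_profile)
        assert devs[model.nt] == min(devs.values())
        assert len(model.trees) == model.nt

    def test_cap_with_improving_deviance_is_flagged(self, binary_data):
        params = BRTParams(bf=1.0, lr=0.001, tc=1, ss=10, max_trees=20,
                           n_folds=4, seed=43)
        model = fit_brt(binary_data, params)
        assert model.metadata["nt_at_cap_still_improving"]
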