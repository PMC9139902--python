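"""Bootstrap, logistic-fit, 0.632+, forward-selection and DeLong tests.

Independent oracles: sklearn's ridge-penalized logistic regression for the
in-package Newton fit; a label-preserving permutation test for the DeLong
p-value; closed-form hand evaluations for the 0.632+ estimator.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hccradiomics import (
    BootstrapConfig,
    LogisticModel,
    auc,
    balanced_bootstrap,
    delong_compare,
    estimate_632plus,
    evaluate_model,
    fit_logistic,
    forward_select,
    pairwise_delong,
    predict,
    select_best_order,
)
from hccradiomics.errors import (
    ConstantFeatureError,
    DegenerateVarianceError,
    SingleClassError,
)
from hccradiomics.modeling import ModelPerformance, overfitting_weight


class TestBalancedBootstrap:
    def test_imbalance_adjustment_equalizes_class_draw(self):
        y = np.r_[np.ones(7), np.zeros(31)].astype(int)
        pairs = balanced_bootstrap(y, BootstrapConfig(b=1000, seed=3))
        mean_pos = np.mean([(y[in_bag] == 1).sum() for in_bag, _ in pairs])
        se = np.sqrt(38 * 0.25 / 1000)  # SE of the mean of Binomial(38, 1/2)
        assert abs(mean_pos - 19.0) < 3 * se

    def test_plain_bootstrap_keeps_class_rates(self):
        y = np.r_[np.ones(7), np.zeros(31)].astype(int)
        pairs = balanced_bootstrap(
            y, BootstrapConfig(b=1000, seed=3, imbalance_adjusted=False)
        )
        mean_pos = np.mean([(y[in_bag] == 1).sum() for in_bag, _ in pairs])
        assert abs(mean_pos - 7.0) < 1.0

    def test_in_bag_and_oob_partition_rows(self):
        y = np.r_[np.ones(4), np.zeros(20)].astype(int)
        for in_bag, oob in balanced_bootstrap(y, BootstrapConfig(b=200, seed=0)):
            assert len(in_bag) == 24
            assert len(np.intersect1d(in_bag, oob)) == 0
            assert set(in_bag) | set(oob) == set(range(24))

    def test_in_bag_positive_counts_are_binomial(self):
        # chi-square goodness of fit of in-bag positive counts vs Binomial(n, 1/2)
        from scipy import stats

        y = np.r_[np.ones(7), np.zeros(31)].astype(int)
        pairs = balanced_bootstrap(y, BootstrapConfig(b=1000, seed=5))
        counts = np.array([(y[in_bag] == 1).sum() for in_bag, _ in pairs])
        support = np.arange(39)
        pmf = stats.binom.pmf(support, 38, 0.5)
        # pool tails so expected cell counts stay >= 5
        edges = support[(pmf * 1000).cumsum() > 5][0], support[::-1][(pmf[::-1] * 1000).cumsum() > 5][0]
        bins = np.clip(counts, *edges)
        observed = pd.Series(bins).value_counts().reindex(
            np.arange(edges[0], edges[1] + 1), fill_value=0
        )
        expected = pmf.copy()
        expected[edges[0]] = pmf[: edges[0] + 1].sum()
        expected[edges[1]] = pmf[edges[1]:].sum()
        expected = expected[edges[0] : edges[1] + 1] * 1000
        p = stats.chisquare(observed.to_numpy(), expected).pvalue
        assert p > 0.001

    def test_reproducible_from_seed(self):
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        a = balanced_bootstrap(y, BootstrapConfig(b=50, seed=9))
        b = balanced_bootstrap(y, BootstrapConfig(b=50, seed=9))
        assert all(
            np.array_equal(x1, x2) and np.array_equal(o1, o2)
            for (x1, o1), (x2, o2) in zip(a, b)
        )

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            balanced_bootstrap(np.ones(10, dtype=int), BootstrapConfig(b=10, seed=0))


class TestFitLogistic:
    def test_symmetric_data_yields_null_model(self):
        m = fit_logistic(np.array([-1.0, -1.0, 1.0, 1.0]), [0, 1, 0, 1])
        assert m.beta0 == pytest.approx(0.0, abs=1e-8)
        assert m.betas[0] == pytest.approx(0.0, abs=1e-8)

    def test_separable_data_finite_positive_slope(self):
        m = fit_logistic(np.array([-1.0, -1.0, 1.0, 1.0]), [0, 0, 1, 1])
        assert np.isfinite(m.betas[0]) and m.betas[0] > 0

    def test_matches_sklearn_ridge_oracle(self, rng):
        from sklearn.linear_model import LogisticRegression

        X = rng.normal(size=(20, 3))
        y = (X @ [1.0, -0.5, 0.2] + rng.normal(size=20) > 0).astype(int)
        m = fit_logistic(X, y)
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        sk = LogisticRegression(C=1e6, tol=1e-12, max_iter=100_000).fit(Z, y)
        np.testing.assert_allclose(m.betas, sk.coef_[0], atol=1e-6)
        assert m.beta0 == pytest.approx(sk.intercept_[0], abs=1e-6)

    def test_constant_column_rejected(self):
        with pytest.raises(ConstantFeatureError):
            fit_logistic(np.ones((6, 1)), [0, 1, 0, 1, 0, 1])

    def test_model_json_roundtrip(self, rng, tmp_path):
        X = rng.normal(size=(30, 2))
        y = (X[:, 0] > 0).astype(int)
        m = fit_logistic(X, y, features=["f1", "f2"])
        path = tmp_path / "model.json"
        m.save(path)
        back = LogisticModel.load(path)
        np.testing.assert_allclose(back.predict_proba(X), m.predict_proba(X))


class TestPredict:
    def test_published_style_coefficients_worked_example(self):
        # g = 0.18 - 21.4*0.1 + 7.41*0.2 = -0.478 on standardized inputs
        m = LogisticModel(["f1", "f2"], 0.18, [-21.4, 7.41], [0.0, 0.0], [1.0, 1.0])
        p = predict(m, {"f1": 0.1, "f2": 0.2})
        assert p == pytest.approx(0.3827, abs=1e-4)

    def test_midpoint_probability(self):
        m = LogisticModel(["f"], 0.0, [1.0], [0.0], [1.0])
        assert predict(m, {"f": 0.0}) == pytest.approx(0.5)

    @given(st.floats(-30, 30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_logistic_symmetry(self, g):
        m = LogisticModel(["f"], 0.0, [1.0], [0.0], [1.0])
        assert predict(m, {"f": g}) + predict(m, {"f": -g}) == pytest.approx(1.0)

    def test_missing_feature_rejected(self):
        m = LogisticModel(["f1", "f2"], 0.0, [1.0, 1.0], [0.0, 0.0], [1.0, 1.0])
        with pytest.raises(KeyError, match="f2"):
            predict(m, {"f1": 0.1})


class TestAuc:
    def test_hand_counted_concordance(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_and_tied(self):
        assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert auc([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1]) == 0.5

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_increasing_transform(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=20)
        y = rng.integers(0, 2, size=20)
        y[:2] = [0, 1]
        assert auc(np.exp(s), y) == pytest.approx(auc(s, y))


class TestEstimate632Plus:
    @pytest.mark.parametrize(
        "apparent,oob,expected",
        [
            (0.8, 0.8, 0.8),       # no overfitting: fixed point
            (1.0, 0.5, 0.5),       # maximal overfitting collapses to chance
            (0.9, 0.7, 0.745098),  # R = 0.5, w = 0.632/0.816
        ],
    )
    def test_closed_form_cases(self, apparent, oob, expected):
        assert estimate_632plus(apparent, oob, 0.5) == pytest.approx(expected, abs=1e-4)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_weight_and_bracketing(self, apparent, oob):
        w = overfitting_weight(apparent, oob, 0.5)
        assert 0.632 <= w <= 1.0
        est = estimate_632plus(apparent, oob, 0.5)
        m_prime = max(oob, 0.5)
        assert min(apparent, m_prime) - 1e-12 <= est <= max(apparent, m_prime) + 1e-12


class TestEvaluateModel:
    def test_label_copy_feature_near_perfect(self, rng):
        y = np.r_[np.ones(19), np.zeros(19)].astype(int)
        values = pd.DataFrame({"signal": y + rng.normal(scale=1e-3, size=38)})
        perf = evaluate_model(["signal"], values, y, BootstrapConfig(b=200, seed=0))
        assert perf.auc632 >= 0.95

    def test_pure_noise_feature_calibrated_near_chance(self):
        # for a pre-specified noise feature the 0.632+ AUC concentrates at
        # chance; single datasets with a spurious sample association (the
        # |Z| > 2 tail at n = 38) carry it into both in-bag and out-of-bag
        # rows, so individual estimates can reach the apparent AUC but
        # never exceed it
        estimates, hits = [], 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.r_[np.ones(19), np.zeros(19)].astype(int)
            values = pd.DataFrame({"noise": rng.normal(size=38)})
            perf = evaluate_model(["noise"], values, y, BootstrapConfig(b=200, seed=seed))
            estimates.append(perf.auc632)
            hits += 0.4 <= perf.auc632 <= 0.6
            assert perf.auc632 <= max(perf.apparent_auc, 0.5) + 1e-9
        assert 0.45 <= np.mean(estimates) <= 0.60
        assert hits >= 14

    def test_metrics_within_unit_interval(self, rng):
        y = np.r_[np.ones(10), np.zeros(14)].astype(int)
        values = pd.DataFrame(rng.normal(size=(24, 2)), columns=["a", "b"])
        perf = evaluate_model(["a", "b"], values, y, BootstrapConfig(b=50, seed=1))
        for v in perf.to_dict().values():
            assert 0 <= v <= 1 or isinstance(v, int)


class TestForwardSelect:
    def test_nested_feature_sets_and_exhaustion(self, rng):
        y = np.r_[np.ones(15), np.zeros(15)].astype(int)
        values = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        values["a"] += y
        built = forward_select(list("abcd"), values, y, max_order=4,
                               config=BootstrapConfig(b=30, seed=2))
        feats = [set(m.features) for _, m, _ in built]
        for lower, upper in zip(feats, feats[1:]):
            assert lower < upper
        assert feats[-1] == set("abcd")
        assert [o for o, _, _ in built] == [1, 2, 3, 4]

    def test_planted_pair_recovered_at_order_two(self, rng):
        y = np.r_[np.ones(19), np.zeros(19)].astype(int)
        values = pd.DataFrame(rng.normal(size=(38, 5)), columns=list("abcde"))
        values["b"] += 2.0 * y
        values["d"] += 2.0 * y
        built = forward_select(list("abcde"), values, y, max_order=2,
                               config=BootstrapConfig(b=100, seed=4))
        assert set(built[1][1].features) == {"b", "d"}


class TestSelectBestOrder:
    def _perfs(self, aucs, specs=None):
        specs = specs or [0.5] * len(aucs)
        return [
            ModelPerformance(i + 1, a, 0.5, s, 0.5, a, 0.5, s, 0.5)
            for i, (a, s) in enumerate(zip(aucs, specs))
        ]

    def test_plateau_picks_simplest_within_epsilon(self):
        assert select_best_order(self._perfs([0.90, 0.96, 0.96, 0.95, 0.94])) == 2

    def test_strictly_increasing_picks_max_order(self):
        assert select_best_order(self._perfs([0.7, 0.8, 0.9, 0.95, 0.99])) == 5

    def test_all_equal_picks_order_one(self):
        assert select_best_order(self._perfs([0.9] * 5)) == 1

    def test_specificity_tie_break(self):
        perfs = self._perfs([0.90, 0.95, 0.95, 0.95, 0.90], [0.5, 0.6, 0.8, 0.7, 0.9])
        assert select_best_order(perfs, tie_break="specificity") == 3


class TestDeLong:
    def test_identical_scores_give_p_one(self, rng):
        s = rng.normal(size=20)
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        assert delong_compare(s, s.copy(), y) == 1.0

    def test_degenerate_variance_with_unequal_aucs(self):
        y = np.r_[np.ones(6), np.zeros(6)].astype(int)
        with pytest.raises(DegenerateVarianceError):
            delong_compare(y.astype(float), 1.0 - y, y)

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(77)
        y = np.r_[np.ones(6), np.zeros(6)].astype(int)
        a = y + rng.normal(scale=1.2, size=12)
        b = rng.normal(size=12)
        p_delong = delong_compare(a, b, y)

        t_obs = auc(a, y) - auc(b, y)
        hits = 0
        n_perm = 10_000
        for _ in range(n_perm):
            m = rng.random(12) < 0.5
            a2, b2 = np.where(m, b, a), np.where(m, a, b)
            if abs(auc(a2, y) - auc(b2, y)) >= abs(t_obs) - 1e-12:
                hits += 1
        p_perm = hits / n_perm
        assert p_delong == pytest.approx(p_perm, abs=0.1)

    def test_pairwise_bonferroni_caps_at_one(self, rng):
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        scores = {i: rng.normal(size=20) for i in range(4)}
        out = pairwise_delong(scores, y)
        assert len(out) == 6
        np.testing.assert_allclose(
            out["p_bonferroni"], np.minimum(out["p_value"] * 6, 1.0)
        )
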