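"""Statistical pipeline against independent oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps

from sitstandgo.errors import ConfigurationError, DegenerateInputError
from sitstandgo.stats import (
    Preprocessor, bootstrap_optimism, check_linearity_rcs, compute_auc,
    delong_test, dichotomize_llfdi, fit_logistic, group_to_binary,
    iterative_vif_prune, preprocess_features, rcs_nonlinear_basis,
    stepwise_backward, univariable_screen,
)


def _cohort(llfdi):
    return pd.DataFrame({"subject_id": [f"S{i}" for i in range(len(llfdi))],
                         "llfdi": llfdi})


class TestDichotomize:
    def test_even_split(self):
        out = dichotomize_llfdi(_cohort([60.0, 70.0, 80.0, 90.0]))
        assert (out["group"] == "VHFS").sum() == 2
        assert (out["group"] == "HFS").sum() == 2

    def test_median_value_itself_is_vhfs(self):
        # the median score belongs to the upper (very high) group
        out = dichotomize_llfdi(_cohort([44.33, 65.0, 72.31, 80.0, 100.0]))
        assert out.loc[out["llfdi"] == 72.31, "group"].item() == "VHFS"

    def test_no_tie_split_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(0)
        out = dichotomize_llfdi(_cohort(rng.uniform(44, 100, 160)))
        sizes = out["group"].value_counts()
        assert abs(sizes["VHFS"] - sizes["HFS"]) <= 1

    def test_identical_scores_rejected(self):
        with pytest.raises(ConfigurationError):
            dichotomize_llfdi(_cohort([70.0] * 5))


class TestPreprocess:
    def test_zscore_moments(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"a": rng.normal(5, 2, 100),
                              "b": rng.lognormal(0, 1, 100)})
        z = preprocess_features(table, njs_columns=["b"])
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_log_applied_to_njs_columns(self):
        table = pd.DataFrame({"njs": np.exp([1.0, 2.0, 3.0])})
        pre = Preprocessor(njs_columns=["njs"])
        z = pre.fit_transform(table)
        # log makes the column exactly {1,2,3}; z-scores are equidistant
        assert np.allclose(np.diff(z["njs"]), z["njs"].iloc[1] - z["njs"].iloc[0])
        assert pre.means["njs"] == pytest.approx(2.0)

    def test_nonpositive_jerk_rejected_with_location(self):
        table = pd.DataFrame({"njs": [1.0, -0.5, 2.0]})
        with pytest.raises(ConfigurationError, match="njs"):
            preprocess_features(table, njs_columns=["njs"])

    def test_constant_column_rejected(self):
        table = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ConfigurationError):
            preprocess_features(table, njs_columns=[])


class TestLinearityCheck:
    def test_knots_are_empirical_quantiles(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        knots = np.quantile(x, (0.1, 0.5, 0.9))
        basis = rcs_nonlinear_basis(x, tuple(knots))
        # below the first knot the nonlinear basis vanishes identically
        assert np.all(basis[x < knots[0]] == 0.0)

    def test_detects_strong_quadratic_logit(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2000)
        p = 1 / (1 + np.exp(-(x ** 2 - 1)))
        y = (rng.uniform(size=x.size) < p).astype(float)
        assert check_linearity_rcs(x, y) < 0.05

    def test_linear_logit_usually_not_flagged(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(10):
            x = rng.normal(size=800)
            y = (rng.uniform(size=800) < 1 / (1 + np.exp(-x))).astype(float)
            hits += check_linearity_rcs(x, y) < 0.05
        assert hits <= 3

    def test_too_few_observations_rejected(self):
        with pytest.raises(DegenerateInputError):
            check_linearity_rcs(np.arange(10.0), np.tile([0, 1.0], 5))


def _brute_force_vif(X: np.ndarray) -> np.ndarray:
    """Independent VIF oracle via explicit OLS R^2 regressions."""
    import statsmodels.api as sm
    out = []
    for j in range(X.shape[1]):
        r2 = sm.OLS(X[:, j], sm.add_constant(np.delete(X, j, 1))).fit().rsquared
        out.append(np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2))
    return np.array(out)


class TestVifPrune:
    def test_independent_columns_untouched(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        report = iterative_vif_prune(table)
        assert report.removed == []
        assert report.surviving == list("abcd")

    def test_constructed_collinear_triple(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=(2, 300))
        table = pd.DataFrame({"a": a, "b": b,
                              "c": a + b + rng.normal(0, 0.01, 300),
                              "d": rng.normal(size=300)})
        report = iterative_vif_prune(table)
        assert len(report.removed) == 1
        assert report.removed[0][0] in {"a", "b", "c"}
        assert _brute_force_vif(table[report.surviving].to_numpy()).max() < 10

    def test_duplicated_column_removed_with_infinite_vif(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=100)
        table = pd.DataFrame({"x1": x, "x2": x.copy(),
                              "y": rng.normal(size=100)})
        report = iterative_vif_prune(table)
        assert report.removed[0][0] == "x1"     # tie-break: first column
        assert np.isinf(report.removed[0][1])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(3):
            base = rng.normal(size=(200, 5))
            mix = base @ rng.normal(size=(5, 7)) + 0.4 * rng.normal(size=(200, 7))
            table = pd.DataFrame(mix, columns=[f"f{i}" for i in range(7)])
            mine = iterative_vif_prune(table)
            # replay the loop with the oracle VIFs
            cols = list(table.columns)
            removed = []
            while True:
                v = _brute_force_vif(table[cols].to_numpy())
                j = int(np.argmax(v))
                if v[j] < 10:
                    break
                removed.append(cols.pop(j))
            assert [r[0] for r in mine.removed] == removed
            assert mine.surviving == cols


class TestLogisticFits:
    def test_coefficients_match_independent_optimizer(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(300, 3)), columns=list("abc"))
        logit = 0.4 * X["a"] - 0.7 * X["b"]
        y = (rng.uniform(size=300) < 1 / (1 + np.exp(-logit))).astype(float)
        fit = fit_logistic(X, y)

        D = np.column_stack([np.ones(300), X.to_numpy()])

        def nll(beta):
            eta = D @ beta
            return np.sum(np.log1p(np.exp(eta)) - y * eta)

        res = optimize.minimize(nll, np.zeros(4), method="BFGS",
                                options={"gtol": 1e-10})
        assert np.allclose(fit.coefficients, res.x, atol=1e-6)

    def test_two_by_two_odds_ratio_closed_form(self):
        # counts: exposed cases 30, exposed controls 10, unexposed 10/30
        x = np.r_[np.ones(40), np.zeros(40)]
        y = np.r_[np.ones(30), np.zeros(10), np.ones(10), np.zeros(30)]
        fit, trail = stepwise_backward(pd.DataFrame({"x": x}), y)
        assert trail == []
        orr = fit.odds_ratios["x"][0]
        assert orr == pytest.approx(9.0, abs=1e-6)

    def test_screen_keeps_strong_drops_empty(self):
        rng = np.random.default_rng(10)
        n = 160
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        table = pd.DataFrame({"signal": y + rng.normal(0, 1, n),
                              "noise": rng.normal(size=n)})
        assert "signal" in univariable_screen(table, y)
        assert univariable_screen(pd.DataFrame(index=range(n)), y) == []

    def test_stepwise_recovers_single_predictive_feature(self):
        rng = np.random.default_rng(11)
        n = 500
        y = rng.integers(0, 2, n).astype(float)
        table = pd.DataFrame(rng.normal(size=(n, 5)),
                             columns=[f"n{i}" for i in range(5)])
        table["real"] = y + rng.normal(0, 1, n)
        fit, _ = stepwise_backward(table, y)
        assert "real" in fit.features

    def test_all_null_collapses_to_intercept_only_mostly(self):
        rng = np.random.default_rng(12)
        n = 400
        hits = 0
        for _ in range(10):
            y = rng.integers(0, 2, n).astype(float)
            table = pd.DataFrame(rng.normal(size=(n, 4)),
                                 columns=list("abcd"))
            fit, _ = stepwise_backward(table, y)
            hits += len(fit.features)
        assert hits <= 4  # ~5% per-variable false retention


class TestAucAndDelong:
    def test_perfect_separation_is_one(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        scores = np.r_[np.zeros(10), np.ones(10)]
        assert compute_auc(scores, y)[0] == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(13)
        y = rng.integers(0, 2, 1000).astype(float)
        auc, (lo, hi), _ = compute_auc(rng.normal(size=1000), y)
        assert abs(auc - 0.5) < 0.05
        assert lo < 0.5 < hi

    def test_binormal_closed_form(self):
        rng = np.random.default_rng(14)
        n = 100_000
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        scores = np.r_[rng.normal(0, 1, n // 2), rng.normal(1, 1, n // 2)]
        expect = sps.norm.cdf(1 / np.sqrt(2))
        assert compute_auc(scores, y)[0] == pytest.approx(expect, abs=0.01)

    def test_matches_sklearn_on_tied_scores(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(15)
        y = rng.integers(0, 2, 200).astype(float)
        scores = rng.integers(0, 5, 200).astype(float)   # many ties
        assert compute_auc(scores, y)[0] == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12)

    def test_identical_models_p_one(self):
        rng = np.random.default_rng(16)
        y = rng.integers(0, 2, 100).astype(float)
        s = rng.normal(size=100)
        cmp_ = delong_test(s, s.copy(), y)
        assert cmp_.auc_a == cmp_.auc_b
        assert cmp_.delong_p == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(17)
        y = rng.integers(0, 2, 150).astype(float)
        s = rng.normal(size=150)
        cmp_ = delong_test(s, np.exp(2.0 * s), y)
        assert cmp_.auc_a == pytest.approx(cmp_.auc_b, abs=1e-12)
        assert cmp_.delong_p == pytest.approx(1.0)

    def test_one_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_auc(np.arange(5.0), np.ones(5))


class TestBootstrapOptimism:
    @staticmethod
    def _strong_cohort(n=120, seed=18):
        rng = np.random.default_rng(seed)
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        table = pd.DataFrame({"f": 1.5 * y + rng.normal(0, 1, n)})
        return table, y

    def test_optimism_nonnegative_in_expectation(self):
        # optimism >= 0 in expectation; allow small Monte-Carlo slack at B=200
        table, y = self._strong_cohort()
        out = bootstrap_optimism(table, y, B=200,
                                 rng=np.random.default_rng(0))
        assert out["corrected_auc"] <= out["apparent_auc"] + 0.03
        assert out["optimism"] >= -0.03

    def test_same_seed_same_output(self):
        table, y = self._strong_cohort()
        a = bootstrap_optimism(table, y, B=50, rng=np.random.default_rng(5))
        b = bootstrap_optimism(table, y, B=50, rng=np.random.default_rng(5))
        assert a == b


def test_group_to_binary_mapping():
    assert group_to_binary(pd.Series(["HFS", "VHFS", "HFS"])).tolist() == \
        [0.0, 1.0, 0.0]
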