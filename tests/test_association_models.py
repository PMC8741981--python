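"""Group comparisons against a frozen R oracle; logistic inference properties."""

import math

import numpy as np
import pytest

import weanpower as wp
from weanpower import association_models as am
from weanpower.indices import DomainError

# fixed fixtures with expected values computed independently in R 4.3
# (t.test var.equal=TRUE, wilcox.test exact, chisq.test correct=FALSE,
# fisher.test)
NORMAL_A = [12.1, 14.3, 11.8, 15.2, 13.9, 12.7, 14.8, 13.1, 12.4, 15.6]
NORMAL_B = [16.2, 17.9, 15.4, 18.3, 16.8, 17.1, 15.9, 18.6]
R_T_P = 3.47021255838e-05

SKEWED_A = [0.5, 0.7, 0.9, 1.1, 1.3, 1.6, 2.2, 3.5, 7.9, 25.4, 0.6, 1.0]
SKEWED_B = [1.8, 2.4, 3.1, 4.2, 6.8, 13.5, 30.2, 2.9]
R_W_P = 0.0201317774073

R_CHI2_P = 0.000471337409856   # COPD 16/100 vs 14/30 table
R_FISHER_P = 0.0503633888709   # 5/100 vs 5/30 table


class TestCompareGroups:
    def test_t_route_matches_r(self):
        vals = np.array(NORMAL_A + NORMAL_B)
        labels = np.array([0] * len(NORMAL_A) + [1] * len(NORMAL_B))
        res = wp.compare_groups(vals, labels, "continuous")
        assert res.test == "t"
        assert res.p_value == pytest.approx(R_T_P, abs=1e-8)

    def test_mann_whitney_route_matches_r(self):
        vals = np.array(SKEWED_A + SKEWED_B)
        labels = np.array([0] * len(SKEWED_A) + [1] * len(SKEWED_B))
        res = wp.compare_groups(vals, labels, "continuous")
        assert res.test == "mann-whitney"
        assert res.p_value == pytest.approx(R_W_P, abs=1e-8)

    def test_copd_prevalence_difference(self):
        """COPD 16/100 vs 14/30 reproduces the published p < 0.001 pattern."""
        vals = np.array([1] * 16 + [0] * 84 + [1] * 14 + [0] * 16)
        labels = np.array([0] * 100 + [1] * 30)
        res = wp.compare_groups(vals, labels, "categorical", name="copd")
        assert res.test == "chi-square"
        assert res.p_value == pytest.approx(R_CHI2_P, abs=1e-8)
        assert res.p_value < 0.001

    def test_fisher_when_expected_cell_small(self):
        vals = np.array([1] * 5 + [0] * 95 + [1] * 5 + [0] * 25)
        labels = np.array([0] * 100 + [1] * 30)
        res = wp.compare_groups(vals, labels, "categorical")
        assert res.test == "fisher"
        assert res.p_value == pytest.approx(R_FISHER_P, abs=1e-8)

    def test_identical_groups_not_significant(self, rng):
        vals = np.tile(rng.normal(size=40), 2)
        labels = np.repeat([0, 1], 40)
        res = wp.compare_groups(vals, labels, "continuous")
        assert res.p_value > 0.9

    def test_five_sd_shift_is_overwhelming(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        res = wp.compare_groups(np.concatenate([a, b]),
                                np.repeat([0, 1], 50), "continuous")
        assert res.p_value < 1e-6

    def test_errors(self):
        with pytest.raises(DomainError):
            wp.compare_groups([1, 2], [0, 0], "continuous")
        with pytest.raises(DomainError):
            wp.compare_groups([1, 1, 1, 1], [0, 0, 1, 1], "categorical")


class TestFitLogistic:
    def test_score_equations_vanish_at_optimum(self, rng):
        x = rng.normal(size=(400, 2))
        y = (rng.random(400) < 1 / (1 + np.exp(-(x[:, 0] - 0.5)))).astype(int)
        fit = wp.fit_logistic(x, y)
        X = np.column_stack([np.ones(400), x])
        score = X.T @ (y - fit.fitted)
        assert np.max(np.abs(score)) < 1e-6

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.linear_model import LogisticRegression
        x = rng.normal(size=(500, 1))
        y = (rng.random(500) < 1 / (1 + np.exp(-1.5 * x[:, 0]))).astype(int)
        fit = wp.fit_logistic(x, y)
        sk = LogisticRegression(penalty=None, tol=1e-10, max_iter=200)
        sk.fit(x, y)
        assert fit.params[1] == pytest.approx(float(sk.coef_[0, 0]), rel=1e-5)
        assert fit.params[0] == pytest.approx(float(sk.intercept_[0]), rel=1e-5)

    def test_unit_scaling_consistency(self, rng):
        x = rng.normal(5696, 2884, size=(1000, 1))
        y = (rng.random(1000) < 0.25).astype(int)
        f1 = wp.fit_logistic(x, y, names=["pi"], unit_scales={"pi": 1000})
        f2 = wp.fit_logistic(x / 1000, y, names=["pi"])
        assert f2.params[1] == pytest.approx(f1.params[1] * 1000, rel=1e-6)
        assert f2.loglike == pytest.approx(f1.loglike, abs=1e-8)
        assert f1.odds_ratios()["or"][0] == pytest.approx(
            f2.odds_ratios()["or"][0], rel=1e-6)

    def test_true_or_recovery(self):
        """The 1.48-per-1000-units effect is recovered within its Wald CI."""
        beta1 = math.log(1.48) / 1000
        beta0 = wp.calibrate_intercept(beta1, 5696, 2884, 30 / 130)
        x, y = wp.generate_logistic_cohort(5000, beta0, beta1, 5696, 2884,
                                           seed=17)
        fit = wp.fit_logistic(x.reshape(-1, 1), y, names=["pi"],
                              unit_scales={"pi": 1000})
        orr = fit.odds_ratios().iloc[0]
        assert orr["or_lo"] <= 1.48 <= orr["or_hi"]
        assert orr["or"] == pytest.approx(1.48, rel=0.1)

    def test_null_effect_wald_coverage(self):
        """95% Wald CIs cover OR=1 between 92% and 98% of the time."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            x, y = wp.generate_logistic_cohort(2000, -1.2, 0.0, 0.0, 1.0,
                                               seed=seed)
            fit = wp.fit_logistic(x.reshape(-1, 1), y)
            orr = fit.odds_ratios().iloc[0]
            hits += orr["or_lo"] <= 1.0 <= orr["or_hi"]
        assert 0.92 <= hits / n_seeds <= 0.98

    def test_mean_or_recovery_over_seeds(self):
        """Mean estimated OR over repeated simulations stays near 1.48/1000."""
        beta1 = math.log(1.48) / 1000
        beta0 = wp.calibrate_intercept(beta1, 5696, 2884, 30 / 130)
        ors = []
        for seed in range(60):
            x, y = wp.generate_logistic_cohort(5000, beta0, beta1, 5696, 2884,
                                               seed=1000 + seed)
            fit = wp.fit_logistic(x.reshape(-1, 1), y, names=["pi"],
                                  unit_scales={"pi": 1000})
            ors.append(fit.odds_ratios()["or"][0])
        assert 1.43 <= float(np.mean(ors)) <= 1.53

    def test_perfect_separation_detected(self):
        x = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(am.SeparationError):
            wp.fit_logistic(x, y)

    def test_input_validation(self, rng):
        with pytest.raises(DomainError):
            wp.fit_logistic(np.ones((10, 1)), np.repeat([0, 1], 5))  # constant
        with pytest.raises(DomainError):
            wp.fit_logistic(rng.normal(size=(6, 1)), [0, 1, 2, 0, 1, 0])


class TestForwardSelect:
    def _pool(self, rng, n=2000, strong=True):
        x = rng.normal(size=(n, 5))
        eta = 1.5 * x[:, 0] - 1.0 if strong else -1.0 + 0.0 * x[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        import pandas as pd
        return pd.DataFrame(x, columns=["signal", "n1", "n2", "n3", "n4"]), y

    def test_strong_predictor_selected(self):
        """The true predictor always enters first; noise variables slip in at
        roughly the per-variable entry rate, so exact recovery happens in
        about (1 - entry_p)^4 of runs."""
        first, exact = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = self._pool(rng)
            fit = wp.forward_select(X, y)
            first += bool(fit.names) and fit.names[0] == "signal"
            exact += fit.names == ("signal",)
        assert first == 20
        assert exact >= 13

    def test_all_noise_mostly_intercept_only(self):
        empty = 0
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            X, y = self._pool(rng, strong=False)
            fit = wp.forward_select(X, y)
            empty += fit.names == ()
        assert empty >= 24  # roughly (1 - entry_p)^m of runs

    def test_a_priori_always_in_pool(self, rng):
        X, y = self._pool(rng, strong=False)
        # n1 is pure noise: screened out normally, forced into the pool here;
        # it still only ENTERS if its LRT p beats the entry threshold
        fit = wp.forward_select(X, y, a_priori=["n1"], entry_p=1.0)
        assert "n1" in fit.names

    def test_unknown_a_priori_rejected(self, rng):
        X, y = self._pool(rng)
        with pytest.raises(DomainError):
            wp.forward_select(X, y, a_priori=["ghost"])


class TestGoodnessOfFit:
    def test_nagelkerke_bounds(self, rng):
        x = rng.normal(size=(800, 1))
        y_null = (rng.random(800) < 0.3).astype(int)
        fit = wp.fit_logistic(x, y_null)
        assert 0.0 <= wp.nagelkerke_r2(fit) < 0.05
        # near-deterministic covariate drives R2 toward 1
        strong = 8.0 * x[:, 0]
        y = (rng.random(800) < 1 / (1 + np.exp(-strong))).astype(int)
        fit = wp.fit_logistic(x, y)
        assert wp.nagelkerke_r2(fit) > 0.7

    def test_hl_calibrated_model_rejects_nominally(self):
        """Data simulated from the fitted family rejects ~5% at alpha=.05."""
        rejections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(1500, 1))
            y = (rng.random(1500) < 1 / (1 + np.exp(-(0.8 * x[:, 0] - 1.0))))
            fit = wp.fit_logistic(x, y.astype(int))
            _, _, p = wp.hosmer_lemeshow(fit)
            rejections += p < 0.05
        assert rejections <= 15

    def test_hl_detects_misspecified_link(self):
        """Quadratic truth fitted linearly is flagged as miscalibrated."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(4000, 1))
        eta = 2.0 * x[:, 0] ** 2 - 2.0
        y = (rng.random(4000) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = wp.fit_logistic(x, y)
        _, _, p = wp.hosmer_lemeshow(fit)
        assert p < 0.01

    def test_hl_group_edge_cases(self, rng):
        x = rng.normal(size=(100, 1))
        y = (rng.random(100) < 0.4).astype(int)
        fit = wp.fit_logistic(x, y)
        stat, df, p = wp.hosmer_lemeshow(fit, groups=10)
        assert df == 8 and 0 <= p <= 1
        with pytest.raises(DomainError):
            wp.hosmer_lemeshow(fit, groups=2)


class TestPearson:
    def test_hand_computed_example(self):
        r, lo, hi, p = wp.pearson_with_ci([1, 2, 3, 4], [2, 4, 7, 8])
        import numpy as np
        expected = np.corrcoef([1, 2, 3, 4], [2, 4, 7, 8])[0, 1]
        assert r == pytest.approx(expected, rel=1e-12)
        assert lo <= r <= hi

    def test_perfect_and_null(self, rng):
        x = rng.normal(size=50)
        r, lo, hi, _ = wp.pearson_with_ci(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        y = rng.normal(size=10_000)
        x2 = rng.normal(size=10_000)
        r2, *_ = wp.pearson_with_ci(x2, y)
        assert abs(r2) < 0.05

    def test_errors(self):
        with pytest.raises(DomainError):
            wp.pearson_with_ci([1, 2, 3], [1, 2, 3])  # too short
        with pytest.raises(DomainError):
            wp.pearson_with_ci([1, 1, 1, 1], [1, 2, 3, 4])
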