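import numpy as np
import pytest

from angiosig import (
    ConvergenceError,
    SimulationConfig,
    cox_fit,
    generate_cohort,
    km_estimate,
    logrank_test,
    median_dichotomize,
    survival_table,
)


class TestKaplanMeier:
    def test_uniform_no_censoring(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])
        assert np.array_equal(km.at_risk, [4, 3, 2, 1])

    def test_all_censored_survival_stays_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert len(km.event_times) == 0
        assert km.survival_at(5.0) == 1.0

    def test_hand_product_limit_with_censoring(self):
        # events at 1 and 3, censored at 2: S(1)=2/3, S(3)=(2/3)*(1-1/1)=0
        km = km_estimate([1, 2, 3], [1, 0, 1])
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, size=50)
        km = km_estimate(t, np.ones(50))
        for q in (np.quantile(t, 0.3), np.quantile(t, 0.7)):
            assert km.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


def hand_logrank_2group(times, events, groups):
    """Textbook O-E / hypergeometric-variance tabulation for two groups."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups, int)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        chi2, df, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 1

    def test_matches_hand_tabulation(self):
        t = [1, 3, 5, 2, 4, 6]
        e = [1, 1, 0, 1, 1, 1]
        g = [0, 0, 0, 1, 1, 1]
        chi2, df, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(hand_logrank_2group(t, e, g), abs=1e-10)

    def test_two_group_chi2_is_squared_standardized_oe(self, rng):
        t = rng.exponential(5, size=40)
        e = (rng.random(40) < 0.7).astype(int)
        g = (rng.random(40) < 0.5).astype(int)
        chi2, _, _ = logrank_test(t, e, g)
        assert chi2 == pytest.approx(hand_logrank_2group(t, e, g), abs=1e-8)

    def test_power_against_strong_hazard_ratio(self):
        """HR=3 between exponential groups, n=200/group: near-certain
        rejection at alpha=0.05."""
        rng = np.random.default_rng(77)
        hits = 0
        reps = 60
        for _ in range(reps):
            t0 = rng.exponential(1.0, 200)
            t1 = rng.exponential(1 / 3.0, 200)
            t = np.concatenate([t0, t1])
            g = np.array([0] * 200 + [1] * 200)
            _, _, p = logrank_test(t, np.ones(400), g)
            hits += p < 0.05
        assert hits / reps > 0.95

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


def toy_cox_data():
    times = np.array([2.0, 5.0, 7.0, 9.0, 12.0, 14.0, 17.0, 20.0])
    events = np.array([1, 1, 0, 1, 1, 0, 1, 1])
    x = np.array([1.2, -0.4, 0.8, 2.0, -1.1, 0.3, -0.6, -1.8])
    return times, events, x


def partial_loglik_untied(beta, times, events, x):
    """Independent partial likelihood (no ties) for the grid oracle."""
    ll = 0.0
    for i in np.where(events == 1)[0]:
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCoxFit:
    def test_coefficient_matches_grid_oracle(self):
        times, events, x = toy_cox_data()
        fit = cox_fit(times, events, x)
        grid = np.arange(-3.0, 3.0, 1e-4)
        ll = [partial_loglik_untied(b, times, events, x) for b in grid]
        assert fit.coefficients[0] == pytest.approx(grid[int(np.argmax(ll))], abs=1e-4)
        assert fit.hazard_ratios[0] == pytest.approx(np.exp(fit.coefficients[0]))

    def test_matches_lifelines_cross_check(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        n = 120
        x = rng.normal(size=(n, 2))
        t = rng.exponential(np.exp(-(0.5 * x[:, 0] - 0.3 * x[:, 1])))
        e = (rng.random(n) < 0.8).astype(int)
        fit = cox_fit(t, e, x, ties="efron")
        df = pd.DataFrame({"t": t, "e": e, "x1": x[:, 0], "x2": x[:, 1]})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert np.allclose(fit.coefficients,
                           cph.params_[["x1", "x2"]].to_numpy(), atol=1e-5)
        assert np.allclose(fit.se, cph.standard_errors_[["x1", "x2"]].to_numpy(),
                           atol=1e-5)

    def test_breslow_and_efron_agree_without_ties(self):
        times, events, x = toy_cox_data()
        f1 = cox_fit(times, events, x, ties="efron")
        f2 = cox_fit(times, events, x, ties="breslow")
        assert f1.coefficients[0] == pytest.approx(f2.coefficients[0], abs=1e-10)

    def test_invariant_to_affine_time_rescaling(self):
        times, events, x = toy_cox_data()
        f1 = cox_fit(times, events, x)
        f2 = cox_fit(times * 3.7, events, x)
        assert np.allclose(f1.coefficients, f2.coefficients, atol=1e-8)

    def test_recovers_planted_log_hazard_ratio(self):
        """Binary covariate with true log-HR = ln 2: small mean bias over
        repeated simulations."""
        rng = np.random.default_rng(55)
        coefs = []
        for _ in range(120):
            z = (rng.random(400) < 0.5).astype(float)
            t = rng.exponential(np.exp(-np.log(2) * z))
            coefs.append(cox_fit(t, np.ones(400), z).coefficients[0])
        assert abs(np.mean(coefs) - np.log(2)) < 0.05

    def test_null_covariate_type_i_error(self):
        rng = np.random.default_rng(66)
        rejections = 0
        coefs = []
        reps = 200
        for _ in range(reps):
            z = rng.normal(size=300)
            t = rng.exponential(1.0, size=300)
            fit = cox_fit(t, np.ones(300), z)
            coefs.append(fit.coefficients[0])
            rejections += fit.wald_p[0] < 0.05
        assert abs(np.mean(coefs)) < 0.02
        assert 0.02 <= rejections / reps <= 0.09

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3, 4], [1, 1, 1, 1], np.ones(4))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_fit([1, 2, 3, 4], [0, 0, 0, 0], np.arange(4.0))

    def test_horizon_truncation(self):
        times, events, x = toy_cox_data()
        fit = cox_fit(times, events, x, horizon=10.0)
        # only the events before t=10 remain; fit still converges
        assert fit.converged


class TestMedianDichotomize:
    def test_basic_and_degenerate(self):
        assert list(median_dichotomize([1, 2, 3])) == [0, 0, 1]
        with pytest.warns(UserWarning):
            out = median_dichotomize([2.0, 2.0, 2.0])
        assert list(out) == [0, 0, 0]

    def test_group_sizes_balanced_up_to_ties(self, rng):
        v = rng.normal(size=101)
        out = median_dichotomize(v)
        n_ties = int((v == np.median(v)).sum())
        assert abs(int(out.sum()) - (101 - int(out.sum()))) <= n_ties

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_dichotomize([])


class TestSignatureSurvivalLink:
    def test_planted_signature_effect_detected(self):
        """On cohorts whose hazard depends on the planted signature score,
        the median-dichotomized log-rank test is significant in almost all
        seeds."""
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(n_tumor=600, n_normal=0, n_background_genes=0,
                                   seed=1000 + seed)
            _, ann, truth = generate_cohort(cfg)
            groups = median_dichotomize(truth.signature_score.to_numpy())
            _, _, p = logrank_test(ann["time"].to_numpy(),
                                   ann["event"].to_numpy(), groups)
            hits += p < 0.05
        assert hits >= 9

    def test_survival_table_shape(self, small_cohort):
        import pandas as pd

        _, expr, ann, truth = small_cohort
        tumors = ann[ann["tissue"] == "tumor"]
        factors = pd.DataFrame({
            "TN": truth.tn.astype(int).to_numpy(),
            "node": tumors["node"].astype(float).to_numpy(),
        }, index=tumors.index)
        table = survival_table(tumors["time"].to_numpy(),
                               tumors["event"].to_numpy(), factors)
        assert list(table.index) == ["TN", "node"]
        assert {"HR_univariate", "HR_multivariate"} <= set(table.columns)
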