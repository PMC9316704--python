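"""Weighted constancy regression: WLS, stepwise selection, prediction, discount."""

import math

import numpy as np
import pytest

from metaconstancy import (
    ConstancyFit,
    RegressionRow,
    ValidationError,
    fit_wls,
    ni_discount,
    predict_future,
    simulate_regression_rows,
    stepwise_select,
)


def make_rows(smd_dl, year_diff, year_last, y, w):
    return [
        RegressionRow(
            review_id=f"R{i}", smd_lt=float(y[i]), smd_dl=float(smd_dl[i]),
            year_diff=float(year_diff[i]), year_last=float(year_last[i]),
            weight=float(w[i]),
        )
        for i in range(len(y))
    ]


def random_rows(rng, n=30):
    smd_dl = rng.normal(0.3, 0.3, n)
    year_diff = rng.uniform(1, 40, n)
    year_last = rng.uniform(1990, 2016, n)
    y = 0.1 + 0.8 * smd_dl - 0.004 * year_diff + rng.normal(0, 0.2, n)
    w = rng.lognormal(7, 1, n)
    return make_rows(smd_dl, year_diff, year_last, y, w)


def wls_normal_equations(x, y, w):
    """Independent brute-force weighted normal-equation solver."""
    xtw = x.T * w
    return np.linalg.solve(xtw @ x, xtw @ y)


class TestFitWls:
    def test_noiseless_plane_recovered_exactly(self, rng):
        smd_dl = rng.normal(0.3, 0.3, 40)
        y = 0.2 + 0.9 * smd_dl
        rows = make_rows(smd_dl, rng.uniform(1, 40, 40), rng.uniform(1990, 2016, 40),
                         y, rng.lognormal(7, 1, 40))
        fit = fit_wls(rows, covariates=())
        assert fit.intercept == pytest.approx(0.2, abs=1e-8)
        assert fit.b_smd_dl == pytest.approx(0.9, abs=1e-8)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-8)

    def test_equal_weights_match_ols_oracle(self, rng):
        rows = random_rows(rng)
        rows = [RegressionRow(r.review_id, r.smd_lt, r.smd_dl, r.year_diff,
                              r.year_last, 1.0) for r in rows]
        fit = fit_wls(rows)
        x = np.column_stack([np.ones(len(rows)),
                             [r.smd_dl for r in rows],
                             [r.year_diff for r in rows],
                             [r.year_last for r in rows]])
        y = np.array([r.smd_lt for r in rows])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        for term, b in zip(fit.terms, beta):
            assert fit.params[term] == pytest.approx(b, abs=1e-8)

    def test_saturated_two_point_fit_interpolates(self):
        rows = make_rows([0.1, 0.5], [5, 10], [2000, 2010], [0.2, 0.6], [100, 200])
        fit = fit_wls(rows, covariates=())
        for r in rows:
            pred, _ = predict_future(fit, smd_dl=r.smd_dl)
            assert pred == pytest.approx(r.smd_lt, abs=1e-10)
        assert math.isnan(fit.adj_r2)

    def test_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(50):
            rows = random_rows(rng, n=30)
            ncov = int(rng.integers(0, 3))
            cov = ("year_diff", "year_last")[:ncov]
            fit = fit_wls(rows, covariates=cov)
            cols = [np.ones(30), [r.smd_dl for r in rows]]
            cols += [[getattr(r, c) for r in rows] for c in cov]
            x = np.column_stack(cols)
            y = np.array([r.smd_lt for r in rows])
            w = np.array([r.weight for r in rows])
            beta = wls_normal_equations(x, y, w)
            for term, b in zip(fit.terms, beta):
                assert fit.params[term] == pytest.approx(b, abs=1e-8)

    def test_weight_scaling_invariance(self, rng):
        rows = random_rows(rng)
        scaled = [RegressionRow(r.review_id, r.smd_lt, r.smd_dl, r.year_diff,
                                r.year_last, r.weight * 137.5) for r in rows]
        a, b = fit_wls(rows), fit_wls(scaled)
        for term in a.terms:
            assert a.params[term] == pytest.approx(b.params[term], abs=1e-10)
            assert a.ses[term] == pytest.approx(b.ses[term], rel=1e-9)
        assert a.adj_r2 == pytest.approx(b.adj_r2, abs=1e-10)

    def test_centering_year_changes_only_intercept(self, rng):
        rows = random_rows(rng)
        a = fit_wls(rows, covariates=("year_last",))
        b = fit_wls(rows, covariates=("year_last",), center_year=True)
        assert a.params["year_last"] == pytest.approx(b.params["year_last"], abs=1e-10)
        assert a.params["smd_dl"] == pytest.approx(b.params["smd_dl"], abs=1e-10)
        assert a.intercept != pytest.approx(b.intercept, abs=1e-6)

    def test_collinear_design_rejected_with_column_named(self, rng):
        rows = random_rows(rng)
        rows = [RegressionRow(r.review_id, r.smd_lt, r.smd_dl, r.year_diff,
                              2.0 * r.year_diff + 5.0, r.weight) for r in rows]
        with pytest.raises(ValidationError, match="year_last"):
            fit_wls(rows)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValidationError, match="weight"):
            RegressionRow("R1", 0.1, 0.2, 5, 2000, 0.0)

    def test_parameter_recovery_and_ci_coverage(self):
        truth = {"intercept": 0.15, "smd_dl": 0.85, "year_diff": -0.006, "year_last": -0.01}
        estimates = {t: [] for t in truth}
        covered = {t: 0 for t in truth}
        n_rep = 200
        for rep in range(n_rep):
            rows, _ = simulate_regression_rows(truth, noise_sd=0.2, n_rows=500, seed=rep)
            fit = fit_wls(rows)
            for t, v in truth.items():
                estimates[t].append(fit.params[t])
                if fit.ci_lows[t] <= v <= fit.ci_highs[t]:
                    covered[t] += 1
        for t, v in truth.items():
            e = np.array(estimates[t])
            mc_se = e.std(ddof=1) / math.sqrt(n_rep)
            assert abs(e.mean() - v) <= 3 * mc_se, f"{t}: {e.mean()} vs {v}"
            assert 0.92 <= covered[t] / n_rep <= 0.98, f"{t} coverage {covered[t] / n_rep}"


class TestStepwise:
    def test_null_candidate_dropped_in_most_replicates(self):
        truth = {"intercept": 0.1, "smd_dl": 0.8, "year_diff": -0.006}
        kept = 0
        for rep in range(100):
            rows, _ = simulate_regression_rows(truth, noise_sd=0.2, n_rows=500, seed=1000 + rep)
            fit = stepwise_select(rows)
            if "year_last" in fit.selected:
                kept += 1
        assert kept <= 10  # pure-noise year term enters at ~the 5% threshold

    def test_strong_candidate_always_retained(self):
        truth = {"intercept": 0.1, "smd_dl": 0.8, "year_diff": -0.02}
        for rep in range(100):
            rows, _ = simulate_regression_rows(truth, noise_sd=0.1, n_rows=500, seed=2000 + rep)
            fit = stepwise_select(rows)
            assert "year_diff" in fit.selected

    def test_type_one_error_of_year_test_near_nominal(self):
        truth = {"intercept": 0.1, "smd_dl": 0.8}
        rejections = 0
        n_rep = 400
        for rep in range(n_rep):
            rows, _ = simulate_regression_rows(truth, noise_sd=0.2, n_rows=500, seed=3000 + rep)
            fit = fit_wls(rows, covariates=("year_last",))
            if fit.p_values["year_last"] < 0.05:
                rejections += 1
        assert 0.025 <= rejections / n_rep <= 0.075

    def test_empty_candidate_set_gives_core_model(self, rng):
        fit = stepwise_select(random_rows(rng), candidates=())
        assert fit.terms == ("intercept", "smd_dl")
        assert fit.selected == ()

    def test_deterministic_given_rows(self, rng):
        rows = random_rows(rng, n=60)
        a, b = stepwise_select(rows), stepwise_select(rows)
        assert a.params == b.params and a.selected == b.selected

    def test_bad_thresholds_rejected(self, rng):
        with pytest.raises(ValidationError):
            stepwise_select(random_rows(rng), entry_p=0.2, removal_p=0.1)


def fixed_fit(params, terms=("intercept", "smd_dl", "year_diff", "year_last")):
    k = len(terms)
    return ConstancyFit(
        terms=terms, params=dict(zip(terms, params)),
        ses={t: 0.1 for t in terms}, ci_lows={t: -1 for t in terms},
        ci_highs={t: 1 for t in terms}, p_values={t: 0.01 for t in terms},
        adj_r2=0.5, n_rows=224, selected=terms[2:], residual_variance=0.0,
        df_resid=220, median_weight=1160.0, cov_params=np.zeros((k, k)),
        x_wmean=np.zeros(k), y_wmean=0.0,
    )


class TestPredictAndDiscount:
    def test_linear_combination_of_published_style_coefficients(self):
        # a fit frozen to headline-style coefficients: prediction is the
        # hand-evaluated linear combination
        fit = fixed_fit([36.14, 0.88, -0.009, -0.018])
        pred, _ = predict_future(fit, smd_dl=0.5, year_diff=20, year_last=2016)
        expected = 36.14 + 0.88 * 0.5 - 0.009 * 20 - 0.018 * 2016
        assert pred == pytest.approx(expected, abs=1e-12)

    def test_missing_selected_covariate_rejected(self):
        fit = fixed_fit([36.14, 0.88, -0.009, -0.018])
        with pytest.raises(ValidationError, match="year_last"):
            predict_future(fit, smd_dl=0.5, year_diff=20)

    def test_prediction_at_weighted_means_equals_weighted_mean_response(self, rng):
        rows = random_rows(rng)
        fit = fit_wls(rows)
        xm = fit.x_wmean
        pred, _ = predict_future(fit, smd_dl=xm[1], year_diff=xm[2], year_last=xm[3])
        assert pred == pytest.approx(fit.y_wmean, abs=1e-10)

    def test_interval_width_grows_away_from_weighted_means(self, rng):
        rows = random_rows(rng)
        fit = fit_wls(rows, covariates=())
        center = fit.x_wmean[1]
        widths = []
        for step in (0.0, 0.5, 1.0, 2.0):
            _, (lo, hi) = predict_future(fit, smd_dl=center + step)
            widths.append(hi - lo)
        assert all(b > a for a, b in zip(widths, widths[1:]))
        _, (lo, hi) = predict_future(fit, smd_dl=center - 2.0)
        assert hi - lo > widths[0]

    def test_larger_future_weight_narrows_interval(self, rng):
        fit = fit_wls(random_rows(rng), covariates=())
        _, (lo1, hi1) = predict_future(fit, smd_dl=0.3, weight=100)
        _, (lo2, hi2) = predict_future(fit, smd_dl=0.3, weight=10000)
        assert hi2 - lo2 < hi1 - lo1

    @pytest.mark.parametrize("slope, expected", [(0.88, 0.12), (1.0, 0.0), (0.5, 0.5)])
    def test_ni_discount_is_one_minus_slope(self, slope, expected):
        fit = fixed_fit([0.1, slope], terms=("intercept", "smd_dl"))
        assert ni_discount(fit) == pytest.approx(expected, abs=1e-12)
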