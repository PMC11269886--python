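import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gapelimit as g
from gapelimit.size_inference import GlmFit


def _loglik(b0, b1, x, y):
    eta = b0 + b1 * x
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _grid_mle(x, y, centre=(0.0, 0.0), width=(4.0, 4.0), levels=6, points=41):
    """Brute-force maximizer of the Bernoulli log-likelihood by grid refinement."""
    b0, b1 = centre
    w0, w1 = width
    for _ in range(levels):
        grid0 = np.linspace(b0 - w0, b0 + w0, points)
        grid1 = np.linspace(b1 - w1, b1 + w1, points)
        best = max(
            itertools.product(grid0, grid1), key=lambda b: _loglik(b[0], b[1], x, y)
        )
        b0, b1 = best
        w0 /= points / 4
        w1 /= points / 4
    return b0, b1


def _logistic_sample(rng, n, beta0, beta1):
    x = rng.normal(0.0, 1.0, size=n)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * x)))
    y = (rng.random(n) < p).astype(float)
    return x, y


class TestFitLogistic:
    def test_symmetric_design_gives_exactly_zero_coefficients(self):
        fit = g.fit_logistic([0, 1, 0, 1], [-1.0, -1.0, 1.0, 1.0])
        assert fit.coefficients == (0.0, 0.0)
        assert fit.converged

    def test_matches_brute_force_likelihood_grid(self):
        rng = np.random.default_rng(7)
        x, y = _logistic_sample(rng, 20, beta0=-1.0, beta1=0.5)
        if y.min() == y.max():  # would be separated; seed chosen to avoid this
            pytest.skip("degenerate draw")
        fit = g.fit_logistic(y, x)
        b0, b1 = _grid_mle(x, y)
        assert fit.coefficients[0] == pytest.approx(b0, abs=1e-4)
        assert fit.coefficients[1] == pytest.approx(b1, abs=1e-4)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        x, y = _logistic_sample(rng, 120, beta0=0.2, beta1=-0.8)
        fit = g.fit_logistic(y, x)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.coefficients == pytest.approx(tuple(ref.params), abs=1e-6)
        assert fit.standard_errors == pytest.approx(tuple(ref.bse), rel=1e-5)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-8)

    def test_single_class_raises_separation_error(self):
        with pytest.raises(g.SeparationError):
            g.fit_logistic([1, 1, 1, 1], [1.0, 2.0, 3.0, 4.0])

    def test_input_contract(self):
        with pytest.raises(ValueError):
            g.fit_logistic([0, 1], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            g.fit_logistic([0, 1], [1.0, 2.0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=25)
    def test_score_vanishes_at_the_optimum(self, seed):
        rng = np.random.default_rng(seed)
        x, y = _logistic_sample(rng, 40, beta0=0.3, beta1=1.0)
        if y.min() == y.max():
            return
        fit = g.fit_logistic(y, x)
        if not fit.converged:
            return
        b0, b1 = fit.coefficients
        p = 1.0 / (1.0 + np.exp(-(b0 + b1 * x)))
        score = np.array([(y - p).sum(), ((y - p) * x).sum()])
        assert np.abs(score).max() < 1e-6

    def test_invariant_to_observation_order(self):
        rng = np.random.default_rng(3)
        x, y = _logistic_sample(rng, 50, beta0=-0.5, beta1=0.7)
        perm = rng.permutation(50)
        fit = g.fit_logistic(y, x)
        fit_p = g.fit_logistic(y[perm], x[perm])
        assert fit.coefficients == pytest.approx(fit_p.coefficients, abs=1e-10)

    def test_slope_rescales_with_the_covariate(self):
        rng = np.random.default_rng(5)
        x, y = _logistic_sample(rng, 60, beta0=0.1, beta1=0.9)
        a = 10.0
        fit = g.fit_logistic(y, x)
        fit_scaled = g.fit_logistic(y, a * x)
        assert fit_scaled.coefficients[1] == pytest.approx(
            fit.coefficients[1] / a, rel=1e-6
        )
        assert fit_scaled.coefficients[0] == pytest.approx(
            fit.coefficients[0], rel=1e-6
        )

    def test_null_slope_rejected_at_nominal_rate(self):
        # type-I calibration: with no true prey-mass effect the Wald test on
        # the slope should reject in about 5% of cohorts
        rng = np.random.default_rng(2024)
        rejections = 0
        n_cohorts = 1000
        for _ in range(n_cohorts):
            mass = rng.uniform(60.5, 86.3, size=171)
            y = (rng.random(171) < 0.52).astype(float)
            if y.min() == y.max():
                continue
            fit = g.fit_logistic(y, mass)
            if fit.converged and fit.p_values[1] < 0.05:
                rejections += 1
        assert rejections / n_cohorts == pytest.approx(0.05, abs=0.02)


class TestWaldTest:
    def _glm(self, z):
        se = 1.0
        return GlmFit(
            coefficients=(0.0, z * se), standard_errors=(1.0, se),
            z_values=(0.0, z), p_values=(1.0, 0.5), converged=True,
            n_iterations=1, log_likelihood=0.0, n_obs=10,
        )

    def test_zero_statistic_gives_p_one(self):
        assert g.wald_test(self._glm(0.0))[1] == pytest.approx(1.0)

    def test_critical_normal_quantile(self):
        _, p = g.wald_test(self._glm(1.959964))
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_t_zero_gives_p_one_at_any_df(self):
        for n in (3, 10, 30):
            x = np.arange(n, dtype=float)
            rng = np.random.default_rng(0)
            y = np.pi + rng.normal(0, 1, n)
            y = y - np.polyfit(x, y, 1)[0] * x  # force an exactly flat slope
            fit = g.fit_ols(x, y)
            assert fit.t_value == pytest.approx(0.0, abs=1e-10)
            assert g.wald_test(fit)[1] == pytest.approx(1.0)

    def test_unconverged_fit_is_refused(self):
        bad = GlmFit(
            coefficients=(0.0, 0.0), standard_errors=(1.0, 1.0),
            z_values=(0.0, 0.0), p_values=(1.0, 1.0), converged=False,
            n_iterations=50, log_likelihood=0.0, n_obs=10,
        )
        with pytest.raises(ValueError, match="unconverged"):
            g.wald_test(bad)


class TestFitOls:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        fit = g.fit_ols(x, 2.0 * x + 1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        # oracle: beta = (X'X)^-1 X'y via explicit matrix inversion,
        # slope SE from the (1,1) entry of sigma^2 (X'X)^-1
        rng = np.random.default_rng(30)
        x = rng.uniform(100, 600, size=30)
        y = 10.0 + 0.12 * x + rng.normal(0, 8, size=30)
        X = np.column_stack([np.ones(30), x])
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / (30 - 2)
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        fit = g.fit_ols(x, y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        assert fit.slope_se == pytest.approx(se, abs=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(31)
        x = rng.uniform(0, 1, size=25)
        y = 1.0 - 2.0 * x + rng.normal(0, 0.3, size=25)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        fit = g.fit_ols(x, y)
        assert fit.t_value == pytest.approx(ref.tvalues[1], rel=1e-10)
        assert fit.p_value == pytest.approx(ref.pvalues[1], rel=1e-8)
        assert fit.r_squared == pytest.approx(ref.rsquared, rel=1e-10)

    def test_constant_covariate_is_degenerate(self):
        with pytest.raises(g.DegenerateDesignError):
            g.fit_ols([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            g.fit_ols([1.0, 2.0], [1.0, 2.0])


class TestRpm:
    def _event(self, prey, predator, birds=("b1",), outcome=g.Outcome.INGESTED):
        return g.PredationEvent(
            bird_ids=birds, prey_mass_g=prey, outcome=outcome,
            snake_event_id="c1" if outcome is g.Outcome.INGESTED else None,
            predator_mass_g=predator,
        )

    def test_extreme_observed_value(self):
        # the record meal: a 90-g snake swallowing a 71.9-g fledgling
        rpm = g.compute_rpm(self._event(71.9, 90.0))
        assert round(100 * rpm, 1) == 79.9

    def test_equal_masses_give_unity(self):
        assert g.compute_rpm(self._event(100.0, 100.0)) == pytest.approx(1.0)

    def test_double_meal_sums_prey_mass(self):
        event = self._event(60.0, 100.0, birds=("b1", "b2"))
        assert g.compute_rpm(event) == pytest.approx(0.6)

    def test_failed_attempt_has_no_rpm(self):
        event = self._event(70.0, None, outcome=g.Outcome.SLIMED)
        with pytest.raises(ValueError, match="failed"):
            g.compute_rpm(event)

    def test_missing_predator_mass(self):
        with pytest.raises(ValueError, match="predator mass"):
            g.compute_rpm(self._event(70.0, None))

    def test_summary_of_two_values(self):
        events = [self._event(20.0, 100.0), self._event(40.0, 100.0)]
        s = g.rpm_summary(events)
        assert (s.mean, s.min, s.max) == (pytest.approx(0.3), 0.2, 0.4)

    def test_single_event_summary_is_flagged(self):
        s = g.rpm_summary([self._event(50.0, 100.0)])
        assert s.n == 1 and s.single_event and s.se == 0.0
        assert s.mean == pytest.approx(0.5)

    def test_matches_direct_recomputation(self, default_dataset):
        events = [
            e for e in default_dataset["events"]
            if e.outcome is g.Outcome.INGESTED and e.predator_mass_g
        ]
        s = g.rpm_summary(events)
        vals = np.array([e.prey_mass_g / e.predator_mass_g for e in events])
        assert s.mean == pytest.approx(vals.mean())
        assert s.se == pytest.approx(vals.std(ddof=1) / np.sqrt(len(vals)))
        assert (s.min, s.max) == (pytest.approx(vals.min()), pytest.approx(vals.max()))
        assert all(v > 0 for v in s.values)

    def test_excluding_the_double_meal_drops_exactly_one(self):
        events = [self._event(20.0, 100.0), self._event(40.0, 100.0),
                  self._event(60.0, 100.0, birds=("b1", "b2"))]
        assert g.rpm_summary(events).n - g.rpm_summary(events, exclude_multi_prey=True).n == 1
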