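import numpy as np
import pytest
from scipy import integrate, optimize, stats

from accrual.models import (
    AccrualPrior,
    PosteriorState,
    fit_posterior,
    fit_posterior_sites,
    flag_slow_accrual,
    linear_predict,
    p_late,
    predict_accrual,
    predict_completion_time,
    predict_with_sites,
)
from accrual.trial_data import InterimState


def gridded_posterior_mean(prior_shape, prior_scale, m, t, grid=200_000):
    """Independent oracle: numerically normalize prior x likelihood.

    Prior density on theta proportional to theta^-(a0+1) exp(-b0/theta)
    (a0 = 0 is the non-informative 1/theta case, handled by the same
    formula); exponential waiting-time likelihood theta^-m exp(-t/theta).
    """
    b = prior_scale + t
    a = prior_shape + m
    # integrate on a log-spaced grid wide enough to capture the mass
    mode = b / (a + 1)
    theta = np.geomspace(mode / 50, mode * 50, grid)
    log_dens = -(a + 1) * np.log(theta) - b / theta
    dens = np.exp(log_dens - log_dens.max())
    z = integrate.trapezoid(dens, theta)
    return integrate.trapezoid(theta * dens, theta) / z


class TestFitPosterior:
    def test_informative_update_arithmetic(self):
        post = fit_posterior(
            AccrualPrior(n=200, T=24, P=0.5), InterimState(m=1, t=0.1, n=200)
        )
        assert post.shape == pytest.approx(101.0)
        assert post.scale == pytest.approx(12.1)

    def test_noninformative_is_data_only(self):
        post = fit_posterior(AccrualPrior(n=200, P=0.0), InterimState(m=50, t=5, n=200))
        assert (post.shape, post.scale) == (50, 5)
        assert post.mean_theta == pytest.approx(5 / 49)

    def test_noninformative_with_no_events_is_improper(self):
        with pytest.raises(ValueError, match="improper"):
            fit_posterior(AccrualPrior(n=10, P=0.0), InterimState(m=0, t=2, n=10))

    def test_posterior_mean_matches_gridded_bayes_update(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            P = rng.uniform(0.05, 1.0)
            n = int(rng.integers(20, 500))
            T = rng.uniform(6, 48)
            m = int(rng.integers(1, n))
            t = rng.uniform(0.5, 36)
            post = fit_posterior(AccrualPrior(n=n, T=T, P=P), InterimState(m=m, t=t, n=n))
            oracle = gridded_posterior_mean(P * n, P * T, m, t)
            assert abs(post.mean_theta - oracle) / oracle < 1e-4

    def test_prior_washes_out_with_data(self):
        # informative and non-informative posterior means within 1% at m=5000
        rng = np.random.default_rng(0)
        theta_true = 0.1
        m = 5000
        t = float(np.sum(rng.exponential(theta_true, m)))
        interim = InterimState(m=m, t=t, n=6000)
        inf = fit_posterior(AccrualPrior(n=200, T=24, P=1.0), interim)
        noninf = fit_posterior(AccrualPrior(n=200, P=0.0), interim)
        assert abs(inf.mean_theta - noninf.mean_theta) / noninf.mean_theta < 0.01


class TestPredictCompletionTime:
    def test_zero_remaining_is_degenerate(self):
        post = PosteriorState(shape=50, scale=5, m=50, t=5)
        pred = predict_completion_time(post, 0, seed=1)
        assert pred.point == 5
        assert pred.interval == (5, 5)

    def test_monte_carlo_mean_matches_closed_form(self):
        # E[T_pred] = t + remaining * scale / (shape - 1)
        rng = np.random.default_rng(3)
        for _ in range(20):
            shape = rng.uniform(10, 300)
            scale = rng.uniform(1, 30)
            t = rng.uniform(0.5, 24)
            remaining = int(rng.integers(5, 400))
            post = PosteriorState(shape=shape, scale=scale, m=1, t=t)
            pred = predict_completion_time(
                post, remaining, draws=40_000, seed=int(rng.integers(2**31))
            )
            closed = t + remaining * scale / (shape - 1)
            mc_se = np.std(pred.draws) / np.sqrt(pred.draws.size)
            assert pred.mean == pytest.approx(closed, abs=3 * mc_se)

    def test_doubling_draws_shrinks_monte_carlo_error(self):
        # sqrt-law: SD of the point estimate over repeats falls ~1/sqrt(2)
        post = PosteriorState(shape=50, scale=5, m=50, t=5)

        def point_sd(draws, seeds):
            pts = [
                predict_completion_time(post, 150, draws=draws, seed=s).point
                for s in seeds
            ]
            return np.std(pts)

        sd_small = point_sd(2_000, range(40))
        sd_big = point_sd(8_000, range(100, 140))
        assert sd_big < sd_small / 1.4  # expect ~1/2, allow noise

    def test_interval_is_equal_tailed_and_ordered(self):
        post = PosteriorState(shape=50, scale=5, m=50, t=5)
        pred = predict_completion_time(post, 150, draws=20_000, seed=0, level=0.9)
        lo, hi = pred.interval
        assert lo < pred.point < hi
        frac_below = np.mean(pred.draws < lo)
        frac_above = np.mean(pred.draws > hi)
        assert frac_below == pytest.approx(0.05, abs=0.01)
        assert frac_above == pytest.approx(0.05, abs=0.01)

    def test_reproducible_under_seed(self):
        post = PosteriorState(shape=50, scale=5, m=50, t=5)
        a = predict_completion_time(post, 100, draws=5000, seed=11)
        b = predict_completion_time(post, 100, draws=5000, seed=11)
        assert np.array_equal(a.draws, b.draws)


class TestPredictAccrual:
    def test_mean_additional_count_matches_expectation(self):
        # E[count] = (horizon - t) * E[1/theta] = (horizon - t) * shape/scale
        post = PosteriorState(shape=50, scale=5, m=50, t=5)
        pred = predict_accrual(post, horizon=10, draws=50_000, seed=2)
        mc_se = np.std(pred.draws) / np.sqrt(pred.draws.size)
        assert pred.mean == pytest.approx(50 + 5 * 50 / 5, abs=3 * mc_se)

    def test_horizon_before_now_rejected(self):
        post = PosteriorState(shape=50, scale=5, m=50, t=5)
        with pytest.raises(ValueError, match="horizon"):
            predict_accrual(post, horizon=5)

    def test_overdispersed_relative_to_fixed_rate_poisson(self):
        post = PosteriorState(shape=30, scale=3, m=30, t=3)
        pred = predict_accrual(post, horizon=9, draws=50_000, seed=4)
        lam = (9 - 3) * post.shape / post.scale  # fixed-rate mean count
        assert np.var(pred.draws) > lam  # rate uncertainty adds variance


class TestPLate:
    post = PosteriorState(shape=50, scale=5, m=50, t=5)

    def test_limits(self):
        assert p_late(self.post, 150, T=1e6, draws=5000, seed=0) == 0.0
        assert p_late(self.post, 150, T=5.0, draws=5000, seed=0) == 1.0

    def test_monotone_non_increasing_in_T(self):
        grid = np.linspace(6, 60, 20)
        vals = [p_late(self.post, 150, T=T, draws=20_000, seed=8) for T in grid]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_monotone_non_decreasing_in_remaining(self):
        vals = [
            p_late(self.post, r, T=24, draws=20_000, seed=8)
            for r in (50, 100, 150, 200)
        ]
        assert all(b >= a - 0.01 for a, b in zip(vals, vals[1:]))

    def test_matches_quadrature_oracle(self):
        # Pr(T_pred > T) = E_theta[ Pr(Gamma(remaining, theta) > T - t) ]
        # integrated against the inverse-gamma posterior density
        post, remaining, T = self.post, 150, 24

        def integrand(theta):
            tail = stats.gamma.sf((T - post.t) / theta, remaining)
            dens = stats.invgamma.pdf(theta, post.shape, scale=post.scale)
            return tail * dens

        oracle, _ = integrate.quad(integrand, 1e-6, 2.0, limit=200)
        est = p_late(post, remaining, T=T, draws=200_000, seed=5)
        se = np.sqrt(oracle * (1 - oracle) / 200_000)
        assert est == pytest.approx(oracle, abs=4 * se)


class TestFlagSlowAccrual:
    @pytest.mark.parametrize("T, expected", [(12, True), (24, False), (18, False)])
    def test_boundary_convention(self, T, expected):
        from accrual.models import PredictionResult

        pred = PredictionResult(
            kind="completion_time", point=22, interval=(18, 30), level=0.95
        )
        assert flag_slow_accrual(pred, T) is expected


class TestLinearPredict:
    def test_point_estimate_is_constant_rate_extrapolation(self):
        pred = linear_predict(InterimState(m=50, t=5, n=200))
        assert pred.point == pytest.approx(20.0)

    def test_already_done_returns_elapsed_time(self):
        pred = linear_predict(InterimState(m=200, t=15, n=200))
        assert pred.point == 15
        assert pred.interval == (15, 15)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="inestimable"):
            linear_predict(InterimState(m=0, t=5, n=200))

    def test_interval_matches_poisson_cdf_inversion(self):
        # brute-force inversion of the Poisson CDF in the rate parameter
        m, t, n, level = 50, 5.0, 200, 0.95
        alpha = (1 - level) / 2

        def upper_tail(lam):  # Pr(X >= m | lam * t)
            return stats.poisson.sf(m - 1, lam * t)

        def lower_tail(lam):  # Pr(X <= m | lam * t)
            return stats.poisson.cdf(m, lam * t)

        rate_lo = optimize.brentq(lambda lam: upper_tail(lam) - alpha, 1e-6, 100)
        rate_hi = optimize.brentq(lambda lam: lower_tail(lam) - alpha, 1e-6, 100)
        pred = linear_predict(InterimState(m=m, t=t, n=n))
        expect_hi = t + (n - m) / rate_lo
        expect_lo = t + (n - m) / rate_hi
        assert pred.interval[0] == pytest.approx(expect_lo, rel=1e-6)
        assert pred.interval[1] == pytest.approx(expect_hi, rel=1e-6)


class TestPredictWithSites:
    def test_simultaneous_activation_reduces_to_site_naive(self):
        # k sites active from day 0 == single-process model with t -> k*t
        prior = AccrualPrior(n=200, T=24, P=0.5)
        interim = InterimState(m=50, t=5, n=200)
        k = 4
        site_pred = predict_with_sites(
            prior, interim, [0.0] * k, draws=20_000, seed=9
        )
        scaled_prior = AccrualPrior(n=200, T=24 * k, P=0.5)
        post = fit_posterior(scaled_prior, InterimState(m=50, t=5 * k, n=200))
        naive = predict_completion_time(post, 150, draws=20_000, seed=9)
        # same seed: identical theta and gamma draws, times scale by 1/k
        expected = interim.t + (naive.draws - post.t) / k
        np.testing.assert_allclose(np.sort(site_pred.draws), np.sort(expected), rtol=1e-10)

    def test_staggered_activation_shortens_prediction_under_staggering(self):
        # half the sites activate at month 6; evaluated at month 3 the
        # schedule-aware model knows capacity will double, so its median
        # predicted completion time is below the site-naive model's
        rng = np.random.default_rng(21)
        diffs = []
        for rep in range(100):
            rates = np.full(4, 2.0)
            sched = [0.0, 0.0, 6.0, 6.0]
            n = 120
            # simulate events from the staggered truth
            times = []
            for r, a in zip(rates, sched):
                t_ev = a + np.cumsum(rng.exponential(1 / r, size=300))
                times.append(t_ev)
            all_t = np.sort(np.concatenate(times))[:n]
            m3 = int(np.sum(all_t < 3.0))
            if m3 < 1:
                continue
            interim = InterimState(m=m3, t=3.0, n=n)
            prior = AccrualPrior(n=n, T=15.0, P=0.3)
            aware = predict_with_sites(prior, interim, sched, draws=4000, seed=rep)
            post = fit_posterior(prior, interim)
            naive = predict_completion_time(post, n - m3, draws=4000, seed=rep)
            diffs.append(aware.point - naive.point)
        assert np.median(diffs) < 0

    def test_empty_schedule_rejected(self):
        prior = AccrualPrior(n=100, T=12, P=0.5)
        with pytest.raises(ValueError, match="future capacity|empty"):
            predict_with_sites(prior, InterimState(m=10, t=2, n=100), [])

    def test_parameter_recovery_noninformative(self):
        # data at theta=0.1: posterior mean within 3 posterior SDs of truth
        # for m >= 100 in >= 95% of 200 replicates
        rng = np.random.default_rng(17)
        theta = 0.1
        hits = 0
        for _ in range(200):
            m = 150
            t = float(np.sum(rng.exponential(theta, m)))
            post = fit_posterior(AccrualPrior(n=m + 1, P=0.0), InterimState(m=m, t=t, n=m + 1))
            post_sd = post.scale / ((post.shape - 1) * np.sqrt(post.shape - 2))
            hits += abs(post.mean_theta - theta) <= 3 * post_sd
        assert hits >= 0.95 * 200
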