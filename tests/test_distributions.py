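import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

import erstress as es
from erstress.distributions import log1mexp


@pytest.fixture
def sched():
    return es.StressSchedule((4.0, 8.0))


@pytest.fixture
def params():
    return es.CEMParams(0.8, (0.01, 0.02, 0.03))


class TestERPrimitives:
    def test_cdf_boundaries(self):
        p = es.ERParams(0.8, 0.01)
        assert es.er_cdf(0.0, p) == 0.0
        assert es.er_cdf(1e4, p) == pytest.approx(1.0)
        t = np.linspace(0, 50, 200)
        assert np.all(np.diff(es.er_cdf(t, p)) >= 0)

    def test_rayleigh_reduction(self):
        p = es.ERParams(1.0, 1.0)
        assert es.er_cdf(1.0, p) == pytest.approx(1 - np.exp(-1), abs=1e-14)
        assert es.er_quantile(1 - np.exp(-1), p) == pytest.approx(1.0, abs=1e-12)

    def test_cdf_matches_pdf_quadrature(self):
        p = es.ERParams(0.8, 0.01)
        for t in [2.0, 8.0, 15.0, 25.0]:
            q, _ = integrate.quad(lambda u: es.er_pdf(u, p), 0, t)
            assert abs(q - es.er_cdf(t, p)) < 1e-8

    @pytest.mark.parametrize("alpha,beta", [(0.8, 0.01), (0.8, 1.0), (1.5, 0.01), (1.5, 1.0)])
    def test_pdf_normalized(self, alpha, beta):
        p = es.ERParams(alpha, beta)
        hi = es.er_quantile(1 - 1e-14, p)
        val, _ = integrate.quad(lambda t: es.er_pdf(t, p), 0, hi, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_pdf_shape_regimes(self):
        # unimodal above alpha = 1/2, monotone decreasing below
        t = np.linspace(1e-3, 4, 400)
        uni = es.er_pdf(t, es.ERParams(2.0, 1.0))
        peak = np.argmax(uni)
        assert 0 < peak < len(t) - 1
        dec = es.er_pdf(t, es.ERParams(0.4, 1.0))
        assert np.all(np.diff(dec) < 0)

    def test_pdf_at_origin(self):
        assert es.er_pdf(0.0, es.ERParams(0.8, 1.0)) == 0.0
        assert np.isinf(es.er_pdf(0.0, es.ERParams(0.3, 1.0)))

    def test_hazard_definition_and_shape(self):
        t = np.linspace(0.05, 3, 100)
        p = es.ERParams(2.5, 1.0)
        hz = es.er_hazard(t, p)
        assert np.allclose(hz, es.er_pdf(t, p) / (1 - es.er_cdf(t, p)), rtol=0, atol=1e-10)
        assert np.all(np.diff(hz) > 0)  # increasing for alpha >= 1/2
        # below alpha = 1/2 the hazard diverges at both ends of the support
        # with an interior minimum (bathtub), as the formula implies
        tg = np.geomspace(0.01, 10, 300)
        bath = es.er_hazard(tg, es.ERParams(0.2, 1.0))
        turn = np.argmin(bath)
        assert 0 < turn < len(tg) - 1
        assert np.all(np.diff(bath[:turn]) < 0) and np.all(np.diff(bath[turn + 1:]) > 0)

    def test_negative_time_rejected(self):
        p = es.ERParams(1.0, 1.0)
        with pytest.raises(ValueError):
            es.er_cdf(-1.0, p)
        with pytest.raises(ValueError):
            es.er_pdf(np.array([1.0, -2.0]), p)
        with pytest.raises(ValueError):
            es.er_hazard(0.0, p)
        with pytest.raises(ValueError):
            es.er_quantile(1.0, p)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        u=st.floats(min_value=1e-6, max_value=0.999),
        alpha=st.floats(min_value=0.5, max_value=5.0),
        beta=st.floats(min_value=1e-4, max_value=10.0),
    )
    def test_quantile_cdf_roundtrip(self, u, alpha, beta):
        # small shapes amplify float error through u^{1/alpha}, so the tight
        # tolerance is asserted on moderate shapes
        p = es.ERParams(alpha, beta)
        assert es.er_cdf(es.er_quantile(u, p), p) == pytest.approx(u, abs=1e-10)

    def test_mean_rayleigh_and_monotonicity(self):
        assert es.er_mean(es.ERParams(1.0, 1.0)) == pytest.approx(np.sqrt(np.pi) / 2, abs=1e-9)
        means = [es.er_mean(es.ERParams(0.8, b)) for b in (0.01, 0.02, 0.05, 0.2)]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_mean_matches_sampling(self):
        p = es.ERParams(0.8, 0.01)
        u = np.random.default_rng(5).uniform(size=10**6)
        draws = es.er_quantile(u, p)
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - es.er_mean(p)) < 3 * se


class TestCEM:
    def test_offsets_trivial_and_continuity_values(self, sched):
        assert es.cem_offsets(es.StressSchedule(()), [0.01]).c == (0.0,)
        # continuity-correct offsets: c_{k-1} = sum sqrt(beta_j/beta_k) dtau_j
        c = es.cem_offsets(sched, [0.01, 0.02, 0.03]).c
        assert c[0] == 0.0
        assert c[1] == pytest.approx(np.sqrt(0.01 / 0.02) * 4, abs=1e-12)
        assert c[2] == pytest.approx((np.sqrt(0.01) * 4 + np.sqrt(0.02) * 4) / np.sqrt(0.03),
                                     abs=1e-12)

    def test_offsets_length_mismatch(self, sched):
        with pytest.raises(ValueError):
            es.cem_offsets(sched, [0.01, 0.02])

    def test_cdf_continuous_at_change_points(self, params, sched):
        c = np.asarray(es.cem_offsets(sched, params.betas).c)
        for k, tau in enumerate(sched.change_times):
            left = es.cem_cdf(tau, params, sched)
            right = es.er_cdf(c[k + 1], es.ERParams(params.alpha, params.betas[k + 1]))
            assert abs(left - right) < 1e-10

    def test_cdf_continuity_random_parameters(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = rng.integers(1, 4)
            taus = np.cumsum(rng.uniform(1, 5, m))
            sched = es.StressSchedule(taus)
            betas = np.sort(rng.uniform(0.005, 0.5, m + 1))
            p = es.CEMParams(rng.uniform(0.3, 3.0), betas)
            c = np.asarray(es.cem_offsets(sched, betas).c)
            for k, tau in enumerate(sched.change_times):
                left = es.cem_cdf(tau, p, sched)
                right = es.er_cdf(c[k + 1], es.ERParams(p.alpha, betas[k + 1]))
                assert abs(left - right) < 1e-10

    def test_first_branch_is_single_level_law(self, params, sched):
        t = np.linspace(0.1, 4.0, 30)
        single = es.ERParams(params.alpha, params.betas[0])
        assert np.allclose(es.cem_cdf(t, params, sched), es.er_cdf(t, single), atol=1e-14)
        assert np.allclose(es.cem_pdf(t[:-1], params, sched), es.er_pdf(t[:-1], single),
                           atol=1e-14)

    def test_cdf_matches_pdf_quadrature(self, params, sched):
        for t in [2.0, 5.0, 9.0, 14.0]:
            q, _ = integrate.quad(lambda u: es.cem_pdf(u, params, sched), 0, t,
                                  points=[4, 8], limit=200)
            assert abs(q - es.cem_cdf(t, params, sched)) < 1e-7

    def test_pdf_is_cdf_derivative(self, params, sched):
        for t in [1.5, 5.5, 10.0]:
            h = 1e-5
            num = (es.cem_cdf(t + h, params, sched) - es.cem_cdf(t - h, params, sched)) / (2 * h)
            assert num == pytest.approx(es.cem_pdf(t, params, sched), abs=1e-5)

    def test_pdf_normalized(self, params, sched):
        val, _ = integrate.quad(lambda t: es.cem_pdf(t, params, sched), 0, 80,
                                points=[4, 8], limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_pdf_at_change_point_is_right_limit(self, params, sched):
        at = es.cem_pdf(4.0, params, sched)
        right = es.cem_pdf(4.0 + 1e-9, params, sched)
        assert at == pytest.approx(right, rel=1e-6)


class TestSampler:
    def test_output_sorted_positive(self, params, sched):
        times, counts = es.cem_sample(500, params, sched, 0)
        assert np.all(times > 0)
        assert np.all(np.diff(times) >= 0)
        assert counts.sum() == 500

    def test_empirical_cdf_at_change_points(self, params, sched):
        n = 10**5
        times, counts = es.cem_sample(n, params, sched, 1)
        for tau in sched.change_times:
            pk = es.cem_cdf(tau, params, sched)
            emp = np.mean(times <= tau)
            assert abs(emp - pk) < 3 * np.sqrt(pk * (1 - pk) / n)

    def test_single_level_reduction_ks(self):
        p = es.CEMParams(0.8, (0.01,))
        sched = es.StressSchedule(())
        times, _ = es.cem_sample(10**4, p, sched, 2)
        res = stats.kstest(times, lambda t: es.er_cdf(t, es.ERParams(0.8, 0.01)))
        assert res.pvalue > 0.01

    def test_uniform_ks_against_composed_cdf(self, params, sched):
        times, _ = es.cem_sample(10**4, params, sched, 3)
        d = stats.kstest(times, lambda t: es.cem_cdf(t, params, sched)).statistic
        assert d < 0.02

    def test_reproducible(self, params, sched):
        a, _ = es.cem_sample(100, params, sched, 42)
        b, _ = es.cem_sample(100, params, sched, 42)
        assert np.array_equal(a, b)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(x=st.floats(min_value=1e-12, max_value=50.0))
def test_log1mexp_stable(x):
    assert log1mexp(x) == pytest.approx(np.log(1 - np.exp(-x)) if x > 1e-8
                                        else np.log(np.expm1(x)) - x, rel=1e-9)
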