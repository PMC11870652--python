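"""LBA transforms, closed-form likelihood and sampler consistency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import cumulative_trapezoid
from scipy.special import ndtr

from vam.lba import (
    LBAParams,
    TransformedParams,
    accumulator_cdf,
    accumulator_pdf,
    inverse_transform,
    log_jacobian,
    loglik_grads_batch,
    sample_trials,
    transform_params,
    trial_loglik,
    trial_loglik_grads,
)

PARAM_SETS = [
    LBAParams(b=1.0, A=0.5, t0=0.2),
    LBAParams(b=1.5, A=0.25, t0=0.3),
    LBAParams(b=2.0, A=1.0, t0=0.15),
]


class TestTransforms:
    def test_log_examples(self):
        assert transform_params(LBAParams(2, 1, 1)) == TransformedParams(0, 0, 0)
        ts = transform_params(LBAParams(1.5, 0.5, 0.25))
        np.testing.assert_allclose(ts.as_array(),
                                   [0.0, -0.6931472, -1.3862944], atol=1e-6)

    def test_inverse_examples(self):
        p = inverse_transform(TransformedParams(0, 0, 0))
        assert (p.b, p.A, p.t0) == (2.0, 1.0, 1.0)
        tiny = inverse_transform(TransformedParams(-30, -30, -30))
        assert tiny.b > tiny.A > 0 and tiny.t0 > 0

    @given(st.tuples(st.floats(-3, 3), st.floats(-3, 3), st.floats(-3, 3)))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, stars):
        ts = TransformedParams(*stars)
        back = transform_params(inverse_transform(ts))
        np.testing.assert_allclose(back.as_array(), ts.as_array(), atol=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            LBAParams(b=1.0, A=1.0, t0=0.2)   # b must exceed A
        with pytest.raises(ValueError):
            LBAParams(b=1.0, A=-0.1, t0=0.2)
        with pytest.raises(ValueError):
            LBAParams(b=1.0, A=0.5, t0=0.0)
        with pytest.raises(ValueError):
            transform_params(LBAParams(1.0, 0.0, 0.2))  # log A undefined

    def test_log_jacobian_component_sum(self):
        assert log_jacobian(TransformedParams(0, 0, 0)) == 0.0
        assert log_jacobian(TransformedParams(1, -1, 0.5)) == 0.5

    def test_log_jacobian_matches_numeric_determinant(self):
        """log|det J| of T^-1 equals b* + A* + t0* (numeric-Jacobian oracle)."""
        rng = np.random.default_rng(0)
        h = 1e-6
        for _ in range(100):
            stars = rng.uniform(-1.5, 1.5, 3)
            J = np.empty((3, 3))
            for j in range(3):
                up, dn = stars.copy(), stars.copy()
                up[j] += h
                dn[j] -= h
                pu = inverse_transform(TransformedParams(*up))
                pd = inverse_transform(TransformedParams(*dn))
                J[:, j] = (np.array([pu.b, pu.A, pu.t0])
                           - np.array([pd.b, pd.A, pd.t0])) / (2 * h)
            num = np.log(abs(np.linalg.det(J)))
            ana = log_jacobian(TransformedParams(*stars))
            assert abs(num - ana) < 1e-5


class TestAccumulatorDistribution:
    def test_cdf_zero_at_origin_and_monotone(self):
        u = np.linspace(1e-6, 30, 4000)
        F = accumulator_cdf(u, b=1.0, A=0.5, v=1.0)
        assert F[0] < 1e-10
        assert np.all(np.diff(F) >= -1e-12)
        assert np.all((F >= 0) & (F <= 1))

    def test_cdf_asymptote_is_positive_drift_probability(self):
        # P(ever finish) = P(drift > 0) = Phi(v/s)
        val = accumulator_cdf(1e7, b=1.0, A=0.5, v=2.0, s=1.0)
        assert abs(val - ndtr(2.0)) < 1e-6

    def test_cdf_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        n = 10 ** 6
        k = rng.uniform(0, 0.5, n)
        d = rng.normal(1.0, 1.0, n)
        hit = (d > 0) & ((1.0 - k) / np.where(d > 0, d, np.inf) <= 1.0)
        mc, se = hit.mean(), hit.std() / np.sqrt(n)
        assert abs(accumulator_cdf(1.0, 1.0, 0.5, 1.0) - mc) < 3 * se

    def test_pdf_is_cdf_derivative(self):
        u = np.linspace(0.05, 3.0, 50)
        h = 1e-5
        for p in PARAM_SETS:
            for v in (-0.5, 0.5, 2.0):
                fd = (accumulator_cdf(u + h, p.b, p.A, v)
                      - accumulator_cdf(u - h, p.b, p.A, v)) / (2 * h)
                np.testing.assert_allclose(
                    accumulator_pdf(u, p.b, p.A, v), fd, atol=1e-4)

    def test_pdf_small_u_and_negative_drift(self):
        assert accumulator_pdf(1e-9, 1.0, 0.5, 1.0) < 1e-12
        assert accumulator_pdf(1.0, 1.0, 0.5, -10.0) < 1e-6

    def test_zero_start_range_limit(self):
        # A -> 0: deterministic start, F(u) = Phi((uv - b)/(us))
        val = accumulator_cdf(1.0, 1.0, 1e-9, 1.5)
        assert abs(val - ndtr(0.5)) < 1e-6
        u = np.linspace(0.2, 3, 30)
        h = 1e-5
        fd = (accumulator_cdf(u + h, 1.0, 1e-9, 1.5)
              - accumulator_cdf(u - h, 1.0, 1e-9, 1.5)) / (2 * h)
        np.testing.assert_allclose(accumulator_pdf(u, 1.0, 1e-9, 1.5), fd,
                                   atol=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            accumulator_cdf(0.0, 1.0, 0.5, 1.0)
        with pytest.raises(ValueError):
            accumulator_pdf(-1.0, 1.0, 0.5, 1.0)


class TestTrialLoglik:
    def test_rt_at_nondecision_time_is_impossible(self):
        p = LBAParams(1.0, 0.5, 0.2)
        assert trial_loglik(0.2, 1, np.zeros(4), p) == -np.inf
        assert trial_loglik(0.1, 1, np.zeros(4), p) == -np.inf

    def test_symmetric_accumulators_choice_invariance(self):
        p = LBAParams(1.0, 0.5, 0.2)
        v = np.full(4, 1.2)
        vals = [trial_loglik(0.8, c, v, p) for c in (1, 2, 3, 4)]
        assert np.ptp(vals) < 1e-12

    def test_finite_above_t0(self):
        p = LBAParams(1.0, 0.5, 0.2)
        rng = np.random.default_rng(1)
        rts = rng.uniform(0.2001, 10.0, 200)
        v = rng.normal(0, 2, (200, 4))
        ll = trial_loglik(rts, rng.integers(1, 5, 200), v, p)
        assert np.all(np.isfinite(ll))

    def test_choice_out_of_range(self):
        with pytest.raises(ValueError):
            trial_loglik(0.5, 5, np.zeros(4), LBAParams(1.0, 0.5, 0.2))

    def test_total_mass_matches_simulation(self):
        """Integrated defective density over (rt, choice) equals the
        simulated fraction of defined trials (Monte-Carlo oracle)."""
        p = LBAParams(1.0, 0.5, 0.2)
        v = np.array([1.0, 0.5, -0.5, -1.0])
        # geometric grid: the defective race has a ~1/T late tail
        grid = p.t0 + np.geomspace(1e-6, 1e6, 60000)
        mass = sum(
            np.trapezoid(np.exp(trial_loglik(
                grid, np.full(grid.size, c), v, p)), grid)
            for c in (1, 2, 3, 4))
        n = 10 ** 6
        _, _, valid = sample_trials(np.tile(v, (n, 1)), p, seed=0)
        mc, se = valid.mean(), valid.std() / np.sqrt(n)
        assert abs(mass - mc) < 3 * se

    def test_gradients_match_finite_differences(self):
        p = LBAParams(1.0, 0.5, 0.2)
        rng = np.random.default_rng(3)
        rts = rng.uniform(0.4, 2.0, 30)
        ch = rng.integers(1, 5, 30)
        v = rng.normal(0.5, 1.0, (30, 4))
        g = trial_loglik_grads(rts, ch, v, p)
        h = 1e-6
        for j in range(4):
            vp, vm = v.copy(), v.copy()
            vp[:, j] += h
            vm[:, j] -= h
            fd = (trial_loglik(rts, ch, vp, p)
                  - trial_loglik(rts, ch, vm, p)) / (2 * h)
            np.testing.assert_allclose(g.d_v[:, j], fd, rtol=1e-4, atol=1e-6)
        stars = transform_params(p).as_array()
        for j in range(3):
            up, dn = stars.copy(), stars.copy()
            up[j] += h
            dn[j] -= h
            pu = inverse_transform(TransformedParams(*up))
            pd = inverse_transform(TransformedParams(*dn))
            fd = (trial_loglik(rts, ch, v, pu)
                  - trial_loglik(rts, ch, v, pd)) / (2 * h)
            np.testing.assert_allclose(g.d_theta_star[:, j], fd,
                                       rtol=1e-4, atol=1e-6)

    def test_batched_loglik_agrees_with_scalar_path(self):
        p = LBAParams(1.3, 0.6, 0.22)
        rng = np.random.default_rng(4)
        rts = rng.uniform(0.4, 2.0, 25)
        ch = rng.integers(1, 5, 25)
        v = rng.normal(0.5, 1.0, (25, 4))
        shape = (25, 3)
        ll, *_ = loglik_grads_batch(
            rts, ch, v, np.full(shape, p.b), np.full(shape, p.A),
            np.full(shape, p.t0))
        ref = trial_loglik(rts, ch, v, p)
        np.testing.assert_allclose(ll, ref[:, None].repeat(3, 1), rtol=1e-10)


class TestSampler:
    def test_all_negative_drifts_rarely_valid(self):
        _, _, valid = sample_trials(
            np.tile([-10.0] * 4, (10 ** 5, 1)), LBAParams(1, 0.5, 0.2),
            seed=0)
        assert valid.mean() < 1e-4

    def test_dominant_accumulator(self):
        p = LBAParams(1.0, 1e-9, 0.2)
        rts, ch, valid = sample_trials(
            np.tile([1000.0, -10, -10, -10], (2000, 1)), p, seed=0)
        assert np.all(ch[valid] == 1)
        assert np.all(np.abs(rts[valid] - (0.2 + 1.0 / 1000)) < 1e-2)

    def test_nondecision_floor(self):
        p = LBAParams(1.0, 0.5, 0.25)
        rts, _, valid = sample_trials(
            np.tile([3.0, 1.0, -1.0, -1.0], (20000, 1)), p, seed=1)
        assert np.all(rts[valid] > 0.25)

    def test_determinism(self):
        v = np.tile([1.0, 0.5, -0.5, -1.0], (100, 1))
        p = LBAParams(1, 0.5, 0.2)
        a = sample_trials(v, p, seed=9)
        b = sample_trials(v, p, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    @pytest.mark.parametrize("p", PARAM_SETS)
    def test_sampler_matches_likelihood_distribution(self, p):
        """KS distance between sampled correct-choice RTs and the density
        implied by the likelihood stays below 0.01 at n = 1e5."""
        v = np.array([1.0, 0.5, -0.5, -1.0])
        n = 10 ** 5
        rts, ch, valid = sample_trials(np.tile(v, (n, 1)), p, seed=17)
        sel = valid & (ch == 1)
        samp = np.sort(rts[sel])
        # geometric grid: the defective race has a heavy late tail
        grid = p.t0 + np.geomspace(1e-6, samp[-1] + 10.0, 100_000)
        dens = np.exp(trial_loglik(grid, np.ones(grid.size, int), v, p))
        cdf = cumulative_trapezoid(dens, grid, initial=0.0)
        cdf /= cdf[-1]
        model_cdf = np.interp(samp, grid, cdf)
        emp_cdf = np.arange(1, samp.size + 1) / samp.size
        assert np.max(np.abs(model_cdf - emp_cdf)) < 0.01

    def test_choice_probabilities_match_likelihood_integral(self):
        p = LBAParams(1.0, 0.5, 0.2)
        v = np.array([1.0, 0.5, -0.5, -1.0])
        grid = p.t0 + np.geomspace(1e-6, 1e6, 60000)
        pred = np.trapezoid(
            np.exp(trial_loglik(grid, np.ones(grid.size, int), v, p)), grid)
        n = 10 ** 5
        rts, ch, valid = sample_trials(np.tile(v, (n, 1)), p, seed=2)
        emp = (ch == 1).mean()   # over all trials incl. undefined
        se = np.sqrt(pred * (1 - pred) / n)
        assert abs(emp - pred) < 3 * se
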