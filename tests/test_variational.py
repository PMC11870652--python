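"""Reparameterization, ELBO estimator/gradients, and the fitting loops."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from vam.lba import LBAParams, sample_trials, transform_params, trial_loglik
from vam.variational import (
    Adam,
    FitConfig,
    PosteriorGaussian,
    elbo_estimate,
    elbo_with_grads,
    fit_task_optimized,
    fit_vam,
    gaussian_logq,
    map_estimate,
    reparameterize,
    sample_model_behavior,
    steps_per_epoch,
    total_steps,
)

MU = np.array([0.1, -0.5, -1.2])
L = np.array([[0.3, 0.0, 0.0],
              [0.05, 0.2, 0.0],
              [-0.02, 0.01, 0.15]])
# tight posterior well inside the likelihood's smooth region (all t0 draws
# far below the fastest RT): used where estimator smoothness matters
MU_T = np.array([0.1, -0.5, -1.6])
L_T = np.array([[0.05, 0.0, 0.0],
                [0.01, 0.05, 0.0],
                [-0.005, 0.002, 0.04]])


def _mock_loglik(rts, choices, v, b, A, t0):
    z = np.zeros_like(b)
    return z, np.zeros(b.shape + (4,)), z.copy(), z.copy(), z.copy()


def quadrature_loglik(rt, choice, v, b, A, t0, chunk=200_000):
    """Trial log-likelihood on flat parameter grids (for quadrature oracles)."""
    from vam.lba import loglik_grads_batch
    out = np.empty(b.size)
    for lo in range(0, b.size, chunk):
        sl = slice(lo, lo + chunk)
        ll, *_ = loglik_grads_batch(
            np.array([rt]), np.array([choice]), np.asarray(v)[None],
            b[sl][None], A[sl][None], t0[sl][None])
        out[sl] = ll[0]
    return out


@pytest.fixture(scope="module")
def toy_batch():
    p = LBAParams(1.2, 0.4, 0.25)
    v = np.tile([2.5, -0.5, -0.5, -0.5], (6, 1))
    rts, ch, valid = sample_trials(v, p, seed=3)
    return rts[valid], ch[valid], v[valid]


class TestReparameterization:
    def test_zero_noise_returns_mean(self):
        np.testing.assert_array_equal(reparameterize(MU, L, np.zeros(3)), MU)

    def test_identity_factor_returns_noise(self):
        eps = np.random.default_rng(0).standard_normal((10, 3))
        np.testing.assert_allclose(
            reparameterize(np.zeros(3), np.eye(3), eps), eps)

    def test_sample_covariance(self):
        eps = np.random.default_rng(1).standard_normal((100_000, 3))
        ts = reparameterize(MU, L, eps)
        cov = np.cov(ts.T)
        se = 3.0 / np.sqrt(100_000)
        assert np.all(np.abs(cov - L @ L.T) < 3 * se)


class TestGaussianLogq:
    def test_standard_normal_at_mode(self):
        val = gaussian_logq(np.zeros(3), np.zeros(3), np.eye(3))
        assert abs(val - (-1.5 * np.log(2 * np.pi))) < 1e-12

    def test_diagonal_factorizes(self):
        sig = np.array([0.5, 1.5, 2.0])
        th = np.array([0.3, -0.2, 1.0])
        expected = sum(
            -0.5 * np.log(2 * np.pi) - np.log(s) - 0.5 * (t / s) ** 2
            for t, s in zip(th, sig))
        val = gaussian_logq(th, np.zeros(3), np.diag(sig))
        assert abs(val - expected) < 1e-12

    def test_matches_dense_covariance_oracle(self):
        rng = np.random.default_rng(2)
        th = rng.normal(size=(20, 3))
        oracle = multivariate_normal(MU, L @ L.T).logpdf(th)
        np.testing.assert_allclose(gaussian_logq(th, MU, L), oracle,
                                   atol=1e-10)

    def test_nonpositive_diagonal_rejected(self):
        bad = np.diag([1.0, -1.0, 1.0])
        with pytest.raises(ValueError):
            gaussian_logq(np.zeros(3), np.zeros(3), bad)


class TestElboEstimator:
    def test_mocked_likelihood_reduction(self):
        """With the likelihood zeroed out, the estimate equals the direct
        per-sample mean of log prior + log-Jacobian - log q."""
        rng = np.random.default_rng(4)
        eps = rng.standard_normal((8, 5, 3))
        rts = np.full(8, 0.6)
        ch = np.ones(8, int)
        v = np.zeros((8, 4))
        est = elbo_estimate(rts, ch, v, MU, L, eps=eps,
                            loglik_fn=_mock_loglik)
        ts = reparameterize(MU, L, eps)
        A = np.exp(ts[..., 1])
        b = np.exp(ts[..., 0]) + A
        t0 = np.exp(ts[..., 2])
        lp = -1.5 * np.log(2 * np.pi) - 0.5 * (b ** 2 + A ** 2 + t0 ** 2)
        direct = (lp + ts.sum(-1) - gaussian_logq(ts, MU, L)).mean()
        assert abs(est - direct) < 1e-12

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            elbo_estimate(np.array([]), np.array([], int),
                          np.zeros((0, 4)), MU, L,
                          eps=np.zeros((0, 2, 3)))

    def test_variance_shrinks_with_mc_samples(self, toy_batch):
        rts, ch, v = toy_batch
        var = {}
        for n_mc in (1, 10, 100):
            vals = [elbo_estimate(rts, ch, v, MU_T, L_T, n_samples=n_mc,
                                  seed=1000 + r) for r in range(100)]
            var[n_mc] = np.var(vals)
        assert var[1] > var[10] > var[100]
        assert 3 < var[1] / var[10] < 30        # ~ 1/L scaling
        assert 3 < var[10] / var[100] < 30

    def test_gradients_match_finite_differences(self, toy_batch):
        rts, ch, v = toy_batch
        eps = np.random.default_rng(6).standard_normal((len(rts), 10, 3))
        _, d_mu, d_L, d_v = elbo_with_grads(rts, ch, v, MU_T, L_T, eps)
        h = 1e-6
        for j in range(3):
            up, dn = MU_T.copy(), MU_T.copy()
            up[j] += h
            dn[j] -= h
            fd = (elbo_estimate(rts, ch, v, up, L_T, eps=eps)
                  - elbo_estimate(rts, ch, v, dn, L_T, eps=eps)) / (2 * h)
            assert abs(fd - d_mu[j]) < 1e-4 * max(1, abs(fd))
        for i in range(3):
            for j in range(i + 1):
                Lu, Ld = L_T.copy(), L_T.copy()
                Lu[i, j] += h
                Ld[i, j] -= h
                fd = (elbo_estimate(rts, ch, v, MU_T, Lu, eps=eps)
                      - elbo_estimate(rts, ch, v, MU_T, Ld, eps=eps)) / (2 * h)
                assert abs(fd - d_L[i, j]) < 1e-4 * max(1, abs(fd))
        for j in range(4):
            vu, vd = v.copy(), v.copy()
            vu[:, j] += h
            vd[:, j] -= h
            fd = (elbo_estimate(rts, ch, vu, MU_T, L_T, eps=eps)
                  - elbo_estimate(rts, ch, vd, MU_T, L_T, eps=eps)) / (2 * h)
            assert abs(fd - d_v[:, j].mean()) < 1e-4 * max(1, abs(fd))

    def test_elbo_below_quadrature_log_evidence(self):
        """Jensen bound on a 1-trial toy: the ELBO never exceeds the log
        evidence computed by dense quadrature over the natural parameters."""
        rt, choice = 0.8, 1
        v = np.array([2.0, -0.5, -0.5, -0.5])
        # log Z = log  integral  f(rt, c | theta) N(theta; 0, I) dtheta over
        # b~ = b - A, A, t0 > 0 (the transform's image)
        gb = np.linspace(1e-4, 6, 90)
        ga = np.linspace(1e-4, 6, 90)
        gt = np.linspace(1e-4, rt - 1e-4, 90)
        B, Aa, T0 = np.meshgrid(gb, ga, gt, indexing="ij")
        lik = np.exp(quadrature_loglik(rt, choice, v, B.ravel() + Aa.ravel(),
                                       Aa.ravel(), T0.ravel())
                     ).reshape(B.shape)
        prior = np.exp(-1.5 * np.log(2 * np.pi)
                       - 0.5 * (((B + Aa) ** 2) + Aa ** 2 + T0 ** 2))
        integ = np.trapezoid(np.trapezoid(np.trapezoid(
            lik * prior, gt, axis=2), ga, axis=1), gb, axis=0)
        log_z = np.log(integ)
        for seed in range(3):
            elbo = elbo_estimate([rt], [choice], v[None], MU, L,
                                 n_samples=4000, seed=seed)
            assert elbo < log_z


class TestAdamAndSchedule:
    def test_step_accounting(self):
        assert steps_per_epoch(16_250, 256) == 64
        assert total_steps(200, 16_250, 256) == 12_800

    def test_adam_converges_on_quadratic(self):
        params = {"x": np.array([5.0, -3.0])}
        opt = Adam(params, lr=0.1)
        for _ in range(500):
            params = opt.step(params, {"x": 2 * params["x"]})
        assert np.abs(params["x"]).max() < 1e-3


class TestFitting:
    def test_bias_encoder_fit_improves_elbo_and_stays_pd(self):
        p = LBAParams(1.2, 0.4, 0.25)
        v = np.tile([2.5, -0.5, -0.5, -0.5], (600, 1))
        rts, ch, valid = sample_trials(v, p, seed=11)
        rts, ch = rts[valid], ch[valid]
        n = len(rts)
        tr, va = np.arange(0, n - 100), np.arange(n - 100, n)
        cfg = FitConfig(epochs=30, batch_size=128, mc_samples=5, seed=0,
                        augment=False)
        post, zeta, log, diag = fit_vam(None, rts, ch, tr, va, cfg=cfg,
                                        encoder_kind="bias")
        frame = log.frame
        assert frame["val_elbo"].iloc[-1] >= frame["val_elbo"].iloc[0]
        assert np.all(np.diag(post.L_chol) > 0)
        assert np.all(np.linalg.eigvalsh(post.cov) > 0)
        assert set(diag) >= {"chance_accuracy_flag", "negative_drift_flag"}

    def test_fit_deterministic_given_seed(self):
        p = LBAParams(1.2, 0.4, 0.25)
        v = np.tile([2.5, -0.5, -0.5, -0.5], (200, 1))
        rts, ch, valid = sample_trials(v, p, seed=12)
        rts, ch = rts[valid], ch[valid]
        idx = np.arange(len(rts))
        cfg = FitConfig(epochs=3, batch_size=64, mc_samples=3, seed=5,
                        augment=False)
        out1 = fit_vam(None, rts, ch, idx, None, cfg=cfg, encoder_kind="bias")
        out2 = fit_vam(None, rts, ch, idx, None, cfg=cfg, encoder_kind="bias")
        np.testing.assert_array_equal(out1[0].mu, out2[0].mu)
        np.testing.assert_array_equal(out1[0].L_chol, out2[0].L_chol)
        np.testing.assert_array_equal(out1[1]["bias"], out2[1]["bias"])
        np.testing.assert_array_equal(out1[2].frame["train_elbo"],
                                      out2[2].frame["train_elbo"])

    def test_map_estimate_examples(self):
        post = PosteriorGaussian(np.zeros(3), 0.1 * np.eye(3))
        p = map_estimate(post)
        assert (p.b, p.A, p.t0) == (2.0, 1.0, 1.0)
        post = PosteriorGaussian(np.log([0.5, 0.5, 0.3]), 0.1 * np.eye(3))
        p = map_estimate(post)
        np.testing.assert_allclose([p.b, p.A, p.t0], [1.0, 0.5, 0.3])

    def test_sample_model_behavior_consistency(self):
        """Simulated choice distribution matches the likelihood-implied
        choice probabilities (forced drift means)."""
        post = PosteriorGaussian(
            transform_params(LBAParams(1.0, 0.5, 0.2)).as_array(),
            1e-6 * np.eye(3))
        zeta = {"bias": np.array([5.0, -5.0, -5.0, -5.0])}
        images = np.zeros((10_000, 1))
        rts, ch, valid, excl, v = sample_model_behavior(
            post, zeta, None, images, seed=0)
        assert excl >= 0
        assert (ch[valid] == 1).mean() > 0.999

    def test_posterior_requires_valid_factor(self):
        with pytest.raises(ValueError):
            PosteriorGaussian(np.zeros(3), -np.eye(3))
        with pytest.raises(ValueError):
            PosteriorGaussian(np.zeros(2), np.eye(3))


class TestTaskOptimized:
    def test_cross_entropy_chance_and_gradient(self):
        """Uniform logits give the 4-class chance loss log 4; the logits
        gradient is (softmax - onehot)/n, checked by finite differences."""
        from vam.variational import cross_entropy
        labels = np.array([0, 1, 2, 3, 1])
        loss, grad = cross_entropy(np.zeros((5, 4)), labels)
        assert loss == pytest.approx(np.log(4), abs=1e-12)
        rng = np.random.default_rng(0)
        logits = rng.normal(0, 2, (5, 4))
        loss, grad = cross_entropy(logits, labels)
        h = 1e-6
        for i in range(5):
            for j in range(4):
                up, dn = logits.copy(), logits.copy()
                up[i, j] += h
                dn[i, j] -= h
                fd = (cross_entropy(up, labels)[0]
                      - cross_entropy(dn, labels)[0]) / (2 * h)
                assert abs(fd - grad[i, j]) < 1e-6

    def test_learns_easy_set(self, desk_encoder_cfg):
        """Training accuracy exceeds 95% on a small easy stimulus set
        (all-congruent displays at a fixed position)."""
        from vam.stimuli import (RenderConfig, TrialSpec, render_batch,
                                 sample_trial_specs)
        rcfg = RenderConfig(out_hw=(32, 32), canvas_scale=0.25)
        specs = [TrialSpec(s.target_dir, s.flanker_dir, s.layout, (320, 240))
                 for s in sample_trial_specs(500, 1.0, seed=20, cfg=rcfg)]
        images = render_batch(specs, rcfg)
        labels = np.array([{"left": 0, "right": 1, "up": 2,
                            "down": 3}[s.target_dir] for s in specs])
        cfg = FitConfig(epochs=15, batch_size=64, lr=2e-3, seed=0,
                        augment=False)
        zeta, log = fit_task_optimized(images, labels, np.arange(500), None,
                                       encoder_cfg=desk_encoder_cfg, cfg=cfg)
        assert log.frame["train_accuracy"].iloc[-1] > 0.95
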