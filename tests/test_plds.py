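import numpy as np
import pytest
from scipy.optimize import minimize

from gaitdyn import gaussian_lds as gl
from gaitdyn import plds


def random_params(rng, k=3, n_units=5, stable=0.9):
    M = rng.standard_normal((k, k))
    A = stable * np.linalg.qr(M)[0]
    Q = 0.05 * np.eye(k)
    Q0 = 0.3 * np.eye(k)
    C = 0.5 * rng.standard_normal((n_units, k))
    d = rng.normal(-0.5, 0.3, n_units)
    x0 = rng.standard_normal(k)
    return plds.PLDSParams(A=A, Q=Q, C=C, d=d, x0=x0, Q0=Q0)


def joint_gaussian_conditioning(y, p, r):
    """Brute-force oracle: stack (x_1..x_T, y_1..y_T) as one multivariate
    normal and condition on y directly."""
    k = p.latent_dim
    U = p.n_units
    T = y.shape[1]
    # latent joint moments by propagation
    mean_x = np.zeros(T * k)
    cov_x = np.zeros((T * k, T * k))
    means = [p.x0]
    for t in range(1, T):
        means.append(p.A @ means[-1])
    for t in range(T):
        mean_x[t * k : (t + 1) * k] = means[t]
    # cov recursion: Cov(x_t) and Cov(x_t, x_s) = Cov(x_t) (A^{s-t})'
    covs = [p.Q0]
    for t in range(1, T):
        covs.append(p.A @ covs[-1] @ p.A.T + p.Q)
    for t in range(T):
        acc = covs[t]
        cov_x[t * k : (t + 1) * k, t * k : (t + 1) * k] = covs[t]
        for s in range(t + 1, T):
            acc = acc @ p.A.T
            cov_x[t * k : (t + 1) * k, s * k : (s + 1) * k] = acc
            cov_x[s * k : (s + 1) * k, t * k : (t + 1) * k] = acc.T
    Cbig = np.kron(np.eye(T), p.C)
    dbig = np.tile(p.d, T)
    Rbig = np.kron(np.eye(T), np.diag(r))
    mean_y = Cbig @ mean_x + dbig
    cov_y = Cbig @ cov_x @ Cbig.T + Rbig
    cov_xy = cov_x @ Cbig.T
    yv = y.T.ravel()
    sol = np.linalg.solve(cov_y, yv - mean_y)
    post_mean = mean_x + cov_xy @ sol
    post_cov = cov_x - cov_xy @ np.linalg.solve(cov_y, cov_xy.T)
    return post_mean.reshape(T, k).T, post_cov


class TestSimulate:
    def test_zero_loading_gives_iid_poisson(self, rng):
        p = random_params(rng, k=2, n_units=4)
        p.C = np.zeros_like(p.C)
        lat, counts = plds.simulate(p, 4000, seed=7)
        mean = counts.mean(axis=1)
        expect = np.exp(p.d)
        se = np.sqrt(expect / 4000)
        assert np.all(np.abs(mean - expect) < 3 * se + 1e-12)

    def test_degenerate_noise_constant_latents(self, rng):
        k = 2
        p = plds.PLDSParams(
            A=np.eye(k), Q=1e-14 * np.eye(k), C=0.1 * np.ones((3, k)),
            d=-np.ones(3), x0=np.array([1.0, -1.0]), Q0=1e-14 * np.eye(k),
        )
        lat, _ = plds.simulate(p, 50, seed=0)
        assert np.allclose(lat, p.x0[:, None], atol=1e-5)

    def test_silent_unit_stays_silent(self, rng):
        p = random_params(rng, k=2, n_units=3)
        p.d[0] = -40.0  # effectively rate zero
        p.C[0] = 0.0
        _, counts = plds.simulate(p, 500, seed=3)
        assert counts[0].sum() == 0

    def test_reproducible_by_seed(self, rng):
        p = random_params(rng)
        l1, c1 = plds.simulate(p, 100, seed=42)
        l2, c2 = plds.simulate(p, 100, seed=42)
        assert np.array_equal(c1, c2) and np.array_equal(l1, l2)


class TestLaplaceEstep:
    def test_zero_loading_posterior_equals_prior_mean(self, rng):
        p = random_params(rng, k=2, n_units=4)
        p.C = np.zeros_like(p.C)
        y = rng.poisson(0.5, size=(4, 30))
        post = plds.laplace_estep(y, p)
        expect = np.empty((2, 30))
        expect[:, 0] = p.x0
        for t in range(1, 30):
            expect[:, t] = p.A @ expect[:, t - 1]
        assert np.allclose(post.mean, expect, atol=1e-7)

    @pytest.mark.parametrize("T", [1, 5, 20])
    def test_gaussian_matches_kalman(self, rng, T):
        p = random_params(rng, k=3, n_units=5)
        r = rng.uniform(0.2, 0.8, 5)
        y = rng.standard_normal((5, T))
        post = plds.laplace_estep(y, p, observation="gaussian", obs_var=r)
        gp = gl.GaussianLDSParams(A=p.A, Q=p.Q, C=p.C, d=p.d, r=r, x0=p.x0, Q0=p.Q0)
        ks = gl.kalman_smoother(y, gp)
        assert np.allclose(post.mean, ks.mean, atol=1e-8)
        assert np.allclose(post.cov, ks.cov, atol=1e-8)
        if T > 1:
            assert np.allclose(post.cov_cross, ks.cov_cross, atol=1e-8)
        assert post.loglik_approx == pytest.approx(ks.loglik, abs=1e-8)

    @pytest.mark.parametrize("T", [2, 5])
    def test_gaussian_matches_bruteforce_joint(self, rng, T):
        p = random_params(rng, k=2, n_units=4)
        r = rng.uniform(0.3, 0.7, 4)
        y = rng.standard_normal((4, T))
        post = plds.laplace_estep(y, p, observation="gaussian", obs_var=r)
        mean_o, cov_o = joint_gaussian_conditioning(y, p, r)
        assert np.allclose(post.mean, mean_o, atol=1e-8)
        k = p.latent_dim
        for t in range(T):
            assert np.allclose(post.cov[t], cov_o[t * k : (t + 1) * k, t * k : (t + 1) * k], atol=1e-8)
        for t in range(T - 1):
            assert np.allclose(
                post.cov_cross[t],
                cov_o[t * k : (t + 1) * k, (t + 1) * k : (t + 2) * k],
                atol=1e-8,
            )

    def test_single_bin_wide_prior_approaches_glm_mle(self, rng):
        k, U = 2, 30
        C = rng.uniform(0.2, 1.0, size=(U, k))
        d = np.full(U, -0.2)
        p = plds.PLDSParams(
            A=np.eye(k), Q=np.eye(k), C=C, d=d, x0=np.zeros(k),
            Q0=1e6 * np.eye(k),
        )
        y = rng.poisson(1.0, size=(U, 1))

        def negll(x):
            eta = C @ x + d
            return np.exp(eta).sum() - y[:, 0] @ eta

        mle = minimize(negll, np.zeros(k), method="BFGS").x
        post = plds.laplace_estep(y[:, :1], p)
        assert np.allclose(post.mean[:, 0], mle, atol=1e-3)

    def test_gradient_norm_small_at_mode(self, rng):
        p = random_params(rng)
        _, y = plds.simulate(p, 40, seed=1)
        post = plds.laplace_estep(y, p)
        assert post.grad_norm < 1e-8

    def test_rejects_negative_counts(self, rng):
        p = random_params(rng)
        with pytest.raises(ValueError):
            plds.laplace_estep(-np.ones((5, 3)), p)

    def test_empty_trial_rejected(self, rng):
        p = random_params(rng)
        with pytest.raises(ValueError):
            plds.decode_latents(np.empty((5, 0)), p)


class TestSimilarityInvariance:
    def test_rates_and_evidence_invariant(self, rng):
        p = random_params(rng, k=3, n_units=6)
        _, y = plds.simulate(p, 30, seed=2)
        M = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        Mi = np.linalg.inv(M)
        p2 = plds.PLDSParams(
            A=M @ p.A @ Mi,
            Q=M @ p.Q @ M.T,
            C=p.C @ Mi,
            d=p.d,
            x0=M @ p.x0,
            Q0=M @ p.Q0 @ M.T,
        )
        post1 = plds.laplace_estep(y, p)
        post2 = plds.laplace_estep(y, p2)
        r1 = plds.predicted_rates(p, post1)
        r2 = plds.predicted_rates(p2, post2)
        assert np.allclose(r1, r2, rtol=1e-6)
        assert post1.loglik_approx == pytest.approx(post2.loglik_approx, rel=1e-8)

    def test_scaling_c_vs_scaling_latents(self, rng):
        p = random_params(rng, k=2, n_units=5)
        _, y = plds.simulate(p, 25, seed=9)
        p2 = plds.PLDSParams(
            A=p.A, Q=4.0 * p.Q, C=p.C / 2.0, d=p.d, x0=2.0 * p.x0,
            Q0=4.0 * p.Q0,
        )
        r1 = plds.predicted_rates(p, plds.laplace_estep(y, p))
        r2 = plds.predicted_rates(p2, plds.laplace_estep(y, p2))
        assert np.allclose(r1, r2, rtol=1e-6)


class TestEM:
    def test_latent_dim_zero_rejected(self):
        with pytest.raises(ValueError):
            plds.fit_em([np.zeros((3, 10), dtype=int)] * 3, 0)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            plds.fit_em([np.zeros((3, 10), dtype=int)], 2)

    def test_loglik_nondecreasing_small_fixture(self, rng):
        p = random_params(rng, k=2, n_units=10, stable=0.95)
        trials = [plds.simulate(p, 40, seed=s)[1] for s in range(8)]
        _, diag = plds.fit_em(trials, 2, max_iter=12, tol=0)
        ll = np.array(diag.loglik_trace)
        increments = np.diff(ll)
        assert np.all(increments >= -1e-6 * np.maximum(np.abs(ll[:-1]), 1.0))

    def test_improves_evidence_over_init(self, rng):
        p = random_params(rng, k=2, n_units=8, stable=0.95)
        trials = [plds.simulate(p, 30, seed=s)[1] for s in range(6)]
        _, diag = plds.fit_em(trials, 2, max_iter=10, tol=0)
        assert diag.loglik_trace[-1] > diag.loglik_trace[0]


class TestGaussianEM:
    def test_exact_monotonicity(self, rng):
        k, U = 2, 4
        for trial_seed in range(3):
            r = np.random.default_rng(trial_seed)
            p = gl.GaussianLDSParams(
                A=0.8 * np.linalg.qr(r.standard_normal((k, k)))[0],
                Q=0.1 * np.eye(k), C=r.standard_normal((U, k)),
                d=r.standard_normal(U), r=np.full(U, 0.5),
                x0=np.zeros(k), Q0=np.eye(k),
            )
            trials = []
            for s in range(5):
                rs = np.random.default_rng(100 + s)
                x = np.zeros((k, 30))
                x[:, 0] = p.x0 + np.linalg.cholesky(p.Q0) @ rs.standard_normal(k)
                for t in range(1, 30):
                    x[:, t] = p.A @ x[:, t - 1] + np.linalg.cholesky(p.Q) @ rs.standard_normal(k)
                y = p.C @ x + p.d[:, None] + np.sqrt(p.r)[:, None] * rs.standard_normal((U, 30))
                trials.append(y)
            init = gl.GaussianLDSParams(
                A=0.5 * np.eye(k), Q=np.eye(k), C=np.ones((U, k)),
                d=np.zeros(U), r=np.ones(U), x0=np.zeros(k), Q0=np.eye(k),
            )
            _, diag = gl.fit_em_gaussian(trials, k, init, max_iter=25, tol=0)
            ll = np.array(diag.loglik_trace)
            assert np.all(np.diff(ll) >= -1e-9 * np.maximum(np.abs(ll[:-1]), 1.0))
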