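"""Poisson linear dynamical system (PLDS).

Latent states follow linear-Gaussian dynamics,

    x_1 ~ N(x0, Q0),   x_{t+1} = A x_t + w_t,   w_t ~ N(0, Q),

and spike counts are conditionally Poisson through an exponential link,

    y_t | x_t ~ Poisson(exp(C x_t + d))   per 10 ms bin.

Posterior inference uses a Laplace approximation: Newton's method on the log
joint of the whole latent sequence, whose Hessian is block tridiagonal, so
each iteration costs O(T K^3). Parameter learning is EM with closed-form
updates for (A, Q, x0, Q0) and per-unit Newton ascent for (C, d) on the
expected Poisson log likelihood, using E[exp(c'x)] = exp(c'mu + c'Sigma c / 2).

A Gaussian-observation variant of the same E-step is provided as a test hook;
with Gaussian observations the log joint is quadratic, so the "Laplace"
posterior is exact and must agree with a Kalman smoother.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.random import Generator, default_rng
from scipy.special import gammaln

logger = logging.getLogger(__name__)

_LOG_RATE_CAP = 30.0  # exponent clip guarding exp overflow
_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class PLDSParams:
    """Model parameters. ``Q``/``Q0`` must be symmetric positive definite."""

    A: np.ndarray
    Q: np.ndarray
    C: np.ndarray
    d: np.ndarray
    x0: np.ndarray
    Q0: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.d = np.asarray(self.d, dtype=float).ravel()
        self.x0 = np.asarray(self.x0, dtype=float).ravel()
        self.Q0 = np.atleast_2d(np.asarray(self.Q0, dtype=float))
        k = self.A.shape[0]
        if self.A.shape != (k, k) or self.Q.shape != (k, k) or self.Q0.shape != (k, k):
            raise ValueError("A, Q, Q0 must all be k x k")
        if self.C.shape[1] != k or self.x0.shape != (k,):
            raise ValueError("C and x0 must match the latent dimension")
        if self.C.shape[0] != self.d.shape[0]:
            raise ValueError("C and d must match the unit count")
        for name, M in (("Q", self.Q), ("Q0", self.Q0)):
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(M).min() <= 0:
                raise ValueError(f"{name} must be positive definite")
        rho = np.abs(np.linalg.eigvals(self.A)).max()
        if rho > 1.0 + 1e-6:
            logger.warning("dynamics matrix spectral radius %.4f > 1", rho)

    @property
    def latent_dim(self) -> int:
        return self.A.shape[0]

    @property
    def n_units(self) -> int:
        return self.C.shape[0]


@dataclass
class LatentPosterior:
    """Laplace-approximate posterior over one trial's latent sequence."""

    mean: np.ndarray  # (K, T)
    cov: np.ndarray  # (T, K, K) marginal covariance blocks
    cov_cross: np.ndarray  # (T-1, K, K); Cov(x_t, x_{t+1})
    loglik_approx: float
    n_newton: int = 0
    grad_norm: float = 0.0

    @property
    def latent_dim(self) -> int:
        return self.mean.shape[0]

    @property
    def n_bins(self) -> int:
        return self.mean.shape[1]


class EStepError(RuntimeError):
    """Raised when the Newton inner loop fails to converge."""

    def __init__(self, msg: str, grad_norm: float):
        super().__init__(f"{msg} (last gradient norm {grad_norm:.3e})")
        self.grad_norm = grad_norm


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate(
    params: PLDSParams, n_bins: int, seed: int | Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one latent sequence and conditionally Poisson counts.

    Returns ``(latents, counts)`` with shapes (K, T) and (units, T).
    """
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    k, T = params.latent_dim, int(n_bins)
    if T < 1:
        raise ValueError("n_bins must be >= 1")
    x = np.empty((k, T))
    x[:, 0] = rng.multivariate_normal(params.x0, params.Q0)
    chol_q = np.linalg.cholesky(params.Q)
    for t in range(1, T):
        x[:, t] = params.A @ x[:, t - 1] + chol_q @ rng.standard_normal(k)
    log_rate = params.C @ x + params.d[:, None]
    if log_rate.max() > _LOG_RATE_CAP:
        raise FloatingPointError("simulated log rate exceeds overflow guard")
    counts = rng.poisson(np.exp(log_rate))
    return x, counts


# ---------------------------------------------------------------------------
# block-tridiagonal linear algebra
# ---------------------------------------------------------------------------


def _block_thomas(D, B, rhs, want_cov=False):
    """Solve ``H z = rhs`` for symmetric PD block-tridiagonal H.

    H has diagonal blocks ``D[t]`` and super-diagonal blocks ``B[t]`` (the
    (t, t+1) block). Returns ``(z, logdet)`` and, when ``want_cov``, the
    marginal blocks ``Sigma[t]`` and cross blocks ``Cov(x_t, x_{t+1})`` of
    ``H^{-1}``.
    """
    T, k, _ = D.shape
    # small-block inverses via numpy keep per-step overhead low; the Schur
    # complements are PD whenever H is (always true for the concave log joint)
    lam_inv = np.empty_like(D)
    y = np.empty_like(rhs)
    y[0] = rhs[0]
    lam = D[0]
    logdet = 0.0
    for t in range(T):
        if t > 0:
            g = lam_inv[t - 1] @ B[t - 1]
            lam = D[t] - B[t - 1].T @ g
            y[t] = rhs[t] - g.T @ y[t - 1]
        if want_cov:
            L = np.linalg.cholesky(lam)
            logdet += 2.0 * np.log(np.diag(L)).sum()
        lam_inv[t] = np.linalg.inv(lam)
    z = np.empty_like(rhs)
    z[T - 1] = lam_inv[T - 1] @ y[T - 1]
    for t in range(T - 2, -1, -1):
        z[t] = lam_inv[t] @ (y[t] - B[t] @ z[t + 1])
    if not want_cov:
        return z, logdet, None, None
    sig = np.empty_like(D)
    cross = np.empty((T - 1, k, k)) if T > 1 else np.empty((0, k, k))
    sig[T - 1] = lam_inv[T - 1]
    for t in range(T - 2, -1, -1):
        u = lam_inv[t] @ B[t]
        cross[t] = -u @ sig[t + 1]
        sig[t] = lam_inv[t] + u @ sig[t + 1] @ u.T
        sig[t] = 0.5 * (sig[t] + sig[t].T)
    return z, logdet, sig, cross


# ---------------------------------------------------------------------------
# Laplace E-step
# ---------------------------------------------------------------------------


def _prior_blocks(params: PLDSParams, T: int):
    """Precision blocks of the latent prior and its quadratic form helpers."""
    k = params.latent_dim
    q0i = np.linalg.inv(params.Q0)
    qi = np.linalg.inv(params.Q)
    aqa = params.A.T @ qi @ params.A
    aq = params.A.T @ qi
    D = np.empty((T, k, k))
    for t in range(T):
        D[t] = (q0i if t == 0 else qi) + (aqa if t < T - 1 else 0.0)
    B = np.repeat(-aq[None], max(T - 1, 0), axis=0)
    return D, B, q0i, qi


def _prior_neglog(params, x, q0i, qi):
    """Negative log prior density of a latent path, constants included."""
    T = x.shape[1]
    r0 = x[:, 0] - params.x0
    val = 0.5 * r0 @ q0i @ r0
    if T > 1:
        r = x[:, 1:] - params.A @ x[:, :-1]
        val += 0.5 * np.einsum("it,ij,jt->", r, qi, r)
    k = params.latent_dim
    val += 0.5 * (np.linalg.slogdet(params.Q0)[1] + (T - 1) * np.linalg.slogdet(params.Q)[1])
    val += T * k * _HALF_LOG_2PI
    return val


def laplace_estep(
    counts: np.ndarray,
    params: PLDSParams,
    *,
    observation: str = "poisson",
    obs_var: np.ndarray | float = 1.0,
    max_newton: int = 100,
    grad_tol: float = 1e-8,
    x_init: np.ndarray | None = None,
) -> LatentPosterior:
    """Posterior over one trial's latents under the Laplace approximation.

    The mode of the log joint is found by Newton's method with backtracking;
    the Poisson log joint is concave in the latents, so the block-tridiagonal
    Hessian is positive definite everywhere. Marginal and adjacent-bin cross
    covariances are the corresponding blocks of the inverse Hessian at the
    mode, and ``loglik_approx`` is the Laplace evidence.

    ``observation="gaussian"`` swaps the Poisson term for an independent
    Gaussian likelihood with variances ``obs_var`` (test hook; exact there).
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 2 or y.shape[1] < 1:
        raise ValueError("counts must be (units, T) with T >= 1")
    if observation == "poisson" and ((y < 0).any() or not np.allclose(y, np.round(y))):
        raise ValueError("Poisson observations must be non-negative integers")
    if y.shape[0] != params.n_units:
        raise ValueError("unit count mismatch with params")
    T = y.shape[1]
    k = params.latent_dim
    C, d = params.C, params.d
    if observation == "gaussian":
        r = np.broadcast_to(np.asarray(obs_var, dtype=float), (params.n_units,))
        ri = 1.0 / r
        ctrc = (C * ri[:, None]).T @ C
        obs_const = 0.5 * np.log(r).sum() + params.n_units * _HALF_LOG_2PI
    elif observation != "poisson":
        raise ValueError("observation must be 'poisson' or 'gaussian'")

    Dp, B, q0i, qi = _prior_blocks(params, T)

    def neglog(x):
        eta = np.clip(C @ x + d[:, None], -np.inf, _LOG_RATE_CAP)
        if observation == "poisson":
            obs = (np.exp(eta) - y * eta).sum() + gammaln(y + 1.0).sum()
        else:
            res = y - eta
            obs = 0.5 * np.einsum("ut,u,ut->", res, ri, res) + T * obs_const
        return obs + _prior_neglog(params, x, q0i, qi)

    def grad_and_hessdiag(x):
        eta = np.clip(C @ x + d[:, None], -np.inf, _LOG_RATE_CAP)
        if observation == "poisson":
            lam = np.exp(eta)
            g_obs = C.T @ (lam - y)  # (k, T)
            h_obs = np.einsum("ut,ui,uj->tij", lam, C, C)
        else:
            g_obs = -C.T @ ((y - eta) * ri[:, None])
            h_obs = np.repeat(ctrc[None], T, axis=0)
        g_pr = np.empty((k, T))
        g_pr[:, 0] = q0i @ (x[:, 0] - params.x0)
        if T > 1:
            r_ = x[:, 1:] - params.A @ x[:, :-1]
            qr = qi @ r_
            g_pr[:, 1:] = qr
            g_pr[:, :-1] -= params.A.T @ qr
        return (g_obs + g_pr).T, h_obs + Dp  # grad (T,k), diag blocks (T,k,k)

    if x_init is not None:
        x = np.array(x_init, dtype=float)
    else:
        x = np.empty((k, T))
        x[:, 0] = params.x0
        for t in range(1, T):
            x[:, t] = params.A @ x[:, t - 1]

    f = neglog(x)
    gnorm = np.inf
    for it in range(max_newton):
        grad, D = grad_and_hessdiag(x)
        gnorm = float(np.abs(grad).max())
        if gnorm < grad_tol:
            break
        step, _, _, _ = _block_thomas(D, B, -grad)
        alpha = 1.0
        decrement = float((grad * step).sum())  # negative for a descent step
        for _ in range(40):
            x_new = x + alpha * step.T
            f_new = neglog(x_new)
            if f_new <= f + 1e-4 * alpha * decrement or alpha < 1e-12:
                break
            alpha *= 0.5
        if f_new > f + 1e-10 and alpha < 1e-12:
            raise EStepError("Newton line search failed", gnorm)
        x, f = x_new, f_new
    else:
        grad, D = grad_and_hessdiag(x)
        gnorm = float(np.abs(grad).max())
        if gnorm > max(grad_tol * 1e4, 1e-4):
            raise EStepError("Newton did not converge", gnorm)

    grad, D = grad_and_hessdiag(x)
    _, logdet, sig, cross = _block_thomas(D, B, -grad, want_cov=True)
    loglik = -f + T * k * _HALF_LOG_2PI - 0.5 * logdet
    return LatentPosterior(
        mean=x, cov=sig, cov_cross=cross, loglik_approx=float(loglik),
        n_newton=it + 1, grad_norm=gnorm,
    )


def decode_latents(counts: np.ndarray, params: PLDSParams, **kw) -> LatentPosterior:
    """Posterior-mean latent trajectory for a novel trial.

    Identical computation to :func:`laplace_estep` (fixed-interval smoothing
    over the trial); the returned mean is the latent feature time series.
    """
    counts = np.asarray(counts)
    if counts.size == 0 or counts.shape[-1] == 0:
        raise ValueError("empty trial")
    return laplace_estep(counts, params, **kw)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


@dataclass
class FitDiagnostics:
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    messages: list[str] = field(default_factory=list)


def _smooth_sqrt(counts: np.ndarray, width: int = 5) -> np.ndarray:
    """Square-root transform + boxcar smoothing (variance stabilising)."""
    x = np.sqrt(counts.astype(float))
    kernel = np.ones(width) / width
    return np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, x)


def init_params(
    trial_counts: list[np.ndarray], latent_dim: int, seed: int = 0
) -> PLDSParams:
    """PCA-based initialisation on smoothed square-root counts.

    C and d come from the top principal subspace of the z-scored transformed
    counts; A from least-squares regression of successive projected states;
    Q from the regression residuals.
    """
    rng = default_rng(seed)
    y = np.concatenate(trial_counts, axis=1)
    s = _smooth_sqrt(y)
    mu = s.mean(axis=1)
    sd = s.std(axis=1)
    sd[sd == 0] = 1.0
    z = (s - mu[:, None]) / sd[:, None]
    cov = np.cov(z)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][: min(latent_dim, z.shape[0])]
    W = evecs[:, order]  # (units, <=k)
    if W.shape[1] < latent_dim:
        # more latent dims than units: pad with random orthonormal directions
        extra = rng.standard_normal((z.shape[0], latent_dim - W.shape[1]))
        extra -= W @ (W.T @ extra)
        extra, _ = np.linalg.qr(extra)
        W = np.hstack([W, extra[:, : latent_dim - W.shape[1]]])
    lat = W.T @ z  # projected states
    scale = lat.std(axis=1)
    scale[scale == 0] = 1.0
    lat = lat / scale[:, None]
    # per-trial regression of successive states
    X0, X1 = [], []
    offset = 0
    starts = []
    for c in trial_counts:
        T = c.shape[1]
        seg = lat[:, offset : offset + T]
        X0.append(seg[:, :-1])
        X1.append(seg[:, 1:])
        starts.append(seg[:, 0])
        offset += T
    X0 = np.concatenate(X0, axis=1)
    X1 = np.concatenate(X1, axis=1)
    A = (X1 @ X0.T) @ np.linalg.pinv(X0 @ X0.T)
    rho = np.abs(np.linalg.eigvals(A)).max()
    if rho > 0.999:
        A *= 0.999 / rho
    resid = X1 - A @ X0
    Q = np.cov(resid) + 1e-4 * np.eye(latent_dim)
    Q = 0.5 * (Q + Q.T)
    mean_rate = y.mean(axis=1)
    C = W * sd[:, None] * 0.5  # modest scale; refined by the M-step
    C = C * scale[None, :]
    lat_var = np.einsum("ui,ij,uj->u", C, np.cov(lat), C)
    d = np.log(np.maximum(mean_rate, 1.0 / y.shape[1])) - 0.5 * lat_var
    x0 = np.mean(starts, axis=0)
    Q0 = np.cov(np.array(starts).T) if len(starts) > 1 else np.eye(latent_dim)
    Q0 = 0.5 * (Q0 + Q0.T) + 1e-3 * np.eye(latent_dim)
    return PLDSParams(A=A, Q=Q, C=C, d=d, x0=x0, Q0=Q0)


def _mstep_loading(posteriors, trial_counts, C, d, n_newton=3):
    """Per-unit Newton ascent of the expected Poisson log likelihood."""
    k = C.shape[1]
    mus = np.concatenate([p.mean for p in posteriors], axis=1)  # (k, T_tot)
    sigs = np.concatenate([p.cov for p in posteriors], axis=0)  # (T_tot, k, k)
    ys = np.concatenate(trial_counts, axis=1).astype(float)
    m_aug = np.vstack([mus, np.ones(mus.shape[1])])  # (k+1, T)
    T_tot = mus.shape[1]
    for u in range(C.shape[0]):
        a = np.concatenate([C[u], [d[u]]])
        for _ in range(n_newton):
            sa = np.einsum("tij,j->ti", sigs, a[:k])  # Sigma_t c
            eta = a @ m_aug + 0.5 * np.einsum("ti,i->t", sa, a[:k])
            eta = np.clip(eta, -_LOG_RATE_CAP, _LOG_RATE_CAP)
            lam = np.exp(eta)
            w = m_aug.copy()
            w[:k] += sa.T  # m_t + Sigma_t c (augmented)
            grad = ys[u] @ m_aug.T - lam @ w.T
            hess = -np.einsum("t,it,jt->ij", lam, w, w)
            hess[:k, :k] -= np.einsum("t,tij->ij", lam, sigs)
            try:
                step = np.linalg.solve(hess - 1e-9 * np.eye(k + 1), grad)
            except np.linalg.LinAlgError:
                break
            a_new = a - step
            if not np.isfinite(a_new).all():
                break
            a = a_new
            if np.abs(step).max() < 1e-10:
                break
        C[u] = a[:k]
        d[u] = a[k]
    return C, d


def fit_em(
    trial_counts: list[np.ndarray],
    latent_dim: int,
    *,
    init_seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    init: PLDSParams | None = None,
    estep_kw: dict | None = None,
) -> tuple[PLDSParams, FitDiagnostics]:
    """Laplace-EM parameter learning over a set of independent trials.

    Trials of unequal length are independent sequences sharing parameters,
    each restarting from ``(x0, Q0)``. Stops when the relative change of the
    summed Laplace evidence falls below ``tol`` or after ``max_iter``
    iterations; the per-iteration evidence trace is returned.
    """
    if latent_dim < 1:
        raise ValueError("latent_dim must be >= 1")
    trial_counts = [np.asarray(c) for c in trial_counts]
    if len(trial_counts) < 2:
        raise ValueError("need at least two trials")
    estep_kw = dict(estep_kw or {})
    params = init if init is not None else init_params(trial_counts, latent_dim, init_seed)
    diag = FitDiagnostics()
    k = latent_dim
    warm: list[np.ndarray | None] = [None] * len(trial_counts)
    prev_ll = -np.inf
    for it in range(max_iter):
        posteriors = []
        total_ll = 0.0
        for i, y in enumerate(trial_counts):
            post = laplace_estep(y, params, x_init=warm[i], **estep_kw)
            warm[i] = post.mean
            posteriors.append(post)
            total_ll += post.loglik_approx
        diag.loglik_trace.append(total_ll)

        # --- closed-form dynamics updates from posterior moments
        s00 = np.zeros((k, k))
        s10 = np.zeros((k, k))
        s11 = np.zeros((k, k))
        n_pairs = 0
        firsts = []
        first_covs = []
        for post in posteriors:
            mu, sig, cross = post.mean, post.cov, post.cov_cross
            T = post.n_bins
            firsts.append(mu[:, 0])
            first_covs.append(sig[0])
            if T < 2:
                continue
            exx = sig + np.einsum("it,jt->tij", mu, mu)  # E[x_t x_t']
            # E[x_{t+1} x_t'] = cross_t' + mu_{t+1} mu_t'
            ex1x = np.transpose(cross, (0, 2, 1)) + np.einsum(
                "it,jt->tij", mu[:, 1:], mu[:, :-1]
            )
            s00 += exx[:-1].sum(axis=0)
            s11 += exx[1:].sum(axis=0)
            s10 += ex1x.sum(axis=0)
            n_pairs += T - 1
        A = np.linalg.solve(s00.T, s10.T).T
        Q = (s11 - A @ s10.T - s10 @ A.T + A @ s00 @ A.T) / n_pairs
        Q = 0.5 * (Q + Q.T)
        emin = np.linalg.eigvalsh(Q).min()
        if emin <= 1e-10:
            Q += (1e-8 - min(emin, 0.0)) * np.eye(k)
            diag.messages.append(f"iter {it}: Q jitter-repaired")
        x0 = np.mean(firsts, axis=0)
        dev = np.array(firsts) - x0
        Q0 = np.mean(first_covs, axis=0) + dev.T @ dev / len(firsts)
        Q0 = 0.5 * (Q0 + Q0.T)
        emin = np.linalg.eigvalsh(Q0).min()
        if emin <= 1e-10:
            Q0 += (1e-8 - min(emin, 0.0)) * np.eye(k)
            diag.messages.append(f"iter {it}: Q0 jitter-repaired")

        C, d = _mstep_loading(posteriors, trial_counts, params.C.copy(), params.d.copy())
        params = PLDSParams(A=A, Q=Q, C=C, d=d, x0=x0, Q0=Q0)

        if it > 0:
            rel = (total_ll - prev_ll) / max(abs(prev_ll), 1.0)
            if abs(rel) < tol:
                diag.converged = True
                diag.n_iter = it + 1
                break
        prev_ll = total_ll
    diag.n_iter = diag.n_iter or max_iter
    logger.info(
        "EM finished after %d iterations (converged=%s)", diag.n_iter, diag.converged
    )
    return params, diag


def predicted_rates(params: PLDSParams, posterior: LatentPosterior) -> np.ndarray:
    """Posterior-mean firing rates exp(C mu + d), spikes per bin."""
    eta = np.clip(params.C @ posterior.mean + params.d[:, None], None, _LOG_RATE_CAP)
    return np.exp(eta)
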