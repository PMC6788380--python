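"""Gaussian-observation linear dynamical system: Kalman smoother + exact EM.

Same state model as :mod:`gaitdyn.plds` but with observations
``y_t = C x_t + d + v_t``, ``v_t ~ N(0, diag(r))``. Inference here is exact,
which makes this module the reference implementation against which the
Laplace machinery is validated, and gives an exactly monotone EM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class GaussianLDSParams:
    A: np.ndarray
    Q: np.ndarray
    C: np.ndarray
    d: np.ndarray
    r: np.ndarray  # per-unit observation variances
    x0: np.ndarray
    Q0: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, float))
        self.Q = np.atleast_2d(np.asarray(self.Q, float))
        self.C = np.atleast_2d(np.asarray(self.C, float))
        self.d = np.asarray(self.d, float).ravel()
        self.r = np.asarray(self.r, float).ravel()
        self.x0 = np.asarray(self.x0, float).ravel()
        self.Q0 = np.atleast_2d(np.asarray(self.Q0, float))
        if (self.r <= 0).any():
            raise ValueError("observation variances must be positive")

    @property
    def latent_dim(self) -> int:
        return self.A.shape[0]


@dataclass
class SmootherResult:
    mean: np.ndarray  # (K, T)
    cov: np.ndarray  # (T, K, K)
    cov_cross: np.ndarray  # (T-1, K, K); Cov(x_t, x_{t+1})
    loglik: float


def kalman_smoother(y: np.ndarray, p: GaussianLDSParams) -> SmootherResult:
    """Fixed-interval RTS smoother with exact log marginal likelihood."""
    y = np.asarray(y, float)
    n_units, T = y.shape
    k = p.latent_dim
    R = np.diag(p.r)
    # filter
    mf = np.empty((T, k))
    pf = np.empty((T, k, k))
    mp = np.empty((T, k))
    pp = np.empty((T, k, k))
    ll = 0.0
    for t in range(T):
        if t == 0:
            mp[t] = p.x0
            pp[t] = p.Q0
        else:
            mp[t] = p.A @ mf[t - 1]
            pp[t] = p.A @ pf[t - 1] @ p.A.T + p.Q
        innov = y[:, t] - (p.C @ mp[t] + p.d)
        s = p.C @ pp[t] @ p.C.T + R
        s = 0.5 * (s + s.T)
        cs = np.linalg.cholesky(s)
        alpha = np.linalg.solve(cs, innov)
        ll -= 0.5 * alpha @ alpha + np.log(np.diag(cs)).sum() + n_units * _HALF_LOG_2PI
        gain = pp[t] @ np.linalg.solve(s, p.C).T  # K_t
        mf[t] = mp[t] + gain @ innov
        pf[t] = pp[t] - gain @ s @ gain.T
        pf[t] = 0.5 * (pf[t] + pf[t].T)
    # RTS smoother
    ms = np.empty((T, k))
    ps = np.empty((T, k, k))
    cross = np.empty((max(T - 1, 0), k, k))
    ms[T - 1] = mf[T - 1]
    ps[T - 1] = pf[T - 1]
    for t in range(T - 2, -1, -1):
        j = pf[t] @ np.linalg.solve(pp[t + 1], p.A).T  # smoother gain J_t
        ms[t] = mf[t] + j @ (ms[t + 1] - mp[t + 1])
        ps[t] = pf[t] + j @ (ps[t + 1] - pp[t + 1]) @ j.T
        ps[t] = 0.5 * (ps[t] + ps[t].T)
        cross[t] = j @ ps[t + 1]  # Cov(x_t, x_{t+1})
    return SmootherResult(mean=ms.T, cov=ps, cov_cross=cross, loglik=float(ll))


@dataclass
class GaussianEMDiagnostics:
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def fit_em_gaussian(
    trials: list[np.ndarray],
    latent_dim: int,
    init: GaussianLDSParams,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[GaussianLDSParams, GaussianEMDiagnostics]:
    """Exact EM for the Gaussian LDS; the log likelihood never decreases."""
    p = init
    k = latent_dim
    diag = GaussianEMDiagnostics()
    prev = -np.inf
    for it in range(max_iter):
        total_ll = 0.0
        s00 = np.zeros((k, k))
        s10 = np.zeros((k, k))
        s11 = np.zeros((k, k))
        n_pairs = 0
        firsts, first_covs = [], []
        sxx = np.zeros((k, k))
        sxy = np.zeros((k, p.C.shape[0]))
        sy = np.zeros(p.C.shape[0])
        sm = np.zeros(k)
        syy = np.zeros(p.C.shape[0])
        n_obs = 0
        for y in trials:
            res = kalman_smoother(y, p)
            total_ll += res.loglik
            mu, sig, cross = res.mean, res.cov, res.cov_cross
            T = mu.shape[1]
            exx = sig + np.einsum("it,jt->tij", mu, mu)
            firsts.append(mu[:, 0])
            first_covs.append(sig[0])
            if T > 1:
                ex1x = np.transpose(cross, (0, 2, 1)) + np.einsum(
                    "it,jt->tij", mu[:, 1:], mu[:, :-1]
                )
                s00 += exx[:-1].sum(axis=0)
                s11 += exx[1:].sum(axis=0)
                s10 += ex1x.sum(axis=0)
                n_pairs += T - 1
            sxx += exx.sum(axis=0)
            sxy += mu @ y.T
            sy += y.sum(axis=1)
            sm += mu.sum(axis=1)
            syy += (y**2).sum(axis=1)
            n_obs += T
        diag.loglik_trace.append(total_ll)
        A = np.linalg.solve(s00.T, s10.T).T
        Q = (s11 - A @ s10.T - s10 @ A.T + A @ s00 @ A.T) / n_pairs
        Q = 0.5 * (Q + Q.T) + 1e-10 * np.eye(k)
        x0 = np.mean(firsts, axis=0)
        dev = np.array(firsts) - x0
        Q0 = np.mean(first_covs, axis=0) + dev.T @ dev / len(firsts)
        Q0 = 0.5 * (Q0 + Q0.T) + 1e-10 * np.eye(k)
        # joint (C, d) regression on augmented moments
        G = np.zeros((k + 1, k + 1))
        G[:k, :k] = sxx
        G[:k, k] = sm
        G[k, :k] = sm
        G[k, k] = n_obs
        H = np.vstack([sxy, sy])
        sol = np.linalg.solve(G, H)  # (k+1, units)
        C = sol[:k].T
        d = sol[k]
        r = (syy - np.einsum("iu,iu->u", H, sol)) / n_obs
        r = np.maximum(r, 1e-10)
        p = GaussianLDSParams(A=A, Q=Q, C=C, d=d, r=r, x0=x0, Q0=Q0)
        if it > 0 and abs(total_ll - prev) / max(abs(prev), 1.0) < tol:
            diag.converged = True
            diag.n_iter = it + 1
            break
        prev = total_ll
    diag.n_iter = diag.n_iter or max_iter
    return p, diag
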