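"""Comparison feature extractors: PCA projection and predictive subsampling.

PCA operates on z-scored firing rates concatenated across trials; the
projection stacks the eigenvectors of the training covariance with the
largest eigenvalues. Predictive subsampling (PSS) greedily grows a neuron
subset, at each step adding the unit that maximises the mean validation R2
of the downstream lagged linear decoder on an inner split of the training
folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.random import default_rng

from . import preprocess as pp

logger = logging.getLogger(__name__)


@dataclass
class ProjectionMatrix:
    W: np.ndarray  # (n_components, n_units), orthonormal rows
    fit_means: np.ndarray
    fit_sds: np.ndarray
    n_components: int
    eigenvalues: np.ndarray | None = None
    fit_tag: tuple = field(default_factory=tuple)


@dataclass
class SubsetSelection:
    chosen_units: list[int]
    criterion_trace: list[float]
    fit_tag: tuple = field(default_factory=tuple)


def fit_pca(
    rates: pp.FiringRateMatrix, n_components: int, fit_tag: tuple = ()
) -> ProjectionMatrix:
    """Eigendecomposition of the covariance of z-scored training rates.

    Rows of W are the top eigenvectors ordered by descending eigenvalue; the
    sign of each is fixed so its largest-magnitude element is positive.
    """
    x = rates.rates
    if n_components < 1 or n_components > x.shape[0]:
        raise ValueError("n_components must be in [1, n_units]")
    mean = x.mean(axis=1)
    sd = x.std(axis=1)
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (x - mean[:, None]) / safe_sd[:, None]
    z[sd == 0, :] = 0.0
    cov = np.cov(z, bias=True)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    rank = int(np.linalg.matrix_rank(cov))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds covariance rank {rank}")
    W = evecs[:, order[:n_components]].T
    for i in range(W.shape[0]):  # deterministic sign convention
        j = np.argmax(np.abs(W[i]))
        if W[i, j] < 0:
            W[i] = -W[i]
    return ProjectionMatrix(
        W=W, fit_means=mean, fit_sds=sd, n_components=n_components,
        eigenvalues=evals[order][:n_components], fit_tag=tuple(fit_tag),
    )


def project(rates: pp.FiringRateMatrix, proj: ProjectionMatrix) -> np.ndarray:
    """Z-score with the fit constants and project: (n_components, bins)."""
    x = rates.rates
    if x.shape[0] != proj.fit_means.shape[0]:
        raise ValueError("unit-count mismatch with fitted projection")
    sd = np.where(proj.fit_sds == 0, 1.0, proj.fit_sds)
    z = (x - proj.fit_means[:, None]) / sd[:, None]
    z[proj.fit_sds == 0, :] = 0.0
    return proj.W @ z


# ---------------------------------------------------------------------------
# predictive subsampling
# ---------------------------------------------------------------------------


def evaluate_subset(
    session,
    inner_train_ids: list[int],
    inner_val_ids: list[int],
    subset: list[int],
    targets,
    order: int = 10,
    rates: pp.FiringRateMatrix | None = None,
) -> float:
    """PSS criterion: mean validation R2 (averaged over target variables and
    validation trials) of the lagged decoder trained on ``subset``."""
    from . import wiener

    trials = session.trials
    if rates is None:
        rates = pp.estimate_rates(session.counts)
    sub = rates.rates[list(subset), :]
    train_bins = np.concatenate([trials[i].bins() for i in inner_train_ids])
    mean = sub[:, train_bins].mean(axis=1)
    sd = sub[:, train_bins].std(axis=1)
    sd_safe = np.where(sd == 0, 1.0, sd)
    feats = ((sub - mean[:, None]) / sd_safe[:, None]).T
    feats[:, sd == 0] = 0.0

    kin_cols = [c for c in targets.columns if c != "gait_phase"]
    Y_kin = targets[kin_cols].to_numpy()
    Y_phase = targets[["gait_phase"]].to_numpy()
    D, valid = wiener.lagged_design(feats, order)
    train_mask = np.zeros(len(valid), bool)
    for i in inner_train_ids:
        train_mask[trials[i].start : trials[i].stop] = True
    A = np.hstack([D, np.ones((len(D), 1))])
    kin_mask = train_mask & valid & np.isfinite(Y_kin).all(axis=1)
    phase_mask = train_mask & valid
    sol_kin = (
        np.linalg.lstsq(A[kin_mask], Y_kin[kin_mask], rcond=None)[0]
        if kin_mask.any() else None
    )
    sol_phase = np.linalg.lstsq(A[phase_mask], Y_phase[phase_mask], rcond=None)[0]
    scores = []
    import warnings as _w

    for i in inner_val_ids:
        tr = trials[i]
        sl = slice(tr.start, tr.stop)
        m = valid[sl]
        if m.sum() < 2:
            continue
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            if tr.has_kinematics and sol_kin is not None:
                r2 = wiener.score_r2(Y_kin[sl][m], (A[sl][m]) @ sol_kin)
                scores.extend(r2[np.isfinite(r2)])
            r2p = wiener.score_r2(Y_phase[sl][m], (A[sl][m]) @ sol_phase)
            scores.extend(r2p[np.isfinite(r2p)])
    return float(np.mean(scores)) if scores else -np.inf


def fit_pss(
    session,
    train_ids: list[int],
    n: int,
    *,
    seed: int = 0,
    targets=None,
    val_fraction: float = 0.2,
    order: int = 10,
    early_stop: bool = False,
) -> SubsetSelection:
    """Greedy forward selection of ``n`` units.

    The training trials are split (seeded) into an inner training set and a
    validation set of ``val_fraction``; at each step the unit whose addition
    maximises the criterion is added, ties broken by lowest unit index. With
    ``early_stop``, selection halts once no candidate improves the criterion.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    n_units = session.counts.n_units
    if n > n_units:
        raise ValueError("n exceeds the number of units")
    if targets is None:
        from . import wiener

        targets = wiener.build_targets(session)
    rng = default_rng(seed)
    shuffled = list(rng.permutation(list(train_ids)))
    n_val = max(1, int(round(val_fraction * len(shuffled))))
    inner_val = sorted(int(i) for i in shuffled[:n_val])
    inner_train = sorted(int(i) for i in shuffled[n_val:])

    rates = pp.estimate_rates(session.counts)
    chosen: list[int] = []
    trace: list[float] = []
    remaining = list(range(n_units))
    while len(chosen) < n:
        best_unit, best_score = None, -np.inf
        for u in remaining:
            score = evaluate_subset(
                session, inner_train, inner_val, chosen + [u], targets, order,
                rates=rates,
            )
            if score > best_score:  # strict: ties keep the lowest index
                best_unit, best_score = u, score
        if early_stop and trace and best_score < trace[-1]:
            logger.info("PSS early stop at %d units", len(chosen))
            break
        chosen.append(best_unit)
        remaining.remove(best_unit)
        trace.append(best_score)
    return SubsetSelection(
        chosen_units=chosen, criterion_trace=trace, fit_tag=tuple(train_ids)
    )
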