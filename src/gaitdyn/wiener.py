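"""Wiener-filter decoding and its cross-validation harness.

The decoder maps a window of the current and nine preceding 10 ms feature
samples to each target variable,

    y_hat[t] = intercept + sum_{n=0..9} A_n X[t - n],

with coefficients solved by least squares on the training folds. Accuracy is
the per-trial coefficient of determination

    R2 = 1 - sum_i (y_i - y_hat_i)^2 / sum_i (y_i - ybar)^2,

where ybar is the trial mean; R2 is unbounded below.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import default_rng

from . import preprocess as pp
from . import plds as plds_mod
from . import reducers

logger = logging.getLogger(__name__)

DEFAULT_ORDER = 10


@dataclass
class WienerFilter:
    """Lagged linear decoder; ``coefficients[n]`` maps X[t-n] to the targets."""

    coefficients: np.ndarray  # (order, n_features, n_targets)
    intercept: np.ndarray  # (n_targets,)
    order: int = DEFAULT_ORDER
    fitted: bool = False
    train_tag: tuple = field(default_factory=tuple)


def lagged_design(X: np.ndarray, order: int = DEFAULT_ORDER,
                  segments: list[tuple[int, int]] | None = None):
    """Stack lags 0..order-1 of ``X`` (T, p) into a (T, p*order) design.

    ``segments`` are half-open contiguous spans; lags never cross a segment
    boundary (missing history is zero-padded). The returned boolean mask
    marks rows with a complete in-segment history.
    """
    T, p = X.shape
    if segments is None:
        segments = [(0, T)]
    D = np.zeros((T, p * order))
    valid = np.zeros(T, dtype=bool)
    for s0, s1 in segments:
        seg = X[s0:s1]
        n = s1 - s0
        for lag in range(order):
            D[s0 + lag : s1, lag * p : (lag + 1) * p] = seg[: n - lag]
        if n >= order:
            valid[s0 + order - 1 : s1] = True
    return D, valid


def fit_wiener(
    X: np.ndarray,
    Y: np.ndarray,
    order: int = DEFAULT_ORDER,
    *,
    segments: list[tuple[int, int]] | None = None,
    sample_mask: np.ndarray | None = None,
    train_tag: tuple = (),
) -> WienerFilter:
    """Least-squares fit of the lagged decoder (minimum-norm if deficient)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    D, valid = lagged_design(X, order, segments)
    mask = valid if sample_mask is None else (valid & sample_mask)
    A = np.hstack([D[mask], np.ones((mask.sum(), 1))])
    sol, _, rank, _ = np.linalg.lstsq(A, Y[mask], rcond=None)
    if rank < A.shape[1]:
        warnings.warn("rank-deficient design; minimum-norm solution returned")
    p = X.shape[1]
    coef = sol[:-1].reshape(order, p, Y.shape[1])
    return WienerFilter(
        coefficients=coef, intercept=sol[-1], order=order, fitted=True,
        train_tag=tuple(train_tag),
    )


def predict(
    filt: WienerFilter,
    X: np.ndarray,
    segments: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Apply the fitted decoder; rows without full history use zero padding."""
    if not filt.fitted:
        raise ValueError("filter is not fitted")
    X = np.asarray(X, float)
    order, p, n_targets = filt.coefficients.shape
    if X.shape[1] != p:
        raise ValueError("feature-count mismatch")
    D, _ = lagged_design(X, order, segments)
    return D @ filt.coefficients.reshape(order * p, n_targets) + filt.intercept


def score_r2(y_true: np.ndarray, y_est: np.ndarray) -> np.ndarray:
    """Per-variable coefficient of determination for one trial.

    The reference mean is the trial mean of the true signal. Variables with
    a constant true signal are undefined (returned as NaN with a warning).
    """
    y_true = np.asarray(y_true, float)
    y_est = np.asarray(y_est, float)
    if y_true.ndim == 1:
        y_true = y_true[:, None]
        y_est = y_est[:, None]
    if y_true.shape != y_est.shape:
        raise ValueError("shape mismatch between true and estimated signals")
    if y_true.shape[0] < 2:
        raise ValueError("need at least two samples per trial")
    ss_res = ((y_true - y_est) ** 2).sum(axis=0)
    ss_tot = ((y_true - y_true.mean(axis=0)) ** 2).sum(axis=0)
    out = np.full(y_true.shape[1], np.nan)
    ok = ss_tot > 0
    if not ok.all():
        warnings.warn("constant true signal; R2 undefined for some variables")
    out[ok] = 1.0 - ss_res[ok] / ss_tot[ok]
    return out


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class DecoderSpec:
    """Which feature stage feeds the decoder."""

    method: str  # 'fp' | 'pca' | 'pss' | 'plds'
    dims: int | None = None
    plds_kw: dict = field(default_factory=dict)
    pss_kw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("fp", "pca", "pss", "plds"):
            raise ValueError(f"unknown decoder method {self.method!r}")
        if self.method != "fp" and not self.dims:
            raise ValueError(f"method {self.method!r} requires dims")


@dataclass
class CVFoldResult:
    fold: int
    trial_scores: pd.DataFrame  # rows: trial index; columns: variables
    n_trials: int
    n_kinematic_trials: int
    train_trial_ids: tuple
    heldout_loglik: float | None = None
    predictions: dict | None = None  # trial id -> DataFrame of decoded targets

    @property
    def mean_r2(self) -> pd.Series:
        return self.trial_scores.mean(axis=0, skipna=True)


def build_targets(session) -> pd.DataFrame:
    """Decoding targets: derived kinematic variables plus gait phase.

    Kinematic columns are NaN on trials without kinematics; ``gait_phase``
    covers every trial.
    """
    kin = pp.derive_kinematics(session.kinematics)
    kin = kin.drop(columns=["degenerate"])
    phase = pp.gait_phase_track(session.trials, session.counts.n_bins)
    kin["gait_phase"] = phase
    return kin


def partition_folds(n_trials: int, folds: int, seed: int) -> list[np.ndarray]:
    """Shuffle trials and split into ``folds`` blocks with sizes differing by
    at most one; remainder trials go to the earliest folds."""
    if n_trials < folds:
        raise ValueError("need at least as many trials as folds")
    order = default_rng(seed).permutation(n_trials)
    base, extra = divmod(n_trials, folds)
    blocks, at = [], 0
    for f in range(folds):
        size = base + (1 if f < extra else 0)
        blocks.append(np.sort(order[at : at + size]))
        at += size
    return blocks


def _fit_features(session, spec: DecoderSpec, train_ids, seed: int):
    """Fit the feature stage on training trials only; return the full-session
    feature matrix (T, p) and the lag-segmentation to use."""
    counts = session.counts
    trials = session.trials
    T = counts.n_bins
    train_bins = np.concatenate([trials[i].bins() for i in train_ids])
    heldout_ll = None

    if spec.method == "plds":
        train_counts = [counts.counts[:, trials[i].start : trials[i].stop] for i in train_ids]
        params, _ = plds_mod.fit_em(train_counts, spec.dims, **spec.plds_kw)
        feats = np.zeros((T, spec.dims))
        heldout_ll = 0.0
        test_ids = set(range(len(trials))) - set(train_ids)
        for i, tr in enumerate(trials):
            post = plds_mod.decode_latents(
                counts.counts[:, tr.start : tr.stop], params
            )
            feats[tr.start : tr.stop] = post.mean.T
            if i in test_ids:
                heldout_ll += post.loglik_approx
        segments = [(tr.start, tr.stop) for tr in trials]
        return feats, segments, heldout_ll

    rates = pp.estimate_rates(counts)
    train_rates = pp.FiringRateMatrix(rates.rates[:, train_bins])
    segments = [(0, T)]
    if spec.method == "fp":
        stats = pp.fit_zscore(train_rates, fit_tag=tuple(train_ids))
        feats = pp.zscore(rates, stats).rates.T
    elif spec.method == "pca":
        proj = reducers.fit_pca(train_rates, spec.dims, fit_tag=tuple(train_ids))
        feats = reducers.project(rates, proj).T
    else:  # pss
        targets = build_targets(session)
        sel = reducers.fit_pss(
            session, list(train_ids), spec.dims, seed=seed,
            targets=targets, **spec.pss_kw,
        )
        sub = pp.FiringRateMatrix(rates.rates[sel.chosen_units, :])
        sub_train = pp.FiringRateMatrix(train_rates.rates[sel.chosen_units, :])
        stats = pp.fit_zscore(sub_train, fit_tag=tuple(train_ids))
        feats = pp.zscore(sub, stats).rates.T
    return feats, segments, heldout_ll


def run_cv(
    session,
    spec: DecoderSpec,
    folds: int = 10,
    seed: int = 0,
    order: int = DEFAULT_ORDER,
    targets: pd.DataFrame | None = None,
    return_predictions: bool = False,
) -> list[CVFoldResult]:
    """10-fold cross-validated decoding of one session.

    Trials of all tasks are shuffled together and partitioned; per fold the
    feature stage and decoder are fitted on the nine training blocks and
    scored on the held-out block. Kinematic variables are scored only on
    trials with kinematics; gait phase on all trials. Rows without a full
    lag history (inside their contiguous segment) are excluded from both
    fitting and scoring.
    """
    trials = session.trials
    if targets is None:
        targets = build_targets(session)
    kin_cols = [c for c in targets.columns if c != "gait_phase"]
    Y_kin = targets[kin_cols].to_numpy()
    Y_phase = targets[["gait_phase"]].to_numpy()
    blocks = partition_folds(len(trials), folds, seed)
    results = []
    for fold, test_ids in enumerate(blocks):
        test_set = set(int(i) for i in test_ids)
        train_ids = tuple(i for i in range(len(trials)) if i not in test_set)
        assert test_set.isdisjoint(train_ids)
        feats, segments, heldout_ll = _fit_features(session, spec, train_ids, seed)
        D, valid = lagged_design(feats, order, segments)

        train_mask = np.zeros(len(valid), bool)
        for i in train_ids:
            train_mask[trials[i].start : trials[i].stop] = True
        kin_mask = train_mask & valid & np.isfinite(Y_kin).all(axis=1)
        phase_mask = train_mask & valid

        A = np.hstack([D, np.ones((len(D), 1))])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol_kin = np.linalg.lstsq(A[kin_mask], Y_kin[kin_mask], rcond=None)[0] \
                if kin_mask.any() else None
            sol_phase = np.linalg.lstsq(A[phase_mask], Y_phase[phase_mask], rcond=None)[0]
        pred_kin = A @ sol_kin if sol_kin is not None else None
        pred_phase = A @ sol_phase

        rows = {}
        preds = {} if return_predictions else None
        n_kin = 0
        for i in test_ids:
            tr = trials[int(i)]
            m = valid[tr.start : tr.stop]
            if m.sum() < 2:
                continue
            sl = slice(tr.start, tr.stop)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores = {}
                if tr.has_kinematics and pred_kin is not None:
                    r2 = score_r2(Y_kin[sl][m], pred_kin[sl][m])
                    scores.update(dict(zip(kin_cols, r2)))
                    n_kin += 1
                scores["gait_phase"] = score_r2(Y_phase[sl][m], pred_phase[sl][m])[0]
            rows[int(i)] = scores
            if return_predictions:
                cols = {"gait_phase": pred_phase[sl][m][:, 0]}
                if pred_kin is not None:
                    cols.update(dict(zip(kin_cols, pred_kin[sl][m].T)))
                preds[int(i)] = pd.DataFrame(cols)
        if n_kin == 0:
            logger.info("fold %d has no kinematic trials", fold)
        results.append(
            CVFoldResult(
                fold=fold,
                trial_scores=pd.DataFrame.from_dict(rows, orient="index"),
                n_trials=len(test_ids),
                n_kinematic_trials=n_kin,
                train_trial_ids=train_ids,
                heldout_loglik=heldout_ll,
                predictions=preds,
            )
        )
    return results


def session_mean_r2(results: list[CVFoldResult]) -> pd.Series:
    """Session-level mean per-trial R2 across all test folds."""
    all_scores = pd.concat([r.trial_scores for r in results])
    return all_scores.mean(axis=0, skipna=True)


@dataclass
class DimSweepResult:
    dims: list[int]
    mean_r2: list[float]
    per_dim: pd.DataFrame  # rows: dims, columns: variables
    loglik: list[float] | None
    plateau_dim: int | None


def dim_sweep(
    session,
    method: str,
    dims: list[int] | None = None,
    folds: int = 10,
    seed: int = 0,
    **spec_kw,
) -> DimSweepResult:
    """Decoding performance as a function of feature dimensionality.

    ``plateau_dim`` is the first dimensionality whose increase in mean R2
    over the previous one is below 0.001 (undefined for a single entry).
    """
    if method not in ("plds", "pca", "pss"):
        raise ValueError("method must be one of plds, pca, pss")
    if dims is None:
        dims = list(range(1, 21))
    targets = build_targets(session)
    means, lls, rows = [], [], []
    for k in dims:
        res = run_cv(session, DecoderSpec(method=method, dims=k, **spec_kw),
                     folds=folds, seed=seed, targets=targets)
        mr = session_mean_r2(res)
        rows.append(mr)
        means.append(float(mr.mean()))
        if method == "plds":
            lls.append(float(sum(r.heldout_loglik for r in res)))
    plateau = None
    for j in range(1, len(dims)):
        if means[j] - means[j - 1] < 0.001:
            plateau = dims[j]
            break
    return DimSweepResult(
        dims=list(dims),
        mean_r2=means,
        per_dim=pd.DataFrame(rows, index=list(dims)),
        loglik=lls if method == "plds" else None,
        plateau_dim=plateau if len(dims) > 1 else None,
    )
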