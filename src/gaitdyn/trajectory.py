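"""Time-normalized latent trajectories and Mahalanobis distance profiles.

Each trial's latent time series is resampled by linear interpolation onto a
100-point gait-phase grid at 1% steps: stance maps to 0-60% and swing to
60-100%, so the 60th grid point is exactly the stance-to-swing transition
and the last point is the end of the cycle. Distances of comparison trials
to a reference trial type are computed per grid point against the reference
distribution (mean and covariance across reference trials at that point).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import spearmanr

from .preprocess import BIN_WIDTH_S, STANCE_END_PCT, Trial, interpolate_gait_phase

logger = logging.getLogger(__name__)

N_GRID = 100
#: Phase grid in percent: 0..99 in 1% steps. Grid point 0 is foot-strike and
#: grid point 60 is exactly toe-off; the cycle end (100% = the next
#: foot-strike) coincides with point 0 of the following cycle.
PHASE_GRID = np.arange(N_GRID, dtype=float)


@dataclass
class NormalizedTrajectory:
    values: np.ndarray  # (latent_dim, N_GRID)
    trial_index: int | None = None
    task: str | None = None
    speed: float | None = None

    def __post_init__(self) -> None:
        if self.values.shape[1] != N_GRID:
            raise ValueError(f"expected exactly {N_GRID} grid points")

    def at_phase(self, pct: float) -> np.ndarray:
        """Value at an on-grid phase percentage (0..99)."""
        idx = int(round(pct))
        if not (0 <= idx < N_GRID):
            raise ValueError("phase must be in [0, 100)")
        return self.values[:, idx]


@dataclass
class DistanceProfile:
    mean: np.ndarray  # (N_GRID,) mean distance per grid point
    sem: np.ndarray  # (N_GRID,)
    per_trial: np.ndarray  # (n_trials, N_GRID)
    reference_label: str
    comparison_label: str
    overall_mean: float


def time_normalize(
    latents: np.ndarray, trial: Trial, t0: float = 0.0
) -> NormalizedTrajectory:
    """Resample one trial's latents onto the 1% gait-phase grid.

    ``latents`` is (latent_dim, n_bins) covering exactly the trial's bin
    range; bin ``i`` is stamped at its left edge. Piecewise-linear in phase:
    stance bins land on 0-60, swing bins on 60-100.
    """
    lat = np.atleast_2d(np.asarray(latents, float))
    if lat.shape[1] != trial.n_bins:
        raise ValueError("latents do not cover the trial bin range")
    times = t0 + BIN_WIDTH_S * np.arange(trial.start, trial.stop)
    phases = interpolate_gait_phase(trial.events, times)
    n_stance = int((phases <= STANCE_END_PCT).sum())
    if n_stance < 2 or trial.n_bins - n_stance < 1:
        raise ValueError("trial needs at least two bins in stance and one in swing")
    # extend with the cycle end (phase 100 = next foot-strike = first bin of
    # the next cycle); linearly extrapolate the final sample to close the cycle
    phases_ext = np.append(phases, 100.0)
    if trial.n_bins >= 2:
        last = lat[:, -1] + (lat[:, -1] - lat[:, -2]) * (
            (100.0 - phases[-1]) / max(phases[-1] - phases[-2], 1e-12)
        )
    else:
        last = lat[:, -1]
    vals_ext = np.hstack([lat, last[:, None]])
    out = np.empty((lat.shape[0], N_GRID))
    for dim in range(lat.shape[0]):
        out[dim] = np.interp(PHASE_GRID, phases_ext, vals_ext[dim])
    return NormalizedTrajectory(
        values=out, trial_index=None, task=trial.task, speed=trial.speed
    )


def average_trajectories(
    trajectories: list[NormalizedTrajectory],
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and standard deviation across trials of one condition."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    stack = np.stack([t.values for t in trajectories])  # (n, k, 100)
    return stack.mean(axis=0), stack.std(axis=0)


def _shrunk_cov(X: np.ndarray, shrinkage: float | str = "auto") -> tuple[np.ndarray, float]:
    """Covariance across reference trials with shrinkage toward its diagonal."""
    n, d = X.shape
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    if shrinkage == "auto":
        lam = min(1.0, d / n) if n <= d else 0.0
        lam = max(lam, 0.05) if n <= d + 1 else lam
    else:
        lam = float(shrinkage)
    if lam > 0:
        cov = (1 - lam) * cov + lam * np.diag(np.diag(cov))
    return cov, lam


def mahalanobis_profile(
    comparison: list[NormalizedTrajectory],
    reference: list[NormalizedTrajectory],
    dims: int = 12,
    shrinkage: float | str = "auto",
    reference_label: str = "",
    comparison_label: str = "",
) -> DistanceProfile:
    """Per-grid-point Mahalanobis distance of comparison trials to the
    reference distribution, averaged across trials with its SEM.

    The reference distribution at each grid point is the mean and (shrunk)
    covariance across reference trials of the first ``dims`` latent
    dimensions. A singular covariance with shrinkage disabled raises an
    error instructing the caller to enable shrinkage.
    """
    if len(reference) < 2:
        raise ValueError("reference needs at least two trials")
    ref = np.stack([t.values[:dims] for t in reference])  # (n_ref, d, 100)
    cmp_ = np.stack([t.values[:dims] for t in comparison])
    n_cmp = cmp_.shape[0]
    dist = np.empty((n_cmp, N_GRID))
    lam_used = None
    for g in range(N_GRID):
        Xr = ref[:, :, g]
        mu = Xr.mean(axis=0)
        cov, lam = _shrunk_cov(Xr, shrinkage)
        lam_used = lam
        try:
            c = cho_factor(cov, lower=True)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular reference covariance; enable shrinkage "
                "(shrinkage='auto' or a positive value)"
            )
        diff = cmp_[:, :, g] - mu
        sol = cho_solve(c, diff.T)
        dist[:, g] = np.sqrt(np.einsum("ij,ji->i", diff, sol))
    if lam_used:
        logger.info("Mahalanobis shrinkage intensity %.3f", lam_used)
    mean = dist.mean(axis=0)
    sem = dist.std(axis=0, ddof=1) / np.sqrt(n_cmp) if n_cmp > 1 else np.zeros(N_GRID)
    return DistanceProfile(
        mean=mean,
        sem=sem,
        per_trial=dist,
        reference_label=reference_label,
        comparison_label=comparison_label,
        overall_mean=float(dist.mean()),
    )


def speed_separation_check(
    profiles: dict[float, DistanceProfile], reference_speed: float
) -> dict:
    """Spearman correlation between |speed - reference speed| and the mean
    distance to the reference-speed distribution.

    With fewer than three speeds the correlation is undefined and reported
    absent (None).
    """
    speeds = sorted(profiles)
    if len(speeds) < 3:
        return {"spearman": None, "n_speeds": len(speeds)}
    deltas = [abs(s - reference_speed) for s in speeds]
    dists = [profiles[s].overall_mean for s in speeds]
    rho = spearmanr(deltas, dists).statistic
    return {
        "spearman": float(rho),
        "n_speeds": len(speeds),
        "deltas": deltas,
        "distances": dists,
    }
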