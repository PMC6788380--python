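"""Synthetic locomotor sessions with known ground truth.

A session is a continuous sequence of single-gait-cycle trials. Latents
rotate once per cycle in a 2-D plane of a fixed linear dynamical system
(modulus 0.995 per bin, free-running, phase set mainly by the trial's initial
state), with an optional per-condition constant offset along one latent axis
proportional to walking speed. Spike counts are conditionally Poisson given
the latents; hind-limb marker positions are affine in the latents plus
i.i.d. Gaussian noise. Gait events sit at 0% and 60% of each cycle, and a
configurable fraction of trials has its kinematics flagged missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from numpy.random import default_rng

from .plds import PLDSParams
from .preprocess import (
    BIN_WIDTH_S,
    MARKERS,
    GaitEvents,
    SpikeCountMatrix,
    Trial,
)

_MEAN_COUNT_BOUND = 20.0  # spikes per 10 ms bin; overflow guard on exp

# resting marker pose relative to the iliac crest (meters); x = walking
# direction, y = height. Chosen so angle triplets stay far from degeneracy.
_BASE_POSE = {
    "hip": (0.00, -0.06),
    "knee": (0.06, -0.18),
    "ankle": (0.02, -0.32),
    "metatarsal": (0.08, -0.40),
    "toe": (0.13, -0.42),
}


@dataclass
class GroundTruthConfig:
    """Knobs of the generative model; see module docstring for semantics."""

    n_units: int = 30
    latent_dim: int = 4
    n_trials_per_condition: int = 20
    conditions: list[tuple[str, float]] = field(
        default_factory=lambda: [("TRM", 4.0)]
    )
    gait_period_range: tuple[float, float] = (0.8, 1.2)
    rotation_frequency: float = 1.0
    speed_offset_axis: int = 2
    speed_offset_gain: float = 0.0
    base_log_rate_range: tuple[float, float] = (-2.0, -0.7)
    kinematic_noise_sd: float = 0.0
    missing_kinematics_fraction: float = 0.0
    latent_noise_sd: float = 0.12  # inter-trial variability knob (unreported)
    start_noise_sd: float = 0.15
    loading_scale: float = 0.35
    #: stationary SD of an optional extra *fast* shared latent (gain-like
    #: population noise). It loads on every unit but has zero kinematic
    #: readout, so it is decoding-irrelevant; a state-space model can isolate
    #: it while direct rate decoding cannot. 0 disables the dimension.
    common_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2 (rotation needs a plane)")
        if not (0.0 <= self.missing_kinematics_fraction <= 1.0):
            raise ValueError("missing_kinematics_fraction must lie in [0, 1]")
        if self.n_units < 1 or self.n_trials_per_condition < 1:
            raise ValueError("n_units and n_trials_per_condition must be positive")
        if self.gait_period_range[0] <= 0 or (
            self.gait_period_range[1] < self.gait_period_range[0]
        ):
            raise ValueError("invalid gait_period_range")
        if self.speed_offset_gain != 0 and not (
            0 <= self.speed_offset_axis < self.latent_dim
        ):
            raise ValueError("speed_offset_axis out of range")
        # worst-case mean count: baseline times a plausible latent swing
        # through a loading row of norm ~1.2 * loading_scale (plus the shared
        # gain dimension when enabled)
        worst = np.exp(
            self.base_log_rate_range[1]
            + 3.0 * 1.2 * self.loading_scale
            + 3.0 * self.common_noise_sd
        )
        if worst >= _MEAN_COUNT_BOUND:
            raise ValueError(
                f"rate parameters can reach {worst:.1f} spikes/bin "
                f"(bound {_MEAN_COUNT_BOUND}); lower base_log_rate_range or "
                "loading_scale"
            )


@dataclass
class SyntheticSession:
    """A generated session plus its ground truth."""

    counts: SpikeCountMatrix
    latents_true: np.ndarray  # (latent_dim, n_bins), offsets included
    kinematics_true: pd.DataFrame  # 100 Hz marker coordinates (meters)
    kinematics: pd.DataFrame  # as above but NaN on kinematics-missing trials
    trials: list[Trial]
    params_true: PLDSParams
    config: GroundTruthConfig
    readout_W: np.ndarray  # markers readout: coords = W @ latents + b (+noise)
    readout_b: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.counts.n_bins

    @property
    def n_units(self) -> int:
        return self.counts.n_units


_MAX_HARMONIC_PLANES = 3


def _rotation_dynamics(k: int, angle: float, modulus: float = 0.995) -> np.ndarray:
    """Block-diagonal dynamics: the fundamental rotation plane, up to two
    harmonic planes (2x, 3x the gait frequency), and slow relaxation modes
    for the remaining dimensions. The harmonic cap keeps the latent (and
    hence kinematic) spectrum below ~6 Hz, matching the smooth, cyclic
    character of locomotor trajectories; relaxation modes keep every extra
    dimension driven and identifiable."""
    A = np.zeros((k, k))
    n_planes = min(k // 2, _MAX_HARMONIC_PLANES)
    for m in range(n_planes):
        c, s = np.cos((m + 1) * angle), np.sin((m + 1) * angle)
        A[2 * m : 2 * m + 2, 2 * m : 2 * m + 2] = modulus * np.array(
            [[c, -s], [s, c]]
        )
    for j in range(2 * n_planes, k):
        A[j, j] = 0.98 - 0.005 * ((j - 2 * n_planes) % 3)
    return A


def _phase_anchor(k: int) -> np.ndarray:
    """Initial-state mean: each plane starts at phase zero with decreasing
    amplitude; relaxation dimensions start from alternating baselines."""
    x0 = np.zeros(k)
    n_planes = min(k // 2, _MAX_HARMONIC_PLANES)
    for m in range(n_planes):
        x0[2 * m] = 1.5 * 0.85**m
    for j in range(2 * n_planes, k):
        x0[j] = 0.8 * (-1.0) ** j
    return x0


def _trial_lengths(cfg: GroundTruthConfig, n_trials: int, rng) -> np.ndarray:
    """Trial lengths in bins, rounded to multiples of 5 so the 60% stance
    mark lands exactly on a bin edge."""
    lo, hi = cfg.gait_period_range
    periods = rng.uniform(lo, hi, size=n_trials)
    bins = np.maximum(np.round(periods / (5 * BIN_WIDTH_S)).astype(int), 4) * 5
    return bins


def generate_session(config: GroundTruthConfig) -> SyntheticSession:
    """Generate one session; bit-reproducible given ``config.seed``."""
    config.validate()
    cfg = config
    rng = default_rng(cfg.seed)
    k = cfg.latent_dim

    n_cond = len(cfg.conditions)
    n_trials = n_cond * cfg.n_trials_per_condition
    lengths = _trial_lengths(cfg, n_trials, rng)
    mean_bins = float(np.mean(lengths))
    angle = 2.0 * np.pi * cfg.rotation_frequency / mean_bins

    # optional extra fast shared latent (gain noise) as the last dimension
    k_tot = k + (1 if cfg.common_noise_sd > 0 else 0)
    A = np.zeros((k_tot, k_tot))
    A[:k, :k] = _rotation_dynamics(k, angle)
    Q = np.eye(k_tot) * cfg.latent_noise_sd**2
    Q0 = np.eye(k_tot) * cfg.start_noise_sd**2
    x0 = np.zeros(k_tot)
    x0[:k] = _phase_anchor(k)
    C = rng.normal(0.0, cfg.loading_scale / np.sqrt(k), size=(cfg.n_units, k_tot))
    # make sure every unit sees the rotation plane a bit
    C[:, :2] += rng.normal(0.0, cfg.loading_scale, size=(cfg.n_units, 2)) * 0.5
    # clip loading-row outliers so the exp link cannot run away
    row = np.linalg.norm(C[:, :k], axis=1)
    cap = 1.2 * cfg.loading_scale
    C[row > cap, :k] *= (cap / row[row > cap])[:, None]
    if cfg.common_noise_sd > 0:
        rho_f = 0.3  # fast, broadband
        A[k, k] = rho_f
        Q[k, k] = cfg.common_noise_sd**2 * (1 - rho_f**2)
        Q0[k, k] = cfg.common_noise_sd**2
        C[:, k] = rng.uniform(0.5, 1.0, size=cfg.n_units)  # shared gain
    d = rng.uniform(*cfg.base_log_rate_range, size=cfg.n_units)
    params = PLDSParams(A=A, Q=Q, C=C, d=d, x0=x0, Q0=Q0)

    # marker readout: affine in the *slow* latents; the shared gain
    # dimension (if any) has zero kinematic readout
    n_coords = 2 * (len(MARKERS) - 1)
    W = np.zeros((n_coords, k_tot))
    W[:, :k] = rng.normal(0.0, 0.015, size=(n_coords, k))
    b = np.array([v for m in MARKERS[1:] for v in _BASE_POSE[m]])

    cond_of_trial = np.repeat(np.arange(n_cond), cfg.n_trials_per_condition)
    order = rng.permutation(n_trials)  # interleave conditions
    cond_of_trial = cond_of_trial[order]

    chol_q = np.linalg.cholesky(Q)
    chol_q0 = np.linalg.cholesky(Q0)
    lat_segments = []
    count_segments = []
    trials: list[Trial] = []
    start = 0
    missing = rng.random(n_trials) < cfg.missing_kinematics_fraction
    for i in range(n_trials):
        T = int(lengths[i])
        task, speed = cfg.conditions[cond_of_trial[i]]
        x = np.empty((k_tot, T))
        x[:, 0] = x0 + chol_q0 @ rng.standard_normal(k_tot)
        for t in range(1, T):
            x[:, t] = A @ x[:, t - 1] + chol_q @ rng.standard_normal(k_tot)
        offset = np.zeros(k_tot)
        if cfg.speed_offset_gain != 0:
            offset[cfg.speed_offset_axis] = cfg.speed_offset_gain * (speed or 0.0)
        z = x + offset[:, None]
        log_rate = C @ z + d[:, None]
        rate = np.exp(np.clip(log_rate, None, np.log(_MEAN_COUNT_BOUND)))
        if np.exp(log_rate).max() >= _MEAN_COUNT_BOUND:
            raise FloatingPointError(
                "generated rate exceeded the mean-count bound; soften the config"
            )
        count_segments.append(rng.poisson(rate))
        lat_segments.append(z)
        fs = start * BIN_WIDTH_S
        nfs = (start + T) * BIN_WIDTH_S
        to = fs + 0.6 * T * BIN_WIDTH_S  # exact bin edge: T divisible by 5
        trials.append(
            Trial(
                start,
                start + T,
                GaitEvents(fs, to, nfs),
                task,
                speed=speed,
                has_kinematics=not bool(missing[i]),
            )
        )
        start += T

    latents = np.concatenate(lat_segments, axis=1)
    counts = SpikeCountMatrix(np.concatenate(count_segments, axis=1))

    coords = W @ latents + b[:, None]
    if cfg.kinematic_noise_sd > 0:
        coords = coords + cfg.kinematic_noise_sd * rng.standard_normal(coords.shape)
    cols = {}
    cols["crest_x"] = np.zeros(latents.shape[1])
    cols["crest_y"] = np.zeros(latents.shape[1])
    for j, m in enumerate(MARKERS[1:]):
        cols[f"{m}_x"] = coords[2 * j]
        cols[f"{m}_y"] = coords[2 * j + 1]
    kin_true = pd.DataFrame(cols)
    kin = kin_true.copy()
    for tr in trials:
        if not tr.has_kinematics:
            kin.iloc[tr.start : tr.stop] = np.nan
    return SyntheticSession(
        counts=counts,
        latents_true=latents,
        kinematics_true=kin_true,
        kinematics=kin,
        trials=trials,
        params_true=params,
        config=cfg,
        readout_W=W,
        readout_b=b,
    )


def ideal_decoding_ceiling(session: SyntheticSession, order: int = 10) -> pd.Series:
    """Per-variable R-squared of decoding marker coordinates from the *true*
    latents with the standard lag-10 linear decoder.

    This is the ceiling any neural decoder is compared against: with zero
    kinematic noise the readout is exactly affine in the latents, so every
    R-squared is 1 up to numerical error.
    """
    from .wiener import fit_wiener, predict, score_r2

    if not any(tr.has_kinematics for tr in session.trials):
        raise ValueError("session has no kinematics")
    X = session.latents_true.T  # (T, k)
    target_cols = [c for c in session.kinematics_true.columns if not c.startswith("crest")]
    Y = session.kinematics_true[target_cols].to_numpy()
    filt = fit_wiener(X, Y, order=order)
    y_hat = predict(filt, X)
    valid = np.zeros(len(X), dtype=bool)
    valid[order - 1 :] = True
    r2 = []
    for tr in session.trials:
        if not tr.has_kinematics:
            continue
        sl = slice(tr.start, tr.stop)
        m = valid[sl]
        r2.append(score_r2(Y[sl][m], y_hat[sl][m]))
    return pd.Series(np.nanmean(np.array(r2), axis=0), index=target_cols)


def config_to_dict(cfg: GroundTruthConfig) -> dict:
    out = asdict(cfg)
    out["conditions"] = [list(c) for c in cfg.conditions]
    return out


def config_from_dict(data: dict) -> GroundTruthConfig:
    data = dict(data)
    if "conditions" in data:
        data["conditions"] = [tuple(c) for c in data["conditions"]]
    for key in ("gait_period_range", "base_log_rate_range"):
        if key in data:
            data[key] = tuple(data[key])
    return GroundTruthConfig(**data)
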