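"""Spike binning, firing-rate estimation, kinematic variable derivation,
gait-phase interpolation and trial segmentation.

All neural data live on a 10 ms bin grid that is in 1:1 correspondence with
100 Hz kinematic frames; frame/bin ``i`` covers the half-open interval
``[t0 + 0.01*i, t0 + 0.01*(i+1))`` seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Width of one spike-count bin, seconds. Fixed so bins align with 100 Hz frames.
BIN_WIDTH_S = 0.01

#: Number of trailing bins summed to form a firing-rate estimate.
RATE_WINDOW_BINS = 10

#: Percent of the gait cycle spent in stance (foot-strike to toe-off).
STANCE_END_PCT = 60.0

#: Recognised task labels.
TASKS = ("TRM", "BIP", "BACK", "CORR", "LAD")

#: Markers tracked on the hind limb, proximal to distal. The iliac crest is the
#: coordinate origin; all positions are reported relative to it.
MARKERS = ("crest", "hip", "knee", "ankle", "metatarsal", "toe")

#: Joint-angle triplets (proximal, vertex, distal marker). The inner angle is
#: measured at the vertex.
ANGLE_TRIPLETS = {
    "hip": ("crest", "hip", "knee"),
    "knee": ("hip", "knee", "ankle"),
    "ankle": ("knee", "ankle", "metatarsal"),
    "metatarsal": ("ankle", "metatarsal", "toe"),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SpikeCountMatrix:
    """Units x bins matrix of non-negative integer spike counts."""

    counts: np.ndarray
    t0: float = 0.0
    bin_width: float = BIN_WIDTH_S

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (units x bins)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if abs(self.bin_width - BIN_WIDTH_S) > 1e-12:
            raise ValueError(f"bin_width is fixed at {BIN_WIDTH_S} s")

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass
class FiringRateMatrix:
    """Units x bins firing rates in spikes/s (optionally z-scored)."""

    rates: np.ndarray
    normalized: bool = False

    @property
    def n_units(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]


@dataclass(frozen=True)
class GaitEvents:
    """Event times (seconds) bounding one gait cycle."""

    foot_strike_t: float
    toe_off_t: float
    next_foot_strike_t: float

    def __post_init__(self) -> None:
        if not (self.foot_strike_t < self.toe_off_t < self.next_foot_strike_t):
            raise ValueError(
                "events must satisfy foot_strike < toe_off < next_foot_strike"
            )


@dataclass
class Trial:
    """One gait cycle: a half-open bin range plus its events and labels."""

    start: int
    stop: int
    events: GaitEvents
    task: str
    speed: float | None = None
    has_kinematics: bool = True

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("empty trial bin range")
        if self.task not in TASKS:
            raise ValueError(f"unknown task label {self.task!r}")

    @property
    def n_bins(self) -> int:
        return self.stop - self.start

    def bins(self) -> np.ndarray:
        return np.arange(self.start, self.stop)


@dataclass
class ZScoreStats:
    """Per-unit normalisation constants, tagged with their fitting provenance."""

    mean: np.ndarray
    sd: np.ndarray
    fit_tag: tuple = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def bin_spikes(
    spike_times: Sequence[np.ndarray], t0: float, t1: float
) -> SpikeCountMatrix:
    """Bin per-unit spike times into 10 ms counts over ``[t0, t1)``.

    Bin edges are half-open; a spike exactly on an edge belongs to the later
    bin. Spike times must be sorted and lie within ``[t0, t1)``.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    n_bins = int(np.ceil((t1 - t0) / BIN_WIDTH_S - 1e-9))
    edges = t0 + BIN_WIDTH_S * np.arange(n_bins + 1)
    counts = np.zeros((len(spike_times), n_bins), dtype=np.int64)
    for u, times in enumerate(spike_times):
        times = np.asarray(times, dtype=float)
        if times.size == 0:
            continue
        if np.any(np.diff(times) < 0):
            raise ValueError(f"unit {u}: spike times not sorted")
        if times[0] < t0 or times[-1] >= t1:
            raise ValueError(f"unit {u}: spike times outside [t0, t1)")
        # 'right' so a spike exactly on an edge lands in the later bin
        idx = np.searchsorted(edges, times, side="right") - 1
        np.add.at(counts[u], idx, 1)
    return SpikeCountMatrix(counts, t0=t0)


def estimate_rates(counts: SpikeCountMatrix) -> FiringRateMatrix:
    """Trailing-window firing rates: sum of the current and previous nine
    10 ms bins divided by 100 ms.

    The first nine bins of the epoch use the partial window that is actually
    available, divided by its true duration, so rates are defined everywhere.
    """
    c = counts.counts.astype(float)
    csum = np.cumsum(c, axis=1)
    w = RATE_WINDOW_BINS
    rates = np.empty_like(c)
    rates[:, w - 1 :] = csum[:, w - 1 :].copy()
    rates[:, w:] -= csum[:, :-w]
    rates[:, w - 1 :] /= w * BIN_WIDTH_S
    # warm-up: partial window divided by its actual duration
    nb = min(w - 1, c.shape[1])
    denom = BIN_WIDTH_S * (np.arange(nb) + 1.0)
    rates[:, :nb] = csum[:, :nb] / denom
    return FiringRateMatrix(rates)


def fit_zscore(rates: FiringRateMatrix, fit_tag: tuple = ()) -> ZScoreStats:
    """Compute per-unit mean/SD (population SD) from training data only."""
    mean = rates.rates.mean(axis=1)
    sd = rates.rates.std(axis=1)
    n_dead = int((sd == 0).sum())
    if n_dead:
        logger.warning("%d zero-variance units will z-score to 0", n_dead)
    return ZScoreStats(mean=mean, sd=sd, fit_tag=tuple(fit_tag))


def zscore(rates: FiringRateMatrix, stats: ZScoreStats) -> FiringRateMatrix:
    """Apply training-fold normalisation constants; SD = 0 units map to 0."""
    sd = np.where(stats.sd == 0, 1.0, stats.sd)
    z = (rates.rates - stats.mean[:, None]) / sd[:, None]
    z[stats.sd == 0, :] = 0.0
    return FiringRateMatrix(z, normalized=True)


def interpolate_gait_phase(events: GaitEvents, query_t) -> np.ndarray | float:
    """Piecewise-linear gait phase in percent.

    Foot-strike maps to 0, toe-off to 60 and the next foot-strike to 100;
    phase is linear in time within stance and within swing.
    """
    q = np.asarray(query_t, dtype=float)
    fs, to, nfs = events.foot_strike_t, events.toe_off_t, events.next_foot_strike_t
    if np.any(q < fs) or np.any(q > nfs):
        raise ValueError("query time outside the gait cycle")
    # divide before scaling so the anchors come out exactly 0 / 60 / 100
    with np.errstate(invalid="ignore"):
        phase = np.where(
            q <= to,
            STANCE_END_PCT * ((q - fs) / (to - fs)),
            STANCE_END_PCT + (100.0 - STANCE_END_PCT) * ((q - to) / (nfs - to)),
        )
    return float(phase) if np.isscalar(query_t) else phase


def derive_kinematics(markers: pd.DataFrame, angles: dict | None = None) -> pd.DataFrame:
    """Derive decoding targets from marker coordinates.

    ``markers`` has columns ``<marker>_x`` / ``<marker>_y`` (meters) for each
    of :data:`MARKERS`; x is the walking direction, y the height. Output
    columns: positions of the five non-crest markers re-referenced to the
    iliac crest, sine and cosine of each joint angle (never the raw angle),
    and ``leg_extension`` (crest-metatarsal distance). Frames with a
    degenerate angle triplet get NaN for that angle and are flagged in the
    boolean ``degenerate`` column.
    """
    if angles is None:
        angles = ANGLE_TRIPLETS
    pos = {}
    for m in MARKERS:
        pos[m] = markers[[f"{m}_x", f"{m}_y"]].to_numpy(dtype=float)
    origin = pos["crest"]
    out = {}
    for m in MARKERS[1:]:
        rel = pos[m] - origin
        out[f"{m}_x"] = rel[:, 0]
        out[f"{m}_y"] = rel[:, 1]
    degenerate = np.zeros(len(markers), dtype=bool)
    for name, (a, b, c) in angles.items():
        v1 = pos[a] - pos[b]
        v2 = pos[c] - pos[b]
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        bad = (n1 == 0) | (n2 == 0)
        degenerate |= bad
        denom = np.where(bad, 1.0, n1 * n2)
        cos = np.einsum("ij,ij->i", v1, v2) / denom
        sin = np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]) / denom
        cos = np.where(bad, 0.0, cos)
        sin = np.where(bad, 0.0, sin)
        norm = np.where(bad, 1.0, np.hypot(sin, cos))  # so sin^2 + cos^2 == 1
        cos = np.where(bad, np.nan, cos / norm)
        sin = np.where(bad, np.nan, sin / norm)
        out[f"sin_{name}"] = sin
        out[f"cos_{name}"] = cos
    out["leg_extension"] = np.linalg.norm(pos["metatarsal"] - origin, axis=1)
    out["degenerate"] = degenerate
    if degenerate.any():
        logger.warning("%d frames with degenerate angle triplets", degenerate.sum())
    return pd.DataFrame(out, index=markers.index)


def gait_phase_track(trials: Sequence[Trial], n_bins: int, t0: float = 0.0) -> np.ndarray:
    """Per-bin gait phase (percent) over a continuous epoch; NaN outside trials.

    Each bin is stamped with the phase of its left edge, so the first bin of a
    trial reads exactly 0 and the bin at toe-off reads exactly 60 when toe-off
    falls on a bin edge.
    """
    phase = np.full(n_bins, np.nan)
    for tr in trials:
        t = t0 + BIN_WIDTH_S * np.arange(tr.start, tr.stop)
        phase[tr.start : tr.stop] = interpolate_gait_phase(tr.events, t)
    return phase


def segment_trials(
    counts: SpikeCountMatrix,
    events: Sequence[GaitEvents],
    tasks: Sequence[str],
    speeds: Sequence[float | None] | None = None,
    kinematics_ok: Sequence[bool] | None = None,
    neural_ok: np.ndarray | None = None,
) -> list[Trial]:
    """Cut a continuous epoch into single-gait-cycle trials.

    One trial per foot-strike-to-foot-strike span. Trials with missing
    kinematic frames are kept with ``has_kinematics=False``; trials whose bin
    range overlaps a corrupt neural bin (``neural_ok`` False) are dropped and
    the exclusion count logged.
    """
    if speeds is None:
        speeds = [None] * len(events)
    if kinematics_ok is None:
        kinematics_ok = [True] * len(events)
    trials: list[Trial] = []
    n_excluded = 0
    prev_stop = -1
    for ev, task, speed, kin in zip(events, tasks, speeds, kinematics_ok):
        start = int(round((ev.foot_strike_t - counts.t0) / BIN_WIDTH_S))
        stop = int(round((ev.next_foot_strike_t - counts.t0) / BIN_WIDTH_S))
        if start < prev_stop:
            raise ValueError("overlapping trial spans")
        if start < 0 or stop > counts.n_bins:
            raise ValueError("trial extends beyond the recorded epoch")
        prev_stop = stop
        if neural_ok is not None and not neural_ok[start:stop].all():
            n_excluded += 1
            continue
        trials.append(
            Trial(start, stop, ev, task, speed=speed, has_kinematics=bool(kin))
        )
    if n_excluded:
        logger.info("excluded %d trials with missing neural data", n_excluded)
    return trials
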