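"""Frequency analysis of decoder outputs and cross-session decoder statistics.

PSDs use Thomson's multitaper method (DPSS tapers); trials of unequal length
are interpolated onto a common 0-50 Hz grid before averaging. Decoder
comparisons are paired per session: a two-tailed Wilcoxon signed-rank test
per variable (exact null distribution for n <= 25, normal approximation with
continuity correction above) with Benjamini-Hochberg step-up control of the
false discovery rate across variables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)

FS_HZ = 100.0
NYQUIST_HZ = FS_HZ / 2.0
_COMMON_GRID = np.linspace(0.0, NYQUIST_HZ, 101)
_EXACT_SIGNRANK_MAX_N = 25


@dataclass
class PSDEstimate:
    frequencies: np.ndarray
    power: np.ndarray  # averaged across trials, same length as frequencies
    n_trials: int
    nw: float
    n_tapers: int


def multitaper_psd(
    trial_signals: list[np.ndarray],
    fs: float = FS_HZ,
    nw: float = 4.0,
    n_tapers: int | None = None,
    demean: bool = False,
) -> PSDEstimate:
    """Multitaper PSD per trial, averaged across trials on a common grid.

    Each trial's eigenspectra (DPSS tapers, time-bandwidth ``nw``, default
    ``2*nw - 1`` tapers) are averaged, interpolated to a fixed 0-Nyquist grid
    and then averaged across trials. Trials shorter than twice the taper
    count are skipped with a warning.

    ``demean`` removes each trial's mean first; essential when comparing
    high-frequency tails of signals with large baselines, whose DC leakage
    otherwise dominates the tail.
    """
    if n_tapers is None:
        n_tapers = int(2 * nw - 1)
    grid = _COMMON_GRID * (fs / FS_HZ)
    acc = np.zeros_like(grid)
    n_used = 0
    for sig in trial_signals:
        x = np.asarray(sig, float).ravel()
        if demean:
            x = x - x.mean()
        n = x.size
        if n < 2 * n_tapers:
            warnings.warn("trial too short for multitaper PSD; skipped")
            continue
        tapers = dpss(n, nw, Kmax=n_tapers)
        spectra = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2 / fs
        psd = spectra.mean(axis=0)
        # one-sided scaling (double interior bins)
        psd[1:] *= 2.0
        if n % 2 == 0:
            psd[-1] /= 2.0
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        acc += np.interp(grid, freqs, psd)
        n_used += 1
    if n_used == 0:
        raise ValueError("no trial long enough for the requested tapers")
    return PSDEstimate(
        frequencies=grid, power=acc / n_used, n_trials=n_used, nw=nw,
        n_tapers=n_tapers,
    )


def high_frequency_ratio(psd: PSDEstimate, cutoff_hz: float) -> float:
    """Fraction of total power above ``cutoff_hz``."""
    total = np.trapezoid(psd.power, psd.frequencies)
    if total <= 0:
        return 0.0
    hi = psd.frequencies >= cutoff_hz
    return float(np.trapezoid(psd.power[hi], psd.frequencies[hi]) / total)


def smoothness_compare(
    psds: dict[str, PSDEstimate], cutoff_hz: float = 10.0
) -> pd.DataFrame:
    """High-frequency power ratios per decoder, ordered smoothest first."""
    rows = {
        name: {"hf_ratio": high_frequency_ratio(psd, cutoff_hz)}
        for name, psd in psds.items()
    }
    out = pd.DataFrame.from_dict(rows, orient="index").sort_values("hf_ratio")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (exact) and Benjamini-Hochberg
# ---------------------------------------------------------------------------


def signed_rank_test(diffs: np.ndarray) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded (Wilcoxon convention); ties get average
    ranks. For n <= 25 the p-value is exact, computed from the full null
    distribution of the signed-rank sum; above that a normal approximation
    with continuity and tie correction is used. All-zero differences return
    (0, 1.0) by convention.
    """
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        logger.warning("all paired differences are zero; p = 1 by convention")
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    m = n * (n + 1) / 2.0
    if n <= _EXACT_SIGNRANK_MAX_N:
        # distribution of W+ over all 2^n sign assignments; ranks may be
        # half-integers under ties, so work on doubled ranks
        r2 = np.round(2 * ranks).astype(int)
        total = r2.sum()
        pmf = np.zeros(total + 1)
        pmf[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(pmf)
            shifted[r:] = pmf[: total + 1 - r]
            pmf = 0.5 * (pmf + shifted)
        w2 = int(round(2 * w_pos))
        # two-tailed: both tails at least as extreme as |W+ - mean|
        dev = abs(w2 - total / 2.0)
        lo = total / 2.0 - dev
        hi = total / 2.0 + dev
        idx = np.arange(total + 1)
        p = float(pmf[(idx <= lo + 1e-9) | (idx >= hi - 1e-9)].sum())
    else:
        mu = m / 2.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (abs(w_pos - mu) - 0.5) / sigma
        p = float(2.0 * norm.sf(z))
    return w_pos, min(p, 1.0)


def benjamini_hochberg(p_values: np.ndarray, fdr: float = 0.10) -> np.ndarray:
    """Step-up FDR control: reject the m smallest p-values where m is the
    largest k with p_(k) <= k * fdr / n. Returns a boolean reject mask."""
    p = np.asarray(p_values, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    thresh = fdr * (np.arange(1, n + 1)) / n
    below = p[order] <= thresh
    reject = np.zeros(n, dtype=bool)
    if below.any():
        k_max = int(np.nonzero(below)[0].max())
        reject[order[: k_max + 1]] = True
    return reject


@dataclass
class ComparisonResult:
    table: pd.DataFrame  # per variable: delta_mean, w, p, significant
    baseline: str
    fdr: float


def compare_decoders(
    session_r2: dict[str, pd.DataFrame],
    baseline: str = "fp",
    fdr: float = 0.10,
) -> dict[str, ComparisonResult]:
    """Paired per-session comparison of each decoder against the baseline.

    ``session_r2`` maps decoder name to a (sessions x variables) table of
    session-mean R2, all sharing index and columns. For each non-baseline
    decoder: per-variable signed-rank test on the paired per-session
    differences, BH-adjusted across variables at the given FDR.
    """
    if baseline not in session_r2:
        raise ValueError(f"baseline decoder {baseline!r} missing")
    base = session_r2[baseline]
    out = {}
    for name, table in session_r2.items():
        if name == baseline:
            continue
        if not table.index.equals(base.index) or not table.columns.equals(base.columns):
            raise ValueError(f"decoder {name!r} not aligned with baseline")
        deltas = table - base
        rows = []
        for var in deltas.columns:
            d = deltas[var].dropna().to_numpy()
            w, p = signed_rank_test(d)
            rows.append(
                {"variable": var, "delta_mean": float(np.mean(d)) if d.size else np.nan,
                 "w": w, "p": p, "n": d.size}
            )
        tab = pd.DataFrame(rows).set_index("variable")
        tab["significant"] = benjamini_hochberg(tab["p"].to_numpy(), fdr)
        out[name] = ComparisonResult(table=tab, baseline=baseline, fdr=fdr)
    return out
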