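"""Resting head-motion tremor spectra and the two-group permutation test.

Power spectral densities use Welch's averaged periodogram (default
nfft = 4096, Bartlett window, 50% overlap) per motion axis.  Group
differences in band power are assessed with an independent-sample
permutation test on the difference of group means: exact enumeration of all
distinct relabelings when feasible, Monte Carlo otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import signal

from .core import MotionRecording

__all__ = ["PsdResult", "PermutationResult", "welch_psd", "band_power", "permutation_test"]


@dataclass
class PsdResult:
    frequencies: np.ndarray  # Hz, 0..Nyquist
    psd: dict[str, np.ndarray]  # power/Hz per channel
    nfft: int
    window: str
    overlap: float


@dataclass
class PermutationResult:
    stat_obs: float
    p_value: float
    n_permutations: int
    exhaustive: bool
    seed: int | None


def welch_psd(
    rec: MotionRecording,
    nfft: int = 4096,
    window: str = "bartlett",
    overlap: float = 0.5,
    window_length: int | None = None,
) -> PsdResult:
    """Welch PSD per channel; density scaling (a unit-variance white input
    integrates to ~1).

    ``window_length`` defaults to ``nfft`` samples; recordings shorter than
    one window raise, and at least two (overlapping) segments are required
    for averaging.
    """
    nperseg = nfft if window_length is None else window_length
    n = len(next(iter(rec.channels.values())))
    if n < nperseg:
        raise ValueError(f"recording ({n} samples) shorter than one window ({nperseg})")
    noverlap = int(overlap * nperseg)
    if n < 2 * nperseg - noverlap:
        raise ValueError("recording must span at least two overlapping windows")
    win = signal.get_window(window, nperseg)
    psd: dict[str, np.ndarray] = {}
    freqs = None
    for name, x in rec.channels.items():
        freqs, p = signal.welch(x, fs=rec.sample_rate, window=win,
                                noverlap=noverlap, nfft=nfft, detrend=False,
                                scaling="density")
        psd[name] = p
    return PsdResult(frequencies=freqs, psd=psd, nfft=nfft, window=window, overlap=overlap)


def band_power(result: PsdResult, f_lo: float, f_hi: float) -> dict[str, float]:
    """Integrated PSD per channel over [f_lo, f_hi] Hz (trapezoidal)."""
    sel = (result.frequencies >= f_lo) & (result.frequencies <= f_hi)
    if sel.sum() < 2:
        raise ValueError("band too narrow for the spectral resolution")
    f = result.frequencies[sel]
    return {name: float(np.trapezoid(p[sel], f)) for name, p in result.psd.items()}


def permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
) -> PermutationResult:
    """Two-sided independent-sample permutation test on the mean difference.

    All C(n_a + n_b, n_a) distinct relabelings are enumerated when their
    count does not exceed ``n_perm``; the exact p is the fraction of
    relabelings with |T*| >= |T_obs| (the observed labeling counts itself, so
    p > 0 and is a multiple of 1/N).  Otherwise ``n_perm`` Monte Carlo
    permutations are drawn and p = (count + 1)/(n_perm + 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n_a, n_tot = a.size, a.size + b.size
    t_obs = float(a.mean() - b.mean())
    # tolerance against float round-off in |T*| >= |T_obs| comparisons
    thresh = abs(t_obs) - 1e-12 * (1.0 + abs(t_obs))

    n_b = b.size
    total = pooled.sum()

    def _stats_from_a_sums(a_sums: np.ndarray) -> np.ndarray:
        return a_sums / n_a - (total - a_sums) / n_b

    n_exhaustive = math.comb(n_tot, n_a)
    if n_exhaustive <= n_perm:
        idx = np.array(list(combinations(range(n_tot), n_a)))
        t_all = _stats_from_a_sums(pooled[idx].sum(axis=1))
        count = int(np.sum(np.abs(t_all) >= thresh))
        return PermutationResult(stat_obs=t_obs, p_value=count / n_exhaustive,
                                 n_permutations=n_exhaustive, exhaustive=True,
                                 seed=seed)

    rng = np.random.default_rng(seed)
    a_sums = np.empty(n_perm)
    for i in range(n_perm):
        a_sums[i] = pooled[rng.permutation(n_tot)[:n_a]].sum()
    t_all = _stats_from_a_sums(a_sums)
    count = int(np.sum(np.abs(t_all) >= thresh))
    return PermutationResult(stat_obs=t_obs, p_value=(count + 1) / (n_perm + 1),
                             n_permutations=n_perm, exhaustive=False, seed=seed)
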