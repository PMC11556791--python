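"""Afferent excitability: spike detection, current threshold, and
transient/sustained classification.

Current-clamp step families (default grid: from -200 pA in 50 pA increments)
are scanned for spikes; the threshold current I_thresh is the smallest step
that evokes any spike (resolution = the grid increment).  The firing pattern
is read at the step nearest 3 x I_thresh: 1-2 spikes in the count window is
'transient' (striolar-like, irregular), more is 'sustained'
(extrastriolar-like, regular).  Calyces with resting potentials less negative
than -50 mV fail QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import StepFamily

__all__ = [
    "ExcitabilityResult", "detect_spikes", "estimate_threshold",
    "classify_pattern", "qc_calyx", "analyze_excitability",
]


@dataclass
class ExcitabilityResult:
    i_thresh: float | None  # pA; None if no step evoked spikes
    pattern: str  # transient | sustained | subthreshold
    n_spikes_at_3x: int | None
    spike_times: list[list[float]] = field(default_factory=list)  # ms per step
    qc_pass: bool | None = None


def detect_spikes(
    trace: np.ndarray,
    sample_interval: float,
    threshold_mv: float = -20.0,
    min_isi: float = 1.0,
) -> np.ndarray:
    """Spike times (ms) as upward threshold crossings with a refractory rule.

    Crossings closer than ``min_isi`` ms to the previous accepted spike are
    discarded.  Times are the crossing-sample times.
    """
    v = np.asarray(trace, dtype=float)
    above = v >= threshold_mv
    crossing_idx = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    times: list[float] = []
    last = -np.inf
    for i in crossing_idx:
        t = i * sample_interval
        if t - last >= min_isi:
            times.append(t)
            last = t
    return np.asarray(times)


def _spikes_per_step(
    family: StepFamily, threshold_mv: float, min_isi: float
) -> list[np.ndarray]:
    """Spike times per step, in ms from step onset, within the step."""
    out = []
    i_on = family.sample_index(family.step_onset)
    i_off = family.sample_index(family.step_offset)
    for trace in family.traces:
        times = detect_spikes(trace[i_on:i_off], family.sample_interval,
                              threshold_mv, min_isi)
        out.append(times)
    return out


def estimate_threshold(
    family: StepFamily,
    threshold_mv: float = -20.0,
    min_isi: float = 1.0,
) -> tuple[float | None, list[np.ndarray]]:
    """Smallest step current evoking >= 1 spike, plus per-step spike times.

    Returns (None, times) if no step spikes (subthreshold cell).
    """
    if family.kind != "current":
        raise ValueError("expected a current-step family")
    times = _spikes_per_step(family, threshold_mv, min_isi)
    for level, t in zip(family.step_levels, times):
        if t.size > 0:
            return float(level), times
    return None, times


def classify_pattern(
    family: StepFamily,
    i_thresh: float,
    spike_times: list[np.ndarray],
    count_window: float = 400.0,
) -> tuple[str, int]:
    """Firing pattern at the grid step nearest 3 x I_thresh.

    Spikes within ``count_window`` ms of step onset are counted: 1-2 is
    transient, > 2 sustained, 0 subthreshold (should not occur at 3x).
    """
    if i_thresh is None:
        raise ValueError("i_thresh undefined: cell never spiked")
    target = 3.0 * i_thresh
    step = int(np.argmin(np.abs(family.step_levels - target)))
    n = int(np.sum(spike_times[step] < count_window))
    if n == 0:
        return "subthreshold", n
    return ("transient" if n <= 2 else "sustained"), n


def qc_calyx(v_rest: float) -> bool:
    """Pass iff resting potential is -50 mV or more negative."""
    return v_rest <= -50.0


def analyze_excitability(
    family: StepFamily,
    threshold_mv: float = -20.0,
    min_isi: float = 1.0,
    count_window: float = 400.0,
) -> ExcitabilityResult:
    """Full excitability read-out of one current-step family."""
    i_thresh, times = estimate_threshold(family, threshold_mv, min_isi)
    v_rest = float(family.traces[0, : family.sample_index(family.step_onset)].mean())
    qc = qc_calyx(v_rest)
    if i_thresh is None:
        return ExcitabilityResult(i_thresh=None, pattern="subthreshold",
                                  n_spikes_at_3x=None,
                                  spike_times=[list(t) for t in times], qc_pass=qc)
    pattern, n3x = classify_pattern(family, i_thresh, times, count_window)
    return ExcitabilityResult(i_thresh=i_thresh, pattern=pattern, n_spikes_at_3x=n3x,
                              spike_times=[list(t) for t in times], qc_pass=qc)
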