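"""MET current analysis: voltage corrections, responder QC, conductance-
displacement Boltzmann fits with operating range, and adaptation decomposition.

The pipeline mirrors standard hair-cell transduction analysis:

1. correct commanded potentials for the liquid junction potential and the
   residual (uncompensated) series resistance;
2. partition cells by peak |I_MET| into non-responders (< 20 pA), responders,
   and the analysis set (> 150 pA);
3. convert onset-peak currents to conductance via the driving force
   (V_eff - E_rev) and fit a first-order Boltzmann G(X); the operating range
   is OR = S * ln 81 (10-90% span);
4. decompose adaptation at the half-activating step into up to three
   exponential components (very fast < 1 ms, fast 1-10 ms, slow > 10 ms) and
   compute the extent of adaptation
   (I_peak - I_SS) / (I_peak - I_0) * 100.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .boltzmann import BoltzmannParams, FitFailure, fit_boltzmann
from .core import StepFamily
from .filters import bessel_lowpass_zerophase

__all__ = [
    "GxBoltzmannFit", "AdaptationFit", "MetCurve",
    "correct_voltages", "qc_met_cells", "met_conductance_curve",
    "fit_gx_boltzmann", "fit_adaptation", "extent_of_adaptation",
    "summarize_met_by_group",
]

#: onset-peak search window after step onset, ms (probe rise ~300 us plus filtering)
ONSET_WINDOW_MS = 10.0


@dataclass
class GxBoltzmannFit:
    """Conductance-displacement Boltzmann fit, nS vs nm."""

    g_max: float
    g_min: float
    x_half: float
    slope_s: float
    operating_range: float
    rss: float
    converged: bool

    @classmethod
    def from_params(cls, p: BoltzmannParams) -> "GxBoltzmannFit":
        return cls(g_max=p.g_max, g_min=p.g_min, x_half=p.u_half, slope_s=p.s,
                   operating_range=p.operating_range, rss=p.rss, converged=p.converged)


@dataclass
class AdaptationFit:
    """Multi-exponential adaptation decomposition at the half-activating step."""

    i_0: float  # pre-step current, pA
    i_peak: float
    i_ss: float
    a_vf: float | None = None
    a_f: float | None = None
    a_s: float | None = None
    tau_vf: float | None = None  # ms
    tau_f: float | None = None
    tau_s: float | None = None
    extent_pct: float = 0.0
    rss: float = np.nan

    @property
    def components_present(self) -> dict[str, bool]:
        return {"vf": self.tau_vf is not None,
                "f": self.tau_f is not None,
                "s": self.tau_s is not None}


@dataclass
class MetCurve:
    """Peak-conductance vs displacement curve of one cell."""

    displacements: np.ndarray  # nm
    conductances: np.ndarray  # nS


def _baseline(family: StepFamily) -> np.ndarray:
    """Per-step pre-onset mean current."""
    i_on = family.sample_index(family.step_onset)
    return family.traces[:, :i_on].mean(axis=1)


def _onset_peak(family: StepFamily, window_ms: float = ONSET_WINDOW_MS) -> tuple[np.ndarray, np.ndarray]:
    """Per-step peak current deviation in the onset window.

    Returns (peak current values, sample indices).  The peak is the extremum
    of |I - I_0| so inward (negative) and outward currents are handled alike.
    """
    i_on = family.sample_index(family.step_onset)
    i_end = min(family.sample_index(family.step_onset + window_ms), family.n_samples)
    base = _baseline(family)
    seg = family.traces[:, i_on:i_end] - base[:, None]
    idx = np.argmax(np.abs(seg), axis=1)
    peaks = family.traces[np.arange(family.n_steps), i_on + idx]
    return peaks, i_on + idx


def correct_voltages(family: StepFamily) -> StepFamily:
    """Apply offline liquid-junction and residual-series-resistance corrections.

    Per step, the effective membrane potential at the onset peak is

        V_eff = HP_commanded + V_junction - I_peak * Rs_residual

    with Rs_residual = (1 - compensated_fraction) * Rs_total and the product
    taken in nA * MOhm = mV.  Raises if the family was already corrected.
    """
    if family.corrected:
        raise ValueError("family is already voltage-corrected")
    meta = family.meta
    rs_residual = (1.0 - meta.rs_compensated_fraction) * meta.rs_total  # MOhm
    peaks, _ = _onset_peak(family)
    v_eff = (meta.holding_potential + meta.junction_potential
             - (peaks / 1000.0) * rs_residual)  # pA -> nA
    return replace(family, corrected=True, effective_potentials=v_eff)


def qc_met_cells(
    families: Sequence[StepFamily],
    responder_threshold: float = 20.0,
    analysis_threshold: float = 150.0,
) -> pd.DataFrame:
    """Label each cell non_responder / responder / analysis_set by peak |I_MET|.

    Cells below ``responder_threshold`` pA are non-responders; those above
    ``analysis_threshold`` enter the analysis set; the rest are responders
    kept out of quantitative analysis.
    """
    if len(families) == 0:
        raise ValueError("no families supplied")
    rows = []
    for i, fam in enumerate(families):
        peaks, _ = _onset_peak(fam)
        base = _baseline(fam)
        peak_abs = float(np.max(np.abs(peaks - base)))
        if peak_abs < responder_threshold:
            label = "non_responder"
        elif peak_abs > analysis_threshold:
            label = "analysis_set"
        else:
            label = "responder"
        rows.append({"cell": i, "peak_i_met_pa": peak_abs, "label": label})
    return pd.DataFrame(rows)


def met_conductance_curve(family: StepFamily) -> MetCurve:
    """Peak MET conductance versus displacement.

    G(X) = (I_peak_onset - I_0) / (V_eff - E_rev) per step, with the onset
    peak taken in a 0-10 ms window after the step and the pre-step current as
    baseline.  Requires a voltage-corrected displacement family.
    """
    if not family.corrected:
        raise ValueError("run correct_voltages first")
    if family.kind != "displacement":
        raise ValueError("met_conductance_curve expects a displacement family")
    peaks, _ = _onset_peak(family)
    base = _baseline(family)
    v_eff = family.effective_potentials
    driving = v_eff - family.meta.met_rev_potential  # mV
    if np.any(np.abs(driving) < 1e-9):
        raise ZeroDivisionError("degenerate driving force: V_eff equals E_rev")
    g = (peaks - base) / driving  # pA / mV = nS
    return MetCurve(displacements=family.step_levels.copy(), conductances=g)


def fit_gx_boltzmann(curve: MetCurve, seed: int = 0) -> GxBoltzmannFit:
    """Nonlinear least-squares Boltzmann fit of a G(X) curve; OR = S * ln 81."""
    p = fit_boltzmann(curve.displacements, curve.conductances, seed=seed)
    return GxBoltzmannFit.from_params(p)


def average_curves(curves: Iterable[MetCurve]) -> MetCurve:
    """Across-cell average of G(X) curves sharing one displacement grid."""
    curves = list(curves)
    x0 = curves[0].displacements
    for c in curves[1:]:
        if not np.allclose(c.displacements, x0):
            raise ValueError("curves must share a common displacement grid to average")
    g = np.mean([c.conductances for c in curves], axis=0)
    return MetCurve(displacements=x0.copy(), conductances=g)


# ---------------------------------------------------------------------------
# adaptation decomposition


def extent_of_adaptation(i_0: float, i_peak: float, i_ss: float) -> float:
    """Extent of adaptation in %: (I_peak - I_SS) / (I_peak - I_0) * 100.

    Signed currents as recorded (inward negative); pre-step, peak and
    steady-state currents in pA.
    """
    if i_peak == i_0:
        raise ZeroDivisionError("no evoked current: I_peak equals I_0")
    return 100.0 * (i_peak - i_ss) / (i_peak - i_0)


def _double_exp(t, a_f, tau_f, a_s, tau_s, i_ss):
    return a_f * np.exp(-t / tau_f) + a_s * np.exp(-t / tau_s) + i_ss


def _single_exp(t, a, tau, i_ss):
    return a * np.exp(-t / tau) + i_ss


def _triple_exp(t, a_vf, tau_vf, a_f, tau_f, a_s, tau_s, i_ss):
    return (a_vf * np.exp(-t / tau_vf) + a_f * np.exp(-t / tau_f)
            + a_s * np.exp(-t / tau_s) + i_ss)


def fit_adaptation(
    family: StepFamily,
    step_index: int | None = None,
    lowpass_hz: float | None = 1500.0,
    fit_window_ms: float = 300.0,
    vf_window_ms: float = 1.5,
    vf_residual_k: float = 3.0,
) -> AdaptationFit:
    """Decompose adaptation of the response at (or nearest to) X_1/2.

    Procedure: (i) fit two exponentials + steady state over ``fit_window_ms``
    from the current peak, with time constants bounded to the fast (1-10 ms)
    and slow (> 10 ms) classes; (ii) if the mean onset residual over the first
    ``vf_window_ms`` exceeds ``vf_residual_k`` times the RMS of later
    residuals, fit a single exponential over that onset window for the very
    fast component; (iii) drop components whose amplitude is indistinguishable
    from zero (< 2x the baseline noise SD) or whose tau pins at a bound.
    The extent of adaptation is (I_peak - I_SS)/(I_peak - I_0) * 100.
    """
    if step_index is None:
        # nearest step to the half-activation displacement of this family
        curve = met_conductance_curve(family if family.corrected else correct_voltages(family))
        try:
            half = fit_gx_boltzmann(curve).x_half
        except FitFailure:
            half = float(np.median(family.step_levels))
        step_index = int(np.argmin(np.abs(family.step_levels - half)))

    dt = family.sample_interval
    trace = family.traces[step_index].astype(float)
    if lowpass_hz is not None:
        trace = bessel_lowpass_zerophase(trace, lowpass_hz, 1000.0 / dt, order=4)

    i_on = family.sample_index(family.step_onset)
    i_0 = float(trace[:i_on].mean())
    noise_sd = float(trace[:i_on].std(ddof=1)) if i_on > 1 else 0.0

    i_win_end = min(family.sample_index(family.step_onset + ONSET_WINDOW_MS), trace.size)
    seg = np.abs(trace[i_on:i_win_end] - i_0)
    i_pk = i_on + int(np.argmax(seg))
    i_peak = float(trace[i_pk])

    n_fit = min(int(round(fit_window_ms / dt)), family.sample_index(family.step_offset) - i_pk)
    t = np.arange(n_fit) * dt
    y = trace[i_pk:i_pk + n_fit]
    sign = np.sign(i_peak - i_0) or 1.0

    decay0 = i_peak - y[-1]
    if abs(decay0) < max(3.0 * noise_sd, 1e-3 * abs(i_peak - i_0), 1e-12):
        # no discernible decay: peak not identifiable as an adapting response
        return AdaptationFit(i_0=i_0, i_peak=i_peak, i_ss=float(y[-1]), extent_pct=0.0)

    tau_bounds_lo = [-np.inf, 1.0, -np.inf, 10.0, -np.inf]
    tau_bounds_hi = [np.inf, 10.0, np.inf, 2000.0, np.inf]
    p0 = [decay0 / 2, 5.0, decay0 / 2, 100.0, float(y[-1])]
    popt, _ = curve_fit(_double_exp, t, y, p0=p0,
                        bounds=(tau_bounds_lo, tau_bounds_hi), maxfev=20000)
    a_f, tau_f, a_s, tau_s, i_ss = (float(v) for v in popt)
    resid = y - _double_exp(t, *popt)
    rss = float(resid @ resid)

    # very-fast detection: onset deviation of the double-exponential fit,
    # judged against the late-residual RMS (noise scale) with an absolute
    # floor so an exactly double-exponential trace never falsely triggers
    n_vf = max(int(round(vf_window_ms / dt)), 2)
    late = resid[min(n_vf * 4, resid.size // 2):]
    late_rms = float(np.sqrt(np.mean(late**2))) if late.size else 0.0
    onset_dev = float(np.mean(np.abs(resid[:n_vf])))
    a_vf = tau_vf = None
    if onset_dev > max(vf_residual_k * late_rms, 1e-3 * abs(decay0)):
        yv = y[:n_vf]
        tv = t[:n_vf]
        offset0 = float(_double_exp(tv[-1], *popt))
        try:
            pv, _ = curve_fit(_single_exp, tv, yv,
                              p0=[yv[0] - offset0, 0.4, offset0],
                              bounds=([-np.inf, 0.02, -np.inf], [np.inf, 1.5, np.inf]),
                              maxfev=20000)
            a_vf, tau_vf = float(pv[0]), float(pv[1])
        except RuntimeError:
            a_vf = tau_vf = None

    # refinement: joint multi-exponential fit excluding the first
    # ``refine_offset_ms`` after the peak, where low-pass filtering blurs the
    # rise/decay junction; beyond it a symmetric filter kernel rescales
    # exponential amplitudes but leaves every time constant intact
    refine_offset_ms = 0.5 * 1000.0 / lowpass_hz if lowpass_hz else 0.0
    j0 = int(round(refine_offset_ms / dt))
    tr, yr = t[j0:], y[j0:]
    try:
        if a_vf is not None:
            pr0 = [a_vf, min(max(tau_vf, 0.05), 1.4), a_f, tau_f, a_s, tau_s, i_ss]
            lo = [-np.inf, 0.02, -np.inf, 1.0, -np.inf, 10.0, -np.inf]
            hi = [np.inf, 1.5, np.inf, 10.0, np.inf, 2000.0, np.inf]
            pr, _ = curve_fit(_triple_exp, tr, yr, p0=pr0, bounds=(lo, hi), maxfev=40000)
            a_vf, tau_vf, a_f, tau_f, a_s, tau_s, i_ss = (float(v) for v in pr)
            resid_r = y - _triple_exp(t, *pr)
        else:
            pr, _ = curve_fit(_double_exp, tr, yr, p0=[a_f, tau_f, a_s, tau_s, i_ss],
                              bounds=(tau_bounds_lo, tau_bounds_hi), maxfev=40000)
            a_f, tau_f, a_s, tau_s, i_ss = (float(v) for v in pr)
            resid_r = y - _double_exp(t, *pr)
        rss = float(resid_r @ resid_r)
    except RuntimeError:
        pass  # keep the stage-wise estimates

    # component-drop rules: amplitude within noise, or tau pinned at a bound
    amp_floor = 2.0 * noise_sd
    def _keep(a: float | None, tau: float | None, lo: float, hi: float) -> bool:
        if a is None or tau is None:
            return False
        if abs(a) <= amp_floor or a * sign < 0:
            return False
        return not (np.isclose(tau, lo, rtol=1e-3) or np.isclose(tau, hi, rtol=1e-3))

    if not _keep(a_f, tau_f, 1.0, 10.0):
        a_f = tau_f = None
    if not _keep(a_s, tau_s, 10.0, 2000.0):
        a_s = tau_s = None
    if not _keep(a_vf, tau_vf, 0.02, 1.5) or (tau_vf is not None and tau_vf > 1.0):
        a_vf = tau_vf = None

    extent = extent_of_adaptation(i_0, i_peak, i_ss) if i_peak != i_0 else 0.0
    return AdaptationFit(i_0=i_0, i_peak=i_peak, i_ss=i_ss,
                         a_vf=a_vf, a_f=a_f, a_s=a_s,
                         tau_vf=tau_vf, tau_f=tau_f, tau_s=tau_s,
                         extent_pct=float(extent), rss=rss)


def summarize_met_by_group(
    fits: pd.DataFrame,
    by: Sequence[str] = ("genotype", "zone", "cell_type"),
) -> pd.DataFrame:
    """Per-group mean, SEM and n for every numeric fit parameter.

    ``fits`` is a tidy table (one row per cell) carrying the grouping columns;
    SEM is empty for singleton groups.
    """
    group_cols = [c for c in by if c in fits.columns]
    if not group_cols:
        raise ValueError("no grouping columns present in the fit table")
    value_cols = [c for c in fits.columns
                  if c not in group_cols and pd.api.types.is_numeric_dtype(fits[c])]
    if fits.empty:
        raise ValueError("empty fit table")
    agg = fits.groupby(list(group_cols), dropna=False)[value_cols].agg(
        ["mean", "sem", "count"])
    agg.columns = [f"{p}_{stat}" for p, stat in agg.columns]
    return agg.reset_index()
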