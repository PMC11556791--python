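"""Eye-movement quantification: quick-phase exclusion, sinusoidal VOR/OKR
gain and phase, OVAR decomposition, and VOR-learning gain change.

Sinusoidal fits are linear least squares at the known stimulus frequency
(offset + a*sin + b*cos), applied jointly over all clean cycles.  Gain is the
eye/head velocity amplitude ratio; phase uses the compensatory convention:
0 deg means the eye exactly opposes the head, positive values lead.

OVAR slow-phase eye velocity is decomposed into a decaying canal-mediated
transient C*exp(-t/tau) plus an otolith-mediated steady state
bias + modulation at the rotation frequency (rotation_velocity/360 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit

from .core import EyeHeadTrial

__all__ = [
    "SinusoidFit", "ReflexResult", "OvarDecomposition", "LearningResult",
    "wrap_phase_deg", "fit_sinusoid", "exclude_quick_phase_cycles",
    "fit_gain_phase", "decompose_ovar", "learning_change",
]


def wrap_phase_deg(phase: float) -> float:
    """Wrap a phase in degrees to (-180, 180]."""
    wrapped = (phase + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else float(wrapped)


@dataclass
class SinusoidFit:
    amplitude: float  # deg/s, >= 0
    phase: float  # degrees in (-180, 180]
    offset: float  # deg/s
    rss: float


@dataclass
class ReflexResult:
    frequency: float  # Hz
    gain: float
    phase: float  # degrees
    n_cycles_used: int
    n_cycles_excluded: int


@dataclass
class OvarDecomposition:
    transient_amplitude: float | None  # deg/s
    transient_tau: float | None  # s
    bias: float  # deg/s
    mod_amplitude: float  # deg/s
    mod_phase: float  # degrees
    mod_frequency: float  # Hz, rotation_velocity / 360
    rss: float


@dataclass
class LearningResult:
    gain_pre: float
    gain_post: float

    @property
    def pct_change(self) -> float:
        return 100.0 * (self.gain_post - self.gain_pre) / self.gain_pre


def fit_sinusoid(t: np.ndarray, y: np.ndarray, frequency: float) -> SinusoidFit:
    """Linear least-squares fit of y = offset + R*sin(2*pi*f*t + phi)."""
    w = 2 * np.pi * frequency * t
    design = np.column_stack([np.ones_like(t), np.sin(w), np.cos(w)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    off, a, b = (float(c) for c in coef)
    amp = float(np.hypot(a, b))
    phase = float(np.rad2deg(np.arctan2(b, a)))
    resid = y - design @ coef
    return SinusoidFit(amplitude=amp, phase=wrap_phase_deg(phase), offset=off,
                       rss=float(resid @ resid))


def _cycle_index(trial: EyeHeadTrial) -> np.ndarray:
    return np.floor(trial.stimulus_frequency * trial.time).astype(int)


def exclude_quick_phase_cycles(
    trial: EyeHeadTrial,
    velocity_threshold: float = 50.0,
    accel_threshold: float = 1000.0,
    smooth_ms: float = 25.0,
) -> tuple[list[int], np.ndarray]:
    """Flag stimulus cycles contaminated by quick phases.

    The slow-phase estimate is an initial sinusoid fit over the whole trial;
    samples whose residual velocity exceeds ``velocity_threshold`` (deg/s) or
    whose residual acceleration exceeds ``accel_threshold`` (deg/s^2) flag
    their containing cycle.  The residual is boxcar-smoothed over
    ``smooth_ms`` first so that sample-to-sample measurement noise does not
    masquerade as acceleration; quick phases (tens of ms) survive the
    smoothing.  Returns (clean cycle indices, per-sample flags).
    """
    if trial.stimulus_frequency is None:
        raise ValueError("trial has no stimulus frequency (not a sinusoidal trial)")
    fit = fit_sinusoid(trial.time, trial.eye_velocity, trial.stimulus_frequency)
    w = 2 * np.pi * trial.stimulus_frequency * trial.time
    model = fit.offset + fit.amplitude * np.sin(w + np.deg2rad(fit.phase))
    resid = trial.eye_velocity - model
    n_sm = max(int(round(smooth_ms * 1e-3 * trial.sample_rate)), 1)
    if n_sm > 1:
        resid = uniform_filter1d(resid, n_sm)
    accel = np.gradient(resid, trial.time)
    flags = (np.abs(resid) > velocity_threshold) | (np.abs(accel) > accel_threshold)
    cycles = _cycle_index(trial)
    n_cycles = int(cycles.max()) + 1
    bad = set(np.unique(cycles[flags]).tolist())
    clean = [c for c in range(n_cycles) if c not in bad]
    if not clean:
        raise ValueError("no clean cycles remain after quick-phase exclusion")
    return clean, flags


def fit_gain_phase(
    trial: EyeHeadTrial,
    clean_cycles: list[int] | None = None,
) -> ReflexResult:
    """Gain and phase of a sinusoidal reflex trial over clean cycles.

    Eye and head are each fit with offset + sin/cos terms at the stimulus
    frequency over the clean-cycle samples; gain = A_eye/A_head and
    phase = phase_eye - phase_head - 180 deg wrapped to (-180, 180], so a
    perfectly compensatory eye gives phase 0.
    """
    if trial.stimulus_frequency is None:
        raise ValueError("trial has no stimulus frequency")
    cycles = _cycle_index(trial)
    n_cycles = int(cycles.max()) + 1
    if clean_cycles is None:
        clean_cycles = list(range(n_cycles))
    if len(clean_cycles) < 3:
        raise ValueError("need >= 3 clean cycles")
    mask = np.isin(cycles, clean_cycles)
    t, eye, head = trial.time[mask], trial.eye_velocity[mask], trial.head_velocity[mask]
    fit_head = fit_sinusoid(t, head, trial.stimulus_frequency)
    if fit_head.amplitude < 1e-9:
        raise ValueError("degenerate stimulus: head velocity amplitude ~ 0")
    fit_eye = fit_sinusoid(t, eye, trial.stimulus_frequency)
    gain = fit_eye.amplitude / fit_head.amplitude
    phase = wrap_phase_deg(fit_eye.phase - fit_head.phase - 180.0)
    return ReflexResult(frequency=trial.stimulus_frequency, gain=float(gain),
                        phase=phase, n_cycles_used=len(clean_cycles),
                        n_cycles_excluded=n_cycles - len(clean_cycles))


def decompose_ovar(
    trial: EyeHeadTrial,
    steady_state_start: float = 20.0,
    transient_window: float = 15.0,
) -> OvarDecomposition:
    """Transient + steady-state decomposition of OVAR slow-phase eye velocity.

    The steady-state segment (t >= ``steady_state_start`` s from plateau
    onset) is fit by OLS to bias + a*sin + b*cos at the rotation frequency;
    the transient is a single exponential fit to the steady-state-model-
    subtracted initial segment (t < ``transient_window`` s).  The two fits
    are alternated a few times so that any transient tail still present in
    the steady-state segment is removed from the bias estimate.  If no
    transient is resolvable its amplitude and tau are reported as None.
    """
    if trial.rotation_velocity is None:
        raise ValueError("trial has no rotation velocity (not an OVAR trial)")
    f_mod = trial.rotation_velocity / 360.0
    tp = trial.time - trial.plateau_start
    on_plateau = tp >= 0
    t_end = tp[on_plateau][-1]
    if t_end - steady_state_start < 2.0 / f_mod:
        raise ValueError("steady-state segment shorter than two rotations")

    ss = on_plateau & (tp >= steady_state_start)
    early = on_plateau & (tp < transient_window)
    te = tp[early]

    transient_amp: float | None = None
    transient_tau: float | None = None
    eye_minus_transient = trial.eye_velocity
    for _ in range(3):
        fit = fit_sinusoid(tp[ss], eye_minus_transient[ss], f_mod)
        w = 2 * np.pi * f_mod * tp
        ss_model = fit.offset + fit.amplitude * np.sin(w + np.deg2rad(fit.phase))
        resid = trial.eye_velocity[early] - ss_model[early]
        resid_scale = float(np.max(np.abs(resid))) if resid.size else 0.0
        if resid_scale <= 1e-9:
            break
        try:
            popt, _ = curve_fit(
                lambda t, c, tau: c * np.exp(-t / tau), te, resid,
                p0=[resid[0] if resid[0] != 0 else resid_scale, 3.0],
                bounds=([-np.inf, 1e-3], [np.inf, 1e3]), maxfev=10000)
        except RuntimeError:
            break
        transient_amp, transient_tau = float(popt[0]), float(popt[1])
        eye_minus_transient = trial.eye_velocity - np.where(
            on_plateau, transient_amp * np.exp(-np.maximum(tp, 0.0) / transient_tau), 0.0)
    if transient_amp is not None and abs(transient_amp) < 1e-9:
        transient_amp = transient_tau = None

    return OvarDecomposition(
        transient_amplitude=transient_amp, transient_tau=transient_tau,
        bias=fit.offset, mod_amplitude=fit.amplitude, mod_phase=fit.phase,
        mod_frequency=f_mod, rss=fit.rss)


def learning_change(pre: ReflexResult, post: ReflexResult) -> LearningResult:
    """Percent VOR gain change after training; negative for gain-down."""
    if pre.frequency != post.frequency:
        raise ValueError("pre and post trials must share the test frequency")
    if pre.gain == 0:
        raise ValueError("pre-training gain is zero; percent change undefined")
    return LearningResult(gain_pre=pre.gain, gain_post=post.gain)
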