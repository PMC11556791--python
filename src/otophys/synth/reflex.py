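"""Synthetic sinusoidal eye/head velocity trials (VOR, OKR) and OVAR trials.

Sinusoidal trials: head velocity A*sin(2*pi*f*t); compensatory eye velocity
-gain*A*sin(2*pi*f*t + phase) plus noise, with optional quick-phase
transients (brief high-velocity half-sines) superimposed.  Ground truth marks
which stimulus cycles a quick phase contaminates.

OVAR trials: a 500 ms velocity ramp to the rotation velocity, then a constant
plateau during which slow-phase eye velocity follows
transient*exp(-t/tau) + bias + mod*sin(2*pi*f_mod*t + phase), with the
modulation frequency locked to rotation_velocity/360 (one cycle per
revolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ..core import EyeHeadTrial, GroundTruth

__all__ = [
    "ReflexSimConfig", "simulate_reflex_trial", "simulate_reflex_trials",
    "OvarSimConfig", "simulate_ovar_trial",
]

#: testing frequencies used on the turntable, Hz
DEFAULT_FREQUENCIES = (0.2, 0.4, 0.8, 1.0, 2.0, 3.0)


@dataclass
class ReflexSimConfig:
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    head_peak_velocity: float = 16.0  # deg/s
    true_gain: dict[float, float] = field(default_factory=dict)  # per frequency
    true_phase_deg: dict[float, float] = field(default_factory=dict)
    default_gain: float = 0.7
    default_phase_deg: float = 0.0
    quick_phase_rate: float = 0.0  # events/s, Poisson
    quick_phase_amplitude: float = 150.0  # deg/s
    quick_phase_duration: float = 0.03  # s, <= 50 ms
    quick_phase_cycles: tuple[int, ...] | None = None  # force QPs into these cycles
    n_cycles: int = 10
    sample_rate: float = 1000.0  # Hz
    noise_sd: float = 0.0  # deg/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 3:
            raise ValueError("need >= 3 stimulus cycles")
        if self.quick_phase_duration > 0.05:
            raise ValueError("quick phases must be <= 50 ms")
        for f in self.frequencies:
            g = self.gain_at(f)
            p = self.phase_at(f)
            if g < 0:
                raise ValueError("gains must be >= 0")
            if not -180.0 < p <= 180.0:
                raise ValueError("phases must lie in (-180, 180]")

    def gain_at(self, f: float) -> float:
        return self.true_gain.get(f, self.default_gain)

    def phase_at(self, f: float) -> float:
        return self.true_phase_deg.get(f, self.default_phase_deg)


def _add_quick_phases(
    eye: np.ndarray, t: np.ndarray, cfg: ReflexSimConfig, freq: float, rng
) -> set[int]:
    """Superimpose half-sine quick phases; return contaminated cycle indices."""
    fs = cfg.sample_rate
    n_qp_samples = max(int(round(cfg.quick_phase_duration * fs)), 2)
    qp = np.sin(np.pi * np.arange(n_qp_samples) / (n_qp_samples - 1))
    onsets: list[float] = []
    if cfg.quick_phase_cycles is not None:
        period = 1.0 / freq
        for c in cfg.quick_phase_cycles:
            onsets.append((c + 0.5) * period - cfg.quick_phase_duration / 2)
    elif cfg.quick_phase_rate > 0:
        n_events = rng.poisson(cfg.quick_phase_rate * t[-1])
        onsets.extend(rng.uniform(0, t[-1] - cfg.quick_phase_duration, size=n_events))
    contaminated: set[int] = set()
    for onset in onsets:
        i0 = int(round(onset * fs))
        if i0 >= eye.size:
            continue
        sign = 1.0 if rng.random() < 0.5 else -1.0
        seg = qp[: eye.size - i0]
        eye[i0:i0 + seg.size] += sign * cfg.quick_phase_amplitude * seg
        contaminated.update({int(freq * t[i0]), int(freq * t[min(i0 + seg.size - 1, eye.size - 1)])})
    return {c for c in contaminated if c < cfg.n_cycles}


def simulate_reflex_trial(
    cfg: ReflexSimConfig, frequency: float | None = None
) -> tuple[EyeHeadTrial, GroundTruth]:
    """One sinusoidal trial at ``frequency`` (default: first configured)."""
    freq = cfg.frequencies[0] if frequency is None else frequency
    gain, phase_deg = cfg.gain_at(freq), cfg.phase_at(freq)
    fs = cfg.sample_rate
    n = int(round(cfg.n_cycles / freq * fs))
    t = np.arange(n) / fs
    a = cfg.head_peak_velocity
    head = a * np.sin(2 * np.pi * freq * t)
    eye = -gain * a * np.sin(2 * np.pi * freq * t + np.deg2rad(phase_deg))

    rng = np.random.default_rng(cfg.seed + int(round(1000 * freq)))
    contaminated = _add_quick_phases(eye, t, cfg, freq, rng)
    if cfg.noise_sd > 0:
        eye = eye + rng.normal(0, cfg.noise_sd, n)

    trial = EyeHeadTrial(time=t, eye_velocity=eye, head_velocity=head,
                         sample_rate=fs, stimulus_frequency=freq)
    params = asdict(cfg)
    params.update(frequency=freq, gain=gain, phase_deg=phase_deg,
                  contaminated_cycles=sorted(contaminated))
    truth = GroundTruth(generator="reflex_trial", seed=cfg.seed, params=params)
    return trial, truth


def simulate_reflex_trials(cfg: ReflexSimConfig) -> list[tuple[EyeHeadTrial, GroundTruth]]:
    """One trial per configured frequency."""
    return [simulate_reflex_trial(cfg, f) for f in cfg.frequencies]


@dataclass
class OvarSimConfig:
    rotation_velocity: float = 50.0  # deg/s
    ramp_duration: float = 0.5  # s
    plateau_duration: float = 72.0  # s (10 revolutions at 50 deg/s)
    transient_amplitude: float = 10.0  # deg/s
    transient_tau: float = 5.0  # s
    bias: float = 3.85  # deg/s, steady-state otolithic bias
    mod_amplitude: float = 2.0  # deg/s
    mod_phase_deg: float = 30.0
    noise_sd: float = 0.0  # deg/s
    sample_rate: float = 1000.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transient_tau <= 0:
            raise ValueError("transient_tau must be positive")
        if self.plateau_duration < 360.0 / self.rotation_velocity:
            raise ValueError("plateau must cover at least one full rotation")

    @property
    def mod_frequency(self) -> float:
        """Modulation frequency, Hz: one cycle per revolution."""
        return self.rotation_velocity / 360.0


def simulate_ovar_trial(cfg: OvarSimConfig) -> tuple[EyeHeadTrial, GroundTruth]:
    fs = cfg.sample_rate
    n_ramp = int(round(cfg.ramp_duration * fs))
    n_plateau = int(round(cfg.plateau_duration * fs))
    n = n_ramp + n_plateau
    t = np.arange(n) / fs

    head = np.empty(n)
    head[:n_ramp] = cfg.rotation_velocity * np.arange(n_ramp) / max(n_ramp, 1)
    head[n_ramp:] = cfg.rotation_velocity

    tp = t[n_ramp:] - t[n_ramp]  # time from plateau start
    eye = np.zeros(n)
    eye[n_ramp:] = (
        cfg.transient_amplitude * np.exp(-tp / cfg.transient_tau)
        + cfg.bias
        + cfg.mod_amplitude * np.sin(2 * np.pi * cfg.mod_frequency * tp
                                     + np.deg2rad(cfg.mod_phase_deg))
    )
    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_sd > 0:
        eye = eye + rng.normal(0, cfg.noise_sd, n)

    trial = EyeHeadTrial(time=t, eye_velocity=eye, head_velocity=head,
                         sample_rate=fs, rotation_velocity=cfg.rotation_velocity,
                         plateau_start=cfg.ramp_duration)
    truth = GroundTruth(generator="ovar_trial", seed=cfg.seed, params=asdict(cfg))
    return trial, truth
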