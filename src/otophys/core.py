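"""Shared containers for step-protocol recordings and trial data.

Unit conventions, fixed package-wide: cellular signals use ms / nm / pA / mV /
nS; behavioral signals use s and deg/s.  A conductance in nS times a driving
force in mV is a current in pA, so no unit constants appear in the math.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Optional

import numpy as np

__all__ = ["RecordingMeta", "StepFamily", "EyeHeadTrial", "MotionRecording", "GroundTruth"]

#: axis order for 6-axis head-motion recordings
MOTION_CHANNELS = ("fore_aft", "lateral", "vertical", "roll", "pitch", "yaw")


@dataclass
class RecordingMeta:
    """Whole-cell recording metadata needed for offline corrections.

    ``holding_potential`` is the commanded holding potential (mV);
    ``junction_potential`` the liquid junction potential added offline;
    ``rs_total`` total series resistance (MOhm) of which
    ``rs_compensated_fraction`` was compensated on-line by the amplifier.
    """

    holding_potential: float = -94.0
    met_rev_potential: float = 0.2
    rs_total: float = 8.1
    rs_compensated_fraction: float = 0.8
    junction_potential: float = -4.0
    cell_type: str = "typeI"
    zone: str = "LES"
    genotype: str = "control"
    cm: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rs_compensated_fraction <= 1.0:
            raise ValueError("rs_compensated_fraction must be in [0, 1]")


@dataclass
class StepFamily:
    """A family of identically timed steps with one response trace per step.

    ``step_levels`` carries the iterated stimulus value per step (nm for
    displacement, mV for voltage, pA for current steps); ``traces`` is an
    (n_steps, n_samples) array of responses (pA or mV); times are in ms.
    """

    step_levels: np.ndarray
    traces: np.ndarray
    sample_interval: float
    step_onset: float
    step_offset: float
    kind: str = "displacement"  # displacement | voltage | current
    n_repeats: int = 1
    meta: RecordingMeta = field(default_factory=RecordingMeta)
    stimulus: Optional[np.ndarray] = None  # filtered command, same shape as traces
    corrected: bool = False
    effective_potentials: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.step_levels = np.asarray(self.step_levels, dtype=float)
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        d = np.diff(self.step_levels)
        if self.step_levels.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("step_levels must be strictly monotonic")
        if self.traces.shape[0] != self.step_levels.size:
            raise ValueError("one trace per step level required")
        if not 0 <= self.step_onset < self.step_offset <= self.duration:
            raise ValueError("require 0 <= onset < offset <= trace end")

    @property
    def n_steps(self) -> int:
        return int(self.step_levels.size)

    @property
    def n_samples(self) -> int:
        return int(self.traces.shape[1])

    @property
    def duration(self) -> float:
        return self.traces.shape[1] * self.sample_interval

    @property
    def time(self) -> np.ndarray:
        """Sample times in ms, starting at 0."""
        return np.arange(self.n_samples) * self.sample_interval

    def sample_index(self, t_ms: float) -> int:
        return int(round(t_ms / self.sample_interval))


@dataclass
class EyeHeadTrial:
    """Eye and head (or visual-surround) velocity over one trial; units s, deg/s."""

    time: np.ndarray
    eye_velocity: np.ndarray
    head_velocity: np.ndarray
    sample_rate: float
    stimulus_frequency: Optional[float] = None  # Hz, sinusoidal trials
    rotation_velocity: Optional[float] = None  # deg/s, OVAR trials
    plateau_start: float = 0.0  # s, OVAR: time the constant-velocity plateau begins

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.eye_velocity = np.asarray(self.eye_velocity, dtype=float)
        self.head_velocity = np.asarray(self.head_velocity, dtype=float)
        if not self.time.shape == self.eye_velocity.shape == self.head_velocity.shape:
            raise ValueError("time, eye and head series must have equal length")
        dt = np.diff(self.time)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("sampling must be uniform")


@dataclass
class MotionRecording:
    """Six-axis resting head motion: 3 linear accelerations + 3 angular velocities."""

    channels: dict[str, np.ndarray]
    sample_rate: float = 200.0

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        n = len(next(iter(self.channels.values())))
        return n / self.sample_rate


@dataclass
class GroundTruth:
    """Generator parameters paired with a synthetic dataset, for recovery scoring."""

    generator: str
    seed: int
    params: dict[str, Any]
    version: str = "otophys-synth-1"

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
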