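"""Synthetic afferent (calyx) responses to current steps.

The generator is phenomenological: it places stereotyped spike waveforms on a
passive membrane-potential baseline, because the downstream analysis consumes
spike times and counts only.  Steps at or above ``true_threshold`` spike;
the transient pattern fires 1-2 onset spikes, the sustained pattern fires at
``sustained_rate`` throughout the step.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np

from ..core import GroundTruth, RecordingMeta, StepFamily

__all__ = ["AfferentSimConfig", "simulate_afferent_response"]


@dataclass
class StepProtocol:
    start: float = -200.0  # pA
    increment: float = 50.0  # pA
    n_steps: int = 14  # -200 .. +450 pA
    duration: float = 500.0  # ms

    def __post_init__(self) -> None:
        if self.increment <= 0:
            raise ValueError("increment must be positive")

    @property
    def levels(self) -> np.ndarray:
        return self.start + self.increment * np.arange(self.n_steps)


@dataclass
class AfferentSimConfig:
    true_threshold: float = 100.0  # pA, smallest spiking step
    pattern: str = "sustained"  # transient | sustained
    resting_potential: float = -65.0  # mV
    sustained_rate: float = 50.0  # spikes/s
    step_protocol: StepProtocol = field(default_factory=StepProtocol)
    input_resistance: float = 0.05  # GOhm, passive depolarization scale
    spike_jitter_ms: float = 0.0  # SD of spike-time jitter
    noise_sd: float = 0.0  # mV, membrane noise
    sample_interval: float = 0.1  # ms
    pre_duration: float = 20.0  # ms
    post_duration: float = 20.0  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in ("transient", "sustained"):
            raise ValueError("pattern must be transient or sustained")


_SPIKE_PEAK = 20.0  # mV
_SPIKE_HALF_WIDTH = 0.5  # ms rise and fall


def _spike_waveform(dt: float) -> np.ndarray:
    """Triangular spike rising to +20 mV; added on top of the baseline."""
    n_half = max(int(round(_SPIKE_HALF_WIDTH / dt)), 1)
    up = np.linspace(0.0, 1.0, n_half + 1)[1:]
    down = np.linspace(1.0, 0.0, n_half + 1)[1:]
    return np.concatenate([up, down])


def _spike_times_for_step(cfg: AfferentSimConfig, level: float, rng) -> np.ndarray:
    """Spike times in ms from step onset; empty below threshold."""
    if level < cfg.true_threshold:
        return np.array([])
    dur = cfg.step_protocol.duration
    if cfg.pattern == "transient":
        # 1-2 onset spikes: stronger drive recruits the second
        times = [2.0] if level < 2 * cfg.true_threshold else [2.0, 8.0]
    else:
        isi = 1000.0 / cfg.sustained_rate
        times = list(np.arange(2.0, dur - 2.0, isi))
    times = np.asarray(times, dtype=float)
    if cfg.spike_jitter_ms > 0:
        jittered = times + rng.normal(0, cfg.spike_jitter_ms, times.size)
        # clip into the step so jitter never deletes a spike
        times = np.sort(np.clip(jittered, 0.5, dur - 1.0))
    return times


def simulate_afferent_response(cfg: AfferentSimConfig) -> tuple[StepFamily, GroundTruth]:
    dt = cfg.sample_interval
    proto = cfg.step_protocol
    n_pre = int(round(cfg.pre_duration / dt))
    n_step = int(round(proto.duration / dt))
    n_post = int(round(cfg.post_duration / dt))
    n_total = n_pre + n_step + n_post

    rng = np.random.default_rng(cfg.seed)
    levels = proto.levels
    spike = _spike_waveform(dt)
    traces = np.full((levels.size, n_total), cfg.resting_potential)
    all_times: list[list[float]] = []
    for i, level in enumerate(levels):
        # passive response, capped below the spike-detection range
        v_dep = min(level * cfg.input_resistance, 25.0)  # pA * GOhm = mV
        traces[i, n_pre:n_pre + n_step] += v_dep
        times = _spike_times_for_step(cfg, level, rng)
        all_times.append([float(t) for t in times])
        base = cfg.resting_potential + v_dep
        amp = _SPIKE_PEAK - base
        for t in times:
            j = n_pre + int(round(t / dt))
            seg = spike[: n_total - j]
            traces[i, j:j + seg.size] = base + amp * seg
    if cfg.noise_sd > 0:
        traces = traces + rng.normal(0, cfg.noise_sd, traces.shape)

    family = StepFamily(
        step_levels=levels,
        traces=traces,
        sample_interval=dt,
        step_onset=cfg.pre_duration,
        step_offset=cfg.pre_duration + proto.duration,
        kind="current",
        meta=RecordingMeta(holding_potential=cfg.resting_potential, cell_type="afferent"),
    )
    params = asdict(cfg)
    params["spike_times_truth"] = all_times
    truth = GroundTruth(generator="afferent_response", seed=cfg.seed, params=params)
    return family, truth
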