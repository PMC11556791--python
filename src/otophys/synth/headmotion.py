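"""Synthetic 6-axis resting head-motion recordings.

Emulates a head-mounted MEMS sensor (3-axis accelerometer + 3-axis gyroscope)
sampled at 200 Hz: independent white Gaussian noise per channel, with an
optional sinusoidal tremor added to selected channels.
"""

from __future__ import annotations

import numpy as np

from ..core import MOTION_CHANNELS, GroundTruth, MotionRecording

__all__ = ["simulate_headmotion"]


def simulate_headmotion(
    duration: float = 120.0,
    fs: float = 200.0,
    tremor_freq: float | None = None,
    tremor_amp: float = 0.0,
    tremor_channels: tuple[str, ...] = MOTION_CHANNELS,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[MotionRecording, GroundTruth]:
    """White-noise 6-axis recording with an optional tremor band.

    ``tremor_freq`` must lie below Nyquist (fs/2); ``tremor_amp`` of 0
    disables the tremor regardless of frequency.
    """
    if tremor_freq is not None and tremor_amp > 0 and tremor_freq >= fs / 2:
        raise ValueError(f"tremor_freq {tremor_freq} Hz at or above Nyquist {fs / 2} Hz")
    unknown = set(tremor_channels) - set(MOTION_CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    channels: dict[str, np.ndarray] = {}
    for name in MOTION_CHANNELS:
        x = rng.normal(0.0, noise_sd, n)
        if tremor_freq is not None and tremor_amp > 0 and name in tremor_channels:
            x = x + tremor_amp * np.sin(2 * np.pi * tremor_freq * t)
        channels[name] = x

    rec = MotionRecording(channels=channels, sample_rate=fs)
    truth = GroundTruth(
        generator="headmotion", seed=seed,
        params=dict(duration=duration, fs=fs, tremor_freq=tremor_freq,
                    tremor_amp=tremor_amp, tremor_channels=list(tremor_channels),
                    noise_sd=noise_sd),
    )
    return rec, truth
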