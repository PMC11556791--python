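"""Low-pass filtering utilities shared by the generators and the analysis code.

Patch-clamp rigs condition both the stimulus command and the recorded current
with 8-pole Bessel low-pass filters, whose near-linear phase preserves step
edges without ringing.  The discrete filters here are bilinear-transform
digitizations of the analog prototype with the cutoff placed at the -3 dB
point (``norm='mag'``), which is how bench-top Bessel filters are specified.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = ["bessel_sos", "bessel_lowpass", "bessel_lowpass_zerophase", "rise_time_10_90"]


def bessel_sos(cutoff_hz: float, fs_hz: float, order: int = 8) -> np.ndarray:
    """Second-order sections of an order-``order`` Bessel low-pass.

    Parameters
    ----------
    cutoff_hz : -3 dB cutoff frequency in Hz; must be below Nyquist.
    fs_hz : sampling rate in Hz.
    order : filter order (poles); 8 matches the hardware used on MET rigs.
    """
    if not 0 < cutoff_hz < fs_hz / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, fs/2={fs_hz / 2}) Hz")
    return signal.bessel(order, cutoff_hz, btype="low", norm="mag", output="sos", fs=fs_hz)


def bessel_lowpass(x: np.ndarray, cutoff_hz: float, fs_hz: float, order: int = 8) -> np.ndarray:
    """Causal Bessel low-pass, as applied on-line to stimulus commands."""
    sos = bessel_sos(cutoff_hz, fs_hz, order)
    # steady initial conditions: pre-charge the filter with the first sample
    zi = signal.sosfilt_zi(sos) * x[..., :1]
    y, _ = signal.sosfilt(sos, x, zi=zi)
    return y


def bessel_lowpass_zerophase(
    x: np.ndarray, cutoff_hz: float, fs_hz: float, order: int = 8
) -> np.ndarray:
    """Zero-phase (forward-backward) Bessel low-pass for offline filtering.

    ``order`` is the per-pass order; the magnitude response is squared by the
    two passes, so order=4 here matches the roll-off of an 8-pole single pass.
    """
    sos = bessel_sos(cutoff_hz, fs_hz, order)
    return signal.sosfiltfilt(sos, x, axis=-1)


def rise_time_10_90(t: np.ndarray, y: np.ndarray) -> float:
    """10-90% rise time of a step response, in the units of ``t``.

    The final value is the mean of the last 5% of samples; threshold times are
    linearly interpolated between bracketing samples.
    """
    y = np.asarray(y, dtype=float)
    yf = float(np.mean(y[int(0.95 * y.size):]))
    y0 = float(y[0])
    span = yf - y0
    if span == 0:
        raise ValueError("flat trace has no rise time")

    def _crossing(level: float) -> float:
        idx = np.argmax(y >= level) if span > 0 else np.argmax(y <= level)
        if idx == 0:
            return float(t[0])
        f = (level - y[idx - 1]) / (y[idx] - y[idx - 1])
        return float(t[idx - 1] + f * (t[idx] - t[idx - 1]))

    return _crossing(y0 + 0.9 * span) - _crossing(y0 + 0.1 * span)
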