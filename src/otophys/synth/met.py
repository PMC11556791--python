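"""Synthetic mechanotransduction (MET) current step families.

The generator emulates voltage-clamp recordings of hair-cell MET currents
evoked by force-probe displacement steps.  Per displacement X the peak
conductance follows a first-order Boltzmann G(X); the command step is shaped
by the rig's 8-pole Bessel low-pass (1 kHz, ~300 us 10-90% rise), and the
current then adapts toward steady state as a sum of up to three exponential
components (very fast < 1 ms, fast 1-10 ms, slow > 10 ms).

The recorded current is referenced to the pre-step level, at which the
resting conductance equals G_min (steps begin slightly negative of the
resting bundle position), so noiseless per-step peaks reproduce
G(X) * (HP - E_rev) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ..boltzmann import boltzmann
from ..core import GroundTruth, RecordingMeta, StepFamily
from ..filters import bessel_sos
from scipy import signal

__all__ = ["MetSimConfig", "simulate_met_family"]

_TAU_BINS = {"vf": (0.0, 1.0), "f": (1.0, 10.0), "s": (10.0, np.inf)}


@dataclass
class MetSimConfig:
    """Parameters of a synthetic MET step family; units ms / nm / pA / mV / nS."""

    g_max: float = 2.75  # nS
    g_min: float = 0.0  # nS
    x_half: float = 250.0  # nm
    slope_s: float = 175.0  # nm
    holding_potential: float = -94.0  # mV (type I convention)
    rev_potential: float = 0.2  # mV
    step_start: float = -70.0  # nm, slightly negative of rest
    step_increment: float = 35.0  # nm
    n_steps: int = 40
    step_duration: float = 400.0  # ms
    n_repeats: int = 3
    # adaptation time constants, ms; None disables the component
    tau_vf: float | None = 0.6
    tau_f: float | None = 6.0
    tau_s: float | None = 100.0
    # fraction of the peak (over-baseline) current decaying per component
    adapt_fractions: dict[str, float] = field(
        default_factory=lambda: {"vf": 0.25, "f": 0.3, "s": 0.2}
    )
    probe_cutoff: float = 1000.0  # Hz, command low-pass
    sample_interval: float = 0.02  # ms (50 kHz)
    pre_duration: float = 10.0  # ms of baseline before the step
    post_duration: float = 10.0  # ms after step offset
    noise_sd: float = 0.0  # pA
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.g_max >= self.g_min >= 0:
            raise ValueError("require g_max >= g_min >= 0")
        if self.slope_s <= 0:
            raise ValueError("slope_s must be positive")
        if self.tau_vf is not None and not 0 < self.tau_vf < 1:
            raise ValueError(f"tau_vf={self.tau_vf} ms must be < 1 ms")
        if self.tau_f is not None and not 1 <= self.tau_f <= 10:
            raise ValueError(f"tau_f={self.tau_f} ms must lie in [1, 10] ms")
        if self.tau_s is not None and not self.tau_s > 10:
            raise ValueError(f"tau_s={self.tau_s} ms must be > 10 ms")
        enabled = self.enabled_components()
        frac_sum = sum(self.adapt_fractions.get(k, 0.0) for k in enabled)
        if frac_sum > 1.0 + 1e-12:
            raise ValueError("enabled adapt_fractions must sum to <= 1")

    def enabled_components(self) -> list[str]:
        return [k for k, tau in (("vf", self.tau_vf), ("f", self.tau_f), ("s", self.tau_s))
                if tau is not None and self.adapt_fractions.get(k, 0.0) > 0]

    def tau_of(self, component: str) -> float:
        return {"vf": self.tau_vf, "f": self.tau_f, "s": self.tau_s}[component]


def _filtered_step_shape(cfg: MetSimConfig, n_rise: int) -> tuple[np.ndarray, int]:
    """Unit step response of the probe filter and the index where it first
    reaches its final value (the 8-pole Bessel overshoots ~0.3%, so a first
    crossing exists)."""
    fs_hz = 1000.0 / cfg.sample_interval
    sos = bessel_sos(cfg.probe_cutoff, fs_hz, order=8)
    w = signal.sosfilt(sos, np.ones(n_rise))
    crossing = np.nonzero(w >= 1.0)[0]
    i_pk = int(crossing[0]) if crossing.size else int(np.argmax(w))
    return w, i_pk


def _adaptation_factor(cfg: MetSimConfig, t_ms: np.ndarray) -> np.ndarray:
    """Multiplicative decay factor a(t), t measured from the current peak."""
    a = np.ones_like(t_ms)
    for comp in cfg.enabled_components():
        f = cfg.adapt_fractions[comp]
        a -= f * (1.0 - np.exp(-t_ms / cfg.tau_of(comp)))
    return a


def simulate_met_family(cfg: MetSimConfig) -> tuple[StepFamily, GroundTruth]:
    """Simulate one MET displacement-step family (repeats averaged).

    Returns the family plus a :class:`GroundTruth` record carrying every
    generator parameter, sufficient to score any downstream fit.
    """
    dt = cfg.sample_interval
    n_pre = int(round(cfg.pre_duration / dt))
    n_step = int(round(cfg.step_duration / dt))
    n_post = int(round(cfg.post_duration / dt))
    n_total = n_pre + n_step + n_post

    levels = cfg.step_start + cfg.step_increment * np.arange(cfg.n_steps)
    driving = cfg.holding_potential - cfg.rev_potential  # mV; nS*mV = pA

    w, i_pk = _filtered_step_shape(cfg, n_step)
    # normalized response shape on the step epoch: filter rise to exactly 1
    # at i_pk, then multi-exponential adaptation
    shape = np.empty(n_step)
    shape[: i_pk + 1] = np.clip(w[: i_pk + 1] / w[i_pk], 0.0, None)
    t_decay = (np.arange(n_step - i_pk - 1) + 1) * dt
    shape[i_pk + 1:] = _adaptation_factor(cfg, t_decay)

    g_peak = boltzmann(levels, cfg.g_max, cfg.g_min, cfg.x_half, cfg.slope_s)
    delta_g = g_peak - cfg.g_min  # conductance recruited above rest

    clean = np.zeros((cfg.n_steps, n_total))
    clean[:, n_pre:n_pre + n_step] = driving * delta_g[:, None] * shape[None, :]
    # offset: release follows the filtered falling edge from the final in-step value
    w_post = w[:n_post] if n_post <= n_step else np.pad(
        w, (0, n_post - n_step), constant_values=w[-1])[:n_post]
    fall = 1.0 - np.clip(w_post / w[i_pk], 0.0, 1.0)
    clean[:, n_pre + n_step:] = clean[:, [n_pre + n_step - 1]] * fall[None, :]

    rng = np.random.default_rng(cfg.seed)
    traces = clean.copy()
    if cfg.noise_sd > 0:
        noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_repeats, cfg.n_steps, n_total))
        traces = clean[None, :, :] + noise
        traces = traces.mean(axis=0)

    stim = np.zeros((cfg.n_steps, n_total))
    stim[:, n_pre:n_pre + n_step] = levels[:, None] * w[None, :]
    stim[:, n_pre + n_step:] = stim[:, [n_pre + n_step - 1]] * fall[None, :]

    # ideal clamp: commanded potential is the effective potential (junction
    # already folded in, series resistance fully compensated)
    meta = RecordingMeta(
        holding_potential=cfg.holding_potential,
        met_rev_potential=cfg.rev_potential,
        junction_potential=0.0,
        rs_compensated_fraction=1.0,
    )
    family = StepFamily(
        step_levels=levels,
        traces=traces,
        sample_interval=dt,
        step_onset=cfg.pre_duration,
        step_offset=cfg.pre_duration + cfg.step_duration,
        kind="displacement",
        n_repeats=cfg.n_repeats,
        meta=meta,
        stimulus=stim,
    )
    params = asdict(cfg)
    params["extent_pct_truth"] = 100.0 * sum(
        cfg.adapt_fractions[c] for c in cfg.enabled_components()
    )
    truth = GroundTruth(generator="met_family", seed=cfg.seed, params=params)
    return family, truth
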