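"""Synthetic voltage-gated K+ current families (type I and type II hair cells).

Protocol: a pre-pulse (default -124 mV) to remove activation, iterated 400 ms
test steps in 5 mV increments, then a common tail step (default -39 mV) whose
instantaneous current reports the open probability reached at the end of the
test step.  Steady-state activation is a first-order Boltzmann in voltage;
type II cells additionally show partial inactivation over the test step.

Activation is treated as instantaneous: the analysis reads steady-state and
tail levels only, so activation kinetics carry no information here.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from ..boltzmann import boltzmann
from ..core import GroundTruth, RecordingMeta, StepFamily

__all__ = ["VgSimConfig", "simulate_vg_family", "type_i_config", "type_ii_config"]


@dataclass
class VgSimConfig:
    """Voltage-step family parameters; units ms / mV / pA / nS / pF."""

    cell_type: str = "typeII"  # typeI (g_K,L) | typeII (delayed rectifier)
    v_half: float = -35.0  # mV
    slope_v: float = 6.0  # mV
    g_max_density: float = 5.0  # nS/pF
    cm: float = 5.0  # pF
    e_k: float = -84.0  # mV, K+ equilibrium potential
    prepulse_potential: float = -124.0  # mV
    test_start: float = -124.0  # mV
    test_end: float = -14.0  # mV
    test_increment: float = 5.0  # mV
    tail_potential: float = -39.0  # mV
    test_duration: float = 400.0  # ms
    prepulse_duration: float = 50.0  # ms
    tail_duration: float = 20.0  # ms
    inactivation_tau: float = 50.0  # ms, type II only
    inactivating_fraction: float = 0.0  # type II only
    g_min: float = 0.0  # nS, residual conductance floor
    sample_interval: float = 0.1  # ms
    noise_sd: float = 0.0  # pA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_type not in ("typeI", "typeII"):
            raise ValueError("cell_type must be typeI or typeII")
        if self.test_increment <= 0:
            raise ValueError("test_increment must be positive")
        if not 0.0 <= self.inactivating_fraction <= 1.0:
            raise ValueError("inactivating_fraction must be in [0, 1]")
        if self.cm <= 0:
            raise ValueError("cm must be positive")
        if self.cell_type == "typeI" and self.inactivating_fraction != 0.0:
            raise ValueError("inactivation applies to type II only")

    @property
    def g_max(self) -> float:
        """Maximal conductance in nS."""
        return self.g_max_density * self.cm

    @property
    def test_potentials(self) -> np.ndarray:
        n = int(np.floor((self.test_end - self.test_start) / self.test_increment)) + 1
        return self.test_start + self.test_increment * np.arange(n)


def type_i_config(**overrides) -> VgSimConfig:
    """Type I preset: large, negatively activating g_K,L with V_1/2 near rest,
    so about half the conductance is active at a resting potential of ~-85 mV."""
    base = dict(cell_type="typeI", v_half=-85.0, slope_v=6.0, g_max_density=10.0,
                inactivating_fraction=0.0)
    base.update(overrides)
    return VgSimConfig(**base)


def type_ii_config(**overrides) -> VgSimConfig:
    """Type II preset: delayed rectifier activating positive to rest, with a
    partially inactivating component."""
    base = dict(cell_type="typeII", v_half=-35.0, slope_v=6.0, g_max_density=5.0,
                inactivation_tau=50.0, inactivating_fraction=0.3)
    base.update(overrides)
    return VgSimConfig(**base)


def _popen(cfg: VgSimConfig, v: np.ndarray) -> np.ndarray:
    return boltzmann(v, 1.0, cfg.g_min / cfg.g_max if cfg.g_max else 0.0,
                     cfg.v_half, cfg.slope_v)


def simulate_vg_family(cfg: VgSimConfig) -> tuple[StepFamily, GroundTruth]:
    """Simulate one voltage-step family with tail currents.

    Current at test potential V: I = g_max * Popen(V) * (V - E_K) * h(t),
    where h(t) relaxes from 1 to (1 - inactivating_fraction) with
    ``inactivation_tau`` (type II).  The tail current at ``tail_potential``
    is Popen(V) * h(end) * g_max * (tail - E_K).
    """
    dt = cfg.sample_interval
    n_pre = int(round(cfg.prepulse_duration / dt))
    n_test = int(round(cfg.test_duration / dt))
    n_tail = int(round(cfg.tail_duration / dt))
    n_total = n_pre + n_test + n_tail

    v_test = cfg.test_potentials
    popen = _popen(cfg, v_test)
    g_open = cfg.g_max * popen  # nS at each test potential

    t_test = np.arange(n_test) * dt
    fr = cfg.inactivating_fraction if cfg.cell_type == "typeII" else 0.0
    h = (1.0 - fr) + fr * np.exp(-t_test / cfg.inactivation_tau)

    clean = np.zeros((v_test.size, n_total))
    # pre-pulse: conductance at the pre-pulse potential (essentially closed)
    g_pre = cfg.g_max * float(_popen(cfg, np.array([cfg.prepulse_potential]))[0])
    clean[:, :n_pre] = g_pre * (cfg.prepulse_potential - cfg.e_k)
    clean[:, n_pre:n_pre + n_test] = (
        g_open[:, None] * h[None, :] * (v_test - cfg.e_k)[:, None]
    )
    # tail: open probability frozen at its end-of-step value, common potential
    g_tail = g_open * h[-1]
    clean[:, n_pre + n_test:] = (g_tail * (cfg.tail_potential - cfg.e_k))[:, None]

    rng = np.random.default_rng(cfg.seed)
    traces = clean if cfg.noise_sd == 0 else clean + rng.normal(
        0.0, cfg.noise_sd, size=clean.shape)

    meta = RecordingMeta(
        holding_potential=cfg.prepulse_potential,
        cell_type=cfg.cell_type,
        cm=cfg.cm,
    )
    family = StepFamily(
        step_levels=v_test,
        traces=traces,
        sample_interval=dt,
        step_onset=cfg.prepulse_duration,
        step_offset=cfg.prepulse_duration + cfg.test_duration,
        kind="voltage",
        meta=meta,
    )
    params = asdict(cfg)
    params["g_max"] = cfg.g_max
    params["tail_conductances_truth"] = g_tail.tolist()
    truth = GroundTruth(generator="vg_family", seed=cfg.seed, params=params)
    return family, truth
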