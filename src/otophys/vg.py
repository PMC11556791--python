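"""Voltage-gated conductance analysis: tail-current G(V), Boltzmann fits,
conductance density, and input resistance.

Tail currents read at a common potential shortly after each test step report
the open probability reached during that step; dividing by the tail driving
force (V_tail - E_K) gives the tail conductance, whose voltage dependence is
fit with a first-order Boltzmann.  G_max / C_m normalizes for cell size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .boltzmann import BoltzmannParams, fit_boltzmann
from .core import StepFamily

__all__ = [
    "TailGvCurve", "GvBoltzmannFit", "PassiveProps",
    "extract_tail_conductance", "fit_gv_boltzmann", "input_resistance",
]


@dataclass
class TailGvCurve:
    """Tail-conductance versus test-potential curve of one cell."""

    test_potentials: np.ndarray  # mV, strictly increasing
    tail_currents: np.ndarray  # pA at the common tail potential
    tail_potential: float = -39.0  # mV
    rev_potential: float = -84.0  # mV (E_K)
    cm: float | None = None  # pF

    def __post_init__(self) -> None:
        self.test_potentials = np.asarray(self.test_potentials, dtype=float)
        self.tail_currents = np.asarray(self.tail_currents, dtype=float)
        if np.any(np.diff(self.test_potentials) <= 0):
            raise ValueError("test potentials must be strictly increasing")
        if self.tail_potential == self.rev_potential:
            raise ValueError("tail potential must differ from the reversal potential")

    @property
    def conductances(self) -> np.ndarray:
        """Tail conductance in nS: I_tail / (V_tail - E_K)."""
        return self.tail_currents / (self.tail_potential - self.rev_potential)


@dataclass
class GvBoltzmannFit:
    g_max: float  # nS
    g_min: float
    v_half: float  # mV
    slope_v: float  # mV
    g_max_density: float | None  # nS/pF
    rss: float
    converged: bool


@dataclass
class PassiveProps:
    r_in: float  # MOhm
    v_rest: float  # mV


def extract_tail_conductance(
    family: StepFamily,
    window_after_step: float = 1.0,
    window_width: float = 0.5,
    tail_potential: float = -39.0,
    rev_potential: float = -84.0,
) -> TailGvCurve:
    """Read tail currents ``window_after_step`` ms after the test step.

    The tail value is the mean over a ``window_width`` ms window centered at
    step_offset + window_after_step, for noise robustness.  No correction is
    made for tail decay during the gap.
    """
    if family.kind != "voltage":
        raise ValueError("expected a voltage-step family")
    t_read = family.step_offset + window_after_step
    lo = family.sample_index(t_read - window_width / 2)
    hi = family.sample_index(t_read + window_width / 2)
    if hi > family.n_samples:
        raise ValueError("tail segment shorter than the read-out window")
    tail_i = family.traces[:, lo:hi].mean(axis=1)
    return TailGvCurve(
        test_potentials=family.step_levels,
        tail_currents=tail_i,
        tail_potential=tail_potential,
        rev_potential=rev_potential,
        cm=family.meta.cm,
    )


def fit_gv_boltzmann(curve: TailGvCurve, seed: int = 0) -> GvBoltzmannFit:
    """Boltzmann fit of tail conductance vs test potential; density = G_max/C_m."""
    p: BoltzmannParams = fit_boltzmann(curve.test_potentials, curve.conductances, seed=seed)
    density = p.g_max / curve.cm if curve.cm else None
    return GvBoltzmannFit(g_max=p.g_max, g_min=p.g_min, v_half=p.u_half,
                          slope_v=p.s, g_max_density=density,
                          rss=p.rss, converged=p.converged)


def input_resistance(
    iv_points: Sequence[tuple[float, float]],
    current_window: float = 50.0,
) -> PassiveProps:
    """Input resistance from the slope of V_m(I) for small injected currents.

    ``iv_points`` are (I in pA, V_m in mV) pairs; points with |I| within
    ``current_window`` pA enter an ordinary least-squares regression whose
    slope (mV/pA = GOhm) is reported in MOhm and whose intercept is the
    resting potential.
    """
    pts = np.asarray(iv_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("iv_points must be (I, Vm) pairs")
    sel = np.abs(pts[:, 0]) <= current_window
    if sel.sum() < 3:
        raise ValueError(f"need >= 3 points with |I| <= {current_window} pA, have {int(sel.sum())}")
    res = stats.linregress(pts[sel, 0], pts[sel, 1])
    return PassiveProps(r_in=float(res.slope * 1000.0), v_rest=float(res.intercept))
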