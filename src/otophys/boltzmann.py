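"""First-order Boltzmann (4-parameter sigmoid) fitting.

Both the conductance-displacement curve of the MET channel and the steady-state
activation curve of voltage-gated K+ conductances are described by

    G(u) = (G_max - G_min) / (1 + exp((u_half - u) / s)) + G_min

where u is displacement (nm) or membrane potential (mV), u_half is the
half-activation point and s the e-fold slope factor.  The fit is nonlinear
least squares with data-driven initialization and a small number of jittered
restarts; failure raises rather than returning silent garbage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["boltzmann", "BoltzmannParams", "FitFailure", "fit_boltzmann", "LN81"]

#: OR = s * ln(81): 10-90% span of a first-order Boltzmann is ln(0.9/0.1 / (0.1/0.9)) = ln 81 slopes
LN81 = float(np.log(81.0))


def boltzmann(u: np.ndarray, g_max: float, g_min: float, u_half: float, s: float) -> np.ndarray:
    return (g_max - g_min) / (1.0 + np.exp((u_half - u) / s)) + g_min


class FitFailure(RuntimeError):
    """Nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class BoltzmannParams:
    g_max: float
    g_min: float
    u_half: float
    s: float
    rss: float
    converged: bool

    @property
    def operating_range(self) -> float:
        """10-90% activation span: OR = s * ln 81."""
        return self.s * LN81


def _initial_guess(u: np.ndarray, g: np.ndarray) -> tuple[float, float, float, float]:
    g_max0, g_min0 = float(np.max(g)), float(np.min(g))
    half = 0.5 * (g_max0 + g_min0)
    # interpolate the half-crossing on the sorted curve
    order = np.argsort(u)
    us, gs = u[order], g[order]
    above = gs >= half
    if above.any() and not above.all():
        i = int(np.argmax(above))
        i = max(i, 1)
        f = (half - gs[i - 1]) / (gs[i] - gs[i - 1]) if gs[i] != gs[i - 1] else 0.5
        u_half0 = float(us[i - 1] + f * (us[i] - us[i - 1]))
    else:
        u_half0 = float(np.median(us))
    s0 = float((us[-1] - us[0]) / 4.0) or 1.0
    return g_max0, g_min0, u_half0, s0


def fit_boltzmann(
    u: np.ndarray,
    g: np.ndarray,
    n_restarts: int = 5,
    seed: int = 0,
) -> BoltzmannParams:
    """Fit G(u) by bounded nonlinear least squares with jittered restarts.

    Requires >= 6 points.  Raises :class:`FitFailure` if every attempt fails
    or the curve has no activation range (all values identical).
    """
    u = np.asarray(u, dtype=float)
    g = np.asarray(g, dtype=float)
    if u.size < 6:
        raise ValueError(f"need >= 6 points to fit a 4-parameter Boltzmann, got {u.size}")
    if np.ptp(g) == 0:
        raise FitFailure("degenerate curve: no activation range", {"g_span": 0.0})

    p0 = np.array(_initial_guess(u, g))
    span_u = float(np.ptp(u))
    lo = [0.0, 0.0, u.min() - span_u, 1e-9]
    hi = [np.inf, np.inf, u.max() + span_u, 10 * span_u]
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for attempt in range(n_restarts):
        trial = p0 if attempt == 0 else p0 * rng.uniform(0.7, 1.3, size=4)
        trial = np.clip(trial, lo, hi)
        try:
            popt, _ = curve_fit(boltzmann, u, g, p0=trial, bounds=(lo, hi), maxfev=20000)
        except (RuntimeError, ValueError) as err:
            last_err = err
            continue
        resid = g - boltzmann(u, *popt)
        return BoltzmannParams(
            g_max=float(popt[0]), g_min=float(popt[1]),
            u_half=float(popt[2]), s=float(popt[3]),
            rss=float(resid @ resid), converged=True,
        )
    raise FitFailure(
        f"Boltzmann fit failed after {n_restarts} restarts",
        {"last_error": str(last_err), "p0": p0.tolist(), "n_points": int(u.size)},
    )
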