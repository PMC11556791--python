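"""Tail-current G(V) analysis of a synthetic type II voltage-step family.

Tail currents at -39 mV, read 1 ms after each 400 ms test step, are divided
by the 45 mV driving force to give tail conductance, then fit with a
Boltzmann activation curve.  Input resistance comes from a linear V(I) fit.
"""

import numpy as np

from otophys import vg
from otophys.synth import simulate_vg_family, type_ii_config

family, truth = simulate_vg_family(type_ii_config(noise_sd=10.0, seed=7,
                                                  inactivating_fraction=0.0))
curve = vg.extract_tail_conductance(family)
fit = vg.fit_gv_boltzmann(curve)
print(f"V_1/2        = {fit.v_half:.1f} mV  (truth {truth.params['v_half']})")
print(f"slope        = {fit.slope_v:.1f} mV per e-fold")
print(f"G_max        = {fit.g_max:.1f} nS; density {fit.g_max_density:.2f} nS/pF")

i = np.array([-40.0, -20.0, 0.0, 20.0, 40.0])
props = vg.input_resistance(list(zip(i, -70.0 + 0.5 * i)))
print(f"R_in         = {props.r_in:.0f} MOhm at V_rest {props.v_rest:.0f} mV")
# A type II delayed rectifier activates positive to rest (V_1/2 ~ -35 mV)
# and such cells show input resistances around 500 MOhm; type I cells with
# g_K,L sit near 50 MOhm.
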