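# otophys

Quantification toolkit for inner-ear hair-cell physiology and vestibular
behavior, written for electrophysiologists and sensory neuroscientists who
study otolith organs (mouse utricle) and lateral-line neuromasts (zebrafish).
The package covers the full analysis chain of a mirror-image hair-cell
orientation study — from single-cell mechanotransduction currents to whole-
animal eye-movement reflexes and imaging read-outs — and pairs every stage
with a seeded synthetic-data generator carrying ground truth, so each
estimator can be validated by parameter recovery.

## What it computes

**Mechanotransduction (MET).** Conductance–displacement curves
G(X) = (I_peak − I_0)/(V_eff − E_rev) from displacement-step families, after
liquid-junction and residual series-resistance corrections, fit with a
first-order Boltzmann

    G(X) = (G_max − G_min) / (1 + exp((X_1/2 − X)/S)) + G_min

with operating range OR = S·ln 81 (the 10–90 % span). Adaptation of the
current at X_1/2 is decomposed into up to three exponentials — very fast
(τ_vf < 1 ms), fast (1–10 ms) and slow (> 10 ms) — plus a steady state, with
extent of adaptation (I_peak − I_SS)/(I_peak − I_0) × 100.

**Voltage-gated conductances.** Tail currents at −39 mV, read 1 ms after
400 ms test steps, divided by the driving force (V − E_K) give tail
conductance; a Boltzmann fit in voltage yields V_1/2, slope and G_max/C_m.
Input resistance is the slope of V_m(I) for small currents.

**Afferent excitability.** Spike detection on current-clamp steps
(−200 pA start, 50 pA increments), threshold current I_thresh, and the
transient (1–2 spikes at 3×I_thresh) vs sustained classification.

**Oculomotor behavior.** Quick-phase exclusion and least-squares sinusoid
fits give VOR/OKR gain and phase per frequency; off-vertical-axis rotation
(OVAR) eye velocity is decomposed into a decaying canal transient plus an
otolith steady state, bias + modulation at the rotation frequency
(rotation/360 Hz); VOR learning is the percent gain change.

**Head-motion spectra.** Welch periodograms (nfft 4096, Bartlett window) of
6-axis head motion, with an exact/Monte-Carlo two-group permutation test on
band power.

**Imaging.** ΔF/F₀ of hair-bundle GCaMP ROIs with direction-specific
orientation calls and per-neuromast magnitudes; synaptic-puncta size
filtering (pre ≥ 0.025 µm², post ≥ 0.04 µm²) with one-to-one pre/post
pairing into complete synapses; afferent innervation and Emx2 selectivity
percentages; hair-cell density per 1000 µm².

## Worked example

```python
from otophys import met
from otophys.synth import MetSimConfig, simulate_met_family

family, truth = simulate_met_family(MetSimConfig(noise_sd=5.0, seed=42))
family = met.correct_voltages(family)
fit = met.fit_gx_boltzmann(met.met_conductance_curve(family))
adapt = met.fit_adaptation(family)
print(fit.g_max, fit.x_half, fit.slope_s, adapt.tau_f, adapt.extent_pct)
```

prints (seed 42)

```
G_max  = 2.775 nS   (truth 2.75)
X_1/2  = 243.7 nm   (truth 250.0)
S      = 181.2 nm   (truth 175.0)
tau_vf = 0.57 ms, tau_f = 5.93 ms, tau_s = 99.5 ms
extent of adaptation = 73.9 %
```

i.e. the maximal MET conductance, half-activating displacement and slope of
this synthetic cell are recovered to a few percent at a realistic 5 pA noise
level, and the three adaptation time constants land in their very-fast /
fast / slow classes. `examples/` holds one script per capability
(`python examples/vor_gain_phase.py`, …), each printing the quantities it
estimates next to the generator's ground truth.

A thin CLI mirrors the library for scripted runs
(`otophys simulate met --out d`, `otophys metfit --input d --out r`, also
`vgfit`, `spikes`, `reflex`, `ovar`, `psd`, `permtest`, `calcium`,
`synapses`, `density`); every invocation writes a run manifest with the
resolved configuration and input checksums.

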