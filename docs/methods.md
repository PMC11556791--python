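# Methods

This note documents the models, estimators and numerical choices behind
`otophys`, and what the synthetic-data generators do and do not emulate.

## Units and conventions

Cellular signals use ms, nm, pA, mV, nS (so nS × mV = pA without unit
constants); behavioral signals use s and deg/s. Inward currents are
negative. Phases are degrees in (−180, 180]. Image coordinates are µm,
origin top-left, y downward, half-open pixel areas.

## Filters

Stimulus and recording conditioning is modeled as 8-pole Bessel low-pass
filters, digitized by the bilinear transform with the cutoff at the −3 dB
point (`norm='mag'`), which is how bench-top filter hardware is specified.
At 1 kHz this gives a 10–90 % step rise time of ≈347 µs, consistent with the
~300 µs rise of a piezo probe driven through such a filter. Offline
filtering (2 kHz for G(X) traces, 1.5 kHz before adaptation fits) is
zero-phase (forward–backward, order 4 per pass, matching an 8-pole
magnitude response) so it delays no feature.

## MET generator

Displacement steps X_j (default 40 steps × 35 nm from −70 nm) produce peak
conductances on a Boltzmann G(X) (defaults G_max 2.75 nS, G_min 0,
X_1/2 250 nm, S 175 nm, inside the ranges reported for utricular hair
cells). The command step is shaped by the 1 kHz probe filter; because the
8-pole Bessel step response slightly overshoots (~0.3 %), there is a first
instant at which the filtered command reaches its plateau, and the
adaptation clock starts there. The rise segment is the normalized filter
step response and the decay segment is

    a(t) = 1 − Σ_k f_k (1 − exp(−t/τ_k)),  k ∈ {vf, f, s}

so noiseless per-step peaks equal G(X_j)·(HP − E_rev) exactly and the decay
from the peak is an exact sum of exponentials with steady-state fraction
1 − Σf_k. The recorded current is referenced to the pre-step level, at
which the resting conductance equals G_min (steps begin slightly negative
of the resting bundle position). Defaults τ_vf 0.6 ms, τ_f 6 ms, τ_s 100 ms
with fractions 0.25/0.30/0.20 (extent 75 %), one exemplar per tau class.
Noise is additive Gaussian per sample (5 pA typical), independent across
the 3 repeats that are averaged — the simplest model supporting recovery
tests; real recordings have colored noise, line pickup and drift, so
passing recovery tests here bounds estimator bias, not robustness to every
artifact.

## Adaptation decomposition

The analysis follows the classic staged procedure and adds a refinement:

1. the trace is zero-phase filtered at 1.5 kHz and the peak located within
   10 ms of step onset (probe rise ~300 µs plus filtering);
2. a double exponential + steady state is fit over 300 ms from the peak,
   with time constants bounded to the fast (1–10 ms) and slow (10–2000 ms)
   classes;
3. if the mean residual over the first 1.5 ms exceeds 3× the RMS of later
   residuals (with an absolute floor of 0.1 % of the decay so exact
   double-exponential traces never trigger), a very-fast component is fit
   as a single exponential over that onset window;
4. all detected components are then re-fit jointly, excluding the first
   0.5/f_c (≈0.33 ms) after the peak: a symmetric filter kernel rescales
   exponential amplitudes but leaves time constants intact once outside the
   blurred rise/decay junction, so the joint fit recovers taus to <0.1 %
   on noiseless data;
5. components with amplitude below 2× the baseline noise SD, the wrong
   sign, or a pinned tau are dropped.

Extent of adaptation uses signed currents as recorded:
(I_peak − I_SS)/(I_peak − I_0)·100. A trace whose decay is under
max(3×noise SD, 0.1 % of the evoked current) is reported as non-adapting
(extent 0, no components).

## Voltage-gated analysis and generator

The generator treats activation as instantaneous (the analysis reads only
steady-state and tail levels; activation kinetics are deliberately out of
scope) with Popen a Boltzmann in voltage; type II cells relax toward
(1 − inactivating_fraction) with a 50 ms default inactivation tau. Tail
currents at −39 mV freeze the end-of-step open probability. The tail
read-out averages a 0.5 ms window centered 1 ms after the step, with no
correction for decay during the gap. Presets: type I (g_K,L) with V_1/2
−85 mV near rest — so about half the conductance is active at rest — and
type II with V_1/2 −35 mV. Input resistance is an OLS slope of V_m(I) for
|I| ≤ 50 pA ("small currents"; mV/pA = GΩ, reported in MΩ).

## Afferent spiking

The generator is phenomenological — stereotyped triangular spikes placed on
a passive baseline — because the pipeline consumes only spike times and
counts. Spike detection is an upward crossing of −20 mV with a 1 ms
refractory period (configurable; the criterion is not physiological
modeling, just event timing). Transient cells fire 1 spike at onset, 2 when
driven at ≥2× threshold; sustained cells fire at their configured rate.
The classification window is 400 ms from step onset although steps last
500 ms, matching the stated counting rule; both are configurable. The
−50 mV resting-potential QC boundary counts −50.0 mV as a pass.

## Oculomotor analysis

Sinusoid fits are linear least squares at the known stimulus frequency
(offset + a·sin + b·cos), applied jointly over all clean-cycle samples (a
per-cycle mode is not provided; the joint fit is the stated least-squares
optimization). Gain is A_eye/A_head; phase is
phase_eye − phase_head − 180° wrapped, so compensation is 0°. Quick-phase
detection thresholds residual velocity at 50 deg/s and residual
acceleration at 1000 deg/s² against an initial whole-trial sinusoid fit;
the residual is boxcar-smoothed over 25 ms first, otherwise white
measurement noise at 1 kHz masquerades as acceleration. Any flagged sample
excludes its whole stimulus cycle.

OVAR decomposition fits the steady state (t ≥ 20 s after plateau onset,
beyond the stated 10–15 s transient) to bias + modulation at rotation/360 Hz
by OLS, then fits a single exponential to the model-subtracted first 15 s.
The two fits are alternated three times because a transient tail (e.g.
10·exp(−20/5) ≈ 0.18 deg/s at the segment start) otherwise leaks into the
bias; the alternation recovers a noiseless bias to <0.001 deg/s. A
transient below 1 nV-equivalent resolution reports amplitude and tau as
None.

## Spectra and the permutation test

Welch PSDs default to nfft = 4096 = window length with a Bartlett window
and 50 % overlap, density scaling (unit-variance white noise integrates to
≈1). The stated "4096 ms" window at 200 Hz would be 819 samples,
inconsistent with nfft = 4096 samples; window length is therefore
independently configurable and defaults to nfft. The permutation statistic
is the difference of group means, two-sided. When the number of distinct
relabelings is within the permutation budget the test enumerates them all
and p = (#{|T*| ≥ |T_obs|})/N — the observed labeling counts itself, so
p > 0 and p is a multiple of 1/N; otherwise Monte Carlo with the add-one
correction p = (count+1)/(n_perm+1). Comparisons of spectra use
band-integrated power per channel by default (per-bin comparison is a
caller choice).

## Imaging

ΔF/F₀ uses the mean pre-stimulus baseline as F₀. A direction responds if
its within-epoch peak ΔF/F exceeds 3× the baseline SD (the study states no
criterion; 3σ is the field default and is configurable); the orientation is
the responding direction, the larger peak if both respond. Neuromast
magnitude is the peak of the direction-averaged trace (peak vs mean is
ambiguous in the source; peak is the default, the mean trace is returned so
callers can take either). Puncta segmentation thresholds each channel by
Otsu (configurable absolute threshold), labels connected components,
filters areas (pre ≥ 0.025 µm², post ≥ 0.04 µm²) and pairs pre/post
centroids greedily, nearest first, one-to-one within 0.5 µm. The synthetic
puncta renderer paints exactly round(area/pixel-area) nearest pixels so
rendered areas respect the filters to half a pixel at the 0.05 µm/px
default. Counting ROIs are rectangles (min edges inclusive) or polygons
(boundary inclusive); density is 1000·count/area.

## Problem sizes

Recovery tests use 100 seeded families (MET), 25 cells (G(V)), 200
randomized responses (spike patterns), 6 frequencies × 10 cycles (reflex),
1000 null draws of 6 vs 6 (permutation type-I calibration), and 100 random
puncta fixtures — sizes at which estimator bias and variance are resolvable
while the whole suite runs in well under a minute per stage.

## Known limitations

The generators share none of the nonstationarity of live recordings: no
electrode drift, no seal degradation, no eye-blink artifacts, no breathing
contamination of head-motion spectra, and hair-cell / afferent variability
enters only through parameter choices. Recovery results therefore validate
the estimators, not the biology. Activation kinetics of voltage-gated
currents, channel-level MET gating, stiffness reconstruction, 3-D image
segmentation and eye-position calibration are out of scope.
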