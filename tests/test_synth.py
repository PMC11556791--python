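"""Generator contracts: noiseless signal correctness, determinism, validation."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from otophys import spikes
from otophys.core import MOTION_CHANNELS
from otophys.synth import (
    AfferentSimConfig, ImagingSimConfig, MetSimConfig, OvarSimConfig,
    ReflexSimConfig, VgSimConfig, simulate_afferent_response, simulate_headmotion,
    simulate_imaging_fixtures, simulate_met_family, simulate_ovar_trial,
    simulate_reflex_trial, simulate_vg_family, type_ii_config,
)


class TestMetGenerator:
    def test_saturating_step_peak_current(self):
        """Noiseless saturating step: peak I = g_max * (HP - E_rev)."""
        cfg = MetSimConfig(noise_sd=0.0, tau_vf=None, tau_f=None, tau_s=None,
                           adapt_fractions={})
        fam, _ = simulate_met_family(cfg)
        # topmost step is far into saturation (1295 nm vs x_half 250, S 175)
        peak = fam.traces[-1].min()
        expected = 2.75 * (-94.0 - 0.2) * (1 / (1 + np.exp((250 - 1295) / 175)))
        assert peak == pytest.approx(expected, rel=1e-3)

    def test_same_seed_bit_identical(self):
        cfg = MetSimConfig(noise_sd=5.0, seed=42)
        fam1, _ = simulate_met_family(cfg)
        fam2, _ = simulate_met_family(MetSimConfig(noise_sd=5.0, seed=42))
        np.testing.assert_array_equal(fam1.traces, fam2.traces)

    def test_slow_only_decay_is_single_exponential_at_onset(self):
        """With only tau_s enabled the early decay holds no fast structure:
        an independent exponential-plus-offset fit leaves ~zero onset residual."""
        cfg = MetSimConfig(noise_sd=0.0, tau_vf=None, tau_f=None,
                           adapt_fractions={"s": 0.3})
        fam, _ = simulate_met_family(cfg)
        trace = fam.traces[-1]
        i_pk = int(np.argmin(trace))
        dt = fam.sample_interval
        n = int(round(300.0 / dt))
        t = np.arange(n) * dt
        y = trace[i_pk:i_pk + n]
        popt, _ = curve_fit(lambda t, a, tau, c: a * np.exp(-t / tau) + c,
                            t, y, p0=[y[0] - y[-1], 100.0, y[-1]], maxfev=10000)
        resid = y - (popt[0] * np.exp(-t / popt[1]) + popt[2])
        onset = resid[: int(round(1.5 / dt))]
        assert np.max(np.abs(onset)) < 1e-3 * np.abs(y[0] - y[-1])

    def test_invalid_tau_class_rejected(self):
        with pytest.raises(ValueError):
            MetSimConfig(tau_vf=2.0)  # very-fast tau must be < 1 ms
        with pytest.raises(ValueError):
            MetSimConfig(tau_s=5.0)  # slow tau must be > 10 ms

    def test_adapt_fractions_must_sum_below_one(self):
        with pytest.raises(ValueError):
            MetSimConfig(adapt_fractions={"vf": 0.5, "f": 0.4, "s": 0.3})


class TestVgGenerator:
    def test_tail_conductance_at_midpoint(self):
        """At V = V_1/2 the tail conductance is half of g_max (g_min = 0)."""
        cfg = type_ii_config(inactivating_fraction=0.0, test_start=-125.0)
        fam, truth = simulate_vg_family(cfg)  # grid hits V_1/2 = -35 exactly
        step = int(np.argmin(np.abs(fam.step_levels - cfg.v_half)))
        assert fam.step_levels[step] == cfg.v_half
        g = fam.traces[step, -10] / (-39.0 - (-84.0))
        assert g == pytest.approx(truth.params["g_max"] / 2, rel=1e-9)

    def test_tail_conductance_far_below_midpoint(self, noiseless_vg_family):
        fam, truth = noiseless_vg_family
        g = fam.traces[0, -10] / 45.0  # most negative test step
        assert g < 0.01 * truth.params["g_max"]

    def test_fast_full_inactivation_halves_steady_state(self):
        """inactivating_fraction 0.5 with tau << 400 ms leaves half the peak."""
        cfg = type_ii_config(inactivating_fraction=0.5, inactivation_tau=5.0)
        fam, _ = simulate_vg_family(cfg)
        i_on = fam.sample_index(fam.step_onset)
        i_off = fam.sample_index(fam.step_offset)
        peak = fam.traces[-1, i_on]
        ss = fam.traces[-1, i_off - 5]
        assert ss == pytest.approx(peak / 2, rel=1e-3)

    def test_invalid_cm_rejected(self):
        with pytest.raises(ValueError):
            VgSimConfig(cm=0.0)


class TestAfferentGenerator:
    def test_threshold_defines_first_spiking_step(self):
        fam, truth = simulate_afferent_response(AfferentSimConfig(true_threshold=100.0))
        times = truth.params["spike_times_truth"]
        levels = fam.step_levels
        assert all(len(t) == 0 for t, lv in zip(times, levels) if lv < 100.0)
        assert len(times[int(np.where(levels == 100.0)[0][0])]) >= 1

    def test_sustained_rate_times_duration(self):
        cfg = AfferentSimConfig(pattern="sustained", sustained_rate=50.0)
        _, truth = simulate_afferent_response(cfg)
        n = len(truth.params["spike_times_truth"][-1])
        assert n == pytest.approx(25, abs=2)  # 50 /s over 500 ms

    def test_transient_caps_at_two_spikes(self):
        cfg = AfferentSimConfig(pattern="transient", true_threshold=100.0)
        _, truth = simulate_afferent_response(cfg)
        for t in truth.params["spike_times_truth"]:
            assert len(t) <= 2


class TestReflexGenerator:
    def test_perfect_compensation(self):
        cfg = ReflexSimConfig(default_gain=1.0, default_phase_deg=0.0)
        trial, _ = simulate_reflex_trial(cfg, 1.0)
        np.testing.assert_allclose(trial.eye_velocity, -trial.head_velocity, atol=1e-12)

    def test_gain_scales_eye_amplitude(self):
        cfg = ReflexSimConfig(default_gain=0.5)
        trial, _ = simulate_reflex_trial(cfg, 0.4)
        assert np.max(np.abs(trial.eye_velocity)) == pytest.approx(8.0, rel=1e-3)
        assert np.max(np.abs(trial.head_velocity)) == pytest.approx(16.0, rel=1e-3)

    def test_no_quick_phases_means_all_cycles_clean(self):
        cfg = ReflexSimConfig(quick_phase_rate=0.0)
        _, truth = simulate_reflex_trial(cfg, 0.4)
        assert truth.params["contaminated_cycles"] == []

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError):
            ReflexSimConfig(n_cycles=2)


class TestOvarGenerator:
    def test_plateau_covers_ten_revolutions(self):
        cfg = OvarSimConfig()
        trial, _ = simulate_ovar_trial(cfg)
        plateau = trial.time >= cfg.ramp_duration
        angle = np.trapezoid(trial.head_velocity[plateau], trial.time[plateau])
        assert angle == pytest.approx(3600.0, rel=1e-3)

    def test_mean_over_whole_rotations_is_bias(self):
        cfg = OvarSimConfig(transient_amplitude=0.0, noise_sd=0.0)
        trial, _ = simulate_ovar_trial(cfg)
        period = 1.0 / cfg.mod_frequency
        sel = (trial.time >= cfg.ramp_duration) & (
            trial.time < cfg.ramp_duration + 9 * period)
        assert trial.eye_velocity[sel].mean() == pytest.approx(cfg.bias, abs=1e-6)

    def test_modulation_frequency_locked_to_rotation(self):
        assert OvarSimConfig(rotation_velocity=50.0).mod_frequency == pytest.approx(
            0.138889, abs=1e-6)

    def test_short_plateau_rejected(self):
        with pytest.raises(ValueError):
            OvarSimConfig(plateau_duration=5.0)  # < one rotation at 50 deg/s


class TestHeadmotionGenerator:
    def test_tremor_peak_in_periodogram(self):
        """Independent check: plain periodogram peaks at the tremor bin."""
        from scipy.signal import periodogram

        rec, _ = simulate_headmotion(duration=60, tremor_freq=25.0, tremor_amp=3.0,
                                     noise_sd=0.5, seed=7)
        f, p = periodogram(rec.channels["pitch"], fs=rec.sample_rate)
        assert abs(f[np.argmax(p)] - 25.0) <= f[1] - f[0]

    def test_reproducible_and_channel_complete(self):
        rec1, _ = simulate_headmotion(duration=10, seed=5)
        rec2, _ = simulate_headmotion(duration=10, seed=5)
        assert set(rec1.channels) == set(MOTION_CHANNELS)
        for name in MOTION_CHANNELS:
            np.testing.assert_array_equal(rec1.channels[name], rec2.channels[name])

    def test_tremor_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            simulate_headmotion(duration=10, fs=200, tremor_freq=120.0, tremor_amp=1.0)


class TestImagingGenerator:
    def test_response_confined_to_matching_epoch(self, imaging_fixture):
        traces, _, truth = imaging_fixture
        epochs = {e.direction: e for e in traces[0].stim_epochs}
        for tr in traces:
            direction = truth.params["orientations"][tr.roi_id]
            other = "PtoA" if direction == "AtoP" else "AtoP"
            ep = epochs[other]
            i0 = int(ep.onset * tr.volume_rate)
            i1 = int(ep.end * tr.volume_rate)
            assert np.allclose(tr.fluorescence[i0:i1], 100.0)

    def test_sub_threshold_punctum_marked(self):
        from otophys.synth import PunctumSpec, paired_puncta_spec

        puncta = paired_puncta_spec() + [PunctumSpec((10.0, 10.0), 0.02, "pre", 99)]
        cfg = ImagingSimConfig(puncta=puncta)
        _, _, truth = simulate_imaging_fixtures(cfg)
        subs = truth.params["sub_threshold_puncta"]
        assert len(subs) == 1 and subs[0]["area"] == 0.02

    def test_pairing_offset_beyond_distance_yields_no_complete(self):
        from otophys.synth import paired_puncta_spec

        cfg = ImagingSimConfig(puncta=paired_puncta_spec(pairing_offset=0.9),
                               pair_distance=0.5)
        _, _, truth = simulate_imaging_fixtures(cfg)
        assert truth.params["n_complete"] == 0

    def test_punctum_outside_bounds_rejected(self):
        from otophys.synth import PunctumSpec

        with pytest.raises(ValueError):
            ImagingSimConfig(puncta=[PunctumSpec((200.0, 5.0), 0.06, "pre", 1)])
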