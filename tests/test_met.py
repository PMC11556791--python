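"""MET analysis: voltage corrections, QC partition, G(X) fitting, adaptation."""

import numpy as np
import pandas as pd
import pytest

from otophys import met
from otophys.boltzmann import LN81, boltzmann
from otophys.core import RecordingMeta, StepFamily
from otophys.synth import MetSimConfig, simulate_met_family


def _flat_family(current_pa=0.0, hp=-90.0, rs_total=8.1, comp=0.8):
    """Minimal displacement family with a constant in-step current."""
    n = 2000
    traces = np.zeros((6, n))
    traces[:, 500:1500] = current_pa
    meta = RecordingMeta(holding_potential=hp, rs_total=rs_total,
                         rs_compensated_fraction=comp)
    return StepFamily(step_levels=np.arange(6) * 100.0, traces=traces,
                      sample_interval=0.02, step_onset=10.0, step_offset=30.0,
                      meta=meta)


class TestCorrectVoltages:
    def test_junction_only_when_no_current(self):
        fam = met.correct_voltages(_flat_family(0.0))
        np.testing.assert_allclose(fam.effective_potentials, -94.0)

    def test_series_resistance_error(self):
        """-1 nA through the residual 20% of 8.1 MOhm drops 1.62 mV."""
        fam = met.correct_voltages(_flat_family(-1000.0))
        np.testing.assert_allclose(fam.effective_potentials, -94.0 + 1.62)

    def test_full_compensation_leaves_junction_term(self):
        fam = met.correct_voltages(_flat_family(-1000.0, comp=1.0))
        np.testing.assert_allclose(fam.effective_potentials, -94.0)

    def test_double_correction_rejected(self):
        fam = met.correct_voltages(_flat_family())
        with pytest.raises(ValueError):
            met.correct_voltages(fam)


class TestQc:
    @pytest.mark.parametrize("peak,label", [
        (18.0, "non_responder"),
        (120.0, "responder"),
        (300.0, "analysis_set"),
    ])
    def test_partition_by_peak_current(self, peak, label):
        fam = met.correct_voltages(_flat_family(-peak))
        assert met.qc_met_cells([fam])["label"].iloc[0] == label

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            met.qc_met_cells([])


class TestConductanceCurve:
    def test_worked_division(self):
        """-259.05 pA over (-94 - 0.2) mV driving force is 2.75 nS."""
        fam = met.correct_voltages(_flat_family(0.0))
        fam.traces[:, 500:1500] = -259.05
        fam.effective_potentials = np.full(6, -94.0)
        g = met.met_conductance_curve(fam).conductances
        np.testing.assert_allclose(g, 2.75, rtol=1e-12)

    def test_linearity_in_current(self, noiseless_met_family):
        fam, _ = noiseless_met_family
        g1 = met.met_conductance_curve(fam).conductances
        fam2 = met.correct_voltages(
            simulate_met_family(MetSimConfig(noise_sd=0.0, g_max=5.5))[0])
        g2 = met.met_conductance_curve(fam2).conductances
        np.testing.assert_allclose(g2, 2 * g1, rtol=1e-9)

    def test_noiseless_curve_matches_generator_boltzmann(self, noiseless_met_family):
        fam, truth = noiseless_met_family
        g = met.met_conductance_curve(fam).conductances
        p = truth.params
        expected = boltzmann(fam.step_levels, p["g_max"], p["g_min"],
                             p["x_half"], p["slope_s"])
        np.testing.assert_allclose(g, expected, atol=1e-9)

    def test_requires_correction_first(self):
        fam, _ = simulate_met_family(MetSimConfig(noise_sd=0.0, n_steps=8))
        with pytest.raises(ValueError):
            met.met_conductance_curve(fam)


class TestGxBoltzmannFit:
    def test_noiseless_recovery_within_0p1_pct(self, noiseless_met_family):
        fam, truth = noiseless_met_family
        fit = met.fit_gx_boltzmann(met.met_conductance_curve(fam))
        p = truth.params
        assert fit.g_max == pytest.approx(p["g_max"], rel=1e-3)
        assert fit.x_half == pytest.approx(p["x_half"], rel=1e-3)
        assert fit.slope_s == pytest.approx(p["slope_s"], rel=1e-3)

    def test_operating_range_identity(self, noiseless_met_family):
        fam, _ = noiseless_met_family
        fit = met.fit_gx_boltzmann(met.met_conductance_curve(fam))
        assert fit.operating_range == pytest.approx(fit.slope_s * LN81, rel=1e-12)
        # slope 200 nm corresponds to an ~879 nm operating range
        assert 200.0 * LN81 == pytest.approx(878.9, abs=0.1)

    def test_midpoint_identity(self, noiseless_met_family):
        fam, _ = noiseless_met_family
        fit = met.fit_gx_boltzmann(met.met_conductance_curve(fam))
        mid = boltzmann(np.array([fit.x_half]), fit.g_max, fit.g_min,
                        fit.x_half, fit.slope_s)[0]
        assert mid == pytest.approx((fit.g_max + fit.g_min) / 2, rel=1e-12)

    def test_scaling_currents_scales_gmax_only(self, noiseless_met_family):
        fam, _ = noiseless_met_family
        curve = met.met_conductance_curve(fam)
        fit1 = met.fit_gx_boltzmann(curve)
        curve.conductances = curve.conductances * 3.0
        fit2 = met.fit_gx_boltzmann(curve)
        assert fit2.g_max == pytest.approx(3 * fit1.g_max, rel=1e-4)
        assert fit2.x_half == pytest.approx(fit1.x_half, rel=1e-4)
        assert fit2.slope_s == pytest.approx(fit1.slope_s, rel=1e-4)


class TestAdaptation:
    def test_extent_worked_example(self):
        """Pre-step 0, peak -200, steady state -80 pA: 60% decay."""
        assert met.extent_of_adaptation(0.0, -200.0, -80.0) == pytest.approx(60.0)

    def test_extent_bounded_when_ss_between_baseline_and_peak(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            i0 = rng.uniform(-50, 50)
            ipk = i0 + rng.choice([-1, 1]) * rng.uniform(10, 500)
            iss = i0 + (ipk - i0) * rng.uniform(0, 1)
            assert 0.0 <= met.extent_of_adaptation(i0, ipk, iss) <= 100.0

    def test_noiseless_tau_recovery_within_1_pct(self, noiseless_met_family):
        fam, truth = noiseless_met_family
        fit = met.fit_adaptation(fam)
        assert fit.tau_vf == pytest.approx(0.6, rel=0.01)
        assert fit.tau_f == pytest.approx(6.0, rel=0.01)
        assert fit.tau_s == pytest.approx(100.0, rel=0.01)

    def test_absent_very_fast_component_not_reported(self):
        cfg = MetSimConfig(noise_sd=0.0, tau_vf=None,
                           adapt_fractions={"f": 0.3, "s": 0.25})
        fam = met.correct_voltages(simulate_met_family(cfg)[0])
        fit = met.fit_adaptation(fam)
        assert fit.components_present == {"vf": False, "f": True, "s": True}
        assert fit.tau_f == pytest.approx(6.0, rel=0.01)
        assert fit.tau_s == pytest.approx(100.0, rel=0.01)

    def test_present_very_fast_component_detected(self, noiseless_met_family):
        fam, _ = noiseless_met_family
        fit = met.fit_adaptation(fam)
        assert fit.components_present["vf"]
        assert fit.tau_vf is not None and fit.tau_vf < 1.0

    def test_no_decay_reports_zero_extent(self):
        cfg = MetSimConfig(noise_sd=0.0, tau_vf=None, tau_f=None, tau_s=None,
                           adapt_fractions={})
        fam = met.correct_voltages(simulate_met_family(cfg)[0])
        fit = met.fit_adaptation(fam, step_index=30)
        assert fit.extent_pct == pytest.approx(0.0, abs=1e-9)
        assert not any(fit.components_present.values())


class TestSummarize:
    def _fits_df(self, values):
        return pd.DataFrame({"genotype": ["ctl"] * len(values),
                             "zone": ["LES"] * len(values),
                             "cell_type": ["typeI"] * len(values),
                             "g_max": values})

    def test_single_fit_has_empty_sem(self):
        out = met.summarize_met_by_group(self._fits_df([2.75]))
        assert out["g_max_mean"].iloc[0] == 2.75
        assert np.isnan(out["g_max_sem"].iloc[0])
        assert out["g_max_count"].iloc[0] == 1

    def test_identical_fits_have_zero_sem(self):
        out = met.summarize_met_by_group(self._fits_df([2.0, 2.0]))
        assert out["g_max_sem"].iloc[0] == 0.0

    def test_group_mean_recovers_truth_over_cells(self):
        rng = np.random.default_rng(1)
        vals = 2.75 + rng.normal(0, 0.05, 8)
        out = met.summarize_met_by_group(self._fits_df(list(vals)))
        assert out["g_max_mean"].iloc[0] == pytest.approx(2.75, abs=0.1)
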