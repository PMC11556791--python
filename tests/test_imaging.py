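"""Imaging quantifications: dF/F, orientation calls, synapse counts, density."""

import numpy as np
import pandas as pd
import pytest

from otophys import imaging as img
from otophys.synth import (
    ImagingSimConfig, PunctumSpec, paired_puncta_spec, simulate_imaging_fixtures,
)

EPOCHS = [img.StimEpoch("AtoP", 2.0, 0.5), img.StimEpoch("PtoA", 4.5, 0.5)]


def _trace(f, rate=10.0, roi_id=0):
    return img.RoiTrace(fluorescence=np.asarray(f, dtype=float), volume_rate=rate,
                        stim_epochs=EPOCHS, roi_id=roi_id)


class TestDff:
    def test_constant_fluorescence_gives_zero(self):
        dff = img.compute_dff(_trace(np.full(80, 50.0)), 1.5)
        assert np.all(dff.dff == 0.0)
        assert dff.f0 == 50.0

    def test_doubling_gives_peak_one(self):
        f = np.full(80, 50.0)
        f[25:30] = 100.0
        dff = img.compute_dff(_trace(f), 1.5)
        assert dff.dff.max() == pytest.approx(1.0)

    def test_gain_invariance(self):
        rng = np.random.default_rng(0)
        f = 100.0 + rng.uniform(0, 20, 80)
        d1 = img.compute_dff(_trace(f), 1.5).dff
        d2 = img.compute_dff(_trace(3.7 * f), 1.5).dff
        np.testing.assert_allclose(d1, d2, rtol=1e-12)

    def test_baseline_must_precede_stimulus(self):
        with pytest.raises(ValueError):
            img.compute_dff(_trace(np.full(80, 50.0)), 3.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            img.compute_dff(_trace(np.zeros(80)), 1.5)


class TestOrientation:
    def test_flat_trace_no_response(self):
        rng = np.random.default_rng(1)
        f = 100.0 + rng.normal(0, 0.5, 80)
        dff = img.compute_dff(_trace(f), 1.5)
        assert img.classify_bundle_orientation(dff).orientation == "no_response"

    def test_direction_specific_response(self):
        f = np.full(80, 100.0)
        f[45:50] = 130.0  # PtoA epoch frames
        dff = img.compute_dff(_trace(f), 1.5)
        assert img.classify_bundle_orientation(dff).orientation == "PtoA"

    def test_noiseless_fixture_fully_correct(self, imaging_fixture):
        traces, _, truth = imaging_fixture
        for tr in traces:
            dff = img.compute_dff(tr, 1.5)
            cls = img.classify_bundle_orientation(dff)
            assert cls.orientation == truth.params["orientations"][tr.roi_id]

    def test_noisy_fixture_mostly_correct(self):
        """>= 95% agreement at SNR ~5 (amp 0.25 * f0 = 25 a.u., noise 5)."""
        correct = total = 0
        for seed in range(10):
            cfg = ImagingSimConfig(noise_sd=5.0, seed=seed)
            traces, _, truth = simulate_imaging_fixtures(cfg)
            for tr in traces:
                cls = img.classify_bundle_orientation(img.compute_dff(tr, 1.5))
                correct += cls.orientation == truth.params["orientations"][tr.roi_id]
                total += 1
        assert correct / total >= 0.95


class TestNeuromastSummary:
    def test_two_identical_bundles_average_to_either(self, imaging_fixture):
        traces, _, _ = imaging_fixture
        dffs = [img.compute_dff(t, 1.5) for t in traces[:2]]
        cls = [img.classify_bundle_orientation(d) for d in dffs]
        out = img.summarize_neuromast_response(dffs, cls)
        np.testing.assert_allclose(out["AtoP"]["mean_dff"], dffs[0].dff)

    def test_magnitude_is_mean_of_member_amplitudes(self):
        f1, f2 = np.full(80, 100.0), np.full(80, 100.0)
        f1[45:50] = 140.0  # dF/F 0.4 in PtoA epoch
        f2[45:50] = 160.0  # dF/F 0.6
        dffs = [img.compute_dff(_trace(f, roi_id=i), 1.5) for i, f in enumerate([f1, f2])]
        cls = [img.classify_bundle_orientation(d) for d in dffs]
        out = img.summarize_neuromast_response(dffs, cls)
        assert out["PtoA"]["magnitude"] == pytest.approx(0.5)

    def test_control_like_asymmetry_preserved(self, imaging_fixture):
        traces, _, _ = imaging_fixture
        dffs = [img.compute_dff(t, 1.5) for t in traces]
        cls = [img.classify_bundle_orientation(d) for d in dffs]
        out = img.summarize_neuromast_response(dffs, cls)
        assert out["PtoA"]["magnitude"] > out["AtoP"]["magnitude"]


class TestSynapseCounts:
    def test_constructed_fixture_counts(self, imaging_fixture):
        _, pair, truth = imaging_fixture
        counts = img.count_synapses(pair)
        assert counts.complete_total == truth.params["n_complete"] == 5
        assert counts.unpaired_pre_total == truth.params["n_unpaired_pre"] == 2
        assert counts.unpaired_post_total == truth.params["n_unpaired_post"] == 1

    def test_small_presynaptic_punctum_filtered(self):
        puncta = paired_puncta_spec(n_complete=2, n_unpaired_pre=0, n_unpaired_post=0)
        puncta.append(PunctumSpec((10.0, 10.0), 0.02, "pre", 50))  # below 0.025
        cfg = ImagingSimConfig(puncta=puncta)
        _, pair, _ = simulate_imaging_fixtures(cfg)
        counts = img.count_synapses(pair)
        assert counts.n_retained_pre == 2  # the 0.02 um^2 punctum is dropped

    def test_zero_pair_distance_leaves_all_unpaired(self, imaging_fixture):
        _, pair, _ = imaging_fixture
        counts = img.count_synapses(pair, pair_distance=0.0)
        assert counts.complete_total == 0
        assert counts.unpaired_pre_total == counts.n_retained_pre

    def test_conservation_invariant_random_fixtures(self):
        rng = np.random.default_rng(7)
        for seed in range(20):
            n_c = int(rng.integers(0, 6))
            n_p = int(rng.integers(0, 4))
            n_q = int(rng.integers(0, 4))
            if n_c + n_p == 0 and n_q == 0:
                continue
            cfg = ImagingSimConfig(
                puncta=paired_puncta_spec(n_complete=n_c, n_unpaired_pre=n_p,
                                          n_unpaired_post=n_q), seed=seed)
            _, pair, _ = simulate_imaging_fixtures(cfg)
            counts = img.count_synapses(pair)
            assert counts.n_retained_pre == counts.complete_total + counts.unpaired_pre_total
            assert counts.n_retained_post == counts.complete_total + counts.unpaired_post_total


class TestSelectivity:
    def _table(self, statuses, contacted):
        return pd.DataFrame({"emx2_status": statuses, "contacted": contacted})

    def test_innervation_percentage(self):
        t = self._table(["negative"] * 10, [True] * 4 + [False] * 6)
        pct, _, _ = img.afferent_selectivity(t)
        assert pct == pytest.approx(40.0)

    def test_pure_class_full_selectivity(self):
        t = self._table(["negative"] * 5 + ["positive"] * 5,
                        [True] * 5 + [False] * 5)
        _, sel, preferred = img.afferent_selectivity(t)
        assert sel == pytest.approx(100.0) and preferred == "negative"

    def test_mixed_contacts_ratio(self):
        """6 Emx2- and 1 Emx2+ contacted: selectivity 6/7 = 85.7%."""
        t = self._table(["negative"] * 6 + ["positive"] * 4,
                        [True] * 7 + [False] * 3)
        _, sel, preferred = img.afferent_selectivity(t)
        assert sel == pytest.approx(85.714, abs=0.01) and preferred == "negative"

    def test_no_contacts(self):
        pct, sel, preferred = img.afferent_selectivity(
            self._table(["positive"] * 3, [False] * 3))
        assert (pct, sel, preferred) == (0.0, None, None)

    def test_selectivity_at_least_half_with_both_classes(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(2, 15))
            statuses = rng.choice(["positive", "negative"], n).tolist()
            contacted = rng.random(n) < 0.6
            if contacted.sum() == 0:
                continue
            _, sel, _ = img.afferent_selectivity(self._table(statuses, list(contacted)))
            assert 50.0 <= sel <= 100.0


class TestHcDensity:
    def test_worked_density(self):
        """120 cells over 15000 um^2 is 8 per 1000 um^2."""
        roi = img.RoiCountSpec(origin=(0.0, 0.0), width=130.0, height=50.0)
        pts = np.column_stack([np.linspace(1, 129, 120), np.full(120, 25.0)])
        count, density = img.hc_density(pts, roi, area=15000.0)
        assert count == 120 and density == pytest.approx(8.0)

    def test_empty_roi(self):
        roi = img.RoiCountSpec(origin=(0.0, 0.0), width=10.0, height=10.0)
        count, density = img.hc_density(np.empty((0, 2)), roi)
        assert count == 0 and density == 0.0

    def test_min_edges_inclusive_max_exclusive(self):
        roi = img.RoiCountSpec(origin=(0.0, 0.0), width=10.0, height=10.0)
        pts = np.array([[0.0, 0.0], [10.0, 5.0], [5.0, 10.0], [9.999, 9.999]])
        count, _ = img.hc_density(pts, roi)
        assert count == 2

    def test_polygon_matches_ray_casting_oracle(self):
        poly = [(0.0, 0.0), (40.0, 5.0), (50.0, 40.0), (10.0, 50.0)]
        roi = img.RoiCountSpec(polygon=poly)
        rng = np.random.default_rng(9)
        pts = rng.uniform(-5, 55, size=(300, 2))

        def inside(x, y):  # independent even-odd ray cast
            n, j, c = len(poly), len(poly) - 1, False
            for i in range(n):
                xi, yi = poly[i]
                xj, yj = poly[j]
                if ((yi > y) != (yj > y)) and (x < (xj - xi) * (y - yi) / (yj - yi) + xi):
                    c = not c
                j = i
            return c

        count, _ = img.hc_density(pts, roi)
        assert count == sum(inside(x, y) for x, y in pts)
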