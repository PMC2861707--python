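"""Traditional and corrected PRC point extraction, smoothing, and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import spikeprc as sp
from spikeprc import estimation as est
from spikeprc.trials import ValidationError


def one_trial_ensemble(spikes, pulse_time=150.0, amplitude=50.0, length=400.0):
    return sp.TrialEnsemble([
        sp.Trial("a", np.asarray(spikes, dtype=float),
                 sp.PulseEvent(pulse_time, amplitude, 0.5), length)
    ])


class TestTraditional:
    @pytest.mark.parametrize("spikes, expected_value", [
        ([0.0, 100.0, 200.0], 0.0),   # unperturbed next spike
        ([0.0, 100.0, 190.0], 0.1),   # next spike advanced by 10 ms
    ])
    def test_single_trial_arithmetic(self, spikes, expected_value, unit_stats):
        pts = sp.traditional_points(one_trial_ensemble(spikes), unit_stats)
        assert len(pts) == 1
        assert pts.loc[0, "phase"] == pytest.approx(0.5)
        assert pts.loc[0, "value"] == pytest.approx(expected_value)
        assert pts.loc[0, "band"] == 1 and pts.loc[0, "ref_offset"] == 0

    def test_no_usable_trials_is_an_error(self, unit_stats):
        ens = one_trial_ensemble([0.0, 100.0], pulse_time=150.0, length=200.0)
        with pytest.raises(ValidationError, match="no usable"):
            sp.traditional_points(ens, unit_stats)

    def test_drop_phase_gt_1_only_removes(self, jittered_ensemble):
        stats = sp.baseline_isi_stats(jittered_ensemble)
        full = sp.traditional_points(jittered_ensemble, stats)
        dropped = sp.traditional_points(jittered_ensemble, stats, drop_phase_gt_1=True)
        assert len(dropped) <= len(full)
        assert (dropped["phase"] <= 1.0).all()

    def test_causality_bound_holds_on_jittered_data(self, jittered_ensemble):
        """Brute-force check: F <= 1 - phase because s_1 must follow the pulse."""
        stats = sp.baseline_isi_stats(jittered_ensemble)
        pts = sp.traditional_points(jittered_ensemble, stats)
        # independent recomputation straight from the spike trains
        by_id = {t.trial_id: t for t in jittered_ensemble}
        for row in pts.itertuples():
            t = by_id[row.trial_id]
            s0 = t.spikes[t.spikes <= t.pulse.time][-1]
            s1 = t.spikes[t.spikes > t.pulse.time][0]
            assert row.phase == pytest.approx((t.pulse.time - s0) / stats.mean_isi)
            assert row.value == pytest.approx((stats.mean_isi - (s1 - s0)) / stats.mean_isi)
            assert row.value <= 1.0 - row.phase + 1e-12
        assert len(sp.causality_violations(pts)) == 0


class TestCorrected:
    def test_noiseless_duplication_and_band2(self, four_spike_trial, unit_stats):
        ens = sp.TrialEnsemble([four_spike_trial])
        pts = sp.corrected_points(ens, unit_stats, m_pre=1, n_post=1)
        band1 = pts[pts["band"] == 1]
        assert len(band1) == 2
        assert band1["phase"].to_numpy() == pytest.approx([0.5, 0.5])
        assert band1["value"].to_numpy() == pytest.approx([0.0, 0.0])
        band2 = pts[pts["band"] == 2]
        assert band2["phase"].to_numpy() == pytest.approx([-0.5])
        assert band2["value"].to_numpy() == pytest.approx([-0.1])
        assert band2["ref_offset"].to_numpy()[0] == -1

    @given(delta=st.floats(-20.0, 20.0))
    def test_second_reference_immune_to_s0_jitter(self, delta, unit_stats):
        """Perturbing s_0 inside its ISI leaves the s_{-1}-referenced point bit-identical."""
        base = sp.corrected_points(
            one_trial_ensemble([0.0, 100.0, 200.0, 310.0]), unit_stats, 1, 0)
        moved = sp.corrected_points(
            one_trial_ensemble([0.0, 100.0 + delta, 200.0, 310.0]), unit_stats, 1, 0)
        ref = base[base["ref_offset"] == 1].iloc[0]
        got = moved[moved["ref_offset"] == 1].iloc[0]
        assert got["phase"] == ref["phase"]
        assert got["value"] == ref["value"]

    def test_trials_contribute_the_bands_they_can(self, unit_stats):
        # only one post-pulse spike -> no band-2 point, band 1 still present
        pts = sp.corrected_points(one_trial_ensemble([0.0, 100.0, 200.0]),
                                  unit_stats, m_pre=1, n_post=4)
        assert set(pts["band"]) == {1}

    def test_negative_orders_rejected(self, four_spike_trial, unit_stats):
        ens = sp.TrialEnsemble([four_spike_trial])
        with pytest.raises(ValueError):
            sp.corrected_points(ens, unit_stats, m_pre=-1)
        with pytest.raises(ValueError):
            sp.corrected_points(ens, unit_stats, n_post=-1)

    def test_noiseless_periodic_all_values_zero(self, periodic_ensemble):
        stats = sp.baseline_isi_stats(periodic_ensemble)
        pts = sp.corrected_points(periodic_ensemble, stats, m_pre=1, n_post=4)
        assert np.allclose(pts["value"], 0.0, atol=1e-9)

    def test_post_bands_cover_documented_intervals(self, jittered_ensemble):
        stats = sp.baseline_isi_stats(jittered_ensemble)
        pts = sp.corrected_points(jittered_ensemble, stats, m_pre=1, n_post=4)
        assert set(pts["band"]) == {1, 2, 3, 4, 5}
        for band in (2, 3, 4, 5):
            lo, hi = est.band_interval(band)
            phases = pts.loc[pts["band"] == band, "phase"]
            # phases concentrate on the canonical interval (jitter spills a little)
            assert ((phases >= lo - 0.5) & (phases <= hi + 0.5)).all()
            assert phases.median() == pytest.approx((lo + hi) / 2, abs=0.15)


class TestControl:
    def test_periodic_control_is_exactly_zero(self, periodic_ensemble):
        stats = sp.baseline_isi_stats(periodic_ensemble)
        for method in ("traditional", "corrected"):
            pts = sp.control_points(periodic_ensemble, stats, 110.0, method)
            assert np.allclose(pts["value"], 0.0, atol=1e-9)
            assert (pts["trial_id"].nunique()) == len(periodic_ensemble)

    def test_virtual_time_beyond_span_skips_trials(self):
        a = sp.Trial("a", np.array([0.0, 10.0, 20.0, 30.0]), sp.PulseEvent(25.0, 1.0), 40.0)
        b = sp.Trial("b", np.array([0.0, 10.0, 20.0, 30.0]), sp.PulseEvent(12.0, 1.0), 40.0)
        ens = sp.TrialEnsemble([a, b])
        stats = sp.baseline_isi_stats(ens)
        pts = sp.control_points(ens, stats, 15.0, "traditional")
        assert set(pts["trial_id"]) == {"a"}  # b has no unperturbed spike after 15 ms


class TestHistogram:
    def test_uniform_points_equal_counts(self):
        pts = pd.DataFrame({"trial_id": "x", "band": 1, "ref_offset": 0,
                            "phase": np.arange(0.005, 1.0, 0.01), "value": 0.0})
        h = est.phase_histogram(pts, 1, 10)
        assert np.all(h.counts == 10)
        assert h.overflow_low == h.overflow_high == 0

    def test_single_bin_and_overflow_accounting(self):
        pts = pd.DataFrame({"trial_id": "x", "band": 1, "ref_offset": 0,
                            "phase": [-0.2, 0.1, 0.5, 0.9, 1.3, 1.4], "value": 0.0})
        h = est.phase_histogram(pts, 1, 1)
        assert h.counts.tolist() == [3]
        assert h.overflow_low == 1 and h.overflow_high == 2
        assert h.n_in_interval == 3

    def test_empty_band_is_an_error(self):
        pts = pd.DataFrame({"trial_id": [], "band": [], "ref_offset": [],
                            "phase": [], "value": []})
        with pytest.raises(ValidationError):
            est.phase_histogram(pts, 1, 10)


class TestSmoothing:
    @staticmethod
    def random_points(n=200, seed=5):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"trial_id": "x", "band": 1, "ref_offset": 0,
                             "phase": rng.uniform(0, 1, n),
                             "value": rng.normal(0.05, 0.02, n)})

    def test_constant_values_give_constant_curve(self):
        pts = self.random_points()
        pts["value"] = 0.05
        c = est.smooth_curve(pts, 1, 0.05, 51)
        assert np.allclose(c.mean[c.reliable], 0.05)

    def test_matches_direct_sum_oracle(self):
        """Independent brute-force Nadaraya-Watson evaluation, node by node."""
        pts = self.random_points()
        bw = 0.07
        c = est.smooth_curve(pts, 1, bw, 41)
        phases = pts["phase"].to_numpy()
        values = pts["value"].to_numpy()
        for i, x in enumerate(c.grid):
            w = np.array([np.exp(-((p - x) ** 2) / (2 * bw * bw))
                          if abs(p - x) <= 3 * bw else 0.0 for p in phases])
            if w.sum() == 0:
                continue
            assert c.mean[i] == pytest.approx(float(w @ values / w.sum()), abs=1e-12)

    @pytest.mark.parametrize("bw", [0.1, 0.05, 0.025])
    def test_curve_is_convex_combination_of_values(self, bw):
        pts = self.random_points(seed=9)
        c = est.smooth_curve(pts, 1, bw, 101)
        vmin, vmax = pts["value"].min(), pts["value"].max()
        ok = c.reliable
        assert np.all(c.mean[ok] >= vmin - 1e-12)
        assert np.all(c.mean[ok] <= vmax + 1e-12)

    def test_sparse_nodes_flagged_unreliable_not_zero(self):
        pts = self.random_points(n=50)
        pts["phase"] = pts["phase"] * 0.3          # leave [0.5, 1] empty
        c = est.smooth_curve(pts, 1, 0.02, 101)
        far = c.grid > 0.6
        assert not c.reliable[far].any()
        assert np.isnan(c.mean[far]).all()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError, match=">= 10"):
            est.smooth_curve(self.random_points(n=5), 1, 0.05, 11)


class TestBinnedMeans:
    def test_means_and_cluster_robust_se(self):
        pts = pd.DataFrame({
            "trial_id": ["a", "a", "b", "b"], "band": 1, "ref_offset": [0, 1, 0, 1],
            "phase": [0.1, 0.12, 0.14, 0.11], "value": [1.0, 1.0, 3.0, 3.0],
        })
        bm = est.binned_means(pts, 1, 5)
        row = bm.iloc[0]
        assert row["n"] == 4 and row["mean"] == pytest.approx(2.0)
        # two clusters with sums 2 and 6 about mean 2 -> SE = sqrt(2*(2^2+2^2))/4
        assert row["se"] == pytest.approx(np.sqrt(2 * 8.0) / 4)


class TestCausalityFlags:
    def test_inequality_boundary(self):
        pts = pd.DataFrame({"trial_id": ["a", "b"], "band": 1, "ref_offset": 0,
                            "phase": [0.5, 0.5], "value": [0.4, 0.6]})
        bad = est.causality_violations(pts)
        assert bad["trial_id"].tolist() == ["b"]


class TestPeaksAndClassification:
    @staticmethod
    def curve_from(values, grid=None):
        grid = np.linspace(0, 1, len(values)) if grid is None else grid
        v = np.asarray(values, dtype=float)
        return est.PRCCurve(1, grid, v, np.full_like(v, 0.01), np.full_like(v, 100.0),
                            np.ones_like(v, dtype=bool), 0.05)

    def test_flat_curve_ratio_one(self):
        pk = est.peak_to_baseline(self.curve_from([0.05] * 21))
        assert pk.early == pk.late == pytest.approx(0.05)
        assert pk.ratio == pytest.approx(1.0)
        assert est.classify_curve(pk) == "phase-independent"

    def test_late_peak_ratio(self):
        grid = np.linspace(0, 1, 101)
        vals = np.full_like(grid, 0.01)
        vals[grid > 0.6] = 0.05        # late-half extremum well inside (0.5, 1]
        pk = est.peak_to_baseline(self.curve_from(vals, grid))
        assert pk.ratio == pytest.approx(5.0)
        assert est.classify_curve(pk) == "phase-dependent"

    def test_near_zero_early_extremum_is_ambiguous(self):
        vals = np.concatenate([np.full(51, 1e-9), np.full(50, 0.05)])
        pk = est.peak_to_baseline(self.curve_from(vals))
        assert pk.label == "ambiguous"
        assert est.classify_curve(pk) == "ambiguous"

    def test_unreliable_half_raises(self):
        c = self.curve_from([0.05] * 40)
        bad = est.PRCCurve(1, c.grid, c.mean, c.se, c.n_eff,
                           np.concatenate([np.zeros(20, bool), np.ones(20, bool)]), 0.05)
        with pytest.raises(ValidationError, match="insufficient"):
            est.peak_to_baseline(bad)

    @pytest.mark.parametrize("ratio, label", [
        (1.0, "phase-independent"), (1.49, "phase-independent"),
        (5.0, "phase-dependent"), (0.2, "ambiguous"), (-2.0, "ambiguous"),
        (float("nan"), "ambiguous"),
    ])
    def test_classification_bands(self, ratio, label):
        pk = est.PeakStats(early=0.01, late=0.01 * ratio, ratio=ratio, label="")
        assert est.classify_curve(pk) == label


class TestPRCError:
    def test_identical_curves_zero(self):
        c = TestPeaksAndClassification.curve_from([0.05] * 51)
        assert est.prc_error(c, c) == 0.0

    def test_constant_offset_integrates_exactly(self):
        a = TestPeaksAndClassification.curve_from([0.05] * 51)
        b = TestPeaksAndClassification.curve_from([0.06] * 51)
        assert est.prc_error(a, b) == pytest.approx(0.01)

    def test_matches_fine_grid_refinement(self):
        rng = np.random.default_rng(3)
        grid = np.linspace(0, 1, 51)
        vals = 0.05 * np.sin(np.pi * grid) ** 2
        curve = TestPeaksAndClassification.curve_from(vals, grid)
        fine = np.linspace(0, 1, 501)
        ref = type("O", (), {})()
        ref.grid = fine
        ref.values = np.full_like(fine, 0.02)
        coarse = est.prc_error(curve, ref)
        fine_val = np.trapezoid(np.abs(np.interp(fine, grid, vals) - 0.02), fine)
        assert coarse == pytest.approx(fine_val, rel=0.01)

    def test_disjoint_grids_rejected(self):
        a = TestPeaksAndClassification.curve_from([0.05] * 11)
        b = type("O", (), {})()
        b.grid = np.linspace(2.0, 3.0, 11)
        b.values = np.zeros(11)
        with pytest.raises(ValidationError, match="disjoint"):
            est.prc_error(a, b)
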