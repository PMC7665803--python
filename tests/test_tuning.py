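import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import whisklocate as wl
from whisklocate import tuning


def _gaussian_curve(n=400, pref=5.0, sd=1.0, peak=2.0, base=0.0, seed=0,
                    window_ms=18.0):
    neuron = wl.GroundTruthNeuron(baseline_rate=base, location_pref=pref,
                                  location_sd=sd, peak_touch_spikes=peak,
                                  count_dispersion=1.0, touch_window=window_ms)
    locs, counts = wl.simulate_touch_counts(neuron, n, (0, 10), seed)
    rates = counts / (window_ms / 1000.0)
    return locs, counts, rates


class TestBuildTuningCurve:
    @given(st.integers(40, 500), st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_equal_occupancy(self, n, seed):
        rng = np.random.default_rng(seed)
        tc = wl.build_tuning_curve(rng.uniform(0, 10, n), rng.poisson(1.0, n))
        occ = tc.bin_occupancy
        assert occ.sum() == n
        assert occ.max() - occ.min() <= 1
        assert np.all(np.diff(tc.bin_stimulus) >= 0)

    def test_400_touches_fill_20_bins_of_20(self):
        locs, _, rates = _gaussian_curve(400)
        tc = wl.build_tuning_curve(locs, rates)
        assert np.all(tc.bin_occupancy == 20)

    def test_constant_response_is_flat(self):
        rng = np.random.default_rng(0)
        tc = wl.build_tuning_curve(rng.uniform(0, 10, 200), np.full(200, 3.0))
        assert tc.abs_mod_depth < 1e-6

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            wl.build_tuning_curve(np.arange(30.0), np.arange(30.0))

    def test_gaussian_preference_recovered(self):
        locs, _, rates = _gaussian_curve(400, pref=5.0, seed=3)
        tc = wl.build_tuning_curve(locs, rates)
        assert abs(tc.preference - 5.0) <= 0.5


class TestTestTuning:
    def test_strong_tuning_detected(self):
        locs, _, rates = _gaussian_curve(400, peak=2.0, seed=1)
        tc = wl.build_tuning_curve(locs, rates)
        assert wl.test_tuning(tc, seed=0)
        assert tc.F_observed > tc.F_shuffle_95

    def test_identical_responses_not_tuned(self):
        tc = wl.build_tuning_curve(np.linspace(0, 10, 100), np.full(100, 2.0))
        assert not wl.test_tuning(tc, seed=0)

    def test_null_type_one_error(self):
        """Two-step test keeps false positives near the 1% ANOVA gate."""
        rng = np.random.default_rng(5)
        hits = 0
        n_sims = 300
        for _ in range(n_sims):
            tc = wl.build_tuning_curve(rng.uniform(0, 10, 400),
                                       rng.poisson(1.0, 400).astype(float))
            hits += wl.test_tuning(tc, seed=rng)
        assert hits / n_sims <= 0.03


class TestTuningWidth:
    def test_needle_width_is_two_bins(self):
        """One hot bin: the immediate neighbors differ from the peak."""
        rng = np.random.default_rng(0)
        stim = np.repeat(np.arange(20.0), 20)
        resp = rng.normal(1.0, 0.05, 400)
        resp[stim == 10] += 10.0
        tc = wl.build_tuning_curve(stim, resp)
        wl.test_tuning(tc, seed=0)
        wb, _ = wl.tuning_width(tc)
        lo, hi = wb
        peak = tc.peak_bin
        assert (lo, hi) == (peak - 1, peak + 1)

    def test_gaussian_fwhm_matches_closed_form(self):
        """FWHM of SD-1mm Gaussian tuning = 2*sqrt(2 ln 2) ~ 2.355 mm."""
        locs, _, rates = _gaussian_curve(4000, pref=5.0, sd=1.0, peak=3.0,
                                         seed=2)
        tc = wl.build_tuning_curve(locs, rates)
        wl.test_tuning(tc, seed=0)
        _, fwhm = wl.tuning_width(tc)
        assert abs(fwhm - 2.355) < 0.3

    def test_untuned_curve_has_no_width(self):
        tc = wl.build_tuning_curve(np.linspace(0, 10, 100), np.full(100, 2.0))
        wl.test_tuning(tc, seed=0)
        with pytest.raises(ValueError):
            wl.tuning_width(tc)


class TestModulationDepths:
    def test_direct_formula(self):
        tc = tuning.TuningCurve(
            stimulus_name="x", bin_stimulus=np.arange(20.0),
            bin_response=np.zeros(20), bin_occupancy=np.full(20, 2),
            smoothed=np.linspace(4.0, 12.0, 20))
        a, m = wl.modulation_depths(tc)
        assert a == pytest.approx(8.0)
        assert m == pytest.approx(0.5)

    def test_flat_curve_zero_depth(self):
        tc = tuning.TuningCurve(
            stimulus_name="x", bin_stimulus=np.arange(20.0),
            bin_response=np.zeros(20), bin_occupancy=np.full(20, 2),
            smoothed=np.full(20, 7.0))
        a, m = wl.modulation_depths(tc)
        assert a == 0.0 and m == 0.0

    def test_all_zero_curve_flagged(self):
        tc = tuning.TuningCurve(
            stimulus_name="x", bin_stimulus=np.arange(20.0),
            bin_response=np.zeros(20), bin_occupancy=np.full(20, 2),
            smoothed=np.zeros(20))
        a, m = wl.modulation_depths(tc)
        assert a == 0.0 and m is None

    def test_recovered_depth_near_generating_range(self):
        locs, _, rates = _gaussian_curve(2000, pref=5.0, sd=1.5, peak=2.0,
                                         base=0.0, seed=7)
        tc = wl.build_tuning_curve(locs, rates)
        generating_abs = 2.0 / (18.0 / 1000.0)  # peak rate, min ~ 0
        assert abs(tc.abs_mod_depth - generating_abs) < 0.15 * generating_abs


class TestStratifiedTuning:
    def test_independent_covariate_gives_equal_halves(self):
        rng = np.random.default_rng(0)
        stim = rng.uniform(0, 10, 2000)
        resp = rng.poisson(3.0, 2000).astype(float)
        cov = rng.uniform(0, 1, 2000)
        s = wl.stratified_tuning(stim, resp, cov)
        used = s.used_bins
        assert np.abs(s.high_response[used] - s.low_response[used]).mean() < 0.5
        assert abs(s.pct_increase) < 10

    def test_covariate_scaled_response_separates(self):
        rng = np.random.default_rng(1)
        stim = rng.uniform(0, 10, 2000)
        cov = rng.uniform(0.5, 1.5, 2000)
        base = 2.0 + np.exp(-0.5 * (stim - 5) ** 2)
        resp = rng.poisson(base * cov)
        s = wl.stratified_tuning(stim, resp.astype(float), cov)
        used = s.used_bins
        assert np.all(s.high_response[used] >= s.low_response[used] - 0.3)
        assert s.pct_increase > 10

    def test_constant_covariate_is_error(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            wl.stratified_tuning(rng.uniform(0, 10, 100),
                                 rng.poisson(1.0, 100).astype(float),
                                 np.ones(100))


class TestFanoPerBin:
    def test_poisson_counts_fano_near_one(self):
        rng = np.random.default_rng(0)
        fanos = []
        for _ in range(10):
            tc = wl.build_tuning_curve(rng.uniform(0, 10, 400),
                                       rng.poisson(1.5, 400))
            fanos.extend(wl.fano_per_bin(tc))
        assert len(fanos) >= 100
        assert abs(np.mean(fanos) - 1.0) < 0.1

    def test_deterministic_counts_fano_zero(self):
        tc = wl.build_tuning_curve(np.linspace(0, 10, 100), np.full(100, 2.0))
        assert np.allclose(wl.fano_per_bin(tc), 0.0)

    def test_doubled_counts_double_fano(self):
        rng = np.random.default_rng(3)
        counts = 2 * rng.poisson(1.0, 2000)
        tc = wl.build_tuning_curve(rng.uniform(0, 10, 2000), counts)
        assert abs(np.mean(wl.fano_per_bin(tc)) - 2.0) < 0.25
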