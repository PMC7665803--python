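import numpy as np
import pytest
from scipy.signal import butter, sosfiltfilt

import whisklocate as wl
from whisklocate.synthetic import draw_counts


class TestSimulateWhisking:
    def test_same_seed_is_deterministic(self):
        m = wl.WhiskingModel()
        a = wl.simulate_whisking(m, 5.0, seed=3).angle
        b = wl.simulate_whisking(m, 5.0, seed=3).angle
        assert np.array_equal(a, b)

    def test_zero_amplitude_gives_constant_quiet_angle(self):
        m = wl.WhiskingModel(amplitude_range=0.0, quiet_angle=62.0)
        sim = wl.simulate_whisking(m, 2.0, seed=0)
        assert np.allclose(sim.angle, 62.0)
        assert not sim.bout_mask.any()

    def test_pure_bout_recovered_by_hilbert(self):
        """A near-continuous 10-Hz bout at ~15 deg envelope decomposes to
        the generating amplitude and zero phase at angle maxima."""
        m = wl.WhiskingModel(bout_rate=0.2, bout_duration_mean=30.0,
                             bout_duration_sd=0.0, carrier_freq=10.0,
                             amplitude_range=(15.0, 15.0),
                             midpoint_drift_sd=0.0)
        sim = wl.simulate_whisking(m, 20.0, seed=1)
        assert sim.bout_mask.mean() > 0.5
        ks = wl.hilbert_decompose(sim.angle)
        core = sim.bout_mask.copy()
        # stay clear of bout edges
        core &= np.roll(core, 200) & np.roll(core, -200)
        assert abs(ks.amplitude[core].mean() - 15.0) < 0.5
        peaks = core & (sim.angle > np.roll(sim.angle, 1)) \
            & (sim.angle > np.roll(sim.angle, -1))
        assert np.abs(ks.phase[peaks]).max() < 0.15

    def test_bout_power_is_in_band(self):
        """During bouts the oscillatory energy lies inside 6-60 Hz."""
        m = wl.WhiskingModel(bout_rate=0.2, bout_duration_mean=30.0,
                             bout_duration_sd=0.0, midpoint_drift_sd=0.0)
        sim = wl.simulate_whisking(m, 20.0, seed=5)
        sos = butter(4, (6, 60), btype="bandpass", fs=1000, output="sos")
        band = sosfiltfilt(sos, sim.angle)
        osc = sim.angle - sim.midpoint
        core = sim.bout_mask & np.roll(sim.bout_mask, 300) \
            & np.roll(sim.bout_mask, -300)
        ratio = np.var(band[core] - osc[core]) / np.var(osc[core])
        assert ratio < 0.05

    def test_duration_must_be_positive(self):
        with pytest.raises(ValueError):
            wl.simulate_whisking(wl.WhiskingModel(), 0.0, seed=0)


class TestDrawCounts:
    @pytest.mark.parametrize("fano", [0.5, 0.94, 1.0, 2.0])
    def test_fano_within_ten_percent(self, fano):
        rng = np.random.default_rng(0)
        c = draw_counts(np.full(20000, 1.2), fano, rng)
        assert c.min() >= 0 and np.issubdtype(c.dtype, np.integer)
        assert abs(c.mean() - 1.2) < 0.05
        assert abs(c.var() / c.mean() - fano) < 0.1 * fano + 0.02

    def test_zero_mean_gives_zero_counts(self):
        rng = np.random.default_rng(0)
        assert draw_counts(np.zeros(10), 1.0, rng).sum() == 0


class TestSimulateSession:
    def test_angle_at_touch_tracks_pole_location(self, location_tuned_bundle):
        locs, angs = [], []
        for tr in location_tuned_bundle.trials:
            for tc in tr.touches:
                locs.append(tr.pole_location)
                angs.append(tc.angle_at_touch)
        assert len(locs) > 100
        assert np.corrcoef(locs, angs)[0, 1] > 0.9

    def test_location_tuning_matches_generating_gaussian(self):
        """Per-location mean counts follow the closed-form tuning profile."""
        neuron = wl.GroundTruthNeuron(baseline_rate=0.0, location_pref=5.0,
                                      location_sd=1.0, peak_touch_spikes=2.0,
                                      count_dispersion=1.0)
        locs, counts = wl.simulate_touch_counts(neuron, 4000, (0, 10), seed=0)
        for lo in (3.0, 4.5, 6.0):
            sel = (locs >= lo) & (locs < lo + 0.5)
            expected = neuron.touch_mean_count(locs[sel]).mean()
            se = np.sqrt(expected / sel.sum()) + 1e-9
            assert abs(counts[sel].mean() - expected) < 4 * se + 0.05

    def test_unresponsive_neuron_has_flat_psth(self, untuned_bundle):
        aligned = wl.touch_psth(untuned_bundle)
        pre = aligned.bins < 0
        post = (aligned.bins >= 5) & (aligned.bins < 50)
        assert abs(aligned.psth[post].mean() - aligned.psth[pre].mean()) < 1.5

    def test_degenerate_pole_range_rejected(self):
        with pytest.raises(ValueError):
            wl.simulate_session(wl.GroundTruthNeuron(), n_trials=5,
                                pole_range=(3.0, 3.0), seed=0)

    def test_fano_knob_controls_touch_count_dispersion(self):
        neuron = wl.GroundTruthNeuron(baseline_rate=0.0, location_pref=None,
                                      peak_touch_spikes=1.5,
                                      count_dispersion=1.0)
        _, counts = wl.simulate_touch_counts(neuron, 5000, (0, 10), seed=1)
        assert abs(counts.var() / counts.mean() - 1.0) < 0.1


class TestSimulatePopulation:
    def test_zero_neurons_is_empty(self):
        assert wl.simulate_population(0, seed=0) == []

    def test_fixed_seed_reproducible(self):
        spec = wl.PopulationSpec(n_trials=10)
        a = wl.simulate_population(2, spec, seed=9)
        b = wl.simulate_population(2, spec, seed=9)
        assert a[0].total_spikes() == b[0].total_spikes()
        assert np.array_equal(a[1].whisker_angle[0], b[1].whisker_angle[0])
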