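import numpy as np
import pytest

import whisklocate as wl


@pytest.fixture(scope="session")
def location_tuned_bundle() -> wl.SessionBundle:
    """A session from a location-tuned touch neuron (pref 5 mm, SD 1 mm)."""
    neuron = wl.GroundTruthNeuron(
        baseline_rate=5.0, touch_latency=10.0, touch_window=18.0,
        location_pref=5.0, location_sd=1.0, peak_touch_spikes=1.5,
        count_dispersion=1.0)
    return wl.simulate_session(neuron, n_trials=60, seed=42,
                               session_id="loc_tuned")


@pytest.fixture(scope="session")
def untuned_bundle() -> wl.SessionBundle:
    """A touch-unresponsive, untuned neuron (homogeneous background)."""
    neuron = wl.GroundTruthNeuron(
        baseline_rate=5.0, touch_responsive=False, location_pref=None,
        peak_touch_spikes=0.0, count_dispersion=1.0)
    return wl.simulate_session(neuron, n_trials=60, seed=43,
                               session_id="untuned")
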