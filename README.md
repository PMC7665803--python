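# whisklocate

Analysis pipeline for head-fixed whisker-guided object localization:
single-unit barrel-cortex (L5) recordings during a go/no-go task in which a
mouse whisks against a vertical pole presented over a contiguous 10-mm
anteroposterior range. The package turns per-session whisker traces, touch
events and spike times into the standard population analyses of this
paradigm:

- **Kinematics** — the 1-kHz whisker-angle series is band-pass filtered
  6–60 Hz (zero-phase Butterworth) and decomposed via the Hilbert transform
  into amplitude, phase (0 = most protracted, ±π = most retracted), and the
  slow midpoint; whisking epochs are amplitude > 5° with bout hygiene.
- **Touch responses** — peri-touch spike histograms (−50..+50 ms, 1-ms
  bins) are smoothed with a GCV-penalized spline; the touch-response window
  is the longest span in 5–50 ms post touch exceeding a null-calibrated
  baseline threshold, with edges relocalized by a Poisson changepoint fit.
  A touch unit needs a window > 4 ms with mean rate > 2 Hz.
- **Tuning curves** — for any stimulus *s* (pole location, whisker angle at
  touch, free-whisking angle/phase), responses are sorted by *s* into 20
  equal-occupancy bins (bin stimulus = median, response = mean rate in the
  unit's response window). Significance is a two-step test: one-way ANOVA
  across bins at α = 0.01, then 1,000 response shuffles with the observed F
  required to exceed the 95th percentile of shuffled F. Preference, tuning
  width (Tukey–Kramer against the peak bin; FWHM of the smoothed curve),
  and modulation depths (max − min and (max − min)/(max + min)) follow.
- **Decoding** — each included neuron's location tuning curve (expected
  spike count per touch) is interpolated to 40 bins (0.25 mm); 50 Poisson
  samples per bin form a pseudo-population design matrix decoded with a
  multinomial elastic-net logistic model (lasso mixing 0.95, 70/30
  stratified splits, 10 iterations). Outputs: confusion matrix, exact-bin
  accuracy, resolution-within-*n*-bins curves, neurometric (simulated
  lick-probability) curves, and accuracy vs neuron-pool size via 500
  with-replacement subsamples of the learned coefficients. A closed-form
  Poisson maximum-likelihood classifier over the true rate maps serves as
  the performance ceiling.
- **Independence** — whether free-whisking and touch representations are
  independent: observed co-tuned fraction vs the product-rule expectation,
  per-neuron tuning-curve shape correlation vs randomly re-paired curves
  (two-sample KS), and preferred-stimulus displacement (circular for phase).
- **Synthetic sessions** — a first-class generator with known ground truth
  (rhythmic whisking bouts, location-mapped touch thresholds, Gaussian
  touch-location tuning, near-Poisson count dispersion with Fano ≈ 0.94)
  so every stage is validated by parameter recovery.

## Worked example

```python
import numpy as np
import whisklocate as wl

neuron = wl.GroundTruthNeuron(baseline_rate=5.0, touch_latency=10.0,
                              touch_window=18.0, location_pref=5.0,
                              location_sd=1.0, peak_touch_spikes=1.5)
bundle = wl.simulate_session(neuron, n_trials=60, seed=42)

profile = wl.detect_window(wl.touch_psth(bundle), seed=0)
print(profile.window, profile.is_touch_unit)

locs, angles, counts = wl.window_counts(bundle, profile.window)
rates = counts / ((profile.window[1] - profile.window[0]) / 1000.0)
curve = wl.build_tuning_curve(locs, rates, "pole_location")
print(wl.test_tuning(curve, seed=0), round(curve.preference, 2))
```

prints

```
(10.0, 28.0) True
True 5.52
```

— the detector recovers the neuron's 10–28 ms touch-response window
exactly, and the equal-occupancy tuning curve is significantly
location-tuned with its peak at 5.52 mm, near the generating preference
(5 mm; ~500 touches put the peak-bin median within one bin width).

The same stages are available from the shell:

```bash
whisklocate simulate --config sim.cfg --out sessions/ --seed 1
whisklocate tuning   --in sessions/ --out results/ --seed 1
whisklocate decode   --in sessions/ --out results/ --seed 1
```

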