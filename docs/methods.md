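# Methods

This note records the models, conventions, and numerical choices behind
`whisklocate`, and what the synthetic-data validation does and does not
establish about real recordings.

## Data model and conventions

A session is one neuron recorded over many trials (0.5 s pre-pole, 0.75 s
stimulus sampling, 1.25 s answer period; 2.5 s total at 1 kHz). All times
are milliseconds from trial start; angles are degrees (larger = more
protracted); pole locations are mm with 0 = most posterior presented
position and the posterior half of the range treated as "go". Times,
spikes and whisker samples share the millisecond grid; spike times keep
sub-millisecond jitter as floats. On disk a session is a directory of
plain CSV tables plus a key–value metadata file; floats are written at
full precision so write → read → write is byte-identical. Trials without a
tracked whisker are retained but excluded from kinematic analyses.

## Kinematic decomposition

The angle series is filtered 6–60 Hz with a 4th-order Butterworth applied
forward–backward (zero phase; the order is a standard, stable choice at
1 kHz for this band). Amplitude and phase are the magnitude and angle of
the analytic signal of the band-passed trace; with this convention phase 0
falls at protraction maxima and negative phase is protraction. The
midpoint is (angle − band-passed) low-pass filtered at 6 Hz, i.e. the slow
set-point of whisking. Velocity is the centred first difference × 1000.
Decomposition requires ≥ 256 samples (filter warm-up).

Whisking is amplitude > 5°; gaps < 50 ms are merged and bouts < 50 ms
dropped to suppress threshold chatter (the hygiene values are a package
choice; segmentation remains monotone in the threshold). Whisking-vs-quiet
rate modulation uses a 1-df chi-squared test of the whisking spike count
against the expectation proportional to time in state, at α = 0.01.

## Touch-response windows

The peri-touch histogram pools touches at least 50 ms after the previous
touch (overlap protection) into 1-ms bins over −50..+50 ms. Smoothing uses
a penalized cubic B-spline (knot per sample, second-difference coefficient
penalty) with the penalty chosen per curve by generalized cross-validation
over a fixed log-spaced grid; factorizations are cached per grid so
smoothing many curves is cheap. The smoother is a hook — any callable
`(x, y) -> smoothed` can be substituted.

The response window is the longest contiguous span in 5–50 ms post touch
where the smoothed rate exceeds a threshold calibrated on the detector's
own null: 19 surrogate PSTHs are simulated from a homogeneous Poisson at
the measured baseline rate and smoothed identically, and the threshold is
the largest value any of them attains in the search region (exact 1-in-20
null exceedance by exchangeability), never below the upper bound of a
2,000-resample bootstrap CI of the baseline mean. Because any
fixed-bandwidth smoother blurs a sharp response's edges outward by a
couple of milliseconds, each window edge is then relocalized by a local
single-step Poisson changepoint fit on the raw pooled counts. A touch unit
requires window duration > 4 ms and mean in-window rate > 2 Hz. On
synthetic responses spanning latencies 6–26 ms and durations 4–39 ms the
recovered parameters are exact to ±2 ms, and homogeneous-Poisson nulls
pass the gate in ≤ 5% of 1,000 simulations. Non-touch units fall back to
the 10–28 ms population-median window wherever a response window is
needed.

## Tuning curves and significance

Samples (touches, or whisking time points taken every 5 ms — adjacent
milliseconds share an integration window and carry little independent
information) are sorted by stimulus with a stable sort (ties keep input
order) and split into 20 equal-count bins; occupancies never differ by
more than one. Responses are rates in the unit's response window; whisking
curves are only evaluated for units with mean whisking response ≥ 2 Hz.
The fitted curve is the same GCV spline evaluated at the bin medians, and
modulation depths are read from it (max − min, and normalized by the sum;
undefined when the curve is identically zero, and negative smoothed rates
are clipped at zero).

Significance is two-step: a one-way ANOVA across bins at α = 0.01, then
1,000 label shuffles with the observed F required to exceed the 95th
percentile of the shuffled F distribution. On Poisson nulls the combined
false-positive rate is ≈ 1%. Tuning width takes a Tukey–Kramer-type
critical value (α = 0.05, family of 20 bins) for comparisons against the
peak bin and reports the first significantly different bin on each side,
plus the full width at half maximum of the smoothed curve on a dense grid.
Curvature stratification median-splits each stimulus bin by the covariate
(bins with < 4 touches excluded). Per-bin Fano factors use spike counts,
skipping zero-mean bins.

## Decoding

Inclusion requires ≥ 75 touches covering ≥ 80% of 0.5-mm location bins.
Count tuning curves are interpolated to 40 bins (0.25 mm) with a monotone
piecewise cubic clipped at zero; 50 Poisson draws per bin per neuron form
a 2,000-row design matrix. The decoder is a multinomial logistic model
with elastic-net regularization at lasso mixing 0.95 (scikit-learn saga on
standardized counts), trained on stratified 70% splits for 10 iterations;
the inverse regularization strength is selected once by 3-fold
cross-validation on the first training split from a small grid. Both
iteration modes are provided: re-split only (default) or redraw the
Poisson design each iteration.

The model's final coefficient matrix is the mean of the 10 iterations'
estimates mapped back to raw count space (the standardizer folded in).
Averaging is deliberate: a single 1,400-row fit of 40 classes × 25 neurons
is estimation-noise limited and sits well below the exact-likelihood
ceiling, while the averaged coefficients in redraw mode come within ~2
percentage points of a brute-force Bayes classifier using the true Poisson
rates. Reported metrics include the per-iteration mean test accuracy, the
ensemble accuracy on held-out rows, the row-normalized confusion matrix,
resolution-within-*n*-bins curves (n = 2 bins ↔ ≤ 0.5 mm), and neurometric
curves (summed predicted mass on the posterior "go" half per true
location; a simulated lick is probability > 50%). Pool-size curves draw
neurons with replacement 500 times and restrict the learned coefficients
to the drawn columns without refitting; argmax ties break to the lower
bin. Comparison against an externally supplied psychometric table uses a
per-location Welch t test, interpolating mismatched grids with a warning.

Because neurons are recorded serially, the design matrix is a
pseudo-population: between-neuron count correlations are absent by
construction, which flatters any decoder relative to simultaneous
recordings.

## Independence analysis

Overlap statistics compare the observed co-tuned fraction with the product
of the marginal tuned fractions; under independence the observed value
must also lie in the Fréchet interval [max(0, p_w + p_t − 1),
min(p_w, p_t)]. Shape correlation resamples both normalized (min–max)
curves onto 20 points spanning the intersection of their stimulus
supports, and compares the within-neuron Pearson r distribution against
random re-pairings of whisking and touch curves across neurons (a
permutation, so each marginal curve multiset is preserved exactly) with a
two-sample KS test. Preference displacement is |pref_touch −
pref_whisking| (circular distance in [0, π] for phase), a one-sample
t test against zero, and the correlation between the two preferences;
skipped below 3 co-tuned units.

## Synthetic sessions

The generator emulates the study's conditions: whisking bouts as a Poisson
process (0.6 bouts/s, gamma durations ~1 s) carrying a 12-Hz carrier under
a slowly varying 8–20° envelope with cosine-ramped edges, a < 6-Hz
midpoint random walk around a 65° set-point, and poles uniform over a
10-mm range. Touches are emitted when the angle crosses a
location-mapped threshold (68° + 1.2°/mm), so angle-at-touch is tightly,
monotonically related to pole location without a contact-mechanics model;
touch "strength" (max curvature change) is a noisy increasing function of
crossing depth with a weak location term. Touch-evoked counts follow
Gaussian location tuning (configurable preference/SD/peak) with dispersion
controlled exactly: Poisson at Fano 1, a two-point binomial mixture for
Fano < 1 (mean and variance matched), negative binomial for Fano > 1; the
default Fano is 0.94. Free-whisking spikes follow multiplicative gain,
Gaussian angle tuning and cosine phase tuning. Population draws give
independent sessions per neuron — a pseudo-population by construction.

What passing recovery tests shows: the estimators are unbiased and
calibrated when their assumptions hold. What they do not show: robustness
to tracking noise and dropped frames, non-Gaussian or multi-peaked tuning,
rate nonstationarity across a session, whisker-curvature dynamics, or
correlated population variability — none of which the generator emulates.
Note also that whisking-phase tuning estimated through a lagged response
window is shifted by the carrier-period fraction of the window delay; this
is a property of the windowed method itself, so phase "preferences" are
interpretable relative to, not identical with, the generating phase.

## Problem sizes and determinism

Validation runs use sizes that make Monte-Carlo error small relative to
the tolerances: 400 touches per tuning curve, 50-neuron recovery
populations, 1,000-run null calibrations, 25-neuron decoding designs with
500 subsample draws. All stochastic steps take an explicit seed or
generator; identical seeds give identical outputs.
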