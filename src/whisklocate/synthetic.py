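"""Synthetic sessions with known ground truth.

Every analysis stage in the package is validated by parameter recovery on
sessions generated here: rhythmic whisking bouts in the 6-60 Hz band with a
drifting midpoint, pole presentations over a contiguous 10-mm range, touches
whose whisker angle tracks pole location, and spike trains with configurable
baseline, whisking/angle/phase tuning, and Gaussian touch-location tuning
with near-Poisson count dispersion (default Fano factor 0.94).

Touches are emitted when the simulated protraction crosses an angle
threshold mapped from pole location, rather than from contact mechanics;
this preserves the angle-location coupling the analyses need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .session_io import SessionBundle, TouchEvent, Trial

FS = 1000.0  # Hz


@dataclass
class WhiskingModel:
    """Generative model of the whisker-angle series.

    Angle = quiet set-point + slow midpoint drift + envelope x cos(2 pi f t),
    with the drift and envelope active only during whisking bouts (cosine
    ramps at bout edges avoid spectral splatter).
    """

    bout_rate: float = 0.6            # bouts/s (Poisson process)
    bout_duration_mean: float = 1.0   # s, gamma distributed
    bout_duration_sd: float = 0.4
    carrier_freq: float = 12.0        # Hz, inside the 6-60 Hz analysis band
    amplitude_range: tuple[float, float] | float = (8.0, 20.0)  # deg envelope
    midpoint_drift_sd: float = 2.5    # deg, slow (<6 Hz) random walk
    quiet_angle: float = 65.0         # deg
    ramp_ms: int = 30

    def _amp_bounds(self) -> tuple[float, float]:
        if np.isscalar(self.amplitude_range):
            a = float(self.amplitude_range)
            return (a, a)
        lo, hi = self.amplitude_range  # type: ignore[misc]
        return float(lo), float(hi)


@dataclass
class GroundTruthNeuron:
    """Ground-truth rate model for one simulated L5 unit.

    Rates in Hz; preferences of ``None`` disable that tuning axis.
    ``count_dispersion`` is the target Fano factor of touch-window spike
    counts (1 = Poisson).
    """

    baseline_rate: float = 4.0
    whisking_gain: float = 1.0
    angle_pref: float | None = None   # deg
    angle_kappa: float = 8.0          # deg (Gaussian SD)
    phase_pref: float | None = None   # rad
    phase_depth: float = 0.0          # [0, 1]
    touch_responsive: bool = True
    touch_latency: float = 10.0       # ms
    touch_window: float = 18.0        # ms
    location_pref: float | None = 5.0  # mm
    location_sd: float = 1.0          # mm
    peak_touch_spikes: float = 1.5    # expected count per touch at preference
    count_dispersion: float = 0.94    # Fano factor

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.peak_touch_spikes < 0:
            raise ValueError("rates must be >= 0")
        if self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be > 0")
        if self.location_pref is not None and not 0 <= self.location_pref <= 10:
            raise ValueError("location_pref must lie in [0, 10] mm")

    def touch_mean_count(self, location: np.ndarray | float) -> np.ndarray:
        """Expected touch-window spike count as a function of pole location,
        including the baseline expectation inside the window."""
        loc = np.asarray(location, dtype=float)
        base = self.baseline_rate * self.touch_window / 1000.0
        if not self.touch_responsive:
            return np.broadcast_to(base, loc.shape).copy()
        if self.location_pref is None:
            evoked = np.full_like(loc, self.peak_touch_spikes)
        else:
            evoked = self.peak_touch_spikes * np.exp(
                -0.5 * ((loc - self.location_pref) / self.location_sd) ** 2)
        return base + evoked


@dataclass
class SimulatedWhisking:
    """Angle trace plus the generator's own decomposition (ground truth)."""

    angle: np.ndarray
    envelope: np.ndarray      # instantaneous amplitude, deg
    midpoint: np.ndarray      # deg
    phase: np.ndarray         # rad, wrapped
    bout_mask: np.ndarray     # True inside bouts (any amplitude)

    def suprathreshold_mask(self, threshold: float = 5.0) -> np.ndarray:
        """Where the ground-truth envelope exceeds ``threshold`` degrees."""
        return self.envelope > threshold


def draw_counts(mean, fano: float, rng: np.random.Generator) -> np.ndarray:
    """Nonnegative integer counts with given mean(s) and Fano factor.

    Poisson for Fano 1; a binomial thinning scheme for Fano < 1; negative
    binomial for Fano > 1.
    """
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    if not np.any(pos):
        return out
    m = mean[pos]
    if abs(fano - 1.0) < 1e-9:
        out[pos] = rng.poisson(m)
    elif fano < 1.0:
        # binomial(n, m/n) has Fano 1 - m/n; mix the two integers bracketing
        # the ideal (real-valued) n so mean and variance match exactly
        nu = m / (1.0 - fano)
        n0 = np.maximum(np.floor(nu), np.ceil(m)).astype(int)
        n0 = np.maximum(n0, 1)
        n1 = n0 + 1
        v = fano * m
        v0 = m * (1.0 - m / n0)
        v1 = m * (1.0 - m / n1)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.clip((v1 - v) / np.where(v1 > v0, v1 - v0, 1.0), 0.0, 1.0)
        n = np.where(rng.random(m.shape) < w, n0, n1)
        out[pos] = rng.binomial(n, m / n)
    else:
        r = m / (fano - 1.0)
        out[pos] = rng.negative_binomial(r, r / (r + m))
    return out


def _slow_noise(n: int, rng: np.random.Generator, cutoff_hz: float = 3.0) -> np.ndarray:
    """Unit-variance noise band-limited below the whisking band."""
    if n < 64:
        return np.zeros(n)
    w = rng.standard_normal(n)
    sos = butter(2, cutoff_hz, btype="lowpass", fs=FS, output="sos")
    s = sosfiltfilt(sos, w)
    sd = s.std()
    return s / sd if sd > 0 else s


def simulate_whisking(model: WhiskingModel, duration: float,
                      seed: int | np.random.Generator) -> SimulatedWhisking:
    """Generate a 1-kHz whisker-angle series of ``duration`` seconds."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration * FS))
    t = np.arange(n) / FS
    amp_lo, amp_hi = model._amp_bounds()

    if amp_hi <= 0:
        flat = np.full(n, model.quiet_angle)
        return SimulatedWhisking(angle=flat, envelope=np.zeros(n),
                                 midpoint=flat.copy(),
                                 phase=np.zeros(n),
                                 bout_mask=np.zeros(n, dtype=bool))

    # Poisson bout onsets, gamma durations, merged if overlapping
    bout_mask = np.zeros(n, dtype=bool)
    n_bouts = rng.poisson(model.bout_rate * duration)
    starts = np.sort(rng.uniform(0, duration, n_bouts))
    mean, sd = model.bout_duration_mean, model.bout_duration_sd
    if sd > 0:
        shape = (mean / sd) ** 2
        durs = rng.gamma(shape, mean / shape, n_bouts)
    else:
        durs = np.full(n_bouts, mean)
    for s, d in zip(starts, durs):
        i0, i1 = int(s * FS), min(n, int((s + d) * FS))
        bout_mask[i0:i1] = True

    # cosine-ramped bout window
    window = bout_mask.astype(float)
    ramp = model.ramp_ms
    if ramp > 0 and n > 2 * ramp:
        kernel = np.hanning(2 * ramp + 1)
        kernel /= kernel.sum()
        window = np.convolve(window, kernel, mode="same")

    # slowly varying envelope within the configured range
    amp_mod = _slow_noise(n, rng, cutoff_hz=1.5)
    amp01 = 0.5 * (1 + np.tanh(amp_mod))
    envelope = (amp_lo + (amp_hi - amp_lo) * amp01) * window

    midpoint = model.quiet_angle + model.midpoint_drift_sd * \
        _slow_noise(n, rng, cutoff_hz=2.0) * window
    phi0 = rng.uniform(-np.pi, np.pi)
    inst_phase = 2 * np.pi * model.carrier_freq * t + phi0
    angle = midpoint + envelope * np.cos(inst_phase)
    wrapped = np.angle(np.exp(1j * inst_phase))
    return SimulatedWhisking(angle=angle, envelope=envelope, midpoint=midpoint,
                             phase=wrapped, bout_mask=bout_mask)


def simulate_touch_counts(neuron: GroundTruthNeuron, n_touches: int,
                          pole_range: tuple[float, float],
                          seed: int | np.random.Generator,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Light-weight generator: (pole locations, touch-window spike counts).

    Locations are uniform over ``pole_range``; counts follow the neuron's
    Gaussian location tuning with its configured dispersion.  Used where the
    full kinematic simulation is unnecessary (tuning and decoding tests).
    """
    lo, hi = pole_range
    if not hi > lo:
        raise ValueError("pole_range must have positive width")
    rng = np.random.default_rng(seed)
    locations = rng.uniform(lo, hi, n_touches)
    counts = draw_counts(neuron.touch_mean_count(locations),
                         neuron.count_dispersion, rng)
    return locations, counts


def _trial_outcome(go: bool, licked: bool) -> str:
    if go:
        return "hit" if licked else "miss"
    return "false_alarm" if licked else "correct_rejection"


def simulate_session(neuron: GroundTruthNeuron,
                     whisking: WhiskingModel | None = None,
                     n_trials: int = 100,
                     pole_range: tuple[float, float] = (0.0, 10.0),
                     seed: int | np.random.Generator = 0,
                     session_id: str = "synthetic",
                     condition: str = "naive",
                     neuron_depth: float = 780.0,
                     touch_theta0: float = 68.0,
                     touch_slope: float = 1.2,
                     max_touch_ms: float = 50.0) -> SessionBundle:
    """Simulate one neuron's session.

    Touch onsets are the times the whisker angle crosses a pole-mapped
    threshold ``touch_theta0 + touch_slope * pole_location`` during
    protraction while the pole is in reach, so angle-at-touch is tightly,
    monotonically related to pole location.  Touch-evoked spikes are laid
    uniformly over ``[onset+latency, onset+latency+window)`` with per-touch
    counts drawn at the neuron's location tuning and dispersion;
    free-whisking spikes follow the angle/phase tuning.
    """
    lo, hi = pole_range
    if not hi > lo:
        raise ValueError("pole_range must have positive width")
    if n_trials <= 0:
        raise ValueError("n_trials must be > 0")
    if whisking is None:
        whisking = WhiskingModel()
    rng = np.random.default_rng(seed)

    trials: list[Trial] = []
    spike_times: list[np.ndarray] = []
    whisker_angle: list[np.ndarray] = []
    mask_flags: list[np.ndarray] = []

    proto = Trial(pole_location=lo)
    dur_ms = proto.duration_ms
    dur_s = dur_ms / 1000.0
    pole_in_reach_ms = int(proto.pole_onset * 1000) + 200  # pole takes ~200 ms

    for _ in range(n_trials):
        sim = simulate_whisking(whisking, dur_s, rng)
        pole = rng.uniform(lo, hi)
        theta = touch_theta0 + touch_slope * pole

        # threshold crossings during protraction = touch onsets
        ang = sim.angle
        above = ang >= theta
        cross = np.flatnonzero(~above[:-1] & above[1:]) + 1
        cross = cross[cross >= pole_in_reach_ms]
        touches: list[TouchEvent] = []
        prev_off = -np.inf
        for c in cross:
            if c <= prev_off:
                continue
            below = np.flatnonzero(~above[c:])
            off = c + (below[0] if below.size else 1)
            off = min(off, c + max_touch_ms, dur_ms)
            if off <= c:
                off = min(c + 1, dur_ms)
            depth = float(ang[c:int(off)].max() - theta) if int(off) > c else 0.0
            kappa = max(0.0, 3e-3 + 4e-3 * depth + 6e-4 * pole
                        + rng.normal(0, 3e-3))
            touches.append(TouchEvent(
                onset=float(c), offset=float(off),
                angle_at_touch=float(ang[c] + rng.normal(0, 0.3)),
                max_curvature_change=kappa, direction="protraction"))
            prev_off = off

        # background + whisking-modulated spikes (Bernoulli per ms ~ Poisson)
        rate = np.full(dur_ms, neuron.baseline_rate)
        wmask = sim.bout_mask
        mod = np.full(dur_ms, neuron.whisking_gain)
        if neuron.angle_pref is not None:
            mod = mod * np.exp(-0.5 * ((ang - neuron.angle_pref)
                                       / neuron.angle_kappa) ** 2)
        if neuron.phase_pref is not None and neuron.phase_depth > 0:
            mod = mod * (1 + neuron.phase_depth
                         * np.cos(sim.phase - neuron.phase_pref))
        rate[wmask] = neuron.baseline_rate * mod[wmask]
        spikes = np.flatnonzero(rng.random(dur_ms) < rate / 1000.0).astype(float)
        spikes += rng.uniform(0, 1, spikes.size)  # jitter within the ms bin

        # touch-evoked spikes with controlled count dispersion
        extra: list[np.ndarray] = []
        for tc in touches:
            mean_evoked = neuron.touch_mean_count(pole) \
                - neuron.baseline_rate * neuron.touch_window / 1000.0
            cnt = int(draw_counts(max(mean_evoked, 0.0),
                                  neuron.count_dispersion, rng)[0])
            if cnt:
                t0 = tc.onset + neuron.touch_latency
                extra.append(np.clip(
                    t0 + rng.uniform(0, neuron.touch_window, cnt), 0, dur_ms))
        if extra:
            spikes = np.sort(np.concatenate([spikes] + extra))
        spikes = spikes[(spikes >= 0) & (spikes <= dur_ms)]

        go = pole <= 0.5 * (lo + hi)  # posterior half = go
        licked = bool(rng.random() < (0.8 if go else 0.25))
        trials.append(Trial(pole_location=pole, touches=touches, licked=licked,
                            outcome=_trial_outcome(go, licked)))
        spike_times.append(np.sort(spikes))
        whisker_angle.append(ang)
        mask_flags.append(np.ones(dur_ms, dtype=bool))

    bundle = SessionBundle(session_id=session_id, neuron_depth=neuron_depth,
                           condition=condition, trials=trials,
                           spike_times=spike_times,
                           whisker_angle=whisker_angle, mask_flags=mask_flags)
    bundle.validate()
    return bundle


@dataclass
class PopulationSpec:
    """Distribution over ground-truth neurons for pseudo-population studies.

    Each draw picks whether the unit is location tuned, its preference
    (uniform over the pole range), and lognormal-ish rates in the ranges
    observed for L5 units.
    """

    p_touch_responsive: float = 0.45
    p_location_tuned: float = 0.78   # of touch-responsive units
    p_angle_tuned: float = 0.47
    pole_range: tuple[float, float] = (0.0, 10.0)
    location_sd: float = 1.0
    fano: float = 0.94
    n_trials: int = 100
    whisking: WhiskingModel = field(default_factory=WhiskingModel)

    def sample_neuron(self, rng: np.random.Generator) -> GroundTruthNeuron:
        lo, hi = self.pole_range
        touch = rng.random() < self.p_touch_responsive
        loc_tuned = touch and rng.random() < self.p_location_tuned
        angle_tuned = rng.random() < self.p_angle_tuned
        return GroundTruthNeuron(
            baseline_rate=float(rng.gamma(2.0, 2.5)),
            whisking_gain=float(np.exp(rng.normal(0.1, 0.3))),
            angle_pref=float(rng.uniform(55, 95)) if angle_tuned else None,
            angle_kappa=float(rng.uniform(5, 12)),
            touch_responsive=touch,
            touch_latency=float(rng.uniform(6, 26)),
            touch_window=float(rng.uniform(5, 39)),
            location_pref=float(rng.uniform(lo, hi)) if loc_tuned else None,
            location_sd=self.location_sd,
            peak_touch_spikes=float(rng.uniform(0.5, 3.0)) if touch else 0.0,
            count_dispersion=self.fano)


def simulate_population(n_neurons: int,
                        spec: PopulationSpec | None = None,
                        seed: int | np.random.Generator = 0,
                        ) -> list[SessionBundle]:
    """Serially 'recorded' sessions, one independent session per neuron."""
    if spec is None:
        spec = PopulationSpec()
    rng = np.random.default_rng(seed)
    bundles = []
    for i in range(n_neurons):
        neuron = spec.sample_neuron(rng)
        bundles.append(simulate_session(
            neuron, spec.whisking, n_trials=spec.n_trials,
            pole_range=spec.pole_range, seed=rng,
            session_id=f"syn{i:03d}"))
    return bundles
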