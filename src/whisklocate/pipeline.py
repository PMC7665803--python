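"""Per-session orchestration: run every analysis stage on one bundle.

Glue used by the CLI, the reporting module, and the acceptance checks.
Whisking tuning-curve samples are taken once per 5 ms of whisking (adjacent
milliseconds share the same spike-integration window and carry little
independent information).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinematics, touch, tuning
from .session_io import SessionBundle

WHISK_SAMPLE_STRIDE_MS = 5


@dataclass
class SessionAnalysis:
    session_id: str
    condition: str
    depth: float
    total_spikes: int
    n_touches: int
    whisking: kinematics.WhiskingRateComparison | None
    touch_profile: touch.TouchResponseProfile | None
    touch_summary: touch.TouchSummary | None
    location_curve: tuning.TuningCurve | None   # pole location at touch
    angle_touch_curve: tuning.TuningCurve | None  # whisker angle at touch
    whisk_angle_curve: tuning.TuningCurve | None  # angle during free-whisking
    whisk_phase_curve: tuning.TuningCurve | None


def _whisking_samples(bundle: SessionBundle,
                      series: list[kinematics.KinematicSeries],
                      window: tuple[float, float],
                      variable: str = "angle",
                      stride: int = WHISK_SAMPLE_STRIDE_MS,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(stimulus, windowed rate in Hz) at whisking time points."""
    w0, w1 = int(window[0]), int(window[1])
    stim_all, resp_all = [], []
    for i, ks in enumerate(series):
        if ks is None:
            continue
        spikes = np.asarray(bundle.spike_times[i])
        n = len(ks)
        counts = np.zeros(n + 1)
        if spikes.size:
            np.add.at(counts, np.clip(spikes.astype(int), 0, n - 1), 1)
        csum = np.concatenate([[0], np.cumsum(counts[:-1])])
        idx = np.flatnonzero(ks.whisking_flag)[::stride]
        idx = idx[idx + w1 <= n]
        if idx.size == 0:
            continue
        rate = (csum[idx + w1] - csum[idx + w0]) / ((w1 - w0) / 1000.0)
        stim = getattr(ks, "angle" if variable == "angle" else "phase")[idx]
        stim_all.append(stim)
        resp_all.append(rate)
    if not stim_all:
        return np.empty(0), np.empty(0)
    return np.concatenate(stim_all), np.concatenate(resp_all)


def _tested_curve(stimulus: np.ndarray, response: np.ndarray, name: str,
                  seed: int) -> tuning.TuningCurve | None:
    if len(stimulus) < tuning.MIN_SAMPLES:
        return None
    tc = tuning.build_tuning_curve(stimulus, response, stimulus_name=name)
    tuning.test_tuning(tc, seed=seed)
    if tc.is_tuned:
        tuning.tuning_width(tc)
    return tc


def analyze_session(bundle: SessionBundle, seed: int = 0,
                    ) -> SessionAnalysis:
    """Run kinematics, touch-response, and tuning stages on one session."""
    rng = np.random.default_rng(seed)
    series: list[kinematics.KinematicSeries | None] = []
    for i in range(bundle.n_trials):
        ang = bundle.whisker_angle[i]
        if bundle.has_tracked_whisker(i) and len(ang) >= kinematics.MIN_SAMPLES:
            series.append(kinematics.hilbert_decompose(ang))
        else:
            series.append(None)
    flags = [s.whisking_flag if s is not None
             else np.zeros(len(bundle.whisker_angle[i]), dtype=bool)
             for i, s in enumerate(series)]

    whisk_cmp = kinematics.whisking_rate_comparison(bundle.spike_times, flags)

    n_touches = sum(len(tr.touches) for tr in bundle.trials)
    profile = None
    summary = None
    loc_curve = angle_curve = None
    if n_touches > 0:
        aligned = touch.touch_psth(bundle)
        profile = touch.detect_window(aligned,
                                      seed=int(rng.integers(2**31 - 1)))
        summary = touch.touch_summary(bundle, profile, flags)
        window = touch.response_window(profile)
        locs, angs, counts = touch.window_counts(bundle, window)
        rates = counts / ((window[1] - window[0]) / 1000.0)
        if len(locs) >= tuning.MIN_SAMPLES:
            loc_curve = _tested_curve(locs, rates, "pole_location",
                                      int(rng.integers(2**31 - 1)))
            angle_curve = _tested_curve(angs, rates, "angle_at_touch",
                                        int(rng.integers(2**31 - 1)))

    window = touch.response_window(profile)
    wa_curve = wp_curve = None
    stim, resp = _whisking_samples(bundle, series, window, "angle")
    if resp.size and resp.mean() >= tuning.MIN_WHISKING_RATE:
        wa_curve = _tested_curve(stim, resp, "whisking_angle",
                                 int(rng.integers(2**31 - 1)))
        stim_p, resp_p = _whisking_samples(bundle, series, window, "phase")
        wp_curve = _tested_curve(stim_p, resp_p, "whisking_phase",
                                 int(rng.integers(2**31 - 1)))

    return SessionAnalysis(
        session_id=bundle.session_id, condition=bundle.condition,
        depth=bundle.neuron_depth, total_spikes=bundle.total_spikes(),
        n_touches=n_touches, whisking=whisk_cmp, touch_profile=profile,
        touch_summary=summary, location_curve=loc_curve,
        angle_touch_curve=angle_curve, whisk_angle_curve=wa_curve,
        whisk_phase_curve=wp_curve)


def ledger_row(sa: SessionAnalysis) -> dict:
    """Flatten a SessionAnalysis into a classification-ledger row."""
    touch_unit = sa.touch_profile is not None and sa.touch_profile.is_touch_unit
    return dict(
        neuron_id=sa.session_id,
        depth=sa.depth,
        condition=sa.condition,
        total_spikes=sa.total_spikes,
        active=sa.total_spikes > 0,
        touch_unit=touch_unit,
        location_tuned=bool(touch_unit and sa.location_curve is not None
                            and sa.location_curve.is_tuned),
        angle_tuned_whisking=bool(sa.whisk_angle_curve is not None
                                  and sa.whisk_angle_curve.is_tuned),
        phase_tuned_whisking=bool(sa.whisk_phase_curve is not None
                                  and sa.whisk_phase_curve.is_tuned),
    )
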