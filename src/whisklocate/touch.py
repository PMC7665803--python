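"""Touch-evoked response windows and touch-unit classification.

The response window is found on a smoothed peri-touch histogram (PSTH,
-50..+50 ms around touch onset, 1-ms bins): the longest contiguous span
between 5 and 50 ms post touch where the smoothed rate exceeds the upper
95% confidence bound of the pre-touch baseline (-50..0 ms).  A unit is a
touch unit only if the mean rate inside the window exceeds 2 Hz and the
window is longer than 4 ms.

Smoothing uses a penalized cubic smoothing spline with its penalty chosen
by generalized cross-validation (a ``smoother`` hook allows swapping in any
other smoother with the same signature).  The baseline CI is a bootstrap
over touches of the mean pre-touch rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ._smooth import get_spline, gcv_smooth
from .session_io import SessionBundle

PSTH_WINDOW = (-50, 50)   # ms around touch onset
SEARCH_WINDOW = (5, 50)   # ms post touch for the response window
FALLBACK_WINDOW = (10.0, 28.0)  # ms; population-median window for non-touch units
MIN_WINDOW_RATE = 2.0     # Hz
MIN_WINDOW_MS = 4.0       # ms (strict >)
MIN_TOUCH_ISI = 50.0      # ms; touches closer to the previous one are dropped


def gcv_spline_smoother(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Penalized cubic smoothing spline, penalty by GCV, evaluated at x."""
    return gcv_smooth(np.asarray(x, float), np.asarray(y, float))


@dataclass
class TouchAligned:
    """Touch-aligned spike counts: one row per accepted touch, 1-ms bins."""

    counts: np.ndarray   # (n_touches, 100) ints
    bins: np.ndarray     # left bin edges, -50..49 ms
    n_touches: int

    @property
    def psth(self) -> np.ndarray:
        """Across-touch mean rate per bin, Hz."""
        return self.counts.mean(axis=0) * 1000.0


def _refine_edge(totals: np.ndarray, bins: np.ndarray, c0: int,
                 b_lo: int, b_hi: int) -> int:
    """Maximum-likelihood single-step changepoint inside [b_lo, b_hi).

    ``totals`` are per-bin spike counts pooled over touches; the step
    position maximizing the two-segment Poisson likelihood relocates a
    window edge that threshold crossing on the smoothed curve blurred.
    """
    i_lo = int(b_lo - bins[0])
    i_hi = int(b_hi - bins[0])
    seg = totals[i_lo:i_hi].astype(float)
    if len(seg) < 3:
        return c0
    best, best_c = -np.inf, c0
    for c in range(b_lo + 1, b_hi):
        left = seg[:c - b_lo]
        right = seg[c - b_lo:]
        ll = 0.0
        for s in (left, right):
            m = s.mean()
            ll += float((s * np.log(max(m, 1e-9))).sum() - m * len(s))
        if ll > best:
            best, best_c = ll, c
    return best_c


@dataclass
class TouchResponseProfile:
    psth: np.ndarray
    smoothed: np.ndarray
    bins: np.ndarray
    baseline_mean: float           # Hz
    baseline_ci95: tuple[float, float]
    window: tuple[float, float] | None  # [start, end) ms post touch
    latency: float | None          # ms (= window start)
    duration: float | None         # ms
    mean_window_rate: float        # Hz (raw PSTH inside window)
    spikes_per_touch: float        # mean count inside window
    response_probability: float    # fraction of touches with >= 1 window spike
    is_touch_unit: bool
    n_touches: int


def touch_psth(bundle: SessionBundle,
               min_isi: float = MIN_TOUCH_ISI) -> TouchAligned:
    """Align spikes to touch onsets over -50..+50 ms.

    Touches closer than ``min_isi`` ms to the previous touch are excluded to
    avoid overlap contamination.
    """
    lo, hi = PSTH_WINDOW
    rows = []
    for i, trial in enumerate(bundle.trials):
        spikes = np.asarray(bundle.spike_times[i], dtype=float)
        prev = -np.inf
        for tc in trial.touches:
            keep = (tc.onset - prev) >= min_isi
            prev = tc.onset
            if not keep:
                continue
            rel = spikes - tc.onset
            rel = rel[(rel >= lo) & (rel < hi)]
            row = np.zeros(hi - lo, dtype=int)
            if rel.size:
                np.add.at(row, np.floor(rel - lo).astype(int), 1)
            rows.append(row)
    if not rows:
        raise ValueError("session has no usable touches")
    return TouchAligned(counts=np.array(rows), bins=np.arange(lo, hi),
                        n_touches=len(rows))


def detect_window(aligned: TouchAligned,
                  smoother: Callable[[np.ndarray, np.ndarray], np.ndarray]
                  = gcv_spline_smoother,
                  n_boot: int = 2000,
                  n_null: int = 19,
                  seed: int | np.random.Generator = 0,
                  ) -> TouchResponseProfile:
    """Find the touch-response window and classify the unit.

    The exceedance threshold is calibrated against the detector's own null:
    ``n_null`` PSTHs are simulated from a homogeneous Poisson at the
    baseline rate, smoothed identically, and the threshold is the largest
    smoothed value any of them reaches in the 5-50 ms search region.  Under
    the null the observed maximum exceeds this with probability
    1/(n_null + 1) by exchangeability (5% for the default 19), before the
    duration and rate criteria tighten it further.
    """
    rng = np.random.default_rng(seed)
    psth = aligned.psth
    bins = aligned.bins
    x = bins.astype(float)
    smoothed = np.maximum(np.asarray(smoother(x, psth)), 0.0)

    pre = bins < 0
    baseline_mean = float(psth[pre].mean())
    # bootstrap over touches of the mean pre-touch rate (descriptive CI)
    per_touch_rate = aligned.counts[:, pre].sum(axis=1) / (pre.sum() / 1000.0)
    n = aligned.n_touches
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = per_touch_rate[idx].mean(axis=1)
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))

    s0, s1 = SEARCH_WINDOW
    search = (bins >= s0) & (bins < s1)
    mu = baseline_mean * n / 1000.0  # expected count per 1-ms bin, all touches
    null_psths = rng.poisson(mu, size=(n_null, len(bins))) / n * 1000.0
    if smoother is gcv_spline_smoother:
        null_sm = get_spline(x).smooth_many(null_psths)
    else:
        null_sm = np.vstack([np.asarray(smoother(x, row)) for row in null_psths])
    threshold = max(ci[1], float(null_sm[:, search].max()))

    above = search & (smoothed > threshold)
    window = None
    best = 0
    run_start = None
    for i in range(len(bins) + 1):
        on = i < len(bins) and above[i]
        if on and run_start is None:
            run_start = i
        elif not on and run_start is not None:
            if i - run_start > best:
                best = i - run_start
                window = (float(bins[run_start]), float(bins[i - 1] + 1))
            run_start = None

    if window is not None:
        # smoothing blurs the crossing points outward by a couple of ms;
        # relocalize each edge by a local Poisson changepoint fit on raw counts
        totals = aligned.counts.sum(axis=0)
        a0, b0 = int(window[0]), int(window[1])
        a = _refine_edge(totals, bins, a0, max(s0, a0 - 5), min(a0 + 5, b0))
        b = _refine_edge(totals, bins, b0, max(b0 - 5, a + 1), min(b0 + 5, s1))
        if b > a:
            window = (float(a), float(b))

    if window is not None:
        inside = (bins >= window[0]) & (bins < window[1])
        mean_window_rate = float(psth[inside].mean())
        duration = window[1] - window[0]
        win_counts = aligned.counts[:, inside].sum(axis=1)
        spikes_per_touch = float(win_counts.mean())
        response_probability = float((win_counts >= 1).mean())
        ok = mean_window_rate > MIN_WINDOW_RATE and duration > MIN_WINDOW_MS
    else:
        mean_window_rate = 0.0
        duration = None
        spikes_per_touch = 0.0
        response_probability = 0.0
        ok = False
    if not ok:
        window = None
        duration = None

    return TouchResponseProfile(
        psth=psth, smoothed=smoothed, bins=bins,
        baseline_mean=baseline_mean, baseline_ci95=ci,
        window=window, latency=None if window is None else window[0],
        duration=duration, mean_window_rate=mean_window_rate,
        spikes_per_touch=spikes_per_touch,
        response_probability=response_probability,
        is_touch_unit=window is not None, n_touches=aligned.n_touches)


def response_window(profile: TouchResponseProfile | None,
                    ) -> tuple[float, float]:
    """The unit's own window, or the population-median fallback (10-28 ms)."""
    if profile is not None and profile.window is not None:
        return profile.window
    return FALLBACK_WINDOW


def window_counts(bundle: SessionBundle, window: tuple[float, float],
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-touch (pole location, angle at touch, spike count in window).

    Counts are taken in ``[onset + w0, onset + w1)`` for every touch (no ISI
    exclusion: tuning/decoding use all touches).
    """
    w0, w1 = window
    locs, angles, counts = [], [], []
    for i, trial in enumerate(bundle.trials):
        spikes = np.asarray(bundle.spike_times[i], dtype=float)
        for tc in trial.touches:
            c = int(np.count_nonzero(
                (spikes >= tc.onset + w0) & (spikes < tc.onset + w1)))
            locs.append(trial.pole_location)
            angles.append(tc.angle_at_touch)
            counts.append(c)
    return np.array(locs), np.array(angles), np.array(counts, dtype=int)


@dataclass
class TouchSummary:
    """Session-level spike bookkeeping in the style of a population table."""

    rate_whisking: float | None
    rate_quiet: float | None
    prop_spikes_touch: float | None
    prop_spikes_touch_or_whisking: float | None
    spikes_per_touch: float | None
    response_probability: float | None
    n_touches: int


def touch_summary(bundle: SessionBundle, profile: TouchResponseProfile | None,
                  whisking_flags: list[np.ndarray] | None = None,
                  ) -> TouchSummary:
    """Proportions of spikes attributable to touch and to whisking.

    A spike counts as touch-evoked if it falls in the unit's response window
    (or the fallback window) after any touch onset.
    """
    w0, w1 = response_window(profile)
    n_spikes = bundle.total_spikes()
    n_touches = sum(len(tr.touches) for tr in bundle.trials)
    if n_touches == 0:
        return TouchSummary(None, None, None, None, None, None, 0)

    in_touch = 0
    in_touch_or_whisk = 0
    touch_counts = []
    for i, trial in enumerate(bundle.trials):
        spikes = np.asarray(bundle.spike_times[i], dtype=float)
        touch_mask = np.zeros(spikes.size, dtype=bool)
        for tc in trial.touches:
            sel = (spikes >= tc.onset + w0) & (spikes < tc.onset + w1)
            touch_mask |= sel
            touch_counts.append(int(sel.sum()))
        in_touch += int(touch_mask.sum())
        if whisking_flags is not None and spikes.size:
            flags = np.asarray(whisking_flags[i], dtype=bool)
            idx = np.clip(spikes.astype(int), 0, len(flags) - 1)
            in_touch_or_whisk += int((touch_mask | flags[idx]).sum())

    rate_w = rate_q = None
    if whisking_flags is not None:
        from .kinematics import whisking_rate_comparison
        cmpres = whisking_rate_comparison(bundle.spike_times, whisking_flags)
        rate_w, rate_q = cmpres.rate_whisking, cmpres.rate_quiet

    tc_arr = np.array(touch_counts)
    return TouchSummary(
        rate_whisking=rate_w, rate_quiet=rate_q,
        prop_spikes_touch=in_touch / n_spikes if n_spikes else None,
        prop_spikes_touch_or_whisking=(in_touch_or_whisk / n_spikes
                                       if (n_spikes and whisking_flags is not None)
                                       else None),
        spikes_per_touch=float(tc_arr.mean()),
        response_probability=float((tc_arr >= 1).mean()),
        n_touches=n_touches)
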