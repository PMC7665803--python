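"""Are whisking and touch representations independent?

Three complementary checks, applied to per-neuron co-tuning records:

* overlap of the tuned populations vs the product-rule expectation under
  independence;
* per-neuron shape correlation between the (normalized) whisking- and
  touch-tuning curves, compared to randomly re-paired curves across
  neurons with a two-sample Kolmogorov-Smirnov test;
* displacement of the preferred stimulus between the two conditions
  (distance from the identity line), with a circular variant for phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import ks_2samp, pearsonr, ttest_1samp


@dataclass
class CoTuningRecord:
    neuron_id: str
    tuned_whisking: bool
    tuned_touch: bool
    pref_whisking: float | None = None
    pref_touch: float | None = None
    abs_mod_whisking: float | None = None
    abs_mod_touch: float | None = None
    # (stimulus, response) pairs for shape comparison; optional
    curve_whisking: tuple[np.ndarray, np.ndarray] | None = None
    curve_touch: tuple[np.ndarray, np.ndarray] | None = None


@dataclass
class OverlapStatistics:
    p_whisking: float          # % of neurons tuned during free-whisking
    p_touch: float             # % tuned at touch
    p_cotuned_observed: float  # % tuned in both
    p_cotuned_expected: float  # product rule, %
    n: int


def overlap_from_counts(n_whisking: int, n_touch: int, n_both: int,
                        n_total: int) -> OverlapStatistics:
    """Overlap statistics straight from population counts (percent units)."""
    if n_total <= 0:
        raise ValueError("empty population")
    pw, pt = n_whisking / n_total, n_touch / n_total
    return OverlapStatistics(
        p_whisking=100 * pw, p_touch=100 * pt,
        p_cotuned_observed=100 * n_both / n_total,
        p_cotuned_expected=100 * pw * pt, n=n_total)


def overlap_statistics(records: list[CoTuningRecord]) -> OverlapStatistics:
    """Observed co-tuned proportion vs the independence expectation."""
    if not records:
        raise ValueError("no records")
    n = len(records)
    nw = sum(r.tuned_whisking for r in records)
    nt = sum(r.tuned_touch for r in records)
    nb = sum(r.tuned_whisking and r.tuned_touch for r in records)
    return overlap_from_counts(nw, nt, nb, n)


def _normalize(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, float)
    rng = y.max() - y.min()
    return (y - y.min()) / rng if rng > 0 else np.zeros_like(y)


def _common_grid_r(curve_a: tuple[np.ndarray, np.ndarray],
                   curve_b: tuple[np.ndarray, np.ndarray],
                   n_points: int = 20) -> float | None:
    """Pearson r between min-max-normalized curves resampled onto the
    intersection of their stimulus supports; None if supports disjoint."""
    xa, ya = (np.asarray(v, float) for v in curve_a)
    xb, yb = (np.asarray(v, float) for v in curve_b)
    lo = max(xa.min(), xb.min())
    hi = min(xa.max(), xb.max())
    if not hi > lo:
        return None
    grid = np.linspace(lo, hi, n_points)
    fa = np.interp(grid, xa, ya)
    fb = np.interp(grid, xb, yb)
    fa, fb = _normalize(fa), _normalize(fb)
    if fa.std() == 0 or fb.std() == 0:
        return None
    return float(pearsonr(fa, fb)[0])


@dataclass
class ShapeCorrelationResult:
    observed_r: np.ndarray
    shuffled_r: np.ndarray
    ks_statistic: float
    p_value: float
    n_neurons: int
    n_skipped: int


def shape_correlation_test(records: list[CoTuningRecord],
                           n_shuffles: int = 100,
                           seed: int | np.random.Generator = 0,
                           ) -> ShapeCorrelationResult:
    """Within-neuron curve-shape correlation vs random cross-neuron pairing.

    The shuffle permutes which touch curve is paired with which whisking
    curve, so each marginal curve multiset is preserved exactly.
    """
    rng = np.random.default_rng(seed)
    eligible = [r for r in records
                if r.curve_whisking is not None and r.curve_touch is not None]
    observed, skipped = [], 0
    for r in eligible:
        v = _common_grid_r(r.curve_whisking, r.curve_touch)
        if v is None:
            skipped += 1
        else:
            observed.append(v)
    if len(observed) < 3:
        raise ValueError("need >= 3 neurons with overlapping curve supports")
    shuffled = []
    m = len(eligible)
    for _ in range(n_shuffles):
        perm = rng.permutation(m)
        for i, j in enumerate(perm):
            v = _common_grid_r(eligible[i].curve_whisking,
                               eligible[j].curve_touch)
            if v is not None:
                shuffled.append(v)
    obs = np.array(observed)
    shuf = np.array(shuffled)
    stat, p = ks_2samp(obs, shuf)
    return ShapeCorrelationResult(observed_r=obs, shuffled_r=shuf,
                                  ks_statistic=float(stat), p_value=float(p),
                                  n_neurons=len(obs), n_skipped=skipped)


def circular_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Absolute angular distance in radians, in [0, pi]."""
    return np.abs(np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b)))))


@dataclass
class PreferenceDisplacement:
    distances: np.ndarray        # |pref_touch - pref_whisking| per neuron
    mean: float
    sd: float
    t_stat: float | None         # one-sample t vs 0
    p_value: float | None
    pearson_r: float | None      # correlation between the two preferences
    n: int


def preference_displacement(records: list[CoTuningRecord],
                            circular: bool = False) -> PreferenceDisplacement:
    """Distance of co-tuned units' preferences from the identity line.

    ``circular`` switches to circular distance (for phase preferences).
    The t test and correlation are skipped below 3 co-tuned neurons.
    """
    pw, pt = [], []
    for r in records:
        if r.tuned_whisking and r.tuned_touch \
                and r.pref_whisking is not None and r.pref_touch is not None:
            pw.append(r.pref_whisking)
            pt.append(r.pref_touch)
    pw, pt = np.array(pw, float), np.array(pt, float)
    if circular:
        d = circular_distance(pt, pw)
    else:
        d = np.abs(pt - pw)
    n = len(d)
    if n >= 3:
        t, p = ttest_1samp(d, 0.0)
        r = float(pearsonr(pw, pt)[0]) if np.std(pw) > 0 and np.std(pt) > 0 \
            else None
        return PreferenceDisplacement(d, float(d.mean()), float(d.std(ddof=1)),
                                      float(t), float(p), r, n)
    mean = float(d.mean()) if n else np.nan
    sd = float(d.std(ddof=1)) if n > 1 else np.nan
    return PreferenceDisplacement(d, mean, sd, None, None, None, n)
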