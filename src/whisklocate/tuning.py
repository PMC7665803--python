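"""Equal-occupancy tuning curves with shuffle-tested significance.

A tuning curve maps a stimulus (pole location, whisker angle at touch, or a
free-whisking kinematic variable) to the unit's response (rate in its
touch-response window, or spike count).  Samples are sorted by stimulus and
split into 20 equal-count bins (5% of samples each); the bin stimulus is
the median, the bin response the mean.  The fitted curve is a GCV-penalized
smoothing spline evaluated at the bin medians.

Significance is a two-step test: a one-way ANOVA across bins at alpha 0.01,
then a permutation test in which responses are shuffled across bins 1,000
times and the observed F must exceed the 95th percentile of the shuffled
F distribution.  Tuning width uses a Tukey-Kramer-type multiple comparison
against the peak bin; modulation depths come from the smoothed curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

from .touch import gcv_spline_smoother

N_BINS = 20
MIN_SAMPLES = 2 * N_BINS
MIN_WHISKING_RATE = 2.0  # Hz; quieter units are not evaluated for whisking tuning


@dataclass
class TuningCurve:
    stimulus_name: str
    bin_stimulus: np.ndarray     # per-bin median stimulus (20,)
    bin_response: np.ndarray     # per-bin mean response (20,)
    bin_occupancy: np.ndarray    # per-bin sample counts
    smoothed: np.ndarray         # fitted curve at the bin medians
    bin_responses: list[np.ndarray] = field(repr=False, default_factory=list)
    is_tuned: bool | None = None
    p_anova: float | None = None
    F_observed: float | None = None
    F_shuffle_95: float | None = None
    preference: float | None = None   # stimulus at smoothed peak
    width_bins: tuple[int, int] | None = None
    half_max_width: float | None = None
    abs_mod_depth: float | None = None
    mod_depth: float | None = None

    @property
    def peak_bin(self) -> int:
        return int(np.argmax(self.smoothed))


def build_tuning_curve(stimulus: np.ndarray, response: np.ndarray,
                       stimulus_name: str = "",
                       n_bins: int = N_BINS,
                       smoother: Callable = gcv_spline_smoother) -> TuningCurve:
    """Bin samples into ``n_bins`` equal-occupancy bins and fit the curve."""
    stimulus = np.asarray(stimulus, dtype=float)
    response = np.asarray(response, dtype=float)
    if stimulus.shape != response.shape or stimulus.ndim != 1:
        raise ValueError("stimulus and response must be matching 1-D arrays")
    n = len(stimulus)
    if n < 2 * n_bins:
        raise ValueError(
            f"need >= {2 * n_bins} samples for {n_bins} bins, got {n}")
    order = np.argsort(stimulus, kind="stable")  # stable: ties keep input order
    groups = np.array_split(order, n_bins)       # occupancies differ by <= 1
    bin_stim = np.array([np.median(stimulus[g]) for g in groups])
    bin_resp = np.array([response[g].mean() for g in groups])
    occupancy = np.array([len(g) for g in groups])
    bin_responses = [response[g] for g in groups]
    # spline needs strictly increasing x; nudge ties from duplicate medians
    x = bin_stim.copy()
    for i in range(1, n_bins):
        if x[i] <= x[i - 1]:
            x[i] = x[i - 1] + 1e-9
    smoothed = np.asarray(smoother(x, bin_resp), dtype=float)
    tc = TuningCurve(stimulus_name=stimulus_name, bin_stimulus=bin_stim,
                     bin_response=bin_resp, bin_occupancy=occupancy,
                     smoothed=smoothed, bin_responses=bin_responses)
    tc.preference = float(bin_stim[tc.peak_bin])
    modulation_depths(tc)
    return tc


def _anova_f(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p across groups (nan-free, 0 if degenerate)."""
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n = ns.sum()
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_b, df_w = k - 1, n - k
    if df_w <= 0 or ss_within <= 0:
        return (np.inf if ss_between > 0 else 0.0), (0.0 if ss_between > 0 else 1.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    return F, float(f_dist.sf(F, df_b, df_w))


def test_tuning(tc: TuningCurve, n_shuffles: int = 1000, alpha: float = 0.01,
                seed: int | np.random.Generator = 0) -> bool:
    """Two-step significance test; sets is_tuned/F fields and returns is_tuned."""
    rng = np.random.default_rng(seed)
    groups = tc.bin_responses
    F_obs, p = _anova_f(groups)
    tc.F_observed, tc.p_anova = F_obs, p
    if np.isinf(F_obs) and p < alpha:
        # zero within-bin variance with differing means: trivially tuned
        tc.is_tuned = True
        tc.F_shuffle_95 = None
        return True
    if not np.isfinite(F_obs) or p >= alpha or F_obs == 0.0:
        tc.is_tuned = False
        tc.F_shuffle_95 = None
        return False
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    edges = np.cumsum(sizes)[:-1]
    F_shuf = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(pooled)
        F_shuf[i], _ = _anova_f(np.split(perm, edges))
    tc.F_shuffle_95 = float(np.percentile(F_shuf, 95))
    tc.is_tuned = bool(p < alpha and F_obs > tc.F_shuffle_95)
    return tc.is_tuned


def tuning_width(tc: TuningCurve, alpha: float = 0.05,
                 ) -> tuple[tuple[int, int] | None, float | None]:
    """Tuning width from a Tukey-Kramer comparison against the peak bin,
    plus the full width at half maximum of the smoothed curve.

    ``width_bins`` is (first significant bin below peak, first above); None
    if no bin differs significantly from the peak.  Requires ``is_tuned``.
    """
    if not tc.is_tuned:
        raise ValueError("tuning_width requires a significantly tuned curve")
    groups = tc.bin_responses
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n = ns.sum()
    means = np.array([g.mean() for g in groups])
    mse = sum(((g - m) ** 2).sum() for g, m in zip(groups, means)) / (n - k)
    peak = tc.peak_bin
    if mse <= 0:
        sig = means != means[peak]
    else:
        q = studentized_range.ppf(1 - alpha, k, n - k)
        se = np.sqrt(mse / 2.0 * (1.0 / ns + 1.0 / ns[peak]))
        sig = np.abs(means - means[peak]) > q * se
    below = [i for i in range(peak - 1, -1, -1) if sig[i]]
    above = [i for i in range(peak + 1, k) if sig[i]]
    if below and above:
        tc.width_bins = (below[0], above[0])
    elif below or above:
        # peak at or near an edge: one-sided width
        b = below[0] if below else peak
        a = above[0] if above else peak
        tc.width_bins = (b, a)
    else:
        tc.width_bins = None
    tc.half_max_width = _fwhm(tc)
    return tc.width_bins, tc.half_max_width


def _fwhm(tc: TuningCurve) -> float | None:
    """Full width at half maximum of the smoothed curve (dense spline eval)."""
    from ._smooth import GCVSpline
    x = tc.bin_stimulus
    if np.any(np.diff(x) <= 0):
        xx = x.copy()
        for i in range(1, len(xx)):
            if xx[i] <= xx[i - 1]:
                xx[i] = xx[i - 1] + 1e-9
        x = xx
    grid = np.linspace(x[0], x[-1], 512)
    y = GCVSpline(x).predict(tc.bin_response, grid)
    ymax, ymin = y.max(), y.min()
    if ymax <= ymin:
        return None
    half = ymin + 0.5 * (ymax - ymin)
    peak = int(np.argmax(y))
    above = y >= half
    left = peak
    while left > 0 and above[left - 1]:
        left -= 1
    right = peak
    while right < len(grid) - 1 and above[right + 1]:
        right += 1
    return float(grid[right] - grid[left])


def modulation_depths(tc: TuningCurve) -> tuple[float, float | None]:
    """abs depth = max - min of the smoothed curve; normalized depth =
    (max - min)/(max + min), None when the curve is identically zero."""
    mx, mn = float(tc.smoothed.max()), float(tc.smoothed.min())
    mn = max(mn, 0.0)  # rates below zero are smoothing artifacts
    mx = max(mx, mn)
    tc.abs_mod_depth = mx - mn
    tc.mod_depth = (mx - mn) / (mx + mn) if (mx + mn) > 0 else None
    return tc.abs_mod_depth, tc.mod_depth


@dataclass
class StratifiedTuning:
    bin_stimulus: np.ndarray
    high_response: np.ndarray
    low_response: np.ndarray
    used_bins: np.ndarray       # bool; bins with >= min_split touches
    pct_increase: float         # mean % rate increase of high over low


def stratified_tuning(stimulus: np.ndarray, response: np.ndarray,
                      covariate: np.ndarray, n_bins: int = N_BINS,
                      min_split: int = 4) -> StratifiedTuning:
    """Median-split each stimulus bin by a covariate (e.g. touch strength)
    and compare high- vs low-covariate response curves."""
    stimulus = np.asarray(stimulus, float)
    response = np.asarray(response, float)
    covariate = np.asarray(covariate, float)
    if np.ptp(covariate) == 0:
        raise ValueError("covariate is constant; median split undefined")
    order = np.argsort(stimulus, kind="stable")
    groups = np.array_split(order, n_bins)
    bin_stim = np.array([np.median(stimulus[g]) for g in groups])
    hi = np.full(n_bins, np.nan)
    lo = np.full(n_bins, np.nan)
    used = np.zeros(n_bins, dtype=bool)
    for b, g in enumerate(groups):
        if len(g) < min_split:
            continue
        med = np.median(covariate[g])
        top = covariate[g] > med
        if not top.any() or top.all():
            top = covariate[g] >= med
            if top.all():
                continue
        hi[b] = response[g][top].mean()
        lo[b] = response[g][~top].mean()
        used[b] = True
    if not used.any():
        raise ValueError("no bin had enough touches to split")
    denom = lo[used]
    ok = denom > 0
    pct = float(np.mean((hi[used][ok] - denom[ok]) / denom[ok]) * 100) \
        if ok.any() else np.nan
    return StratifiedTuning(bin_stimulus=bin_stim, high_response=hi,
                            low_response=lo, used_bins=used, pct_increase=pct)


def fano_per_bin(tc: TuningCurve) -> np.ndarray:
    """Variance/mean of per-bin spike counts; zero-mean bins are skipped.

    The curve must have been built from counts, not rates.
    """
    out = []
    for g in tc.bin_responses:
        m = g.mean()
        if m > 0:
            out.append(g.var(ddof=1) / m)
    return np.array(out)
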