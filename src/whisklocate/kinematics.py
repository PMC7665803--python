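"""Hilbert decomposition of whisker motion and whisking segmentation.

The whisker-angle series is band-pass filtered 6-60 Hz (4th-order
Butterworth, applied forward-backward for zero phase); whisking amplitude
and phase are the magnitude and angle of the analytic signal of the
band-passed trace.  Phase 0 is the most protracted point of the whisk
cycle, +/-pi the most retracted; negative phase is protraction, positive
retraction.  The midpoint (slow set-point) is the residual angle minus the
band-passed component, low-pass filtered at 6 Hz.  Whisking periods are
where amplitude exceeds 5 degrees, with short gaps merged and short bouts
dropped to suppress threshold chatter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt
from scipy.stats import chi2

BAND = (6.0, 60.0)  # Hz
FS = 1000.0
MIN_SAMPLES = 256   # filter warm-up
AMP_THRESHOLD = 5.0  # deg
MERGE_GAP_MS = 50
MIN_BOUT_MS = 50

_SOS_BAND = butter(4, BAND, btype="bandpass", fs=FS, output="sos")
_SOS_LOW = butter(4, BAND[0], btype="lowpass", fs=FS, output="sos")


@dataclass
class KinematicSeries:
    """Per-sample kinematic decomposition of one angle trace (1 kHz)."""

    angle: np.ndarray        # deg
    bandpassed: np.ndarray   # deg, 6-60 Hz zero-phase
    amplitude: np.ndarray    # deg, >= 0
    midpoint: np.ndarray     # deg
    phase: np.ndarray        # rad in [-pi, pi]; valid only while whisking
    velocity: np.ndarray     # deg/s, centered difference
    whisking_flag: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.angle)


def hilbert_decompose(angle: np.ndarray,
                      amp_threshold: float = AMP_THRESHOLD) -> KinematicSeries:
    """Decompose a whisker-angle series into amplitude/midpoint/phase/velocity."""
    angle = np.asarray(angle, dtype=float)
    if angle.ndim != 1 or len(angle) < MIN_SAMPLES:
        raise ValueError(
            f"need a 1-D series of >= {MIN_SAMPLES} samples, got {angle.shape}")
    if not np.all(np.isfinite(angle)):
        raise ValueError("angle series contains non-finite values")

    band = sosfiltfilt(_SOS_BAND, angle)
    analytic = hilbert(band)
    amplitude = np.abs(analytic)
    phase = np.angle(analytic)
    midpoint = sosfiltfilt(_SOS_LOW, angle - band)
    velocity = np.gradient(angle) * FS
    ks = KinematicSeries(angle=angle, bandpassed=band, amplitude=amplitude,
                         midpoint=midpoint, phase=phase, velocity=velocity,
                         whisking_flag=np.zeros(len(angle), dtype=bool))
    ks.whisking_flag = segment_whisking(ks, amp_threshold)
    return ks


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def segment_whisking(ks: KinematicSeries,
                     amp_threshold: float = AMP_THRESHOLD,
                     merge_gap_ms: int = MERGE_GAP_MS,
                     min_bout_ms: int = MIN_BOUT_MS) -> np.ndarray:
    """Whisking mask: amplitude > threshold, gaps < merge_gap_ms merged,
    bouts < min_bout_ms dropped."""
    raw = ks.amplitude > amp_threshold
    out = raw.copy()
    # merge short gaps between bouts
    for s, e in _runs(~raw):
        if s > 0 and e < len(raw) and (e - s) < merge_gap_ms:
            out[s:e] = True
    # drop short bouts
    for s, e in _runs(out):
        if (e - s) < min_bout_ms:
            out[s:e] = False
    return out


@dataclass
class WhiskingRateComparison:
    rate_whisking: float   # Hz
    rate_quiet: float      # Hz
    modulated: bool
    p_value: float
    defined: bool          # False if a state had zero time


def whisking_rate_comparison(spike_times_ms: list[np.ndarray],
                             whisking_flags: list[np.ndarray],
                             alpha: float = 0.01) -> WhiskingRateComparison:
    """Firing rate during whisking vs quiet, with a chi-squared test.

    The test compares the observed spike count in the whisking state with
    the expectation proportional to time spent whisking (1 df).
    """
    n_w = n_q = 0
    t_w = t_q = 0.0
    for spikes, flags in zip(spike_times_ms, whisking_flags):
        flags = np.asarray(flags, dtype=bool)
        t_w += flags.sum() / FS
        t_q += (~flags).sum() / FS
        sp = np.asarray(spikes, dtype=float)
        if sp.size:
            idx = np.clip(sp.astype(int), 0, len(flags) - 1)
            in_w = flags[idx]
            n_w += int(in_w.sum())
            n_q += int((~in_w).sum())
    if t_w <= 0 or t_q <= 0:
        return WhiskingRateComparison(
            rate_whisking=n_w / t_w if t_w > 0 else 0.0,
            rate_quiet=n_q / t_q if t_q > 0 else 0.0,
            modulated=False, p_value=np.nan, defined=False)
    rate_w, rate_q = n_w / t_w, n_q / t_q
    total = n_w + n_q
    if total == 0:
        return WhiskingRateComparison(0.0, 0.0, False, 1.0, True)
    exp_w = total * t_w / (t_w + t_q)
    exp_q = total - exp_w
    stat = (n_w - exp_w) ** 2 / exp_w + (n_q - exp_q) ** 2 / exp_q
    p = float(chi2.sf(stat, df=1))
    return WhiskingRateComparison(rate_w, rate_q, p < alpha, p, True)
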