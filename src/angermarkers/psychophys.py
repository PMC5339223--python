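"""Heart-rate series construction and cross-modality coupling statistics.

The heart-rate rule mirrors standard RR-interval processing: between two
successive R peaks the instantaneous rate equals 60 divided by the *previous*
RR interval, and the resulting step function is averaged into 1-s bins.
Coupling between continuous modalities (e.g. heart rate vs. continuous anger
rating, rating vs. EFP) is summarized per subject by a Spearman correlation
after aligning both series to the coarser sampling rate, with a group-level
one-sample t-test on the raw coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .series import SampledSeries

logger = logging.getLogger(__name__)


@dataclass
class HRSeries:
    """1-Hz beats-per-minute series plus provenance."""

    series: SampledSeries
    n_peaks_used: int


@dataclass
class CouplingResult:
    """Per-subject Spearman coupling with a group one-sample t-test."""

    rho: np.ndarray       # per-subject, NaNs dropped from inference
    mean_rho: float
    t: float
    df: int
    p: float
    n_dropped: int


def rr_to_hr(
    rpeaks: np.ndarray,
    duration_s: float,
    bin_s: float = 1.0,
    backfill: bool = True,
) -> HRSeries:
    """Heart-rate series from R-peak times.

    The instantaneous value on ``[t_k, t_{k+1})`` is ``60 / (t_k - t_{k-1})``
    bpm (previous-interval rule), so it is defined from the second peak
    onward.  Each ``bin_s`` bin takes the time-weighted mean of this step
    function; bins (or parts of bins) before the second peak take the first
    defined value when ``backfill`` is on, and are NaN otherwise.
    """
    rpeaks = np.asarray(rpeaks, dtype=float)
    if rpeaks.size < 2:
        raise ValueError("need at least 2 R peaks")
    if np.any(np.diff(rpeaks) <= 0):
        raise ValueError("R-peak times must be strictly increasing")
    n_bins = int(np.ceil(duration_s / bin_s))
    rr = np.diff(rpeaks)
    # Segment k spans [rpeaks[k+1], rpeaks[k+2]) and carries 60/rr[k] bpm
    # (the *previous* interval's rate); the final value is held past the last
    # peak so trailing bins stay defined.
    seg_edges = np.append(rpeaks[1:], max(duration_s, rpeaks[-1]) + bin_s)
    seg_vals = 60.0 / rr
    out = np.full(n_bins, np.nan)
    first_defined = 60.0 / rr[0]
    for b in range(n_bins):
        lo, hi = b * bin_s, min((b + 1) * bin_s, duration_s)
        if hi <= lo:
            continue
        acc, w = 0.0, 0.0
        pre = min(hi, seg_edges[0]) - lo  # portion before the second peak
        if pre > 0 and backfill:
            acc += first_defined * pre
            w += pre
        for k in range(seg_vals.size):
            ov = min(hi, seg_edges[k + 1] if k + 1 < seg_edges.size else hi) - max(lo, seg_edges[k])
            if ov > 0:
                acc += seg_vals[k] * ov
                w += ov
        out[b] = acc / w if w > 0 else np.nan
    return HRSeries(SampledSeries(out, 1.0 / bin_s), n_peaks_used=rpeaks.size)


def _align_to_coarser(a: SampledSeries, b: SampledSeries) -> tuple[np.ndarray, np.ndarray]:
    """Resample both series to the coarser rate by non-overlapping means and
    trim to the common overlapping support."""
    rate = min(a.rate_hz, b.rate_hz)
    ar = a if np.isclose(a.rate_hz, rate) else a.bin_means(rate)
    br = b if np.isclose(b.rate_hz, rate) else b.bin_means(rate)
    t0 = max(ar.start_s, br.start_s)
    t1 = min(ar.end_s, br.end_s)
    av = ar.window_values(t0, t1)
    bv = br.window_values(t0, t1)
    n = min(av.size, bv.size)
    return av[:n], bv[:n]


def coupling(
    pairs: list[tuple[SampledSeries, SampledSeries]],
    min_samples: int = 5,
) -> CouplingResult:
    """Group-level Spearman coupling between two modalities.

    ``pairs`` holds one (series_a, series_b) tuple per subject.  Each pair is
    aligned to the coarser rate and Spearman-correlated; a two-sided
    one-sample t-test is run on the raw coefficients (not Fisher
    transformed).  Subjects with a constant series get a NaN coefficient and
    are dropped from inference with a logged count.
    """
    rhos = []
    for a, b in pairs:
        av, bv = _align_to_coarser(a, b)
        if av.size < min_samples:
            raise ValueError(
                f"fewer than {min_samples} aligned samples ({av.size}); "
                "series supports barely overlap"
            )
        ok = np.isfinite(av) & np.isfinite(bv)
        if ok.sum() < min_samples or np.std(av[ok]) == 0 or np.std(bv[ok]) == 0:
            rhos.append(np.nan)
            continue
        rho = scipy.stats.spearmanr(av[ok], bv[ok]).statistic
        rhos.append(float(rho))
    rhos = np.asarray(rhos)
    valid = rhos[np.isfinite(rhos)]
    n_dropped = int(rhos.size - valid.size)
    if n_dropped:
        logger.info("coupling: dropped %d subject(s) with undefined rho", n_dropped)
    if valid.size < 2:
        return CouplingResult(rhos, float(np.nanmean(rhos)), np.nan,
                              max(valid.size - 1, 0), np.nan, n_dropped)
    t, p = scipy.stats.ttest_1samp(valid, 0.0)
    return CouplingResult(rhos, float(valid.mean()), float(t), valid.size - 1,
                          float(p), n_dropped)


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_difference: float


def paired_window_test(values_low: np.ndarray, values_high: np.ndarray) -> PairedTestResult:
    """Paired two-sided t-test of high-window vs low-window per-subject means."""
    lo = np.asarray(values_low, dtype=float)
    hi = np.asarray(values_high, dtype=float)
    if lo.shape != hi.shape:
        raise ValueError("paired samples must have equal length")
    if lo.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = hi - lo
    if np.std(diff, ddof=1) == 0:
        warnings.warn("zero-variance differences; t undefined", stacklevel=2)
        return PairedTestResult(np.nan if diff.mean() != 0 else 0.0, lo.size - 1,
                                np.nan, float(diff.mean()))
    t, p = scipy.stats.ttest_rel(hi, lo)
    return PairedTestResult(float(t), lo.size - 1, float(p), float(diff.mean()))
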