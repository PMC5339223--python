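"""Uniformly sampled scalar time courses.

Every continuous signal in the package (latent affect, continuous anger
ratings, heart rate, ROI BOLD, EFP output) is carried as a
:class:`SampledSeries`: a 1-D array of values at a fixed sampling rate with a
start time.  All time coordinates are seconds from recording onset; sample
``k`` represents the half-open bin ``[start + k/rate, start + (k+1)/rate)``
with its nominal time at the bin centre.  Windows everywhere in the package
are half-open ``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SampledSeries:
    """A uniformly sampled scalar time course.

    Parameters
    ----------
    values : ndarray of shape (n_samples,)
        Sample values.
    rate_hz : float
        Sampling rate in Hz; must be positive.
    start_s : float, default 0.0
        Time of the left edge of the first sample bin, in seconds.
    """

    values: np.ndarray
    rate_hz: float
    start_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.isfinite(self.rate_hz) or self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        """Total covered duration in seconds."""
        return self.n_samples / self.rate_hz

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def times(self) -> np.ndarray:
        """Bin-centre times of every sample, in seconds."""
        return self.start_s + (np.arange(self.n_samples) + 0.5) / self.rate_hz

    # -- operations --------------------------------------------------------
    def shifted(self, lag_s: float) -> "SampledSeries":
        """Return a copy delayed by ``lag_s`` seconds (edge-hold padding)."""
        n_lag = int(round(lag_s * self.rate_hz))
        if n_lag == 0:
            return SampledSeries(self.values.copy(), self.rate_hz, self.start_s)
        if n_lag > 0:
            shifted = np.concatenate(
                [np.full(min(n_lag, self.n_samples), self.values[0]), self.values[:-n_lag]]
            )[: self.n_samples]
        else:
            n_lag = -n_lag
            shifted = np.concatenate(
                [self.values[n_lag:], np.full(min(n_lag, self.n_samples), self.values[-1])]
            )[: self.n_samples]
        return SampledSeries(shifted, self.rate_hz, self.start_s)

    def bin_means(self, new_rate_hz: float) -> "SampledSeries":
        """Downsample by non-overlapping bin means to ``new_rate_hz``.

        Output bin ``k`` spans ``[start + k/new_rate, start + (k+1)/new_rate)``
        and averages the input samples whose bin centres fall inside it.
        Trailing input that does not fill a complete output bin is dropped.
        If ``new_rate_hz`` equals the current rate this is the identity.
        """
        if new_rate_hz <= 0:
            raise ValueError("new_rate_hz must be positive")
        if np.isclose(new_rate_hz, self.rate_hz):
            return SampledSeries(self.values.copy(), new_rate_hz, self.start_s)
        if new_rate_hz > self.rate_hz:
            raise ValueError(
                "bin_means only downsamples; "
                f"requested {new_rate_hz} Hz from {self.rate_hz} Hz"
            )
        n_out = int(np.floor(self.duration_s * new_rate_hz))
        if n_out < 1:
            raise ValueError("series shorter than one output bin")
        centers = (np.arange(self.n_samples) + 0.5) / self.rate_hz
        idx = np.floor(centers * new_rate_hz).astype(int)
        keep = idx < n_out
        sums = np.bincount(idx[keep], weights=self.values[keep], minlength=n_out)
        counts = np.bincount(idx[keep], minlength=n_out)
        return SampledSeries(sums / counts, new_rate_hz, self.start_s)

    def window_values(self, onset_s: float, offset_s: float) -> np.ndarray:
        """Samples whose bin centres fall in ``[onset_s, offset_s)``."""
        t = self.times()
        return self.values[(t >= onset_s) & (t < offset_s)]

    def window_mean(self, onset_s: float, offset_s: float) -> float:
        """Mean of the samples whose bin centres fall in ``[onset_s, offset_s)``.

        Raises ``ValueError`` if the window contains no samples.
        """
        vals = self.window_values(onset_s, offset_s)
        if vals.size == 0:
            raise ValueError(
                f"window [{onset_s}, {offset_s}) contains no samples of a series "
                f"spanning [{self.start_s}, {self.end_s}) at {self.rate_hz} Hz"
            )
        return float(vals.mean())


@dataclass
class WindowSpec:
    """A labelled analysis window, half-open ``[onset_s, offset_s)``."""

    label: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.onset_s) and np.isfinite(self.offset_s)):
            raise ValueError("window bounds must be finite")
        if self.offset_s <= self.onset_s:
            raise ValueError("offset_s must exceed onset_s")

    @property
    def width_s(self) -> float:
        return self.offset_s - self.onset_s
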