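"""Continuous-rating processing: group-mean trace, extreme 100-s windows and
emotion-label summaries.

The high-anger window is the 100-s window maximizing the sliding mean of the
group-average continuous anger rating (1-s onset grid, earliest onset on
ties); the low-anger window is, per the study design, fixed to the first
100 s of the film (a minimizing scan restricted to that range is available as
an option).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .series import SampledSeries, WindowSpec

logger = logging.getLogger(__name__)

DEFAULT_WIDTH_S = 100.0


def group_mean_trace(traces: Sequence[SampledSeries]) -> SampledSeries:
    """Pointwise mean rating across subjects.

    Traces must share the sampling rate; unequal lengths are trimmed to the
    shortest with a logged warning.
    """
    if len(traces) == 0:
        raise ValueError("no traces given")
    rates = {t.rate_hz for t in traces}
    if len(rates) != 1:
        raise ValueError(f"traces disagree on sampling rate: {sorted(rates)}")
    lengths = [t.n_samples for t in traces]
    n = min(lengths)
    if len(set(lengths)) > 1:
        logger.warning("group_mean_trace: trimming traces from %s to %d samples",
                       sorted(set(lengths)), n)
    stacked = np.stack([t.values[:n] for t in traces])
    return SampledSeries(stacked.mean(axis=0), traces[0].rate_hz, traces[0].start_s)


def sliding_window_means(
    trace: SampledSeries, width_s: float, step_s: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of the trace over every window ``[onset, onset+width)`` on a
    regular onset grid.  Returns (onsets, means)."""
    if trace.duration_s < width_s:
        raise ValueError(
            f"trace ({trace.duration_s:.1f} s) shorter than the window ({width_s} s)"
        )
    last_onset = trace.start_s + trace.duration_s - width_s
    onsets = trace.start_s + np.arange(0.0, last_onset - trace.start_s + 1e-9, step_s)
    means = np.array([trace.window_mean(o, o + width_s) for o in onsets])
    return onsets, means


def find_windows(
    mean_trace: SampledSeries,
    width_s: float = DEFAULT_WIDTH_S,
    step_s: float = 1.0,
    low_mode: str = "first",
) -> tuple[WindowSpec, WindowSpec]:
    """Locate the (low-anger, high-anger) windows on the group-mean trace.

    high: onset maximizing the sliding ``width_s`` mean over the whole trace
    (earliest onset on ties).  low: the first ``width_s`` of the recording
    (``low_mode='first'``, default, the most literal reading of the study
    design) or, with ``low_mode='scan'``, the onset minimizing the sliding
    mean.
    """
    onsets, means = sliding_window_means(mean_trace, width_s, step_s)
    hi_onset = float(onsets[int(np.argmax(means))])  # argmax takes the first max
    if low_mode == "first":
        lo_onset = float(mean_trace.start_s)
    elif low_mode == "scan":
        lo_onset = float(onsets[int(np.argmin(means))])
    else:
        raise ValueError(f"unknown low_mode {low_mode!r}")
    return (
        WindowSpec("low-anger", lo_onset, lo_onset + width_s),
        WindowSpec("high-anger", hi_onset, hi_onset + width_s),
    )


def summarize_labels(label_ratings: pd.DataFrame) -> pd.Series:
    """Per-label median intensity across subjects, sorted descending.

    ``label_ratings`` is subjects x labels with values on the 1..7 scale.
    """
    vals = label_ratings.to_numpy()
    if vals.size and (vals.min() < 1 or vals.max() > 7):
        raise ValueError("ratings must lie in 1..7")
    med = label_ratings.median(axis=0)
    return med.sort_values(ascending=False, kind="stable")
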