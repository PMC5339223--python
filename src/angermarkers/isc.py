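"""Voxel-wise inter-subject correlation (ISC) with group inference.

For each voxel, each subject's time course is correlated with the mean time
course of all other subjects (leave-one-out ISC); the per-subject Pearson
coefficients are Fisher-Z transformed and a two-sided one-sample t-test
against zero is run across subjects, with optional Bonferroni correction over
voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal
import scipy.stats

_Z_CLIP = 1.0 - 1e-7


@dataclass
class ISCResult:
    """Per-voxel ISC statistics.

    ``subject_r`` has shape (n_subjects, n_voxels); voxels flagged in
    ``invalid_mask`` (a constant series in some subject) carry NaN statistics
    and are excluded from inference, never silently zeroed.
    """

    subject_r: np.ndarray
    mean_z: np.ndarray
    t: np.ndarray
    df: int
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    invalid_mask: np.ndarray
    alpha: float
    correction: str


def isc_map(
    data: np.ndarray,
    alpha: float = 0.0001,
    correction: str = "bonferroni",
    detrend: bool = True,
    adjusted_threshold: bool = True,
) -> ISCResult:
    """Leave-one-out ISC map with a group t-test per voxel.

    Parameters
    ----------
    data : ndarray (n_subjects, n_voxels, n_frames)
    alpha : significance threshold.
    correction : 'bonferroni' (adjusted p = min(1, p * n_voxels)) or 'none'.
    detrend : linearly detrend each time course first (mirrors upstream
        high-pass filtering); disable with ``detrend=False``.
    adjusted_threshold : threshold the *adjusted* p at ``alpha`` (default).
        With ``False`` the raw p is thresholded at ``alpha / n_voxels``
        (the alternative reading of a Bonferroni-corrected threshold; the
        two coincide except for the clipping of adjusted p at 1).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be (n_subjects, n_voxels, n_frames)")
    n_sub, n_vox, n_frames = data.shape
    if n_sub < 3:
        raise ValueError("need at least 3 subjects")
    if n_frames < 3:
        raise ValueError("need at least 3 frames")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    if detrend:
        data = scipy.signal.detrend(data, axis=-1)
    sd = data.std(axis=-1)
    invalid = (sd == 0).any(axis=0)  # any subject constant at this voxel
    centered = data - data.mean(axis=-1, keepdims=True)
    total = centered.sum(axis=0)  # (n_vox, n_frames)
    r = np.full((n_sub, n_vox), np.nan)
    for i in range(n_sub):
        others = (total - centered[i]) / (n_sub - 1)
        num = (centered[i] * others).sum(axis=-1)
        den = np.sqrt((centered[i] ** 2).sum(axis=-1) * (others**2).sum(axis=-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r[i] = np.where(den > 0, num / den, np.nan)
    r[:, invalid] = np.nan
    z = np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))
    mean_z = z.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = scipy.stats.ttest_1samp(z, 0.0, axis=0)
    t = np.where(invalid, np.nan, t)
    p = np.where(invalid, np.nan, p)
    if correction == "bonferroni":
        n_tested = int((~invalid).sum())
        p_adj = np.minimum(p * n_tested, 1.0)
    else:
        p_adj = p.copy()
    if adjusted_threshold or correction == "none":
        sig = p_adj < alpha
    else:
        sig = p < alpha / max(int((~invalid).sum()), 1)
    sig = np.where(np.isnan(p), False, sig)
    return ISCResult(
        subject_r=r,
        mean_z=np.where(invalid, np.nan, mean_z),
        t=t,
        df=n_sub - 1,
        p_raw=p,
        p_adjusted=p_adj,
        significant=sig.astype(bool),
        invalid_mask=invalid,
        alpha=alpha,
        correction=correction,
    )


def isc_table(result: ISCResult) -> "pd.DataFrame":  # noqa: F821
    """Per-voxel statistics as a DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "voxel": np.arange(result.t.size),
            "mean_z": result.mean_z,
            "t": result.t,
            "df": result.df,
            "p_raw": result.p_raw,
            "p_adjusted": result.p_adjusted,
            "significant": result.significant,
            "invalid": result.invalid_mask,
        }
    )
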