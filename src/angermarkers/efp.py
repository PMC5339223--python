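"""The fMRI-inspired EEG "electrical fingerprint" (EFP) model.

An EFP model predicts a deep region-of-interest BOLD time course (here the
right amygdala, or an inferior-frontal-gyrus variant) from delay-embedded EEG
time-frequency features of a single electrode.  Once trained against
simultaneous EEG/fMRI, the model turns plain EEG into a surrogate of limbic
BOLD activity.

The pipeline is:

1. :func:`spectrogram` — raw multi-channel EEG to per-band log-power features
   at the fMRI frame rate (one frame per repetition time, 3 s by default).
2. :func:`embed_delays` — a frame x (band*delay) design matrix for one
   electrode, covering the hemodynamic lag.
3. :class:`EFPRidge` — per-subject ridge regression with blocked
   cross-validation over the penalty.
4. :func:`cluster_models` — agglomerative clustering of individual coefficient
   grids to keep the mutually consistent, well-fitting subset.
5. :class:`CommonEFPRidge` / :func:`fit_common` — one shared-coefficient ridge
   on the stacked, per-subject-standardized data, penalty chosen by
   leave-one-subject-out cross-validation.
6. :func:`select_electrode` — the electrode whose common model has the highest
   held-out predictive power.
7. :func:`apply_model` — EFP time course of a new recording, down-binned to
   the nominal 0.03 Hz output rate.

Estimators follow the scikit-learn protocol (``fit`` / ``predict``,
``get_params``, fitted attributes with trailing underscores) and compose with
sklearn model selection; the module-level functions are thin wrappers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.signal
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, RegressorMixin

from .series import SampledSeries, WindowSpec

#: delta, theta, alpha, beta, gamma edges in Hz
DEFAULT_BAND_EDGES_HZ: tuple[float, ...] = (1.0, 4.0, 8.0, 12.0, 30.0, 40.0)

#: logarithmic ridge-penalty grid
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(float(x) for x in np.logspace(-3, 3, 7))

DEFAULT_DELAYS_FRAMES = 6
DEFAULT_OUTPUT_RATE_HZ = 0.03


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class TimeFrequencyTensor:
    """Per-channel, per-band, per-frame log band-power features.

    ``values`` has shape ``(n_channels, n_bands, n_frames)``; frame ``t``
    covers ``[start_s + t*frame_s, start_s + (t+1)*frame_s)``.
    """

    values: np.ndarray
    channel_labels: Sequence[str]
    band_edges_hz: Sequence[float]
    frame_s: float
    start_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.channel_labels = list(self.channel_labels)
        self.band_edges_hz = np.asarray(self.band_edges_hz, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (n_channels, n_bands, n_frames)")
        if len(self.channel_labels) != self.values.shape[0]:
            raise ValueError("channel_labels length does not match values")
        if self.band_edges_hz.size != self.values.shape[1] + 1:
            raise ValueError("band_edges_hz must have n_bands + 1 entries")
        if np.any(np.diff(self.band_edges_hz) <= 0):
            raise ValueError("band edges must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")
        if self.frame_s <= 0:
            raise ValueError("frame_s must be positive")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ValueError(
                f"electrode {label!r} not in tensor; available: {sorted(self.channel_labels)}"
            ) from None


@dataclass
class EFPModel:
    """A trained electrical-fingerprint model.

    ``coefficients`` is the band x delay grid acting on per-column z-scored
    delay-embedded features (bands-major column order, delay fastest);
    predictions are in z-units of the training target.
    """

    electrode: str
    coefficients: np.ndarray  # (n_bands, delays_frames)
    intercept: float
    ridge_lambda: float
    delays_frames: int
    cv_fit_r: float
    training_subject_ids: list = field(default_factory=list)
    band_edges_hz: Sequence[float] | None = None
    frame_s: float | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 2:
            raise ValueError("coefficients must be a (n_bands, delays) grid")
        if self.coefficients.shape[1] != self.delays_frames:
            raise ValueError("coefficient grid width must equal delays_frames")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")
        if not -1.0 <= self.cv_fit_r <= 1.0:
            if not np.isnan(self.cv_fit_r):
                raise ValueError("cv_fit_r must lie in [-1, 1]")

    # -- serialization (JSON; the 5x6 grid is small enough to inline) -----
    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["coefficients"] = self.coefficients.tolist()
        if self.band_edges_hz is not None:
            d["band_edges_hz"] = list(np.asarray(self.band_edges_hz, dtype=float))
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EFPModel":
        d = json.loads(Path(path).read_text())
        d["coefficients"] = np.asarray(d["coefficients"], dtype=float)
        return cls(**d)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------
def spectrogram(
    raw_eeg: np.ndarray,
    rate_hz: float,
    frame_s: float,
    band_edges_hz: Sequence[float] = DEFAULT_BAND_EDGES_HZ,
    channel_labels: Sequence[str] | None = None,
    start_s: float = 0.0,
    log_guard: float = 1e-12,
    normalize: bool = True,
) -> TimeFrequencyTensor:
    """Short-time band power per non-overlapping frame, log-transformed and
    z-scored per (channel, band) over frames.

    Parameters
    ----------
    raw_eeg : ndarray (n_channels, n_samples)
    rate_hz : sampling rate; must be at least twice the top band edge.
    frame_s : frame length in seconds (equals the fMRI repetition time).
    normalize : with ``False``, return the raw (pre-log) band power instead
        of log-z-scored features — useful for inspecting spectral content.
    """
    raw_eeg = np.atleast_2d(np.asarray(raw_eeg, dtype=float))
    band_edges = np.asarray(band_edges_hz, dtype=float)
    if rate_hz < 2 * band_edges[-1]:
        raise ValueError(
            f"sampling rate {rate_hz} Hz below Nyquist for top band edge {band_edges[-1]} Hz"
        )
    nperseg = int(round(frame_s * rate_hz))
    if nperseg > raw_eeg.shape[1]:
        raise ValueError("frame longer than the recording")
    freqs, _, sxx = scipy.signal.spectrogram(
        raw_eeg, fs=rate_hz, window="hann", nperseg=nperseg, noverlap=0, axis=-1
    )
    n_bands = band_edges.size - 1
    feats = np.empty((raw_eeg.shape[0], n_bands, sxx.shape[-1]))
    for b in range(n_bands):
        sel = (freqs >= band_edges[b]) & (freqs < band_edges[b + 1])
        if not sel.any():
            raise ValueError(
                f"no FFT bins inside band [{band_edges[b]}, {band_edges[b + 1]}) Hz; "
                "frame too short for this band"
            )
        feats[:, b, :] = sxx[:, sel, :].mean(axis=1)
    if normalize:
        feats = np.log10(feats + log_guard)
        mean = feats.mean(axis=2, keepdims=True)
        sd = feats.std(axis=2, keepdims=True)
        sd[sd == 0] = 1.0  # constant band stays constant (zero) after centering
        feats = (feats - mean) / sd
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(raw_eeg.shape[0])]
    return TimeFrequencyTensor(feats, channel_labels, band_edges, frame_s, start_s)


def embed_delays(
    tf: TimeFrequencyTensor, channel: str, delays_frames: int = DEFAULT_DELAYS_FRAMES
) -> np.ndarray:
    """Delay-embedded design matrix for one electrode.

    Column ``(f, d)`` (bands-major, delay fastest: index ``f*D + d``) at output
    row ``t`` holds feature ``(f, t - d)``.  The first ``delays_frames - 1``
    frames lack complete lag history and are dropped, so the design has
    ``n_frames - delays_frames + 1`` rows; trim the regression target with
    :func:`trim_target` to match.
    """
    if delays_frames < 1:
        raise ValueError("delays_frames must be >= 1")
    if delays_frames >= tf.n_frames:
        raise ValueError(
            f"delays_frames={delays_frames} must be smaller than n_frames={tf.n_frames}"
        )
    c = tf.channel_index(channel)
    feats = tf.values[c]  # (n_bands, n_frames)
    n_bands, n_frames = feats.shape
    d0 = delays_frames - 1
    n_rows = n_frames - d0
    X = np.empty((n_rows, n_bands * delays_frames))
    for f in range(n_bands):
        for d in range(delays_frames):
            X[:, f * delays_frames + d] = feats[f, d0 - d : n_frames - d]
    return X


def trim_target(y: np.ndarray, delays_frames: int) -> np.ndarray:
    """Drop the initial frames of a target to align it with the embedded design."""
    return np.asarray(y, dtype=float)[delays_frames - 1 :]


# ---------------------------------------------------------------------------
# ridge machinery
# ---------------------------------------------------------------------------
def _zscore_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("rank-0 design: every column is constant")
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd, mean, sd


def _ridge_solve(G: np.ndarray, b: np.ndarray, lam: float, n_rows: int) -> np.ndarray:
    """Solve the ridge normal equations ``(G + lam*n*I) c = b``.

    ``G = X'X`` and ``b = X'y`` on centered data; the penalty is scaled by the
    row count so a given lambda means the same thing whatever the recording
    length.  Falls back to least squares when the system is singular (lam=0
    with a rank-deficient design).
    """
    A = G + lam * n_rows * np.eye(G.shape[0])
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


def blocked_folds(n: int, k: int) -> list[np.ndarray]:
    """Contiguous (blocked) fold indices, respecting temporal autocorrelation."""
    if k < 2 or k > n:
        raise ValueError("need 2 <= k <= n folds")
    return [idx for idx in np.array_split(np.arange(n), k)]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


class EFPRidge(BaseEstimator, RegressorMixin):
    """Per-subject ridge regression with blocked cross-validated penalty.

    The design columns and the target are z-scored internally; the penalty is
    chosen from ``lambda_grid`` by k-fold blocked (contiguous) cross-validation
    maximizing the mean held-out Pearson correlation.  ``alpha=0`` recovers
    ordinary least squares on a full-rank design.

    Attributes
    ----------
    coef_ : ndarray (n_features,)
        Coefficients acting on z-scored columns, predicting the raw target.
    intercept_ : float
    lambda_ : float
        Selected penalty.
    cv_fit_r_ : float
        Mean held-out Pearson r at the selected penalty.
    """

    def __init__(
        self,
        lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
        n_splits: int = 5,
        min_frames: int = 20,
    ):
        self.lambda_grid = lambda_grid
        self.n_splits = n_splits
        self.min_frames = min_frames

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EFPRidge":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with rows matching y")
        if X.shape[0] < self.min_frames:
            raise ValueError(f"need at least {self.min_frames} frames, got {X.shape[0]}")
        lambdas = list(self.lambda_grid)
        folds = blocked_folds(X.shape[0], self.n_splits)
        cv_r = np.zeros(len(lambdas))
        cv_n = np.zeros(len(lambdas))
        for f_idx, val in enumerate(folds):
            train = np.setdiff1d(np.arange(X.shape[0]), val)
            Xt, mean, sd = _zscore_columns(X[train])
            yt = y[train] - y[train].mean()
            G, b = Xt.T @ Xt, Xt.T @ yt
            Xv = (X[val] - mean) / sd
            for i, lam in enumerate(lambdas):
                c = _ridge_solve(G, b, lam, Xt.shape[0])
                r = _pearson(Xv @ c, y[val])
                if np.isfinite(r):
                    cv_r[i] += r
                    cv_n[i] += 1
        with np.errstate(invalid="ignore"):
            mean_r = np.where(cv_n > 0, cv_r / np.maximum(cv_n, 1), -np.inf)
        best = int(np.argmax(mean_r))
        Xz, self.x_mean_, self.x_scale_ = _zscore_columns(X)
        yc = y - y.mean()
        self.coef_ = _ridge_solve(Xz.T @ Xz, Xz.T @ yc, lambdas[best], X.shape[0])
        self.intercept_ = float(y.mean())
        self.lambda_ = float(lambdas[best])
        self.cv_fit_r_ = float(mean_r[best]) if np.isfinite(mean_r[best]) else np.nan
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean_) / self.x_scale_ @ self.coef_ + self.intercept_


class CommonEFPRidge(BaseEstimator, RegressorMixin):
    """One shared-coefficient ridge across subjects.

    Each subject's design columns and target are z-scored within subject, the
    rows are stacked, and a single ridge solution is fit.  The penalty is
    chosen by leave-one-subject-out cross-validation maximizing the mean
    held-out Pearson correlation with the left-out subject's target.

    ``fit(X, y, groups)`` takes stacked rows with a per-row subject id, in the
    style of sklearn's grouped model selection.
    """

    def __init__(self, lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID):
        self.lambda_grid = lambda_grid

    def fit(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> "CommonEFPRidge":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        groups = np.asarray(groups)
        if not (X.shape[0] == y.shape[0] == groups.shape[0]):
            raise ValueError("X, y and groups must agree on the number of rows")
        uniq = list(dict.fromkeys(groups.tolist()))  # stable order
        if len(uniq) < 2:
            warnings.warn(
                "common model with a single subject degenerates to an individual fit",
                stacklevel=2,
            )
            ind = EFPRidge(lambda_grid=self.lambda_grid).fit(X, y)
            self.coef_ = ind.coef_
            self.lambda_ = ind.lambda_
            self.cv_fit_r_ = ind.cv_fit_r_
            self.subject_ids_ = uniq
            self.n_features_in_ = X.shape[1]
            return self
        lambdas = list(self.lambda_grid)
        # per-subject standardized blocks and their Gram contributions
        blocks: list[tuple[np.ndarray, np.ndarray]] = []
        for g in uniq:
            sel = groups == g
            Xg, _, _ = _zscore_columns(X[sel])
            yg = y[sel]
            if np.std(yg) == 0:
                raise ValueError(f"constant target for subject {g!r}")
            yg = (yg - yg.mean()) / yg.std()
            blocks.append((Xg, yg))
        grams = [(Xg.T @ Xg, Xg.T @ yg, Xg.shape[0]) for Xg, yg in blocks]
        n_feat = X.shape[1]
        cv_r = np.zeros(len(lambdas))
        for hold, (Xh, yh) in enumerate(blocks):
            G = np.zeros((n_feat, n_feat))
            b = np.zeros(n_feat)
            n_rows = 0
            for j, (Gj, bj, nj) in enumerate(grams):
                if j != hold:
                    G += Gj
                    b += bj
                    n_rows += nj
            for i, lam in enumerate(lambdas):
                c = _ridge_solve(G, b, lam, n_rows)
                r = _pearson(Xh @ c, yh)
                cv_r[i] += r if np.isfinite(r) else 0.0
        cv_r /= len(blocks)
        best = int(np.argmax(cv_r))
        G = sum(g for g, _, _ in grams)
        b = sum(bb for _, bb, _ in grams)
        n_rows = sum(n for _, _, n in grams)
        self.coef_ = _ridge_solve(G, b, lambdas[best], n_rows)
        self.lambda_ = float(lambdas[best])
        self.cv_fit_r_ = float(cv_r[best])
        self.subject_ids_ = uniq
        self.n_features_in_ = n_feat
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict from an already per-subject-standardized design."""
        X = np.asarray(X, dtype=float)
        return X @ self.coef_


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------
def fit_individual(
    tf: TimeFrequencyTensor,
    channel: str,
    roi_bold: SampledSeries,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    delays_frames: int = DEFAULT_DELAYS_FRAMES,
    n_splits: int = 5,
    subject_id=None,
) -> EFPModel:
    """Fit a per-subject EFP model for one electrode.

    The BOLD series must be sampled at the tensor's frame rate (frame length
    equal to the repetition time).
    """
    tr_s = 1.0 / roi_bold.rate_hz
    if not np.isclose(tr_s, tf.frame_s, rtol=1e-6):
        raise ValueError(
            f"BOLD TR ({tr_s} s) must equal the tensor frame length ({tf.frame_s} s)"
        )
    n = min(tf.n_frames, roi_bold.n_samples)
    X = embed_delays(
        TimeFrequencyTensor(
            tf.values[:, :, :n], tf.channel_labels, tf.band_edges_hz, tf.frame_s, tf.start_s
        ),
        channel,
        delays_frames,
    )
    y = trim_target(roi_bold.values[:n], delays_frames)
    est = EFPRidge(lambda_grid=lambda_grid, n_splits=n_splits).fit(X, y)
    n_bands = tf.n_bands
    return EFPModel(
        electrode=channel,
        coefficients=est.coef_.reshape(n_bands, delays_frames),
        intercept=est.intercept_,
        ridge_lambda=est.lambda_,
        delays_frames=delays_frames,
        cv_fit_r=est.cv_fit_r_,
        training_subject_ids=[subject_id] if subject_id is not None else [],
        band_edges_hz=tf.band_edges_hz,
        frame_s=tf.frame_s,
    )


def _grid_correlation_distance(grids: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between flattened coefficient grids."""
    n = grids.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = grids[i], grids[j]
            if np.std(a) == 0 or np.std(b) == 0:
                r = 1.0 if np.allclose(a, b) else 0.0
            else:
                r = np.corrcoef(a, b)[0, 1]
            D[i, j] = D[j, i] = 1.0 - r
    return squareform(D, checks=False)


def cluster_models(
    models: Sequence[EFPModel], distance_threshold: float = 0.5
) -> list[EFPModel]:
    """Select the mutually consistent subset of individual models.

    Average-linkage agglomerative clustering on 1 - Pearson correlation
    between flattened coefficient grids, cut at ``distance_threshold``; among
    clusters of size >= 2 the one with the highest mean ``cv_fit_r`` is
    returned.  If every cluster is a singleton all models are returned.
    """
    if len(models) < 3:
        raise ValueError("need at least 3 models to cluster")
    shapes = {m.coefficients.shape for m in models}
    if len(shapes) != 1:
        raise ValueError(f"coefficient grids differ in shape: {sorted(shapes)}")
    grids = np.stack([m.coefficients.ravel() for m in models])
    dist = _grid_correlation_distance(grids)
    if np.allclose(dist, 0):
        return list(models)
    Z = linkage(dist, method="average")
    labels = fcluster(Z, t=distance_threshold, criterion="distance")
    best_label, best_score = None, -np.inf
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if members.size < 2:
            continue
        score = float(np.nanmean([models[i].cv_fit_r for i in members]))
        if score > best_score:
            best_label, best_score = lab, score
    if best_label is None:
        return list(models)
    return [models[i] for i in np.flatnonzero(labels == best_label)]


def fit_common(
    designs: Sequence[np.ndarray],
    targets: Sequence[np.ndarray],
    electrode: str,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    subject_ids: Sequence | None = None,
    band_edges_hz: Sequence[float] | None = None,
    frame_s: float | None = None,
    delays_frames: int = DEFAULT_DELAYS_FRAMES,
) -> EFPModel:
    """Fit the common (group) EFP model on stacked standardized subjects."""
    if len(designs) != len(targets) or len(designs) == 0:
        raise ValueError("designs and targets must be equal-length, non-empty")
    if subject_ids is None:
        subject_ids = list(range(len(designs)))
    X = np.vstack(designs)
    y = np.concatenate([np.asarray(t, dtype=float).ravel() for t in targets])
    groups = np.concatenate(
        [np.full(len(t), i) for i, t in enumerate(targets)]
    )
    est = CommonEFPRidge(lambda_grid=lambda_grid).fit(X, y, groups)
    n_bands = X.shape[1] // delays_frames
    return EFPModel(
        electrode=electrode,
        coefficients=est.coef_.reshape(n_bands, delays_frames),
        intercept=0.0,
        ridge_lambda=est.lambda_,
        delays_frames=delays_frames,
        cv_fit_r=est.cv_fit_r_,
        training_subject_ids=list(subject_ids),
        band_edges_hz=band_edges_hz,
        frame_s=frame_s,
    )


def common_model_from_tensors(
    tensors: Sequence[TimeFrequencyTensor],
    bolds: Sequence[SampledSeries],
    channel: str,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    delays_frames: int = DEFAULT_DELAYS_FRAMES,
    subject_ids: Sequence | None = None,
) -> EFPModel:
    """Convenience wrapper: embed each subject's tensor and fit the common model."""
    designs, targets = [], []
    for tf, bold in zip(tensors, bolds):
        n = min(tf.n_frames, bold.n_samples)
        sub = TimeFrequencyTensor(
            tf.values[:, :, :n], tf.channel_labels, tf.band_edges_hz, tf.frame_s, tf.start_s
        )
        designs.append(embed_delays(sub, channel, delays_frames))
        targets.append(trim_target(bold.values[:n], delays_frames))
    return fit_common(
        designs,
        targets,
        electrode=channel,
        lambda_grid=lambda_grid,
        subject_ids=subject_ids,
        band_edges_hz=tensors[0].band_edges_hz,
        frame_s=tensors[0].frame_s,
        delays_frames=delays_frames,
    )


def select_electrode(
    tensors: Sequence[TimeFrequencyTensor],
    bolds: Sequence[SampledSeries],
    channels: Sequence[str] | None = None,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    delays_frames: int = DEFAULT_DELAYS_FRAMES,
) -> tuple[str, dict[str, float]]:
    """Pick the electrode whose common model best predicts held-out subjects.

    Returns the winning channel label and the per-channel leave-one-subject-out
    mean correlation.  Ties break deterministically by lexical label order.
    """
    if len(tensors) < 2:
        raise ValueError("electrode selection needs at least 2 subjects")
    if channels is None:
        channels = list(tensors[0].channel_labels)
    scores: dict[str, float] = {}
    for ch in channels:
        model = common_model_from_tensors(
            tensors, bolds, ch, lambda_grid=lambda_grid, delays_frames=delays_frames
        )
        scores[ch] = model.cv_fit_r
    best = max(sorted(scores), key=lambda ch: scores[ch])
    return best, scores


def apply_model(
    tf: TimeFrequencyTensor,
    model: EFPModel,
    output_rate_hz: float = DEFAULT_OUTPUT_RATE_HZ,
) -> SampledSeries:
    """EFP time course of a recording: frame-rate ridge prediction, then
    non-overlapping mean binning down to ``output_rate_hz``.

    The prediction series starts ``(delays - 1)`` frames into the recording
    (the frames without complete lag history); output bin ``k`` averages the
    prediction frames whose centres fall in ``[k/rate, (k+1)/rate)`` relative
    to the prediction start, and a trailing partial bin is dropped.
    """
    X = embed_delays(tf, model.electrode, model.delays_frames)
    Xz, _, _ = _zscore_columns(X) if np.any(X.std(axis=0) > 0) else (X * 0.0, None, None)
    pred = Xz @ model.coefficients.ravel() + model.intercept
    start = tf.start_s + (model.delays_frames - 1) * tf.frame_s
    series = SampledSeries(pred, 1.0 / tf.frame_s, start_s=start)
    if np.isclose(output_rate_hz, series.rate_hz):
        return series
    return series.bin_means(output_rate_hz)


def window_mean(series: SampledSeries, window: WindowSpec) -> float:
    """Mean EFP amplitude inside a labelled window (half-open, bin centres)."""
    return series.window_mean(window.onset_s, window.offset_s)
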