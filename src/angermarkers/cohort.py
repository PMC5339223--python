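"""Synthetic multi-subject cohort with the statistical structure the
anger-marker analysis assumes.

A single latent "anger intensity" trace — a trapezoidal bump over a
5-min-21-s film timeline plus autocorrelated noise — drives every modality:

* ROI BOLD: the latent convolved with a canonical double-gamma hemodynamic
  response function (HRF), resampled to the repetition time, plus voxel noise.
* EEG band-power features: the hemodynamically filtered latent weighted by a
  ground-truth channel x band x delay coefficient grid (the generative twin of
  the electrical-fingerprint model), plus band-scaled noise.
* Heart rate: R-peak times whose instantaneous rate follows the latent.
* Continuous anger rating: a lagged, noisy, 21-level quantization of the
  latent at 10 Hz.
* Dot-probe trials: lognormal reaction times with a configurable congruency
  shift, fast guesses and errors, so the exclusion rules are exercised.
* Outcome table: a trivariate Gaussian (state-anger, EFP window mean, PTSD
  checklist score) with a correlation structure reconstructed from the
  published hierarchical-regression coefficients.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

from .efp import DEFAULT_BAND_EDGES_HZ, TimeFrequencyTensor
from .series import SampledSeries

DEFAULT_CHANNELS: tuple[str, ...] = (
    "C3", "C4", "Cz", "F3", "F4", "F7", "F8", "Fp1", "Fp2", "Fz",
)


# ---------------------------------------------------------------------------
# latent affect
# ---------------------------------------------------------------------------
@dataclass
class LatentAffectProfile:
    """Shape of the film-evoked latent anger trace.

    The trace is ``baseline`` plus a trapezoidal bump: linear rise from
    ``bump_onset_s`` to ``bump_peak_s``, plateau until ``bump_offset_s``, then
    a linear fall over ``ramp_down_s``.  AR(1) noise (coefficient ``ar_phi``)
    with stationary SD ``noise_frac * bump_amplitude`` rides on top.  Defaults
    place the plateau inside the 189-288 s high-anger window of the film
    timeline, so the maximal 100-s mean window starts near second 189.
    """

    duration_s: float = 321.0
    rate_hz: float = 10.0
    baseline: float = 0.0
    bump_onset_s: float = 179.0
    bump_peak_s: float = 199.0
    bump_offset_s: float = 278.0
    bump_amplitude: float = 1.0
    ramp_down_s: float = 20.0
    noise_frac: float = 0.1
    ar_phi: float = 0.9

    def __post_init__(self) -> None:
        vals = [
            self.duration_s, self.rate_hz, self.baseline, self.bump_onset_s,
            self.bump_peak_s, self.bump_offset_s, self.bump_amplitude,
            self.ramp_down_s, self.noise_frac, self.ar_phi,
        ]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("profile fields must be finite")
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration_s and rate_hz must be positive")
        if not (0 <= self.bump_onset_s <= self.bump_peak_s <= self.bump_offset_s <= self.duration_s):
            raise ValueError("bump interval must be ordered and inside [0, duration]")


def generate_latent(profile: LatentAffectProfile, seed: int) -> SampledSeries:
    """Deterministic latent anger trace: trapezoid plus AR(1) noise."""
    p = profile
    n = int(round(p.duration_s * p.rate_hz))
    t = (np.arange(n) + 0.5) / p.rate_hz
    knots_t = [0.0, p.bump_onset_s, p.bump_peak_s, p.bump_offset_s,
               min(p.bump_offset_s + p.ramp_down_s, p.duration_s), p.duration_s]
    knots_v = [0.0, 0.0, 1.0, 1.0, 0.0, 0.0]
    # degenerate knot spacing is fine for np.interp (later knot wins)
    shape = np.interp(t, knots_t, knots_v)
    x = p.baseline + p.bump_amplitude * shape
    noise_sd = p.noise_frac * abs(p.bump_amplitude)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        e = rng.normal(0.0, 1.0, n)
        ar = np.empty(n)
        ar[0] = e[0] / np.sqrt(1 - p.ar_phi**2)
        for i in range(1, n):
            ar[i] = p.ar_phi * ar[i - 1] + e[i]
        ar *= noise_sd / np.sqrt(1.0 / (1 - p.ar_phi**2))
        x = x + ar
    return SampledSeries(x, p.rate_hz)


# ---------------------------------------------------------------------------
# hemodynamics
# ---------------------------------------------------------------------------
def canonical_hrf(
    rate_hz: float,
    duration_s: float = 32.0,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function, unit-sum.

    Gamma densities with shape 6 and 16, scales chosen so the modes sit at
    ``peak_s`` and ``undershoot_s``; the undershoot is subtracted with weight
    ``undershoot_ratio``.
    """
    t = np.arange(0.0, duration_s, 1.0 / rate_hz)
    peak = _gamma_dist(a=6, scale=peak_s / 5.0).pdf(t)
    under = _gamma_dist(a=16, scale=undershoot_s / 15.0).pdf(t)
    h = peak - undershoot_ratio * under
    return h / h.sum()


def hemodynamic(latent: SampledSeries) -> SampledSeries:
    """The latent convolved with the canonical HRF, truncated to its length."""
    h = canonical_hrf(latent.rate_hz)
    z = np.convolve(latent.values, h)[: latent.n_samples]
    return SampledSeries(z, latent.rate_hz, latent.start_s)


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------
@dataclass
class BoldData:
    """Simulated voxel matrix plus the coupled-ROI mean series."""

    voxels: np.ndarray            # (n_voxels, n_frames)
    coupled_mask: np.ndarray      # (n_voxels,) bool
    roi_mean: SampledSeries | None
    tr_s: float


def generate_bold(
    latent: SampledSeries,
    n_coupled_voxels: int,
    n_null_voxels: int,
    tr_s: float = 3.0,
    snr: float = 1.0,
    seed: int = 0,
) -> BoldData:
    """HRF-convolved latent in coupled voxels, white noise elsewhere.

    Coupled-voxel noise SD is ``sd(signal)/snr`` (``snr=inf`` gives the exact
    noiseless limit); null voxels are unit-variance white noise.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    if latent.duration_s < tr_s:
        raise ValueError("latent shorter than one repetition time")
    if snr <= 0:
        raise ValueError("snr must be positive")
    signal = hemodynamic(latent).bin_means(1.0 / tr_s)
    n_frames = signal.n_samples
    rng = np.random.default_rng(seed)
    sig_sd = float(signal.values.std())
    noise_sd = 0.0 if np.isinf(snr) else (sig_sd if sig_sd > 0 else 1.0) / snr
    voxels = np.empty((n_coupled_voxels + n_null_voxels, n_frames))
    if n_coupled_voxels:
        voxels[:n_coupled_voxels] = signal.values + rng.normal(
            0.0, noise_sd, (n_coupled_voxels, n_frames)
        )
    if n_null_voxels:
        voxels[n_coupled_voxels:] = rng.normal(0.0, 1.0, (n_null_voxels, n_frames))
    mask = np.zeros(voxels.shape[0], dtype=bool)
    mask[:n_coupled_voxels] = True
    roi = (
        SampledSeries(voxels[:n_coupled_voxels].mean(axis=0), 1.0 / tr_s, signal.start_s)
        if n_coupled_voxels
        else None
    )
    return BoldData(voxels, mask, roi, tr_s)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------
@dataclass
class CouplingSpec:
    """Ground-truth coupling of every modality to the latent trace.

    ``eeg_weights`` (channels x bands x delays) couples normalized band-power
    features to the hemodynamically filtered latent at frame lags 0..D-1;
    exactly one channel must carry the maximal total absolute weight so that
    electrode-selection recovery is well defined.
    """

    eeg_weights: np.ndarray
    channel_labels: Sequence[str]
    target_electrode: str
    bold_snr: float = 1.0
    eeg_snr: float = 1.0
    hr_gain: float = 5.0          # bpm per latent unit
    rating_lag_s: float = 1.0
    rating_noise_sd: float = 1.5  # rating levels

    def __post_init__(self) -> None:
        self.eeg_weights = np.asarray(self.eeg_weights, dtype=float)
        self.channel_labels = list(self.channel_labels)
        if self.eeg_weights.ndim != 3:
            raise ValueError("eeg_weights must be (channels, bands, delays)")
        if self.eeg_weights.shape[0] != len(self.channel_labels):
            raise ValueError("eeg_weights channel axis must match channel_labels")
        if self.bold_snr <= 0 or self.eeg_snr <= 0:
            raise ValueError("SNRs must be positive")
        totals = np.abs(self.eeg_weights).sum(axis=(1, 2))
        top = np.flatnonzero(totals == totals.max())
        if top.size != 1:
            tied = [self.channel_labels[i] for i in top]
            raise ValueError(f"maximal total |weight| is tied between channels {tied}")
        if self.channel_labels[top[0]] != self.target_electrode:
            raise ValueError(
                f"target_electrode {self.target_electrode!r} does not hold the maximal "
                f"total weight (that is {self.channel_labels[top[0]]!r})"
            )


def default_coupling(
    channel_labels: Sequence[str] = DEFAULT_CHANNELS,
    target_electrode: str = "Fz",
    n_bands: int = 5,
    delays_frames: int = 6,
    secondary_electrode: str = "F3",
    secondary_gain: float = 0.3,
    **kwargs,
) -> CouplingSpec:
    """Default ground truth: an alpha-dominant band profile times a smoothly
    decaying hemodynamic delay profile on the target electrode, a scaled copy
    on one neighbouring electrode, zeros elsewhere."""
    band_amp = np.array([0.3, 0.8, 1.0, 0.6, 0.25])[:n_bands]
    delay_prof = np.exp(-np.arange(delays_frames) / 2.5)
    delay_prof /= delay_prof.sum()
    W = np.zeros((len(channel_labels), n_bands, delays_frames))
    grid = np.outer(band_amp, delay_prof)
    W[list(channel_labels).index(target_electrode)] = grid
    if secondary_electrode is not None:
        W[list(channel_labels).index(secondary_electrode)] = secondary_gain * grid
    return CouplingSpec(W, list(channel_labels), target_electrode, **kwargs)


def _band_scale(band_edges_hz: Sequence[float]) -> np.ndarray:
    """1/f amplitude scale over band centres, normalized to mean 1."""
    edges = np.asarray(band_edges_hz, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    s = 1.0 / centers
    return s / s.mean()


def generate_eeg(
    latent: SampledSeries,
    coupling: CouplingSpec,
    frame_s: float = 3.0,
    band_edges_hz: Sequence[float] = DEFAULT_BAND_EDGES_HZ,
    seed: int = 0,
) -> TimeFrequencyTensor:
    """Band-power feature tensor coupled to the hemodynamic latent.

    The normalized feature at (channel c, band f, frame t) is
    ``sum_d eeg_weights[c,f,d] * z(t - d)`` plus white noise, where ``z`` is
    the HRF-filtered latent at the frame grid and the noise SD is the maximal
    clean-feature SD divided by ``eeg_snr``.  A 1/f band-amplitude scale
    multiplies signal and noise alike (it cancels under the per-band
    z-scoring the fingerprint model applies).
    """
    W = coupling.eeg_weights
    n_ch, n_bands, D = W.shape
    z = hemodynamic(latent).bin_means(1.0 / frame_s).values
    if D > z.size:
        raise ValueError(f"delay depth {D} exceeds the {z.size}-frame series")
    padded = np.concatenate([np.full(D - 1, z[0]), z])
    lagged = np.stack([padded[D - 1 - d : padded.size - d] for d in range(D)])  # (D, T)
    clean = np.einsum("cfd,dt->cft", W, lagged)
    sd = clean.std(axis=2)
    ref = sd.max() if sd.max() > 0 else 1.0
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, ref / coupling.eeg_snr, clean.shape)
    scale = _band_scale(band_edges_hz)[None, :, None]
    values = scale * (clean + noise)
    return TimeFrequencyTensor(values, coupling.channel_labels, band_edges_hz, frame_s,
                               latent.start_s)


def synthesize_raw_eeg(
    tensor: TimeFrequencyTensor,
    rate_hz: float = 100.0,
    mod_depth: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Optional raw-trace synthesis: band-centre oscillations amplitude
    modulated by the feature tensor.  Off the main pipeline path; provided for
    exercising :func:`angermarkers.efp.spectrogram` end to end."""
    edges = np.asarray(tensor.band_edges_hz, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n = int(round(tensor.n_frames * tensor.frame_s * rate_hz))
    t = np.arange(n) / rate_hz
    frame_idx = np.minimum((t / tensor.frame_s).astype(int), tensor.n_frames - 1)
    rng = np.random.default_rng(seed)
    out = np.zeros((tensor.n_channels, n))
    for c in range(tensor.n_channels):
        for b, fc in enumerate(centers):
            env = 1.0 + mod_depth * np.tanh(tensor.values[c, b, frame_idx])
            out[c] += env * np.sin(2 * np.pi * fc * t + rng.uniform(0, 2 * np.pi))
    return out


# ---------------------------------------------------------------------------
# heart rate
# ---------------------------------------------------------------------------
def generate_rr(
    latent: SampledSeries,
    base_bpm: float = 70.0,
    hr_gain: float = 5.0,
    jitter_sd: float = 0.02,
    seed: int = 0,
) -> np.ndarray:
    """Strictly increasing R-peak times; the inter-beat interval at time t is
    ``60 / (base_bpm + hr_gain * latent(t))`` plus Gaussian jitter."""
    if base_bpm <= 0:
        raise ValueError("base_bpm must be positive")
    lo = base_bpm + hr_gain * float(latent.values.min())
    hi = base_bpm + hr_gain * float(latent.values.max())
    if min(lo, hi) <= 0:
        raise ValueError(
            f"parameters produce non-positive bpm (range {min(lo, hi):.2f}..{max(lo, hi):.2f})"
        )
    rng = np.random.default_rng(seed)
    times = latent.times()
    peaks = [0.0]
    t = 0.0
    while True:
        bpm = base_bpm + hr_gain * float(np.interp(t, times, latent.values))
        rr = 60.0 / bpm
        if jitter_sd > 0:
            rr = max(rr + rng.normal(0.0, jitter_sd), 0.25 * rr)
        t += rr
        if t >= latent.duration_s:
            break
        peaks.append(t)
    return np.asarray(peaks)


# ---------------------------------------------------------------------------
# continuous rating
# ---------------------------------------------------------------------------
def generate_rating(
    latent: SampledSeries,
    lag_s: float = 1.0,
    noise_sd: float = 1.5,
    seed: int = 0,
    level_low: float = 3.0,
    level_high: float = 15.0,
    rate_hz: float = 10.0,
) -> SampledSeries:
    """Continuous anger rating: lagged latent linearly mapped to the 21-level
    scale (latent minimum -> ``level_low``, maximum -> ``level_high``), plus
    noise, rounded to the integer grid 0..20."""
    if lag_s < 0:
        raise ValueError("lag_s must be >= 0")
    x = latent.shifted(lag_s)
    if not np.isclose(rate_hz, x.rate_hz):
        x = x.bin_means(rate_hz)
    lo, hi = float(x.values.min()), float(x.values.max())
    if hi > lo:
        levels = level_low + (x.values - lo) / (hi - lo) * (level_high - level_low)
    else:
        levels = np.full_like(x.values, level_low)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        levels = levels + rng.normal(0.0, noise_sd, levels.shape)
    return SampledSeries(np.clip(np.rint(levels), 0, 20), rate_hz, x.start_s)


# ---------------------------------------------------------------------------
# dot probe
# ---------------------------------------------------------------------------
@dataclass
class RTParams:
    """Reaction-time body parameters: lognormal around ``median_ms`` with
    log-SD ``sigma``; ``guess_rate`` of trials become fast guesses drawn
    uniformly from ``guess_range_ms`` (below the 150 ms exclusion cut)."""

    median_ms: float = 500.0
    sigma: float = 0.15
    guess_rate: float = 0.02
    guess_range_ms: tuple[float, float] = (80.0, 149.0)


def generate_dotprobe(
    n_congruent: int = 64,
    n_incongruent: int = 64,
    n_neutral_pairs: int = 32,
    true_bias_ms: float = 10.0,
    rt_params: RTParams | None = None,
    error_rate: float = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Trial table for one subject.

    Congruent trials (probe at the angry-face location) are shifted by
    ``-true_bias_ms`` relative to incongruent trials, so the scored bias
    (incongruent mean minus congruent mean) recovers ``true_bias_ms``.
    Columns: pair_type, probe_at_angry_location, rt_ms, correct.
    """
    if min(n_congruent, n_incongruent, n_neutral_pairs) <= 0:
        raise ValueError("trial counts must be positive")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    p = rt_params or RTParams()
    rng = np.random.default_rng(seed)
    rows = []
    for pair_type, congruent, n in (
        ("angry-neutral", True, n_congruent),
        ("angry-neutral", False, n_incongruent),
        ("neutral-neutral", None, n_neutral_pairs),
    ):
        rt = p.median_ms * np.exp(rng.normal(0.0, p.sigma, n))
        if congruent is True:
            rt = rt - true_bias_ms
        guess = rng.random(n) < p.guess_rate
        rt[guess] = rng.uniform(*p.guess_range_ms, guess.sum())
        correct = rng.random(n) >= error_rate
        for i in range(n):
            rows.append((pair_type, congruent, float(max(rt[i], 1.0)), bool(correct[i])))
    df = pd.DataFrame(rows, columns=["pair_type", "probe_at_angry_location", "rt_ms", "correct"])
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------
@dataclass
class OutcomeStructure:
    """Population structure of the per-subject outcome triple
    (state-anger, high-anger EFP mean, PTSD-checklist score).

    Default correlations reconstruct the published two-predictor regression:
    the state-anger validity 0.454 is printed directly, and the remaining two
    are solved from the step-2 standardized betas (0.793, 0.513), giving a
    predictor intercorrelation of -0.661 and an EFP validity of -0.011 — a
    classic suppression pattern whose implied R-squared is 0.354.
    """

    r_sa_efp: float = -0.661
    r_sa_ptss: float = 0.454
    r_efp_ptss: float = -0.011
    ptss_mean: float = 27.6
    ptss_sd: float = 9.4
    ptss_floor: float = 17.0
    ptss_ceiling: float = 85.0
    n_subjects: int = 33
    state_anger_mean: float = 22.0
    state_anger_sd: float = 5.0

    def correlation_matrix(self) -> np.ndarray:
        """3x3 matrix over (state_anger, efp_high, ptss)."""
        return np.array(
            [
                [1.0, self.r_sa_efp, self.r_sa_ptss],
                [self.r_sa_efp, 1.0, self.r_efp_ptss],
                [self.r_sa_ptss, self.r_efp_ptss, 1.0],
            ]
        )

    def validate(self) -> None:
        eig = np.linalg.eigvalsh(self.correlation_matrix())
        if eig[0] < -1e-10:
            raise ValueError(
                f"correlation matrix is not positive semidefinite (eigenvalue {eig[0]:.6f})"
            )
        if self.ptss_floor > self.ptss_ceiling:
            raise ValueError("ptss_floor must not exceed ptss_ceiling")


def generate_outcomes(structure: OutcomeStructure, seed: int) -> pd.DataFrame:
    """Per-subject outcome table from the trivariate Gaussian.

    The PTSS column is affinely mapped to the requested mean/SD, rounded to
    integers and clamped to the checklist range (the floor truncates the left
    Gaussian tail — the instrument cannot score below 17).
    """
    structure.validate()
    s = structure
    C = s.correlation_matrix()
    eig, vec = np.linalg.eigh(C)
    L = vec @ np.diag(np.sqrt(np.clip(eig, 0.0, None)))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((s.n_subjects, 3)) @ L.T
    ptss = np.clip(np.rint(s.ptss_mean + s.ptss_sd * z[:, 2]), s.ptss_floor, s.ptss_ceiling)
    return pd.DataFrame(
        {
            "subject": [f"sub-{i:02d}" for i in range(s.n_subjects)],
            "state_anger": s.state_anger_mean + s.state_anger_sd * z[:, 0],
            "efp_high": z[:, 1],
            "ptss": ptss.astype(int),
        }
    )


# ---------------------------------------------------------------------------
# emotion-label ratings
# ---------------------------------------------------------------------------
DEFAULT_EMOTION_LABELS: tuple[str, ...] = tuple(
    ["anger", "hostility", "rage", "irritation", "disgust", "contempt", "tension",
     "frustration", "sadness", "fear", "anxiety", "shame", "guilt", "surprise",
     "interest", "joy", "calm", "pride", "hope", "relief"]
    + [f"label{i:02d}" for i in range(56)]
)


def generate_label_ratings(
    n_subjects: int,
    labels: Sequence[str] = DEFAULT_EMOTION_LABELS,
    elevated: Sequence[str] = ("anger", "hostility"),
    elevated_level: float = 5.0,
    base_level: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Retrospective emotion-label grid (subjects x labels, integers 1..7)
    with the chosen labels centred high."""
    rng = np.random.default_rng(seed)
    centers = np.array([elevated_level if l in set(elevated) else base_level for l in labels])
    vals = np.clip(np.rint(centers + rng.normal(0.0, 0.8, (n_subjects, len(labels)))), 1, 7)
    return pd.DataFrame(vals.astype(int), columns=list(labels))


# ---------------------------------------------------------------------------
# whole-cohort simulation
# ---------------------------------------------------------------------------
@dataclass
class SubjectData:
    subject: str
    eeg: TimeFrequencyTensor
    bold: BoldData
    rpeaks: np.ndarray
    rating: SampledSeries
    dotprobe: pd.DataFrame
    true_bias_ms: float


@dataclass
class Cohort:
    latent: SampledSeries
    subjects: list[SubjectData]
    outcomes: pd.DataFrame
    manifest: dict


@dataclass
class CohortSimulator:
    """Generate a full synthetic cohort with one shared latent (the film) and
    independent per-subject noise in every modality."""

    n_subjects: int = 20
    profile: LatentAffectProfile = field(default_factory=LatentAffectProfile)
    coupling: CouplingSpec = field(default_factory=default_coupling)
    outcome_structure: OutcomeStructure = field(default_factory=OutcomeStructure)
    tr_s: float = 3.0
    frame_s: float = 3.0
    n_coupled_voxels: int = 20
    n_null_voxels: int = 80
    base_bpm: float = 70.0
    rr_jitter_sd: float = 0.02
    bias_sd_ms: float = 20.0
    dotprobe_error_rate: float = 0.03
    rt_params: RTParams = field(default_factory=RTParams)
    bias_efp_effect: float = 0.0  # optional group difference, disabled by default

    def simulate(self, seed: int) -> Cohort:
        root = np.random.SeedSequence(seed)
        latent_seed, outcome_seed, *subject_seeds = root.spawn(2 + self.n_subjects)
        latent = generate_latent(self.profile, _seed_int(latent_seed))
        subjects = []
        for i, ss in enumerate(subject_seeds):
            s_eeg, s_bold, s_rr, s_rate, s_dp, s_bias = (_seed_int(x) for x in ss.spawn(6))
            bias = float(np.random.default_rng(s_bias).normal(0.0, self.bias_sd_ms))
            subjects.append(
                SubjectData(
                    subject=f"sub-{i:02d}",
                    eeg=generate_eeg(latent, self.coupling, frame_s=self.frame_s, seed=s_eeg),
                    bold=generate_bold(
                        latent, self.n_coupled_voxels, self.n_null_voxels,
                        tr_s=self.tr_s, snr=self.coupling.bold_snr, seed=s_bold,
                    ),
                    rpeaks=generate_rr(
                        latent, base_bpm=self.base_bpm, hr_gain=self.coupling.hr_gain,
                        jitter_sd=self.rr_jitter_sd, seed=s_rr,
                    ),
                    rating=generate_rating(
                        latent, lag_s=self.coupling.rating_lag_s,
                        noise_sd=self.coupling.rating_noise_sd, seed=s_rate,
                    ),
                    dotprobe=generate_dotprobe(
                        true_bias_ms=bias, error_rate=self.dotprobe_error_rate,
                        rt_params=self.rt_params, seed=s_dp,
                    ),
                    true_bias_ms=bias,
                )
            )
        structure = OutcomeStructure(**{**asdict(self.outcome_structure),
                                        "n_subjects": self.n_subjects})
        outcomes = generate_outcomes(structure, _seed_int(outcome_seed))
        if self.bias_efp_effect != 0.0:
            signs = np.sign([s.true_bias_ms for s in subjects])
            outcomes["efp_high"] = outcomes["efp_high"] + self.bias_efp_effect * signs
        manifest = {
            "schema_version": 1,
            "seed": int(seed),
            "n_subjects": self.n_subjects,
            "tr_s": self.tr_s,
            "eeg_frame_s": self.frame_s,
            "rating_rate_hz": 10.0,
            "efp_output_rate_hz": 0.03,
            "hr_bin_s": 1.0,
        }
        return Cohort(latent, subjects, outcomes, manifest)


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)
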