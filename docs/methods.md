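# Methods

This note documents the models implemented in `angermarkers`, the choices
made where the design was genuinely open, and what the synthetic cohort does
and does not emulate. Every number quoted here is computed by the test suite
or by `scripts/acceptance.py`.

## The analysis in one paragraph

A cohort of subjects watches an anger-inducing film (5 min 21 s) during
simultaneous EEG/fMRI. An *electrical fingerprint* (EFP) model — a ridge
regression from delay-embedded EEG time-frequency features onto an amygdala
region-of-interest BOLD course — turns EEG alone into a surrogate of limbic
activity. Inter-subject correlation (ISC) of the fMRI data verifies that the
film synchronizes limbic responses across viewers. Continuous anger ratings
locate a 100-s high-anger window (and a first-100-s low-anger window); EFP,
heart rate and rating are summarized in those windows. A dot-probe task
stratifies subjects into vigilance/avoidance attention-bias groups, linked to
the EFP windows by a 2×2 mixed ANOVA. Finally a hierarchical regression
predicts post-traumatic stress symptoms (PTSD checklist, 17–85) from
state-anger (step 1) and the high-anger EFP mean (step 2). Because no raw
data from the original cohort are deposited, the package ships a synthetic
cohort generator that reproduces the *statistical structure* of these data,
so every stage is testable end to end.

## Synthetic cohort

**Latent affect.** One shared latent "anger intensity" trace drives every
modality (all subjects watched the same film). It is a trapezoid —
baseline 0, linear rise 179→199 s, plateau at amplitude 1 until 278 s,
20-s fall — over a 321-s timeline, sampled at 10 Hz, plus AR(1) noise
(φ = 0.9) with stationary SD equal to 10 % of the bump amplitude. With these
defaults the 100-s window maximizing the sliding mean starts near second
188–189, mirroring the empirically reported 189–288 s high-anger period.
The bump geometry is the one free choice here; it was placed so that the
maximizing window reproduces that onset, and it is not revisited.

**Hemodynamics.** BOLD in coupled voxels is the latent convolved with a
canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6, unit-sum
normalized), binned to the 3-s repetition time, plus white noise with SD =
SD(signal)/`bold_snr` (default 1.0). Null voxels are unit white noise.

**EEG features and the recovery target.** The generator emits band-power
feature tensors directly (channels × 5 bands × 3-s frames; δ 1–4, θ 4–8,
α 8–12, β 12–30, γ 30–40 Hz). The normalized feature at (channel, band,
frame *t*) is Σ_d `eeg_weights`[c,f,d]·z(t−d), where **z is the
HRF-filtered latent** at the frame grid — i.e. the ground-truth coupling is
defined in the same predictor→BOLD space the fingerprint model estimates.
This is deliberate: if features coupled to the raw latent, the
population-optimal regression grid would be an HRF *deconvolution* of the
declared weights and "parameter recovery" would have no well-defined target
(numerically, the recovered grid correlates only ~0.3–0.5 with the declared
one). With hemodynamic coupling and a smoothly decaying delay profile
(exp(−d/2.5) over 6 frames — the hemodynamic smear), the declared grid is the
identifiable optimum and 20-subject fits recover it at r ≈ 0.8–0.9. The
default montage has 10 channels; the target electrode (Fz) carries an
alpha-dominant band profile (0.3, 0.8, 1.0, 0.6, 0.25), one neighbour (F3)
carries a 0.3-scaled copy, the rest are zero; exactly one channel must hold
the maximal total |weight| so electrode-selection recovery is well defined.
A 1/f amplitude scale over band centres multiplies signal and noise alike —
raw band power rides on the 1/f background, but the scale cancels under the
per-band z-scoring the model applies, so the normalized weights remain the
recovery target. Feature noise is white with SD = max clean-feature SD /
`eeg_snr` (default 1.0).

**Heart rate.** R-peak times are laid down sequentially with inter-beat
interval 60/(70 bpm + 5·latent) s plus 20-ms Gaussian jitter.

**Continuous rating.** The latent, lagged 1 s, mapped linearly onto levels
3–15 of the 0–20 scale, plus level noise (SD 1.5), rounded and clipped —
a 10-Hz, 21-level trace.

**Dot probe.** 64 congruent + 64 incongruent angry/neutral trials and 32
neutral/neutral trials per subject. Reaction-time bodies are lognormal
(median 500 ms, log-SD 0.15); congruent trials are shifted by −bias; 2 % of
trials become fast guesses (80–149 ms) and 3 % errors, so every exclusion
rule is exercised. Per-subject true bias is drawn N(0, 20 ms), giving both
vigilance and avoidance subjects.

**Outcomes.** (state-anger, high-anger EFP, PTSS) is a trivariate Gaussian
with correlations r(SA,PTSS) = 0.454 (the published step-1 beta, which for a
single standardized predictor equals the validity), and r(SA,EFP) = −0.661,
r(EFP,PTSS) = −0.011 solved from the published step-2 betas (0.793, 0.513)
via the two-predictor algebra below; the implied matrix is positive definite
(smallest eigenvalue 0.203) and implies step-2 R² = 0.354. This is a textbook
*suppression* structure: the EFP has near-zero marginal validity but a large
beta because it removes criterion-irrelevant variance from state-anger.
PTSS is mapped to mean 27.6, SD 9.4, rounded, and clamped to the checklist
range [17, 85]. At these parameters the floor necessarily truncates ~14 % of
draws to 17 (Φ((17.5−27.6)/9.4)); this is a property of the instrument, not a
bug — real PCL distributions pile up at the floor — and the parameter-recovery
simulation still returns mean step-2 R² within ±0.05 of 0.354 with the clamp
active. State-anger is given an arbitrary plausible scale (mean 22, SD 5);
standardized regression is scale-free.

## Fingerprint model

* **Spectrogram.** Non-overlapping 3-s Hann frames (one per TR), FFT power
  averaged within bands, log10 with a 1e−12 guard, z-scored per
  (channel, band) over frames.
* **Delay embedding.** Column (f, d), bands-major with delay fastest, holds
  feature (f, t−d) for lags d = 0..D−1 (default D = 6, covering ≈ 18 s of
  hemodynamic lag at 3-s frames). The first D−1 frames lack complete lag
  history and are dropped from design and target alike, so T frames give
  T−D+1 rows.
* **Per-subject ridge.** Design columns z-scored, target centred; the ridge
  penalty is scaled by the row count so a given λ is length-invariant, and the
  normal equations are solved from the Gram matrix (λ = 0 reproduces OLS;
  verified against scikit-learn's `Ridge`/`LinearRegression`). λ is chosen
  from a log grid 10⁻³..10³ (7 points) by 5-fold *blocked* (contiguous)
  cross-validation maximizing held-out Pearson r, respecting autocorrelation.
  Note that on a single-bump recording some contiguous folds are nearly
  signal-free, so per-subject cv r (median ≈ 0.3 at default SNR) understates
  the model's quality; the leave-one-subject-out r of the common model
  (≈ 0.88) is the meaningful fit index.
* **Model clustering.** Average-linkage agglomerative clustering on
  1 − Pearson r between flattened coefficient grids, cut at distance 0.5;
  among clusters of size ≥ 2 the one with the highest mean cv fit is kept
  (all models returned if every cluster is a singleton).
* **Common model.** Each subject's design columns and target are z-scored
  within subject, rows stacked, and one ridge fit shared across subjects
  ("one-class" regression read as shared coefficients on stacked standardized
  subjects); λ by leave-one-subject-out CV maximizing the mean held-out r.
* **Electrode selection.** The common model is fit per electrode; the
  electrode with the highest leave-one-subject-out mean r wins, ties broken
  lexically. The frontal (IFG) variant pins the electrode (F4) instead.
* **EFP signal.** Frame-rate prediction from z-scored embedded features,
  then non-overlapping mean binning to 0.03 Hz: output bin k spans
  [k/rate, (k+1)/rate) from the prediction start, frames are assigned by bin
  centre, and a trailing partial bin is dropped — a full 321-s recording
  yields 9 samples. Window means take samples whose bin centres fall in the
  half-open window.

## Inter-subject correlation

Per voxel, each subject's (linearly detrended, switchable) course is Pearson-
correlated with the mean of all others; |r| is clipped at 1−10⁻⁷ before
Fisher-z; a two-sided one-sample t across subjects (df = n−1) is Bonferroni-
corrected over tested voxels (adjusted p = min(1, p·V)). The default
significance reading is *adjusted p < α*; a flag gives the alternative raw
p < α/V reading. Voxels constant in any subject are flagged NA and excluded
from inference, never silently zeroed.

**Calibration caveat.** The leave-one-out coefficients share data across
subjects (equicorrelation ≈ 1/(n−1)), which inflates the group t: under an
independent white-noise null the empirical rejection rate at α = 0.05 is
≈ 0.15, not 0.05, essentially independent of series length and subject count
(verified against a brute-force simulation). The package implements the
procedure as defined and documents, rather than hides, this
anticonservativeness; the acceptance suite carries a deliberately failing
check recording that the nominal level is not attained. Calibrated
alternatives (subject-level permutation or circular-shift nulls) are out of
scope because the modelled analysis does not use them.

## Psychophysiology

Heart rate uses the previous-interval rule — the instantaneous value on
[t_k, t_{k+1}) is 60/(t_k − t_{k−1}) bpm — averaged into 1-s bins by
time-weighted means; bins before the second peak back-fill the first defined
value (flag to emit NaN instead), and the last value is held after the final
peak. Cross-modality coupling aligns two series to the coarser rate by
non-overlapping means, Spearman-correlates per subject, and runs a one-sample
t on the *raw* coefficients (not Fisher-transformed, matching the modelled
analysis). Window comparisons use the paired two-sided t with a zero-variance
guard.

## Dot probe

Exclusions run in a fixed order, each rule once (no iteration): incorrect
responses, then reaction times < 150 ms, then a single ±2 SD pass per
condition (congruent / incongruent / neutral-neutral; SD with ddof = 1)
computed on the survivors of the first two rules. Bias = mean RT(incongruent)
− mean RT(congruent); positive is vigilance; an exact zero is assigned to
avoidance by convention (never observed in practice). Neutral-neutral trials
go through the bookkeeping but never enter the bias mean. Group statistics:
t = mean/SE, one-sample d = t/√n. The 2×2 mixed ANOVA uses classical
sums of squares (verified against a full design-matrix projection oracle and
against pingouin on balanced fixtures); partial η² is SS_effect/(SS_effect +
SS_error) against each effect's own error term, and simple group effects
within each period are tested against the omnibus between-subject error
(df = N−2, matching the modelled analysis).

## Windows and labels

The high-anger window maximizes the 100-s sliding mean of the group-average
rating on a 1-s onset grid (earliest onset on ties; equivalence to an
exhaustive scan is tested). The low-anger window is fixed to the first 100 s
— the most literal reading of the study design — with a minimizing scan
available behind a flag. Label summaries are per-label medians across
subjects on the 1–7 scale, sorted descending.

## Outcome regression

Each step is OLS on z-scored variables (statsmodels), so coefficients are
standardized betas; p-values are two-sided with df = n−p−1; tolerance is
1 − R² of a predictor on its co-predictors (1.0 for a lone predictor; an
error names any predictor with tolerance < 10⁻⁸); ΔF = ((R²_s −
R²_{s−1})/q)/((1−R²_s)/(n−p_s−1)). Missing outcomes are dropped listwise with
a logged count. The two-predictor reconstruction inverts the standardized
normal equations: r12 = (r1y − β1)/β2, r2y = β2 + β1·r12, R² = β1·r1y +
β2·r2y, tolerance = 1 − r12². Printed tolerances deviate from the implied
1 − r12² by up to ~0.004 (e.g. 0.561 printed vs 0.563 implied) — consistent
with the printed betas themselves being rounded to three decimals; the
package documents rather than reconciles this.

## What the generator does not emulate

* A single latent shared by all subjects, with only noise differing between
  them. Real viewers differ in affect dynamics, so simulated within-subject
  couplings are much stronger than empirical ones (e.g. HR–rating Spearman
  ρ ≈ 0.7 here vs. weak positive coupling in real data). Sign and ordering
  tests transfer; magnitudes do not.
* The signal-level EFP and the outcome table's EFP column are generated
  independently (the outcome triple comes from its own correlation
  structure), so subject-level agreement between the two is not modelled. An
  optional attention-bias→EFP group-difference parameter exists but ships
  disabled, as no effect size is available to calibrate it.
* No MR-gradient, cardioballistic, blink or motion artifacts; R-peak times
  and feature tensors are the interfaces, artifact correction is upstream.

Passing tests therefore demonstrate the *procedures* are correct and
recoverable under the assumed structure — not that real recordings would
yield the published effect sizes.

## Problem sizes and numerics

The simulation-based checks use 20-subject cohorts (50 seeded replicates for
electrode recovery, 5 held-out subjects for prediction), 2000 voxels × 20
subjects × 100 frames for the ISC null, and 500 cohorts of n = 33 for
regression recovery — sizes at which every Monte-Carlo band in the suite is
stable across seeds. Numerical guards: |r| clipped at 1−10⁻⁷ before atanh;
log-power guard 10⁻¹²; constant design columns are centred out rather than
divided by zero; a fully constant design, constant targets, zero-variance
differences and emptied dot-probe cells raise typed errors or NaN with
warnings, never silent zeros.
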