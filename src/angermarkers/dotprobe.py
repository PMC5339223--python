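"""Dot-probe attention-bias scoring and group statistics.

The dot-probe task shows an angry and a neutral face, then a probe at one
face's location.  The attention-bias score is the mean reaction time to
probes at neutral-face locations (incongruent trials) minus the mean at
angry-face locations (congruent trials): positive scores mean vigilance
toward threat, negative scores avoidance.

Exclusion rules, applied in order and in a single pass:

1. incorrect responses;
2. reaction times faster than 150 ms;
3. reaction times more than 2 SD from the participant's mean *for that
   condition* (congruent / incongruent / neutral-neutral), with mean and SD
   computed on the survivors of rules 1-2.

Neutral-neutral trials run through the exclusion bookkeeping but never enter
the bias mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

RT_FLOOR_MS = 150.0
SD_CRITERION = 2.0


@dataclass
class BiasScore:
    """Per-subject attention bias in ms, with exclusion bookkeeping.

    ``group`` is "vigilance" for a strictly positive bias and "avoidance"
    otherwise (a bias of exactly zero is assigned to avoidance by convention).
    """

    subject: str
    bias_ms: float
    n_used_congruent: int
    n_used_incongruent: int
    n_excluded_by_rule: dict = field(default_factory=dict)
    group: str = ""

    def __post_init__(self) -> None:
        if not self.group:
            self.group = "vigilance" if self.bias_ms > 0 else "avoidance"


class UnscorableSubjectError(ValueError):
    """Raised when exclusions empty a congruency cell."""


def _condition(df: pd.DataFrame) -> pd.Series:
    cond = pd.Series("neutral-neutral", index=df.index)
    angry = df["pair_type"] == "angry-neutral"
    raw = df["probe_at_angry_location"]
    if raw.dtype == object:  # TSV round-trips booleans as strings
        raw = raw.map({"True": True, "False": False, True: True, False: False})
    cong = raw.astype("boolean").fillna(False)
    cond[angry & cong] = "congruent"
    cond[angry & ~cong] = "incongruent"
    return cond


def score_bias(trials: pd.DataFrame, subject: str = "") -> BiasScore:
    """Attention-bias score for one subject's trial table.

    ``trials`` needs columns pair_type ('angry-neutral' / 'neutral-neutral'),
    probe_at_angry_location (bool; NA on neutral-neutral trials), rt_ms and
    correct.  Trial order never affects the score.
    """
    df = trials.reset_index(drop=True)
    if (df["rt_ms"] <= 0).any():
        raise ValueError("rt_ms must be positive")
    cond = _condition(df)
    keep = np.ones(len(df), dtype=bool)
    excluded = {}
    # rule 1: incorrect
    bad = ~df["correct"].astype(bool).to_numpy()
    excluded["incorrect"] = int((keep & bad).sum())
    keep &= ~bad
    # rule 2: anticipations
    bad = df["rt_ms"].to_numpy() < RT_FLOOR_MS
    excluded["fast_guess"] = int((keep & bad).sum())
    keep &= ~bad
    # rule 3: per-condition +-2 SD on survivors of rules 1-2, single pass
    bad = np.zeros(len(df), dtype=bool)
    for c in ("congruent", "incongruent", "neutral-neutral"):
        sel = keep & (cond == c).to_numpy()
        if sel.sum() < 2:
            continue
        rts = df.loc[sel, "rt_ms"]
        m, sd = rts.mean(), rts.std(ddof=1)
        bad |= sel & (np.abs(df["rt_ms"].to_numpy() - m) > SD_CRITERION * sd)
    excluded["outlier_2sd"] = int(bad.sum())
    keep &= ~bad
    used_c = keep & (cond == "congruent").to_numpy()
    used_i = keep & (cond == "incongruent").to_numpy()
    if used_c.sum() == 0 or used_i.sum() == 0:
        raise UnscorableSubjectError(
            f"subject {subject or '?'}: a congruency cell was emptied by exclusions"
        )
    bias = float(df.loc[used_i, "rt_ms"].mean() - df.loc[used_c, "rt_ms"].mean())
    return BiasScore(
        subject=subject,
        bias_ms=bias,
        n_used_congruent=int(used_c.sum()),
        n_used_incongruent=int(used_i.sum()),
        n_excluded_by_rule=excluded,
    )


@dataclass
class GroupStats:
    group: str
    n: int
    mean: float
    se: float
    t: float
    df: int
    p: float
    cohens_d: float


def group_stats(scores: list[BiasScore], group: str) -> GroupStats:
    """One-sample statistics of a bias group against zero.

    ``t = mean/SE`` and the one-sample effect size ``d = t/sqrt(n)``.
    """
    vals = np.array([s.bias_ms for s in scores if s.group == group], dtype=float)
    n = vals.size
    if n < 2:
        raise ValueError(f"group {group!r} needs at least 2 subjects, has {n}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0:
        return GroupStats(group, n, mean, 0.0, np.nan, n - 1, np.nan, np.nan)
    se = sd / np.sqrt(n)
    t = mean / se
    p = 2 * scipy.stats.t.sf(abs(t), n - 1)
    return GroupStats(group, n, mean, float(se), float(t), n - 1, float(p),
                      float(t / np.sqrt(n)))


@dataclass
class MixedAnovaResult:
    """2 (group, between) x 2 (period, within) mixed-model ANOVA.

    ``eta_p2`` entries are partial eta squared, SS_effect/(SS_effect+SS_error)
    against each effect's own error term.  ``simple_effects`` holds the
    one-way group F within each period, tested against the between-subject
    error term of the omnibus fit.
    """

    F: dict
    p: dict
    eta_p2: dict
    df_effect: dict
    df_error: dict
    ss: dict
    simple_effects: dict


def mixed_anova(
    efp_low: np.ndarray, efp_high: np.ndarray, group_labels: np.ndarray
) -> MixedAnovaResult:
    """Classical sums-of-squares mixed ANOVA linking bias group to the EFP
    signal in the low- vs high-anger film periods.

    ``efp_low``/``efp_high`` are per-subject window means (complete cases);
    ``group_labels`` the between-subject factor with exactly two levels.
    """
    low = np.asarray(efp_low, dtype=float)
    high = np.asarray(efp_high, dtype=float)
    labels = np.asarray(group_labels)
    if not (low.shape == high.shape == labels.shape):
        raise ValueError("efp_low, efp_high and group_labels must have equal length")
    groups = [g for g in dict.fromkeys(labels.tolist())]
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    n = low.size
    data = np.stack([low, high], axis=1)  # subjects x periods
    gm = data.mean()
    subj_mean = data.mean(axis=1)
    period_mean = data.mean(axis=0)
    # between-subject partition
    ss_group = 0.0
    ss_subj = 0.0
    for g in groups:
        sel = labels == g
        gmean = data[sel].mean()
        ss_group += 2 * sel.sum() * (gmean - gm) ** 2
        ss_subj += 2 * ((subj_mean[sel] - gmean) ** 2).sum()
    # within-subject partition
    ss_period = n * ((period_mean - gm) ** 2).sum()
    ss_inter = 0.0
    ss_err_within = 0.0
    for g in groups:
        sel = labels == g
        gmean = data[sel].mean()
        for p_idx in range(2):
            cell = data[sel, p_idx].mean()
            ss_inter += sel.sum() * (cell - gmean - period_mean[p_idx] + gm) ** 2
            # period-by-subject residual within this group
            resid = data[sel, p_idx] - subj_mean[sel] - cell + gmean
            ss_err_within += (resid**2).sum()
    df_b, df_w = 1, 1
    df_err_b = n - 2
    df_err_w = n - 2
    ms_err_b = ss_subj / df_err_b
    ms_err_w = ss_err_within / df_err_w

    def _f(ss_eff, df_eff, ms_err, df_err):
        if ms_err == 0:
            return (np.inf if ss_eff > 0 else np.nan), np.nan
        F = (ss_eff / df_eff) / ms_err
        return F, float(scipy.stats.f.sf(F, df_eff, df_err))

    F_g, p_g = _f(ss_group, df_b, ms_err_b, df_err_b)
    F_p, p_p = _f(ss_period, df_w, ms_err_w, df_err_w)
    F_i, p_i = _f(ss_inter, df_w, ms_err_w, df_err_w)

    def _eta(ss_eff, ss_err):
        return ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else np.nan

    simple = {}
    for p_idx, name in enumerate(("low", "high")):
        ss_g_at_p = 0.0
        pm = data[:, p_idx].mean()
        for g in groups:
            sel = labels == g
            ss_g_at_p += sel.sum() * (data[sel, p_idx].mean() - pm) ** 2
        F_s, p_s = _f(ss_g_at_p, 1, ms_err_b, df_err_b)
        simple[name] = {"F": F_s, "p": p_s, "df": (1, df_err_b)}
    return MixedAnovaResult(
        F={"group": F_g, "period": F_p, "interaction": F_i},
        p={"group": p_g, "period": p_p, "interaction": p_i},
        eta_p2={
            "group": _eta(ss_group, ss_subj),
            "period": _eta(ss_period, ss_err_within),
            "interaction": _eta(ss_inter, ss_err_within),
        },
        df_effect={"group": df_b, "period": df_w, "interaction": df_w},
        df_error={"group": df_err_b, "period": df_err_w, "interaction": df_err_w},
        ss={
            "group": ss_group, "subjects_within_group": ss_subj,
            "period": ss_period, "interaction": ss_inter,
            "error_within": ss_err_within,
        },
        simple_effects=simple,
    )
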