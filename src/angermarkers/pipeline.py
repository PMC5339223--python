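"""End-to-end analysis pipeline over a cohort directory.

Stages (each idempotent: an existing output file is reused unless
``force=True``):

    simulate -> windows -> efp-fit -> efp-apply -> isc -> hr -> dotprobe -> predict

``run_pipeline`` takes a configuration dictionary (YAML-loadable), writes all
stage outputs under the output directory and returns a summary dict.  A run
log records seeds and per-stage subject counts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as chm
from . import dotprobe as dpm
from . import efp as efpm
from . import io as iom
from . import isc as iscm
from . import outcomes as outm
from . import psychophys as ppm
from . import windows as winm
from .series import SampledSeries, WindowSpec

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "n_subjects": 20,
    "seed": 0,
    "electrode": None,           # None -> cross-validated electrode selection
    "efp_output_rate_hz": 0.03,
    "window_width_s": 100.0,
    "isc_alpha": 0.0001,
    "isc_correction": "bonferroni",
    "blocks": [["state_anger"], ["efp_high"]],
    "outcome": "ptss",
}


def _validate_config(config: dict) -> dict:
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    if not cfg.get("blocks"):
        raise ValueError("config is missing the regression block spec ('blocks')")
    if not cfg.get("outcome"):
        raise ValueError("config is missing the regression outcome ('outcome')")
    return cfg


def run_pipeline(config: dict, out_dir: str | Path, force: bool = False) -> dict:
    """Execute the full pipeline; returns a summary with stage outputs."""
    cfg = _validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    summary: dict = {"seed": seed}

    # -- simulate ----------------------------------------------------------
    cohort_dir = out / "cohort"
    if force or not (cohort_dir / "manifest.yaml").exists():
        sim = chm.CohortSimulator(n_subjects=int(cfg["n_subjects"]))
        cohort = sim.simulate(seed)
        iom.write_cohort(cohort, cohort_dir)
    cohort = iom.read_cohort(cohort_dir)
    subjects = cohort.subjects
    summary["n_subjects"] = len(subjects)

    # -- windows -----------------------------------------------------------
    windows_file = out / "windows.json"
    if force or not windows_file.exists():
        mean_trace = winm.group_mean_trace([s.rating for s in subjects])
        low, high = winm.find_windows(mean_trace, width_s=float(cfg["window_width_s"]))
        windows_file.write_text(json.dumps(
            [
                {"label": w.label, "onset_s": w.onset_s, "offset_s": w.offset_s}
                for w in (low, high)
            ],
            indent=2,
        ))
    wins = [WindowSpec(**w) for w in json.loads(windows_file.read_text())]
    low_win, high_win = wins
    summary["windows"] = {w.label: [w.onset_s, w.offset_s] for w in wins}

    # -- efp-fit -----------------------------------------------------------
    model_file = out / "efp_model.json"
    if force or not model_file.exists():
        tensors = [s.eeg for s in subjects]
        bolds = [s.bold.roi_mean for s in subjects]
        electrode = cfg["electrode"]
        if electrode is None:
            electrode, scores = efpm.select_electrode(tensors, bolds)
            (out / "electrode_scores.json").write_text(json.dumps(scores, indent=2))
        individuals = [
            efpm.fit_individual(tf, electrode, bold, subject_id=s.subject)
            for tf, bold, s in zip(tensors, bolds, subjects)
        ]
        selected = efpm.cluster_models(individuals)
        sel_ids = {m.training_subject_ids[0] for m in selected}
        keep = [s for s in subjects if s.subject in sel_ids]
        common = efpm.common_model_from_tensors(
            [s.eeg for s in keep], [s.bold.roi_mean for s in keep], electrode,
            subject_ids=[s.subject for s in keep],
        )
        common.to_json(model_file)
    model = efpm.EFPModel.from_json(model_file)
    summary["electrode"] = model.electrode
    summary["common_cv_fit_r"] = model.cv_fit_r

    # -- efp-apply ---------------------------------------------------------
    efp_file = out / "efp_windows.tsv"
    if force or not efp_file.exists():
        rows = []
        for s in subjects:
            series = efpm.apply_model(s.eeg, model, float(cfg["efp_output_rate_hz"]))
            rows.append(
                {
                    "subject": s.subject,
                    "efp_low_measured": efpm.window_mean(series, low_win),
                    "efp_high_measured": efpm.window_mean(series, high_win),
                }
            )
        pd.DataFrame(rows).to_csv(efp_file, sep="\t", index=False)
    efp_windows = pd.read_csv(efp_file, sep="\t")

    # -- isc ---------------------------------------------------------------
    isc_file = out / "isc.tsv"
    if force or not isc_file.exists():
        data = np.stack([s.bold.voxels for s in subjects])
        res = iscm.isc_map(
            data, alpha=float(cfg["isc_alpha"]), correction=cfg["isc_correction"]
        )
        iscm.isc_table(res).to_csv(isc_file, sep="\t", index=False)
    isc_df = pd.read_csv(isc_file, sep="\t")
    summary["isc_significant_voxels"] = int(isc_df["significant"].sum())

    # -- hr ----------------------------------------------------------------
    hr_file = out / "hr.tsv"
    if force or not hr_file.exists():
        frames = []
        for s in subjects:
            hr = ppm.rr_to_hr(s.rpeaks, duration_s=s.rating.duration_s)
            frames.append(pd.DataFrame(
                {"subject": s.subject, "bin_start_s": np.arange(hr.series.n_samples),
                 "bpm": hr.series.values}
            ))
        pd.concat(frames).to_csv(hr_file, sep="\t", index=False)
    hr_df = pd.read_csv(hr_file, sep="\t")
    hr_series = {
        sub: SampledSeries(g.sort_values("bin_start_s")["bpm"].to_numpy(), 1.0)
        for sub, g in hr_df.groupby("subject")
    }
    pairs = [(hr_series[s.subject], s.rating) for s in subjects]
    hr_coupling = ppm.coupling(pairs)
    summary["hr_rating_coupling"] = {
        "mean_rho": hr_coupling.mean_rho, "t": hr_coupling.t, "p": hr_coupling.p,
    }
    hr_low = [hr_series[s.subject].window_mean(low_win.onset_s, low_win.offset_s)
              for s in subjects]
    hr_high = [hr_series[s.subject].window_mean(high_win.onset_s, high_win.offset_s)
               for s in subjects]
    paired = ppm.paired_window_test(hr_low, hr_high)
    summary["hr_paired_t"] = {"t": paired.t, "df": paired.df, "p": paired.p}

    # -- dotprobe ----------------------------------------------------------
    bias_file = out / "bias_scores.tsv"
    if force or not bias_file.exists():
        rows = []
        for s in subjects:
            try:
                b = dpm.score_bias(s.dotprobe, subject=s.subject)
            except dpm.UnscorableSubjectError:
                continue
            rows.append({"subject": b.subject, "bias_ms": b.bias_ms, "group": b.group,
                         "n_used_congruent": b.n_used_congruent,
                         "n_used_incongruent": b.n_used_incongruent})
        pd.DataFrame(rows).to_csv(bias_file, sep="\t", index=False)
    bias_df = pd.read_csv(bias_file, sep="\t")
    scores = [
        dpm.BiasScore(r.subject, r.bias_ms, r.n_used_congruent, r.n_used_incongruent)
        for r in bias_df.itertuples()
    ]
    gstats = {}
    for grp in ("vigilance", "avoidance"):
        if sum(s.group == grp for s in scores) >= 2:
            g = dpm.group_stats(scores, grp)
            gstats[grp] = {"n": g.n, "mean": g.mean, "se": g.se, "t": g.t,
                           "d": g.cohens_d}
    (out / "bias_group_stats.json").write_text(json.dumps(gstats, indent=2))
    summary["bias_groups"] = gstats
    merged = bias_df.merge(efp_windows, on="subject")
    if merged["group"].nunique() == 2 and (merged.groupby("group").size() >= 2).all():
        an = dpm.mixed_anova(
            merged["efp_low_measured"].to_numpy(),
            merged["efp_high_measured"].to_numpy(),
            merged["group"].to_numpy(),
        )
        summary["mixed_anova"] = {"F": an.F, "eta_p2": an.eta_p2}

    # -- predict -----------------------------------------------------------
    table_file = out / "regression.tsv"
    subjects_df = cohort.outcomes.merge(efp_windows, on="subject", how="left")
    steps = outm.hierarchical_regression(
        subjects_df, cfg["outcome"], [list(b) for b in cfg["blocks"]]
    )
    outm.steps_table(steps).to_csv(table_file, sep="\t", index=False)
    summary["regression"] = [
        {"step": s.step, "r_squared": s.r_squared, "betas": s.betas} for s in steps
    ]
    (out / "run_log.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
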