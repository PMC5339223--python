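"""Cohort-directory layout shared by all pipeline stages.

A cohort directory holds::

    subjects.tsv          per-subject outcomes (state_anger, efp_high, ptss, ...)
    manifest.yaml         generator parameters, seeds, acquisition constants
    sub-XX/
        eeg_features.npy  channel x band x frame tensor
        eeg_features.json sidecar (channel labels, band edges, frame length)
        bold.tsv          frames x voxels (columns v000..; 'coupled' flag row in sidecar)
        bold.json         sidecar (tr_s, coupled voxel count)
        rpeaks.tsv        one column of R-peak seconds
        rating.tsv        time_s, level
        dotprobe.tsv      pair_type, probe_at_angry_location, rt_ms, correct

All time coordinates are seconds from recording onset.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import BoldData, Cohort, SubjectData
from .efp import TimeFrequencyTensor
from .series import SampledSeries


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    cohort.outcomes.to_csv(root / "subjects.tsv", sep="\t", index=False)
    inventory = {}
    for s in cohort.subjects:
        sub = root / s.subject
        sub.mkdir(exist_ok=True)
        np.save(sub / "eeg_features.npy", s.eeg.values)
        (sub / "eeg_features.json").write_text(
            json.dumps(
                {
                    "channel_labels": list(s.eeg.channel_labels),
                    "band_edges_hz": list(map(float, s.eeg.band_edges_hz)),
                    "frame_s": s.eeg.frame_s,
                    "start_s": s.eeg.start_s,
                },
                indent=2,
            )
        )
        bold_df = pd.DataFrame(
            s.bold.voxels.T, columns=[f"v{i:03d}" for i in range(s.bold.voxels.shape[0])]
        )
        bold_df.to_csv(sub / "bold.tsv", sep="\t", index=False)
        (sub / "bold.json").write_text(
            json.dumps(
                {"tr_s": s.bold.tr_s, "n_coupled": int(s.bold.coupled_mask.sum())},
                indent=2,
            )
        )
        pd.DataFrame({"time_s": s.rpeaks}).to_csv(sub / "rpeaks.tsv", sep="\t", index=False)
        pd.DataFrame({"time_s": s.rating.times(), "level": s.rating.values.astype(int)}).to_csv(
            sub / "rating.tsv", sep="\t", index=False
        )
        s.dotprobe.to_csv(sub / "dotprobe.tsv", sep="\t", index=False)
        inventory[s.subject] = sorted(p.name for p in sub.iterdir())
    manifest = dict(cohort.manifest)
    manifest["subjects"] = inventory
    (root / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return root


def read_manifest(path: str | Path) -> dict:
    return yaml.safe_load((Path(path) / "manifest.yaml").read_text())


def read_subjects(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path) / "subjects.tsv", sep="\t")


def read_subject(path: str | Path, subject: str) -> SubjectData:
    sub = Path(path) / subject
    side = json.loads((sub / "eeg_features.json").read_text())
    eeg = TimeFrequencyTensor(
        np.load(sub / "eeg_features.npy"),
        side["channel_labels"],
        side["band_edges_hz"],
        side["frame_s"],
        side.get("start_s", 0.0),
    )
    bold_side = json.loads((sub / "bold.json").read_text())
    voxels = pd.read_csv(sub / "bold.tsv", sep="\t").to_numpy().T
    mask = np.zeros(voxels.shape[0], dtype=bool)
    mask[: bold_side["n_coupled"]] = True
    roi = (
        SampledSeries(voxels[mask].mean(axis=0), 1.0 / bold_side["tr_s"])
        if mask.any()
        else None
    )
    bold = BoldData(voxels, mask, roi, bold_side["tr_s"])
    rpeaks = pd.read_csv(sub / "rpeaks.tsv", sep="\t")["time_s"].to_numpy()
    rating_df = pd.read_csv(sub / "rating.tsv", sep="\t")
    dt = np.diff(rating_df["time_s"].to_numpy())
    rate = round(1.0 / float(np.median(dt)), 6) if dt.size else 10.0
    rating = SampledSeries(
        rating_df["level"].to_numpy(dtype=float),
        rate,
        float(rating_df["time_s"].iloc[0]) - 0.5 / rate,
    )
    dotprobe = pd.read_csv(sub / "dotprobe.tsv", sep="\t")
    return SubjectData(subject, eeg, bold, rpeaks, rating, dotprobe, np.nan)


def read_cohort(path: str | Path) -> Cohort:
    root = Path(path)
    manifest = read_manifest(root)
    subjects = [read_subject(root, s) for s in sorted(manifest["subjects"])]
    return Cohort(latent=None, subjects=subjects, outcomes=read_subjects(root),
                  manifest=manifest)
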