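"""File formats: BIDS-style events, motion text, ROI BOLD TSV, sidecars.

Layout written by ``betaconn simulate`` (loosely BIDS-derivatives):

    <root>/participants.tsv
    <root>/sub-XX/reports.tsv
    <root>/sub-XX/ground_truth.json
    <root>/sub-XX/func/sub-XX_run-R_events.tsv
    <root>/sub-XX/func/sub-XX_run-R_motion.txt
    <root>/sub-XX/func/sub-XX_run-R_bold_roi.tsv
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, GroundTruth, SubjectData, SubjectProfile
from .design import TaskDesign, TrialEvent, design_from_trials

__all__ = [
    "write_events",
    "read_events",
    "write_motion",
    "read_motion",
    "write_bold_roi",
    "read_bold_roi",
    "write_subject",
    "write_cohort",
    "read_cohort",
]


def write_events(design: TaskDesign, run_index: int, path: Path) -> None:
    """One BIDS-style events.tsv per run (Guess rows + feedback rows)."""
    rows = []
    for ev in design.run_trials(run_index):
        rt = "" if ev.response_time is None else f"{ev.response_time:.3f}"
        rows.append(
            {
                "onset": f"{ev.guess_onset:.3f}",
                "duration": f"{ev.guess_duration:.3f}",
                "trial_type": ev.condition,
                "response_time": rt,
            }
        )
        rows.append(
            {
                "onset": f"{ev.feedback_onset:.3f}",
                "duration": f"{ev.feedback_duration:.3f}",
                "trial_type": "feedback",
                "response_time": "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events(paths: list[Path], tr: float, volumes_per_run: int) -> TaskDesign:
    """Rebuild a TaskDesign from per-run events.tsv files.

    Jitters are recovered from consecutive onsets so the round-tripped
    design reproduces the written schedule (to the 3-decimal precision of
    the files).
    """
    trials: list[TrialEvent] = []
    for run_index, path in enumerate(paths, start=1):
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:
            raise ValueError(f"cannot parse events file {path}: {exc}") from exc
        for col in ("onset", "duration", "trial_type"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        guesses = df[df["trial_type"] != "feedback"].reset_index(drop=True)
        feedbacks = df[df["trial_type"] == "feedback"].reset_index(drop=True)
        if len(guesses) != len(feedbacks):
            raise ValueError(f"{path}: unmatched Guess/feedback rows")
        for i in range(len(guesses)):
            g, f = guesses.iloc[i], feedbacks.iloc[i]
            rt = g.get("response_time")
            rt = None if pd.isna(rt) or rt == "" else float(rt)
            mid = float(f["onset"]) - float(g["onset"]) - float(g["duration"])
            if i + 1 < len(guesses):
                iti = float(guesses.iloc[i + 1]["onset"]) - float(f["onset"]) - float(f["duration"])
            else:
                iti = volumes_per_run * tr - 15.0 - float(f["onset"]) - float(f["duration"])
            trials.append(
                TrialEvent(
                    run_index=run_index,
                    trial_index=i + 1,
                    condition=str(g["trial_type"]),
                    guess_onset=float(g["onset"]),
                    guess_duration=float(g["duration"]),
                    response_time=rt,
                    mid_jitter=mid,
                    feedback_duration=float(f["duration"]),
                    iti_jitter=iti,
                )
            )
    return design_from_trials(
        trials, tr=tr, volumes_per_run=volumes_per_run, n_runs=len(paths)
    )


def write_motion(params: np.ndarray, path: Path) -> None:
    """Whitespace-delimited 6-column text (translations mm, rotations rad)."""
    np.savetxt(path, np.asarray(params, float), fmt="%.6f")


def read_motion(path: Path) -> np.ndarray:
    params = np.loadtxt(path)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 motion columns")
    return params


def write_bold_roi(bold: pd.DataFrame, path: Path) -> None:
    bold.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_bold_roi(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bold_nifti(data: np.ndarray, affine: np.ndarray, path: Path) -> None:
    """Optional voxel mode: write a 4-D [i, j, k, time] NIfTI-1 image."""
    import nibabel as nib

    nib.Nifti1Image(np.asarray(data, np.float32), np.asarray(affine)).to_filename(
        str(path)
    )


def read_bold_nifti(path: Path) -> tuple[np.ndarray, np.ndarray]:
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def write_subject(subject: SubjectData, root: Path) -> Path:
    sid = subject.profile.subject_id
    sdir = root / sid
    func = sdir / "func"
    func.mkdir(parents=True, exist_ok=True)
    for r in range(1, subject.design.n_runs + 1):
        write_events(subject.design, r, func / f"{sid}_run-{r}_events.tsv")
        if subject.motion:
            write_motion(subject.motion[r - 1], func / f"{sid}_run-{r}_motion.txt")
        if subject.bold is not None:
            write_bold_roi(
                subject.bold[r - 1], func / f"{sid}_run-{r}_bold_roi.tsv"
            )
    subject.reports.to_csv(sdir / "reports.tsv", sep="\t", index=False)
    truth_blob = {
        "rt_offset": subject.rt_offset,
        "true_amplitudes": {
            c: df.round(6).to_dict(orient="list")
            for c, df in subject.true_amplitudes.items()
        },
    }
    (sdir / "ground_truth.json").write_text(json.dumps(truth_blob))
    return sdir


def write_cohort(cohort: Cohort, root: Path, force: bool = False) -> None:
    root = Path(root)
    if root.exists() and any(root.iterdir()) and not force:
        raise FileExistsError(f"output directory {root} not empty (use --force)")
    root.mkdir(parents=True, exist_ok=True)
    parts = []
    for subject in cohort.subjects:
        write_subject(subject, root)
        p = subject.profile
        parts.append(
            {"subject_id": p.subject_id, "age": round(p.age, 3),
             "gender": p.gender, "iq": p.iq}
        )
        behfile = root / p.subject_id / "behavior.tsv"
        subject.behavior.to_csv(behfile, sep="\t", index=False,
                                float_format="%.4f")
    pd.DataFrame(parts).to_csv(root / "participants.tsv", sep="\t", index=False)
    meta = {
        "tr": cohort.subjects[0].design.tr,
        "volumes_per_run": cohort.subjects[0].design.volumes_per_run,
        "n_runs": cohort.subjects[0].design.n_runs,
        "roi_labels": cohort.roi_labels,
        "mode": cohort.mode,
        "truth": dataclasses.asdict(cohort.truth),
    }
    (root / "dataset.json").write_text(json.dumps(meta, indent=1))


def read_cohort(root: Path) -> Cohort:
    """Load a simulated cohort back from disk (BOLD mode layout)."""
    root = Path(root)
    meta = json.loads((root / "dataset.json").read_text())
    participants = pd.read_csv(root / "participants.tsv", sep="\t")
    truth_kwargs = meta["truth"]
    truth_kwargs["age_range"] = tuple(truth_kwargs["age_range"])
    truth_kwargs["reports"] = {
        k: (tuple(v[0]), tuple(v[1])) for k, v in truth_kwargs["reports"].items()
    }
    truth = GroundTruth(**truth_kwargs)
    subjects = []
    for rec in participants.itertuples():
        sid = rec.subject_id
        func = root / sid / "func"
        n_runs = meta["n_runs"]
        design = read_events(
            [func / f"{sid}_run-{r}_events.tsv" for r in range(1, n_runs + 1)],
            tr=meta["tr"],
            volumes_per_run=meta["volumes_per_run"],
        )
        motion = [read_motion(func / f"{sid}_run-{r}_motion.txt")
                  for r in range(1, n_runs + 1)]
        bold = [read_bold_roi(func / f"{sid}_run-{r}_bold_roi.tsv")
                for r in range(1, n_runs + 1)]
        behavior = pd.read_csv(root / sid / "behavior.tsv", sep="\t")
        reports = pd.read_csv(root / sid / "reports.tsv", sep="\t")
        blob = json.loads((root / sid / "ground_truth.json").read_text())
        amps = {
            c: pd.DataFrame(v) for c, v in blob["true_amplitudes"].items()
        }
        subjects.append(
            SubjectData(
                profile=SubjectProfile(sid, float(rec.age), rec.gender,
                                       float(rec.iq)),
                design=design,
                behavior=behavior,
                reports=reports,
                motion=motion,
                bold=bold,
                true_amplitudes=amps,
                rt_offset=float(blob["rt_offset"]),
            )
        )
    return Cohort(subjects=subjects, truth=truth,
                  roi_labels=meta["roi_labels"], mode=meta["mode"])
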