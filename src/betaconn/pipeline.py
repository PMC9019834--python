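"""Stage orchestration: QC -> beta series -> connectivity -> tidy tables.

Turns a :class:`~betaconn.cohort.Cohort` (or per-subject inputs loaded
from disk) into the long-format tables that the inference battery
consumes:

* ``long_table``   - subject x condition network means
* ``node_table``   - subject x condition x node strengths (long)
* ``behavior_table`` - subject x condition mean RT / accuracy
* ``bb_table``     - subject x social level collapsed connectivity,
  behaviour and subjective reports
* ``subject_table`` - one row per subject with covariates and
  condition-collapsed connectivity (for quartile contrasts and the
  motion-matched subsample)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, SubjectData
from .design import CONDITIONS
from .hrf import HrfModel
from .lss import BetaSeries, estimate_beta_series
from .networks import (
    ConnectivityMatrix,
    beta_corr_matrix,
    collapse_conditions,
    network_summary,
    node_strengths,
)
from .qc import QCThresholds, evaluate_run, evaluate_subject, run_qc

__all__ = ["SubjectAnalysis", "analyze_subject", "cohort_tables"]


@dataclass
class SubjectAnalysis:
    subject_id: str
    included: bool
    verdicts: list
    retained_runs: list[int]
    mean_fd: float
    betas: BetaSeries | None = None
    matrices: dict[str, ConnectivityMatrix] = field(default_factory=dict)


def analyze_subject(
    subject: SubjectData,
    rois,
    thresholds: QCThresholds = QCThresholds(),
    hrf: HrfModel = HrfModel(),
    poly_order: int = 3,
) -> SubjectAnalysis:
    """QC + LSS + connectivity for one subject with full BOLD data."""
    sid = subject.profile.subject_id
    verdicts = []
    qcs = []
    for k in range(subject.design.n_runs):
        r = k + 1
        qc = run_qc(subject.motion[k], thresholds=thresholds)
        beh = subject.behavior[subject.behavior["run_index"] == r]
        verdicts.append(evaluate_run(qc, beh, run_index=r, thresholds=thresholds))
        qcs.append(qc)
    included = evaluate_subject(verdicts, thresholds.min_usable_runs)
    retained = [v.run_index for v in verdicts if not v.excluded]
    mean_fd = float(np.mean([qcs[r - 1].mean_fd for r in retained])) if retained else float("nan")
    analysis = SubjectAnalysis(
        subject_id=sid,
        included=included,
        verdicts=verdicts,
        retained_runs=retained,
        mean_fd=mean_fd,
    )
    if not included:
        return analysis

    betas = estimate_beta_series(
        [subject.bold[r - 1].to_numpy() for r in retained],
        subject.design,
        unit_labels=list(subject.bold[0].columns),
        motion=[subject.motion[r - 1] for r in retained],
        censor_masks=[qcs[r - 1].censor_mask for r in retained],
        hrf=hrf,
        poly_order=poly_order,
        run_indices=retained,
    )
    analysis.betas = betas
    for cond, df in betas.betas.items():
        clean = df.dropna()
        analysis.matrices[cond] = beta_corr_matrix(clean, condition=cond)
    return analysis


def _beta_mode_analysis(subject: SubjectData) -> SubjectAnalysis:
    matrices = {
        c: beta_corr_matrix(df, condition=c)
        for c, df in subject.true_amplitudes.items()
    }
    return SubjectAnalysis(
        subject_id=subject.profile.subject_id,
        included=True,
        verdicts=[],
        retained_runs=list(range(1, subject.design.n_runs + 1)),
        mean_fd=float(subject.mean_fd_surrogate),
        betas=BetaSeries(betas=dict(subject.true_amplitudes)),
        matrices=matrices,
    )


def cohort_tables(
    cohort: Cohort,
    rois=None,
    thresholds: QCThresholds = QCThresholds(),
    hrf: HrfModel = HrfModel(),
    poly_order: int = 3,
) -> dict:
    """Run every analysis stage and assemble the tidy inference tables."""
    from .networks import DEFAULT_ROIS

    rois = tuple(rois) if rois is not None else DEFAULT_ROIS
    networks = sorted({s.network for s in rois})
    two_nets = len(networks) == 2

    long_rows, node_rows, beh_rows, bb_rows, subj_rows, excl_rows = [], [], [], [], [], []
    analyses: dict[str, SubjectAnalysis] = {}

    for subject in cohort.subjects:
        prof = subject.profile
        if cohort.mode == "beta":
            ana = _beta_mode_analysis(subject)
        else:
            ana = analyze_subject(subject, rois, thresholds, hrf, poly_order)
        analyses[prof.subject_id] = ana
        for v in ana.verdicts:
            if v.excluded:
                excl_rows.append(
                    {"subject_id": prof.subject_id, "run_index": v.run_index,
                     "reasons": ";".join(v.reasons)}
                )
        if not ana.included:
            excl_rows.append(
                {"subject_id": prof.subject_id, "run_index": 0,
                 "reasons": "subject: fewer than "
                            f"{thresholds.min_usable_runs} usable runs"}
            )
            continue

        covs = {
            "subject_id": prof.subject_id,
            "age": prof.age,
            "gender": prof.gender,
            "iq": prof.iq,
            "mean_fd": ana.mean_fd,
        }
        beh = subject.behavior[
            subject.behavior["run_index"].isin(ana.retained_runs)
        ]
        social_mats: dict[str, list[ConnectivityMatrix]] = {"Peer": [], "Character": []}
        for cond in CONDITIONS:
            if cond not in ana.matrices:
                continue
            C = ana.matrices[cond]
            summ = network_summary(C, rois)
            social, _, ment = cond.partition(" ")
            social_mats[social].append(C)
            row = dict(covs)
            row.update(
                {"condition": cond, "social": social, "mentalizing": ment}
            )
            for net in networks:
                row[f"within_{net}"] = summ.within_mean[net]
            if two_nets:
                row["between"] = summ.between_mean[(networks[0], networks[1])]
            cb = beh[beh["condition"] == cond]
            row["rt"] = float(cb["rt"].mean())
            row["accuracy"] = float(cb["correct"].mean())
            long_rows.append(row)
            beh_rows.append(
                {**covs, "condition": cond, "social": social,
                 "mentalizing": ment, "rt": row["rt"],
                 "accuracy": row["accuracy"]}
            )
            if two_nets:
                ns = node_strengths(C, rois)
                for rec in ns.itertuples():
                    base = dict(covs)
                    base.update({"condition": cond, "social": social,
                                 "mentalizing": ment, "roi": rec.roi})
                    node_rows.append(
                        {**base, "strength_type": "within", "value": rec.within_strength}
                    )
                    node_rows.append(
                        {**base, "strength_type": "between", "value": rec.between_strength}
                    )

        # collapsed Peer / Character rows for brain-behaviour models
        subj_row = dict(covs)
        reports = subject.reports.set_index(["measure", "social"])["score"]
        for social in ("Peer", "Character"):
            if not social_mats[social]:
                continue
            coll = collapse_conditions(social_mats[social], label=social)
            summ = network_summary(coll, rois)
            row = dict(covs)
            row["social"] = social
            for net in networks:
                row[f"within_{net}"] = summ.within_mean[net]
            if two_nets:
                row["between"] = summ.between_mean[(networks[0], networks[1])]
            sb = beh[beh["social"] == social]
            row["rt"] = float(sb["rt"].mean())
            row["accuracy"] = float(sb["correct"].mean())
            for measure in reports.index.get_level_values(0).unique():
                row[measure] = int(reports.loc[(measure, social)])
            bb_rows.append(row)
            suffix = social.lower()
            for net in networks:
                subj_row[f"within_{net}_{suffix}"] = row[f"within_{net}"]
            if two_nets:
                subj_row[f"between_{suffix}"] = row["between"]
        subj_rows.append(subj_row)

    return {
        "long_table": pd.DataFrame(long_rows),
        "node_table": pd.DataFrame(node_rows),
        "behavior_table": pd.DataFrame(beh_rows),
        "bb_table": pd.DataFrame(bb_rows),
        "subject_table": pd.DataFrame(subj_rows),
        "exclusions": pd.DataFrame(
            excl_rows, columns=["subject_id", "run_index", "reasons"]
        ),
        "analyses": analyses,
        "networks": networks,
    }
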