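"""Simulation-based calibration of the inference battery.

These utilities run many small synthetic cohorts in the ROI-level
("beta") mode — amplitude draws stand in for estimated beta series, the
noiseless-recovery limit of the pipeline — to measure:

* the type-I error rate of the social x age interaction test when no
  effect is planted, and
* the sign-recovery rate of the social x age and social x RT interaction
  terms when the generator plants them.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cohort import GroundTruth, generate_cohort
from .networks import DEFAULT_ROIS
from .stats import (
    BRAIN_BEHAVIOR_TERMS,
    CONNECTIVITY_TERMS,
    encode_design,
    fit_lmm,
)

__all__ = [
    "fast_cohort_tables",
    "null_interaction_rejection_rate",
    "planted_sign_recovery",
]


def _network_masks(rois):
    nets = np.array([s.network for s in rois])
    names = sorted(set(nets))
    same = nets[:, None] == nets[None, :]
    iu = np.triu_indices(len(rois), k=1)
    masks = {}
    for n in names:
        in_net = nets == n
        m = np.outer(in_net, in_net)
        masks[f"within_{n}"] = m[iu] & same[iu]
    if len(names) == 2:
        masks["between"] = ~same[iu]
    return iu, masks


def fast_cohort_tables(cohort, rois=DEFAULT_ROIS) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Minimal long / collapsed tables for calibration loops.

    Returns ``(long_table, bb_table)`` with the network-mean outcomes,
    covariates and per-social-level mean RT, skipping node strengths and
    report columns.
    """
    iu, masks = _network_masks(rois)
    long_rows, bb_rows = [], []
    for subject in cohort.subjects:
        prof = subject.profile
        covs = {
            "subject_id": prof.subject_id,
            "age": prof.age,
            "gender": prof.gender,
            "iq": prof.iq,
            "mean_fd": subject.mean_fd_surrogate,
        }
        beh = subject.behavior
        social_r: dict[str, list[np.ndarray]] = {"Peer": [], "Character": []}
        for cond, df in subject.true_amplitudes.items():
            r = np.corrcoef(df.to_numpy(), rowvar=False)[iu]
            social, _, ment = cond.partition(" ")
            social_r[social].append(r)
            row = dict(covs)
            row.update({"social": social, "mentalizing": ment})
            for k, m in masks.items():
                row[k] = float(r[m].mean())
            long_rows.append(row)
        for social, rs in social_r.items():
            r = np.mean(rs, axis=0)
            row = dict(covs)
            row["social"] = social
            for k, m in masks.items():
                row[k] = float(r[m].mean())
            row["rt"] = float(beh.loc[beh["social"] == social, "rt"].mean())
            bb_rows.append(row)
    return pd.DataFrame(long_rows), pd.DataFrame(bb_rows)


def null_interaction_rejection_rate(
    n_cohorts: int = 500,
    n_subjects: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    outcome: str = "within_mentalizing",
    engine: str = "split",
) -> float:
    """Type-I rate of the social x age interaction under a null generator."""
    truth = replace(GroundTruth(), age_coupling=0.0, rt_conn_coupling=0.0)
    root = np.random.default_rng(seed)
    streams = root.spawn(n_cohorts)
    rejections = 0
    for rng in streams:
        cohort = generate_cohort(n_subjects, truth, seed=rng, mode="beta")
        long_table, _ = fast_cohort_tables(cohort)
        res = fit_lmm(encode_design(long_table), outcome, CONNECTIVITY_TERMS,
                      engine=engine)
        if res.p("social:age") < alpha:
            rejections += 1
    return rejections / n_cohorts


def planted_sign_recovery(
    n_reps: int = 50,
    n_subjects: int = 50,
    seed: int = 0,
    truth: GroundTruth | None = None,
    outcome: str = "within_mentalizing",
    engine: str = "split",
) -> dict:
    """Sign-recovery rates for planted interaction effects.

    With the default generator (positive ``age_coupling``, negative
    Peer-specific ``rt_conn_coupling``) the social x age term should come
    back positive and the social x RT term negative.
    """
    truth = truth if truth is not None else GroundTruth()
    root = np.random.default_rng(seed)
    streams = root.spawn(n_reps)
    age_ok = rt_ok = age_sig = rt_sig = 0
    for rng in streams:
        cohort = generate_cohort(n_subjects, truth, seed=rng, mode="beta")
        long_table, bb_table = fast_cohort_tables(cohort)
        res = fit_lmm(encode_design(long_table), outcome, CONNECTIVITY_TERMS,
                      engine=engine)
        est = res.estimate("social:age")
        if np.sign(est) == np.sign(truth.age_coupling):
            age_ok += 1
            if res.p("social:age") < 0.05:
                age_sig += 1
        bb = bb_table.copy()
        bb["behavior"] = bb["rt"]
        res_bb = fit_lmm(encode_design(bb), outcome, BRAIN_BEHAVIOR_TERMS,
                         engine=engine)
        est = res_bb.estimate("social:behavior")
        if np.sign(est) == np.sign(truth.rt_conn_coupling):
            rt_ok += 1
            if res_bb.p("social:behavior") < 0.05:
                rt_sig += 1
    return {
        "age_sign_rate": age_ok / n_reps,
        "rt_sign_rate": rt_ok / n_reps,
        "age_sig_rate": age_sig / n_reps,
        "rt_sig_rate": rt_sig / n_reps,
        "n_reps": n_reps,
    }
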