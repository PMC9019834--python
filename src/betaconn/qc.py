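"""Head-motion quality control.

Framewise displacement (FD) is the Power-style per-volume scalar: the sum
of absolute backward differences of the six rigid-body realignment
parameters, with rotations converted to arc length on a 50 mm sphere.
Volumes with FD above 1 mm are censored; runs are dropped when fewer than
90% of volumes survive, when mean FD exceeds 0.5 mm, or when in-scanner
accuracy is poor (any condition below 50%, or the run overall below
66.7%); subjects need at least three usable runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCThresholds",
    "RunVerdict",
    "QCResult",
    "compute_fd",
    "censor_volumes",
    "evaluate_run",
    "evaluate_subject",
]

DEFAULT_HEAD_RADIUS_MM = 50.0


@dataclass(frozen=True)
class QCThresholds:
    fd_censor: float = 1.0  # mm, per-volume censor threshold
    fd_mean_max: float = 0.5  # mm, run-level mean FD ceiling
    min_volumes_frac: float = 0.90  # fraction of volumes that must survive
    min_condition_acc: float = 0.50  # per-condition accuracy floor within run
    min_run_acc: float = 2.0 / 3.0  # run-level accuracy floor (66.7%)
    min_usable_runs: int = 3


@dataclass
class RunVerdict:
    run_index: int
    excluded: bool
    reasons: list[str] = field(default_factory=list)
    mean_fd: float = float("nan")
    frac_remaining: float = float("nan")
    run_accuracy: float = float("nan")
    condition_accuracy: dict[str, float] = field(default_factory=dict)


@dataclass
class QCResult:
    fd: np.ndarray
    censor_mask: np.ndarray  # True = censored
    mean_fd: float  # over all volumes, before censoring
    verdict: RunVerdict | None = None


def compute_fd(
    params: np.ndarray,
    head_radius: float = DEFAULT_HEAD_RADIUS_MM,
    rotations: str = "radians",
) -> np.ndarray:
    """Framewise displacement from a [volumes x 6] motion-parameter matrix.

    Columns are x, y, z translations (mm) then pitch, roll, yaw rotations.
    ``fd[0] = 0`` by convention; for t >= 1,
    ``fd[t] = sum |d translations| + head_radius * sum |d rotations|``.
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion parameters must be [volumes x 6]")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    if not np.isfinite(params).all():
        raise ValueError("non-finite motion parameters")
    if rotations == "degrees":
        params = params.copy()
        params[:, 3:] = np.deg2rad(params[:, 3:])
    elif rotations != "radians":
        raise ValueError("rotations must be 'radians' or 'degrees'")
    d = np.abs(np.diff(params, axis=0))
    fd = np.zeros(params.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return fd


def censor_volumes(fd: np.ndarray, threshold: float = 1.0) -> np.ndarray:
    """Boolean mask, True where the volume's FD exceeds the threshold."""
    fd = np.asarray(fd, dtype=float)
    return fd > threshold


def run_qc(
    params: np.ndarray,
    head_radius: float = DEFAULT_HEAD_RADIUS_MM,
    thresholds: QCThresholds = QCThresholds(),
    rotations: str = "radians",
) -> QCResult:
    """FD + censoring for one run's motion trace."""
    fd = compute_fd(params, head_radius, rotations)
    mask = censor_volumes(fd, thresholds.fd_censor)
    return QCResult(fd=fd, censor_mask=mask, mean_fd=float(fd.mean()))


def evaluate_run(
    qc: QCResult,
    run_behavior: pd.DataFrame,
    run_index: int = 1,
    thresholds: QCThresholds = QCThresholds(),
) -> RunVerdict:
    """Apply the run-level exclusion rules.

    ``run_behavior`` needs columns ``condition`` and ``correct`` (bool/0-1)
    for the run's trials.  All triggered reasons are recorded.
    """
    if run_behavior is None or len(run_behavior) == 0:
        raise ValueError("missing behavior for run")
    if not {"condition", "correct"} <= set(run_behavior.columns):
        raise ValueError("behavior table needs 'condition' and 'correct' columns")

    n = len(qc.fd)
    frac_remaining = float((~qc.censor_mask).sum()) / n
    cond_acc = run_behavior.groupby("condition")["correct"].mean().to_dict()
    run_acc = float(run_behavior["correct"].mean())

    reasons = []
    if frac_remaining < thresholds.min_volumes_frac:
        reasons.append(f"remaining<{thresholds.min_volumes_frac:.0%}")
    if qc.mean_fd > thresholds.fd_mean_max:
        reasons.append(f"meanFD>{thresholds.fd_mean_max}")
    if any(a < thresholds.min_condition_acc for a in cond_acc.values()):
        reasons.append(f"condition_accuracy<{thresholds.min_condition_acc:.0%}")
    if run_acc < thresholds.min_run_acc:
        reasons.append(f"run_accuracy<{thresholds.min_run_acc:.1%}")

    return RunVerdict(
        run_index=run_index,
        excluded=bool(reasons),
        reasons=reasons,
        mean_fd=qc.mean_fd,
        frac_remaining=frac_remaining,
        run_accuracy=run_acc,
        condition_accuracy={k: float(v) for k, v in cond_acc.items()},
    )


def evaluate_subject(
    verdicts: list[RunVerdict], min_usable_runs: int = 3
) -> bool:
    """Subject is included iff at least ``min_usable_runs`` runs survive."""
    usable = sum(not v.excluded for v in verdicts)
    return usable >= min_usable_runs
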