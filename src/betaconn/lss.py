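"""Trial-wise beta-series estimation via least-squares-single (LSS) GLMs.

For each condition, one GLM is fit per trial (24 by default): the design
holds one column for the target trial and one column aggregating all
remaining same-condition trials, alongside nuisance regressors — the
Guess periods of the other conditions, all Feedback events, the demeaned
motion parameters and their backward-difference derivatives, one spike
indicator per censored volume, and per-run Legendre polynomial baselines.
The target-trial coefficient from each fit is that trial's beta; the
resulting ROI x trial matrices are the beta series that downstream
connectivity correlates.

Runs are concatenated: task columns span runs while motion, spike and
baseline columns are block-diagonal per run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONDITIONS, TaskDesign
from .hrf import HrfModel, RegressorGrid

__all__ = [
    "LssModel",
    "BetaSeries",
    "estimate_beta_series",
    "legendre_basis",
    "motion_nuisance",
    "extract_roi_series",
    "average_betas_by_roi",
]

RANK_RTOL = 1e-10


@dataclass
class BetaSeries:
    """Per-condition trial-amplitude estimates (rows = trials, cols = units)."""

    betas: dict[str, pd.DataFrame]
    diagnostics: dict = field(default_factory=dict)

    def conditions(self) -> list[str]:
        return list(self.betas)


def legendre_basis(n_volumes: int, order: int) -> np.ndarray:
    """Legendre polynomials of degree 0..order on [-1, 1], one per column."""
    x = np.linspace(-1.0, 1.0, n_volumes)
    return np.polynomial.legendre.legvander(x, order)


def motion_nuisance(params: np.ndarray) -> np.ndarray:
    """Demeaned motion parameters plus backward-difference derivatives.

    The derivative's first element is 0; demeaning is per run (this
    function is called once per run).
    """
    params = np.asarray(params, dtype=float)
    demeaned = params - params.mean(axis=0, keepdims=True)
    deriv = np.zeros_like(params)
    deriv[1:] = np.diff(params, axis=0)
    return np.hstack([demeaned, deriv])


class LssModel:
    """Workspace holding the convolved regressors for one subject/session.

    Parameters
    ----------
    design : TaskDesign
        The event schedule (all runs).
    motion : list of [volumes x 6] arrays, optional
        Per-run realignment parameters; omitted -> no motion regressors.
    censor_masks : list of boolean arrays, optional
        Per-run censor masks; each censored volume gets a spike column.
    run_indices : list of int, optional
        Which runs enter the model (1-based); defaults to all runs.
        Excluded (QC-failed) runs are simply left out.
    """

    def __init__(
        self,
        design: TaskDesign,
        motion: list[np.ndarray] | None = None,
        censor_masks: list[np.ndarray] | None = None,
        hrf: HrfModel = HrfModel(),
        poly_order: int = 3,
        run_indices: list[int] | None = None,
        missing_rt_duration: float = 8.0,
    ):
        self.design = design
        self.hrf = hrf
        self.poly_order = poly_order
        self.runs = run_indices or list(range(1, design.n_runs + 1))
        nv = design.volumes_per_run
        self.n_volumes = nv * len(self.runs)
        grid = RegressorGrid(nv, design.tr, hrf)

        # per-trial Guess regressors and the Feedback aggregate, stacked
        self.trial_cols: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
        self.trial_events: dict[str, list] = {c: [] for c in CONDITIONS}
        feedback = np.zeros(self.n_volumes)
        for k, r in enumerate(self.runs):
            sl = slice(k * nv, (k + 1) * nv)
            for ev in design.run_trials(r):
                dur = ev.response_time if ev.response_time else missing_rt_duration
                col = np.zeros(self.n_volumes)
                col[sl] = grid.regressor(ev.guess_onset, dur)
                self.trial_cols[ev.condition].append(col)
                self.trial_events[ev.condition].append(ev)
                feedback[sl] += grid.regressor(ev.feedback_onset, ev.feedback_duration)
        self.feedback_col = feedback
        self.cond_agg = {
            c: np.sum(self.trial_cols[c], axis=0) for c in CONDITIONS if self.trial_cols[c]
        }

        # block-diagonal nuisance: baseline polynomials, motion, spikes
        blocks: list[np.ndarray] = []
        labels: list[str] = []
        for k, r in enumerate(self.runs):
            cols = [legendre_basis(nv, poly_order)]
            lab = [f"run{r}_poly{j}" for j in range(poly_order + 1)]
            if motion is not None:
                cols.append(motion_nuisance(motion[k]))
                lab += [f"run{r}_motion{j}" for j in range(6)]
                lab += [f"run{r}_dmotion{j}" for j in range(6)]
            if censor_masks is not None:
                idx = np.flatnonzero(np.asarray(censor_masks[k], dtype=bool))
                spikes = np.zeros((nv, len(idx)))
                spikes[idx, np.arange(len(idx))] = 1.0
                if len(idx):
                    cols.append(spikes)
                    lab += [f"run{r}_spike{v}" for v in idx]
            block = np.hstack(cols)
            full = np.zeros((self.n_volumes, block.shape[1]))
            full[k * nv : (k + 1) * nv] = block
            blocks.append(full)
            labels += lab
        self.nuisance = np.hstack(blocks)
        self.nuisance_labels = labels
        self.n_fits = 0

    # -- design-matrix construction ------------------------------------
    def design_for(self, condition: str, trial: int) -> tuple[np.ndarray, list[str]]:
        """Full LSS design matrix for one target trial (0-based index)."""
        cols = self.trial_cols.get(condition)
        if not cols:
            raise KeyError(f"no trials for condition {condition!r}")
        if not 0 <= trial < len(cols):
            raise IndexError(f"trial {trial} out of range for {condition!r}")
        target = cols[trial]
        others = self.cond_agg[condition] - target
        parts = [target]
        labels = [f"target[{condition}#{trial}]"]
        if len(cols) > 1:
            parts.append(others)
            labels.append(f"others[{condition}]")
        for c in CONDITIONS:
            if c != condition and c in self.cond_agg:
                parts.append(self.cond_agg[c])
                labels.append(f"guess[{c}]")
        parts.append(self.feedback_col)
        labels.append("feedback")
        X = np.column_stack(parts + [self.nuisance])
        return X, labels + self.nuisance_labels

    # -- estimation ----------------------------------------------------
    def fit_condition(self, Y: np.ndarray, condition: str) -> np.ndarray:
        """LSS betas for one condition: [n_trials x n_units]."""
        n_trials = len(self.trial_cols[condition])
        out = np.full((n_trials, Y.shape[1]), np.nan)
        for t in range(n_trials):
            X, _ = self.design_for(condition, t)
            if X.shape[1] > X.shape[0]:
                raise ValueError(
                    f"more regressors ({X.shape[1]}) than volumes ({X.shape[0]})"
                )
            beta, _, rank, sv = np.linalg.lstsq(X, Y, rcond=RANK_RTOL)
            self.n_fits += 1
            if rank < X.shape[1]:
                # degenerate nuisance columns are harmless under the
                # minimum-norm solve; the target coefficient is unique
                # unless the target column lies in the span of the rest
                others = X[:, 1:]
                coef, *_ = np.linalg.lstsq(others, X[:, 0], rcond=RANK_RTOL)
                resid = X[:, 0] - others @ coef
                if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(X[:, 0]), 1e-30):
                    warnings.warn(
                        f"target regressor for {condition!r} trial {t} is "
                        "collinear with the rest of the design; beta set to missing",
                        stacklevel=2,
                    )
                    continue
            out[t] = beta[0]
        return out

    def regressor_correlations(self) -> pd.DataFrame:
        """Pairwise correlations among the condition/Feedback aggregates.

        A post-hoc collinearity check on the task regressors (flagged at
        |r| >= 0.5).
        """
        names = list(self.cond_agg) + ["feedback"]
        mat = np.column_stack([self.cond_agg[c] for c in self.cond_agg] + [self.feedback_col])
        r = np.corrcoef(mat, rowvar=False)
        return pd.DataFrame(r, index=names, columns=names)


def estimate_beta_series(
    bold_runs: list[np.ndarray],
    design: TaskDesign,
    unit_labels: list[str],
    motion: list[np.ndarray] | None = None,
    censor_masks: list[np.ndarray] | None = None,
    hrf: HrfModel = HrfModel(),
    poly_order: int = 3,
    run_indices: list[int] | None = None,
    conditions: tuple[str, ...] = CONDITIONS,
) -> BetaSeries:
    """Iterated-OLS LSS beta series for each condition.

    ``bold_runs`` is one [volumes x units] matrix per retained run, in the
    order of ``run_indices``; units are ROIs (default mode) or voxels.
    """
    model = LssModel(
        design,
        motion=motion,
        censor_masks=censor_masks,
        hrf=hrf,
        poly_order=poly_order,
        run_indices=run_indices,
    )
    Y = np.vstack(bold_runs).astype(float)
    if Y.shape[0] != model.n_volumes:
        raise ValueError(
            f"BOLD has {Y.shape[0]} volumes; design expects {model.n_volumes}"
        )
    if not np.isfinite(Y).all():
        raise ValueError("non-finite values in BOLD data")

    betas: dict[str, pd.DataFrame] = {}
    for c in conditions:
        if not model.trial_cols.get(c):
            continue
        b = model.fit_condition(Y, c)
        betas[c] = pd.DataFrame(b, columns=unit_labels)

    reg_corr = model.regressor_correlations()
    off = reg_corr.to_numpy()[~np.eye(len(reg_corr), dtype=bool)]
    max_corr = float(np.abs(off).max()) if off.size else 0.0
    if max_corr >= 0.5:
        warnings.warn(
            f"task regressor collinearity: max |r| = {max_corr:.2f} >= 0.5",
            stacklevel=2,
        )
    diagnostics = {
        "n_fits": model.n_fits,
        "max_task_regressor_corr": max_corr,
        "n_volumes": model.n_volumes,
        "n_nuisance": model.nuisance.shape[1],
    }
    return BetaSeries(betas=betas, diagnostics=diagnostics)


# -- voxel mode ---------------------------------------------------------

def extract_roi_series(
    data: np.ndarray,
    affine: np.ndarray,
    rois,
) -> pd.DataFrame:
    """Average a 4-D voxel image over each 5 mm ROI sphere.

    ``data`` is [i, j, k, time]; ``affine`` maps voxel indices to MNI mm.
    Returns a [time x ROI] DataFrame.
    """
    data = np.asarray(data)
    if data.ndim != 4:
        raise ValueError("voxel data must be 4-D (i, j, k, time)")
    ii, jj, kk = np.meshgrid(
        np.arange(data.shape[0]),
        np.arange(data.shape[1]),
        np.arange(data.shape[2]),
        indexing="ij",
    )
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)])
    mm = (vox @ np.asarray(affine).T)[:, :3]
    flat = data.reshape(-1, data.shape[3])
    out = {}
    for spec in rois:
        d2 = ((mm - np.asarray(spec.mni_xyz)) ** 2).sum(axis=1)
        inside = d2 <= spec.radius**2
        if not inside.any():
            raise ValueError(f"ROI sphere {spec.name!r} contains no voxels")
        out[spec.name] = flat[inside].mean(axis=0)
    return pd.DataFrame(out)


def average_betas_by_roi(
    voxel_betas: BetaSeries,
    voxel_mm: np.ndarray,
    rois,
) -> BetaSeries:
    """Collapse voxel-wise beta series to ROI means (5 mm spheres)."""
    out: dict[str, pd.DataFrame] = {}
    for cond, df in voxel_betas.betas.items():
        cols = {}
        for spec in rois:
            d2 = ((voxel_mm - np.asarray(spec.mni_xyz)) ** 2).sum(axis=1)
            inside = d2 <= spec.radius**2
            if not inside.any():
                raise ValueError(f"ROI sphere {spec.name!r} contains no voxels")
            cols[spec.name] = df.to_numpy()[:, inside].mean(axis=1)
        out[cond] = pd.DataFrame(cols)
    return BetaSeries(betas=out, diagnostics=dict(voxel_betas.diagnostics))
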