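"""Synthetic cohort generation with planted ground truth.

Every downstream stage of the pipeline (QC, LSS, connectivity, group
inference) is validated against cohorts generated here, where the
connectivity structure, age effects and behavioural effects are known by
construction.

The generator plants, per subject:

* trial amplitudes per condition drawn from a multivariate normal across
  the 14 ROIs, whose correlation structure carries a within-network
  (default 0.25) and between-network (default 0.10) baseline plus a
  Peer-minus-Character offset that grows linearly with age
  (``age_coupling`` r/year) and, in the Peer conditions only, tracks the
  subject's response-time deviation (``rt_conn_coupling`` r/s);
* response times that are faster for Peer than Character (default
  -0.08 s) and decrease with age, with trial-level noise truncated to
  (0.2, 8] s;
* Bernoulli accuracy around 90.17% with an optional Character-specific
  age slope;
* 5-point ordinal post-scan reports from a discretized latent-normal
  model with Peer-shifted locations for the enjoyment / motivation /
  attention measures and an unshifted Perceived Difficulty;
* realistic motion traces (drift + jitter + spikes) and BOLD as the sum
  of amplitude-weighted duration-modulated responses, Feedback responses,
  polynomial drift, AR(1) noise and a motion-coupled component.

Two cohort modes exist: ``"bold"`` synthesizes full ROI time series to be
run through the LSS stage, while ``"beta"`` emits the amplitude draws
directly as beta series — the noiseless-recovery limit, used for
large-replicate statistical calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONDITIONS, TaskDesign, generate_design
from .hrf import HrfModel, RegressorGrid
from .lss import legendre_basis
from .qc import compute_fd

__all__ = [
    "GroundTruth",
    "SubjectProfile",
    "SubjectData",
    "Cohort",
    "REPORT_MEASURES",
    "amplitude_correlation",
    "generate_behavior",
    "generate_reports",
    "generate_motion",
    "generate_bold",
    "generate_subject",
    "generate_cohort",
]

#: post-scan questionnaire measures with default latent locations
#: (Peer, Character) and latent SDs, on the 1-5 report scale.
REPORT_MEASURES: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "Liked Chatting": ((4.30, 2.76), (0.81, 1.04)),
    "Liked Guessing": ((3.84, 3.26), (0.96, 1.12)),
    "Felt When Matched": ((4.26, 3.96), (0.83, 0.88)),
    "Wanted to See": ((4.08, 3.38), (0.92, 1.23)),
    "Paid Attention": ((3.90, 3.40), (0.91, 0.97)),
    # Perceived Difficulty is unshifted between social contexts
    "Perceived Difficulty": ((2.29, 2.29), (1.26, 1.26)),
}


@dataclass
class GroundTruth:
    """Planted parameters of the synthetic cohort."""

    # amplitude model (arbitrary BOLD units)
    amplitude_mean: float = 1.0
    amplitude_sd: float = 1.0
    within_r: float = 0.25
    between_r: float = 0.10
    age_coupling: float = 0.04  # Peer-Character correlation offset, r per year
    rt_conn_coupling: float = -0.05  # Peer-only correlation offset, r per second
    feedback_amplitude: float = 0.5

    # behaviour
    rt_base: float = 2.04  # s, at the age midpoint
    rt_age_slope: float = -0.10  # s per year
    rt_social_effect: float = -0.08  # s, Peer minus Character
    rt_subject_sd: float = 0.25  # s, between-subject spread
    rt_trial_sd: float = 0.45  # s, within-subject trial noise
    rt_missing_prob: float = 0.0
    accuracy_base: float = 0.9017
    accuracy_age_slope_character: float = 0.025  # per year, Character only

    # BOLD noise
    noise_ar1: float = 0.3
    # stationary SD in amplitude units at ROI scale: voxel-level noise of
    # about one amplitude unit averaged over the ~8 voxels of a 5 mm
    # sphere on a 2 mm grid
    noise_sd: float = 0.35
    drift_sd: float = 0.3  # SD of Legendre drift coefficients (orders 1-3)
    motion_coupling: float = 0.2

    # motion trace
    motion_drift_step: float = 0.01  # mm random-walk step per volume
    motion_trans_jitter: float = 0.02  # mm white jitter
    motion_rot_jitter: float = 0.0004  # rad white jitter
    motion_spike_prob: float = 0.01
    motion_spike_mag: float = 1.2  # mm

    # demographics
    age_range: tuple[float, float] = (8.18, 12.97)
    p_male: float = 0.6
    # fast-mode surrogate for the QC mean-FD covariate
    mean_fd_loc: float = 0.23
    mean_fd_sd: float = 0.08
    fd_age_corr: float = -0.24

    reports: dict = field(default_factory=lambda: dict(REPORT_MEASURES))

    def __post_init__(self) -> None:
        if not 0 < self.accuracy_base <= 1:
            raise ValueError("accuracy_base must lie in (0, 1]")
        if not -1 < self.noise_ar1 < 1:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")

    @property
    def age_mid(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])


@dataclass
class SubjectProfile:
    subject_id: str
    age: float
    gender: str  # "M" / "F"
    iq: float


@dataclass
class SubjectData:
    profile: SubjectProfile
    design: TaskDesign
    behavior: pd.DataFrame  # run_index, trial_index, condition, rt, correct
    reports: pd.DataFrame  # measure, social, score
    motion: list[np.ndarray]
    bold: list[pd.DataFrame] | None  # per-run [volumes x ROI]; None in beta mode
    true_amplitudes: dict[str, pd.DataFrame]
    rt_offset: float
    mean_fd_surrogate: float | None = None  # beta mode only


@dataclass
class Cohort:
    subjects: list[SubjectData]
    truth: GroundTruth
    roi_labels: list[str]
    mode: str


# -- planted covariance -------------------------------------------------

def _nearest_psd_correlation(R: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clip a symmetric matrix and renormalize to unit diagonal."""
    w, v = np.linalg.eigh(R)
    if w.min() >= floor:
        return R
    w = np.clip(w, floor, None)
    R2 = (v * w) @ v.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


def amplitude_correlation(
    truth: GroundTruth,
    networks: list[str],
    condition: str,
    age: float | None = None,
    rt_dev: float = 0.0,
) -> np.ndarray:
    """Planted trial-amplitude correlation matrix for one condition.

    ``networks`` gives each ROI's network label; ``rt_dev`` is the
    subject's age-independent RT deviation in seconds (couples to the
    Peer conditions only).
    """
    if age is None:
        age = truth.age_mid
    nets = np.asarray(networks)
    same = nets[:, None] == nets[None, :]
    R = np.where(same, truth.within_r, truth.between_r)
    delta = truth.age_coupling * (age - truth.age_mid)
    is_peer = condition.startswith("Peer")
    off = 0.5 * delta if is_peer else -0.5 * delta
    if is_peer:
        off += truth.rt_conn_coupling * rt_dev
    R = np.clip(R + off, -0.95, 0.95)
    np.fill_diagonal(R, 1.0)
    return _nearest_psd_correlation(R)


def draw_amplitudes(
    truth: GroundTruth,
    networks: list[str],
    condition: str,
    n_trials: int,
    rng: np.random.Generator,
    age: float | None = None,
    rt_dev: float = 0.0,
) -> np.ndarray:
    """[n_trials x n_roi] multivariate-normal trial amplitudes."""
    mean = np.full(len(networks), truth.amplitude_mean)
    if truth.amplitude_sd == 0:
        return np.tile(mean, (n_trials, 1))
    R = amplitude_correlation(truth, networks, condition, age, rt_dev)
    cov = truth.amplitude_sd**2 * R
    return rng.multivariate_normal(mean, cov, size=n_trials, method="cholesky")


# -- behaviour ----------------------------------------------------------

def generate_behavior(
    design: TaskDesign,
    profile: SubjectProfile,
    truth: GroundTruth,
    rng: np.random.Generator,
    rt_offset: float = 0.0,
    rt_lo: float = 0.2,
    rt_hi: float = 8.0,
) -> pd.DataFrame:
    """Per-trial response time and accuracy.

    RT = base(age) + subject offset + social effect for Peer trials +
    truncated-normal trial noise on (rt_lo, rt_hi].
    """
    labels = [ev.label for ev in design.trials]
    is_peer = np.array([lab.social == "Peer" for lab in labels])
    base = truth.rt_base + truth.rt_age_slope * (profile.age - truth.age_mid) + rt_offset
    mu = base + np.where(is_peer, truth.rt_social_effect, 0.0)
    if truth.rt_trial_sd > 0:
        a = (rt_lo - mu) / truth.rt_trial_sd
        b = (rt_hi - mu) / truth.rt_trial_sd
        # inverse-CDF truncated normal, vectorized over trials
        u = rng.random(len(mu))
        from scipy.special import ndtr, ndtri

        lo_cdf, hi_cdf = ndtr(a), ndtr(b)
        rt = mu + truth.rt_trial_sd * ndtri(lo_cdf + u * (hi_cdf - lo_cdf))
    else:
        rt = np.clip(mu, rt_lo, rt_hi)
    if truth.rt_missing_prob > 0:
        rt = np.where(rng.random(len(mu)) < truth.rt_missing_prob, np.nan, rt)
    p = np.full(len(mu), truth.accuracy_base)
    p[~is_peer] += truth.accuracy_age_slope_character * (profile.age - truth.age_mid)
    p = np.clip(p, 0.0, 1.0)
    correct = rng.random(len(mu)) < p
    return pd.DataFrame(
        {
            "run_index": [ev.run_index for ev in design.trials],
            "trial_index": [ev.trial_index for ev in design.trials],
            "condition": [ev.condition for ev in design.trials],
            "social": [lab.social for lab in labels],
            "mentalizing": [lab.mentalizing for lab in labels],
            "rt": rt,
            "correct": correct,
        }
    )


def generate_reports(
    profile: SubjectProfile,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Ordinal 1-5 reports from the discretized latent-normal model."""
    rows = []
    for measure, (locs, sds) in truth.reports.items():
        for social, loc, sd in zip(("Peer", "Character"), locs, sds):
            latent = loc + sd * rng.standard_normal()
            score = int(np.clip(np.rint(latent), 1, 5))
            rows.append({"measure": measure, "social": social, "score": score})
    return pd.DataFrame(rows)


# -- motion & BOLD ------------------------------------------------------

def generate_motion(
    n_volumes: int,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> np.ndarray:
    """[volumes x 6] rigid-body trace: random-walk drift + jitter + spikes."""
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    scale = np.array([1.0] * 3 + [1.0 / 50.0] * 3)  # rotations drift smaller
    drift = np.cumsum(
        rng.normal(0.0, truth.motion_drift_step, size=(n_volumes, 6)) * scale, axis=0
    )
    jitter = rng.normal(0.0, 1.0, size=(n_volumes, 6))
    jitter[:, :3] *= truth.motion_trans_jitter
    jitter[:, 3:] *= truth.motion_rot_jitter
    params = drift + jitter
    if truth.motion_spike_prob > 0 and truth.motion_spike_mag > 0:
        hits = rng.random(n_volumes) < truth.motion_spike_prob
        hits[0] = False
        for t in np.flatnonzero(hits):
            axis = rng.integers(0, 3)
            params[t, axis] += truth.motion_spike_mag * rng.choice([-1.0, 1.0])
    return params


def generate_bold(
    design: TaskDesign,
    truth: GroundTruth,
    motion: list[np.ndarray],
    rng: np.random.Generator,
    roi_labels: list[str],
    networks: list[str],
    age: float | None = None,
    rt_dev: float = 0.0,
    hrf: HrfModel = HrfModel(),
) -> tuple[list[pd.DataFrame], dict[str, pd.DataFrame]]:
    """Synthesize per-run ROI BOLD and return the drawn trial amplitudes.

    The signal inverts the analysis model: each trial contributes its
    amplitude times the duration-modulated response (duration = the
    trial's RT, falling back to the full 8 s Guess window), Feedback
    events add a fixed nuisance amplitude, and noise is polynomial drift
    plus AR(1) plus a motion-coupled component.
    """
    n_roi = len(roi_labels)
    nv = design.volumes_per_run
    grid = RegressorGrid(nv, design.tr, hrf)

    # amplitudes drawn per condition, trial order matching the design
    amps: dict[str, pd.DataFrame] = {}
    for c in CONDITIONS:
        trials = design.condition_trials(c)
        if not trials:
            continue
        a = draw_amplitudes(truth, networks, c, len(trials), rng, age, rt_dev)
        amps[c] = pd.DataFrame(a, columns=roi_labels)

    counters = {c: 0 for c in amps}
    runs: list[pd.DataFrame] = []
    coupling_w = rng.standard_normal(n_roi)
    for k in range(design.n_runs):
        r = k + 1
        sig = np.zeros((nv, n_roi))
        for ev in design.run_trials(r):
            dur = ev.response_time if ev.response_time and np.isfinite(ev.response_time) else 8.0
            reg = grid.regressor(ev.guess_onset, dur)
            a = amps[ev.condition].iloc[counters[ev.condition]].to_numpy()
            counters[ev.condition] += 1
            sig += np.outer(reg, a)
            fb = grid.regressor(ev.feedback_onset, ev.feedback_duration)
            sig += truth.feedback_amplitude * fb[:, None]
        # drift
        if truth.drift_sd > 0:
            basis = legendre_basis(nv, 3)[:, 1:]
            sig += basis @ rng.normal(0.0, truth.drift_sd, size=(3, n_roi))
        # AR(1) noise
        if truth.noise_sd > 0:
            phi = truth.noise_ar1
            innov_sd = truth.noise_sd * np.sqrt(1.0 - phi**2)
            eps = rng.normal(0.0, innov_sd, size=(nv, n_roi))
            eps[0] = rng.normal(0.0, truth.noise_sd, size=n_roi)
            noise = np.empty_like(eps)
            noise[0] = eps[0]
            for t in range(1, nv):
                noise[t] = phi * noise[t - 1] + eps[t]
            sig += noise
        # motion-coupled component
        if truth.motion_coupling > 0 and motion is not None:
            fd = compute_fd(motion[k])
            sig += truth.motion_coupling * np.outer(fd - fd.mean(), coupling_w)
        runs.append(pd.DataFrame(sig, columns=roi_labels))
    return runs, amps


# -- subjects and cohorts ----------------------------------------------

def _draw_profile(i: int, truth: GroundTruth, rng: np.random.Generator) -> SubjectProfile:
    lo, hi = truth.age_range
    return SubjectProfile(
        subject_id=f"sub-{i + 1:02d}",
        age=float(rng.uniform(lo, hi)),
        gender="M" if rng.random() < truth.p_male else "F",
        iq=float(np.clip(np.rint(rng.normal(100.0, 15.0)), 55, 145)),
    )


def generate_subject(
    i: int,
    truth: GroundTruth,
    rng: np.random.Generator,
    roi_labels: list[str],
    networks: list[str],
    mode: str = "bold",
    n_trials_per_condition: int = 24,
    design: TaskDesign | None = None,
) -> SubjectData:
    profile = _draw_profile(i, truth, rng)
    rt_offset = float(rng.normal(0.0, truth.rt_subject_sd))

    if mode == "beta":
        # ROI-level shortcut: amplitude draws stand in for estimated betas
        amps = {
            c: pd.DataFrame(
                draw_amplitudes(
                    truth, networks, c, n_trials_per_condition, rng,
                    profile.age, rt_offset,
                ),
                columns=roi_labels,
            )
            for c in CONDITIONS
        }
        if design is None:
            design = generate_design(seed=rng)
        behavior = _summary_behavior(design, profile, truth, rng, rt_offset)
        reports = generate_reports(profile, truth, rng)
        z_age = (profile.age - truth.age_mid) / (
            (truth.age_range[1] - truth.age_range[0]) / np.sqrt(12.0)
        )
        rho = truth.fd_age_corr
        z = rho * z_age + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal()
        mean_fd = float(np.clip(truth.mean_fd_loc + truth.mean_fd_sd * z, 0.03, None))
        return SubjectData(
            profile=profile,
            design=design,
            behavior=behavior,
            reports=reports,
            motion=[],
            bold=None,
            true_amplitudes=amps,
            rt_offset=rt_offset,
            mean_fd_surrogate=mean_fd,
        )

    if design is None:
        design = generate_design(seed=rng)
    behavior = generate_behavior(design, profile, truth, rng, rt_offset)
    # write measured RTs back onto the schedule: they set regressor durations
    rt_map = {
        (int(b.run_index), int(b.trial_index)): b.rt for b in behavior.itertuples()
    }
    for ev in design.trials:
        rt = rt_map[(ev.run_index, ev.trial_index)]
        ev.response_time = None if not np.isfinite(rt) else float(rt)
    motion = [
        generate_motion(design.volumes_per_run, truth, rng)
        for _ in range(design.n_runs)
    ]
    bold, amps = generate_bold(
        design, truth, motion, rng, roi_labels, networks,
        age=profile.age, rt_dev=rt_offset,
    )
    reports = generate_reports(profile, truth, rng)
    return SubjectData(
        profile=profile,
        design=design,
        behavior=behavior,
        reports=reports,
        motion=motion,
        bold=bold,
        true_amplitudes=amps,
        rt_offset=rt_offset,
    )


def _summary_behavior(
    design: TaskDesign,
    profile: SubjectProfile,
    truth: GroundTruth,
    rng: np.random.Generator,
    rt_offset: float,
) -> pd.DataFrame:
    """Trial-level behaviour for beta-mode cohorts (no BOLD synthesis)."""
    return generate_behavior(design, profile, truth, rng, rt_offset)


def generate_cohort(
    n_subjects: int,
    truth: GroundTruth | None = None,
    seed: int | np.random.Generator | None = 0,
    rois=None,
    mode: str = "bold",
    n_trials_per_condition: int = 24,
) -> Cohort:
    """Generate a complete synthetic cohort.

    ``mode="bold"`` produces full ROI time series for the LSS stage;
    ``mode="beta"`` emits the planted amplitude draws directly as beta
    series (used for large statistical calibrations).
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if mode not in ("bold", "beta"):
        raise ValueError("mode must be 'bold' or 'beta'")
    from .networks import DEFAULT_ROIS

    rois = tuple(rois) if rois is not None else DEFAULT_ROIS
    truth = truth if truth is not None else GroundTruth()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [s.name for s in rois]
    networks = [s.network for s in rois]
    streams = rng.spawn(n_subjects)
    # in beta mode the schedule itself is irrelevant to the summaries;
    # share one design across subjects to keep large calibrations cheap
    shared = generate_design(seed=rng) if mode == "beta" else None
    subjects = [
        generate_subject(i, truth, streams[i], labels, networks, mode,
                         n_trials_per_condition, design=shared)
        for i in range(n_subjects)
    ]
    return Cohort(subjects=subjects, truth=truth, roi_labels=labels, mode=mode)
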