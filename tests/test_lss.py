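"""LSS estimation: oracle equivalence, exact recovery, linear-model invariants."""

import numpy as np
import pytest
from dataclasses import replace

from betaconn.cohort import GroundTruth, generate_bold, generate_cohort
from betaconn.design import CONDITIONS, TrialEvent, design_from_trials, generate_design
from betaconn.hrf import RegressorGrid
from betaconn.lss import (
    LssModel,
    estimate_beta_series,
    extract_roi_series,
    legendre_basis,
    motion_nuisance,
)
from betaconn.networks import DEFAULT_ROIS
from betaconn.pipeline import cohort_tables

LABELS = [s.name for s in DEFAULT_ROIS]
NETS = [s.network for s in DEFAULT_ROIS]

NOISELESS = replace(
    GroundTruth(),
    noise_sd=0.0, drift_sd=0.0, motion_coupling=0.0,
    motion_spike_prob=0.0, motion_drift_step=0.0,
    motion_trans_jitter=0.0, motion_rot_jitter=0.0,
)


def _spaced_design(n_trials=4, iti=40.0, rt=3.0):
    """Widely spaced design: one trial per condition per cycle."""
    trials, t = [], 10.0
    for i in range(n_trials):
        ev = TrialEvent(
            run_index=1, trial_index=i + 1, condition=CONDITIONS[i % 4],
            guess_onset=t, response_time=rt, mid_jitter=4.0, iti_jitter=iti,
        )
        trials.append(ev)
        t = ev.end
    return design_from_trials(trials)


def test_noiseless_wide_spacing_exact_recovery():
    """When the model spans the signal, betas equal planted amplitudes."""
    design = _spaced_design(4)
    rng = np.random.default_rng(5)
    motion = [np.zeros((design.volumes_per_run, 6))]
    bold, amps = generate_bold(design, NOISELESS, motion, rng, LABELS, NETS)
    bs = estimate_beta_series([bold[0].to_numpy()], design, LABELS, motion=motion)
    for cond in bs.betas:
        assert bs.betas[cond].to_numpy() == pytest.approx(
            amps[cond].to_numpy(), abs=1e-6
        )


def test_noiseless_full_design_equal_amplitudes_exact():
    """With equal within-condition amplitudes the aggregate columns span
    the signal, so the full 96-trial design is recovered exactly."""
    truth = replace(NOISELESS, amplitude_sd=0.0)
    design = generate_design(seed=2)
    rng = np.random.default_rng(8)
    motion = [np.zeros((design.volumes_per_run, 6))] * 4
    bold, amps = generate_bold(design, truth, motion, rng, LABELS, NETS)
    bs = estimate_beta_series(
        [b.to_numpy() for b in bold], design, LABELS, motion=motion
    )
    for cond in bs.betas:
        assert bs.betas[cond].to_numpy() == pytest.approx(
            amps[cond].to_numpy(), abs=1e-6
        )


def _oracle_lss_beta(design, Y, motion, condition, trial):
    """Independent brute-force reference: build the two-task-column design
    from first principles and solve the normal equations."""
    nv = design.volumes_per_run
    grid = RegressorGrid(nv, design.tr)
    cols = []
    target = None
    evs = design.condition_trials(condition)
    others = np.zeros(nv)
    for j, ev in enumerate(evs):
        reg = grid.regressor(ev.guess_onset, ev.response_time or 8.0)
        if j == trial:
            target = reg
        else:
            others += reg
    cols = [target, others]
    for c in CONDITIONS:
        if c == condition:
            continue
        agg = np.zeros(nv)
        for ev in design.condition_trials(c):
            agg += grid.regressor(ev.guess_onset, ev.response_time or 8.0)
        cols.append(agg)
    fb = np.zeros(nv)
    for ev in design.trials:
        fb += grid.regressor(ev.feedback_onset, ev.feedback_duration)
    cols.append(fb)
    X = np.column_stack(cols + [legendre_basis(nv, 3), motion_nuisance(motion)])
    from scipy.linalg import solve

    beta = solve(X.T @ X, X.T @ Y, assume_a="sym")
    return beta[0]


def test_betas_match_normal_equations_oracle():
    """Overlapping single-run design: iterated lstsq == explicit normal
    equations, to 1e-8."""
    design = generate_design(
        n_runs=1, trials_per_run=8, volumes_per_run=120, seed=4
    )
    rng = np.random.default_rng(12)
    for ev in design.trials:
        ev.response_time = float(rng.uniform(1.0, 6.0))
    motion = [rng.normal(scale=0.05, size=(design.volumes_per_run, 6))]
    Y = rng.normal(size=(design.volumes_per_run, 3))
    bs = estimate_beta_series(
        [Y], design, ["a", "b", "c"], motion=motion,
        censor_masks=[np.zeros(design.volumes_per_run, bool)],
    )
    for cond in CONDITIONS:
        for t in range(2):
            oracle = _oracle_lss_beta(design, Y, motion[0], cond, t)
            assert bs.betas[cond].iloc[t].to_numpy() == pytest.approx(
                oracle, abs=1e-8
            )


def test_one_fit_per_trial():
    design = generate_design(n_runs=1, trials_per_run=8, volumes_per_run=120, seed=4)
    rng = np.random.default_rng(0)
    Y = rng.normal(size=(design.volumes_per_run, 2))
    bs = estimate_beta_series([Y], design, ["a", "b"])
    assert bs.diagnostics["n_fits"] == 8  # one GLM per trial


class TestLinearInvariants:
    @pytest.fixture(scope="class")
    def setup(self):
        design = generate_design(
            n_runs=1, trials_per_run=8, volumes_per_run=120, seed=9
        )
        rng = np.random.default_rng(3)
        motion = [rng.normal(scale=0.05, size=(design.volumes_per_run, 6))]
        Y = rng.normal(size=(design.volumes_per_run, 4))
        return design, motion, Y

    def _fit(self, design, motion, Y):
        return estimate_beta_series(
            [Y], design, list("wxyz"), motion=motion
        )

    def test_scale_equivariance(self, setup):
        design, motion, Y = setup
        b1 = self._fit(design, motion, Y)
        b2 = self._fit(design, motion, 3.5 * Y)
        for c in b1.betas:
            assert 3.5 * b1.betas[c].to_numpy() == pytest.approx(
                b2.betas[c].to_numpy(), abs=1e-8
            )

    def test_nuisance_invariance(self, setup):
        """Adding any combination of nuisance columns leaves betas unchanged."""
        design, motion, Y = setup
        model = LssModel(design, motion=motion)
        rng = np.random.default_rng(77)
        shift = model.nuisance @ rng.normal(size=model.nuisance.shape[1])
        b1 = self._fit(design, motion, Y)
        b2 = self._fit(design, motion, Y + shift[:, None])
        for c in b1.betas:
            assert b1.betas[c].to_numpy() == pytest.approx(
                b2.betas[c].to_numpy(), abs=1e-8
            )

    def test_roi_mean_equals_mean_of_voxel_betas(self, setup):
        """OLS linearity: beta of the mean series = mean of voxel betas."""
        design, motion, Y = setup
        b_vox = self._fit(design, motion, Y)
        mean_series = Y.mean(axis=1, keepdims=True)
        b_mean = estimate_beta_series([mean_series], design, ["m"], motion=motion)
        for c in b_vox.betas:
            assert b_vox.betas[c].to_numpy().mean(axis=1) == pytest.approx(
                b_mean.betas[c]["m"].to_numpy(), abs=1e-8
            )

    def test_lss_equals_lsa_when_orthogonal(self):
        """Wide spacing: LSS betas equal the all-trials-in-one-GLM solution."""
        design = _spaced_design(8, iti=40.0)
        rng = np.random.default_rng(21)
        nv = design.volumes_per_run
        Y = rng.normal(size=(nv, 2))
        # order-0 baseline: higher polynomials would re-couple the
        # orthogonal trial regressors through the shared smooth drift
        bs = estimate_beta_series([Y], design, ["a", "b"], poly_order=0)
        # LSA: one column per trial plus feedback and intercept
        grid = RegressorGrid(nv, design.tr)
        cols = [
            grid.regressor(ev.guess_onset, ev.response_time or 8.0)
            for ev in design.trials
        ]
        fb = np.zeros(nv)
        for ev in design.trials:
            fb += grid.regressor(ev.feedback_onset, ev.feedback_duration)
        X = np.column_stack(cols + [fb, np.ones(nv)])
        lsa = np.linalg.lstsq(X, Y, rcond=None)[0][: len(design.trials)]
        for i, ev in enumerate(design.trials):
            cond_trials = design.condition_trials(ev.condition)
            k = cond_trials.index(ev)
            # 1e-6: the two solvers take different factorization paths
            assert bs.betas[ev.condition].iloc[k].to_numpy() == pytest.approx(
                lsa[i], abs=1e-6
            )


def test_null_signal_betas_near_zero():
    """Pure nuisance data (drift + motion coupling, no task) -> betas ~ 0."""
    design = generate_design(seed=13)
    truth = replace(NOISELESS, amplitude_mean=0.0, amplitude_sd=0.0,
                    feedback_amplitude=0.0, noise_sd=0.1, drift_sd=0.3)
    rng = np.random.default_rng(31)
    motion = [np.zeros((design.volumes_per_run, 6))] * 4
    bold, _ = generate_bold(design, truth, motion, rng, LABELS, NETS)
    bs = estimate_beta_series(
        [b.to_numpy() for b in bold], design, LABELS, motion=motion
    )
    for c in bs.betas:
        b = bs.betas[c].to_numpy()
        se = b.std(ddof=1) / np.sqrt(b.size)
        assert abs(b.mean()) < 2 * max(se, 1e-12) + 0.01


def test_recovery_floor_at_default_noise():
    """Pinned regression floor: per-ROI planted-vs-estimated correlation,
    pooled over all 96 trials, stays above 0.40 for every seed."""
    worst = 1.0
    for seed in range(20):
        cohort = generate_cohort(2, GroundTruth(), seed=seed, mode="bold")
        tabs = cohort_tables(cohort)
        s = cohort.subjects[0]
        a = tabs["analyses"][s.profile.subject_id]
        if not a.included:
            continue
        est_all, true_all = [], []
        for cond, est in a.betas.betas.items():
            evs = s.design.condition_trials(cond)
            idx = [i for i, ev in enumerate(evs) if ev.run_index in a.retained_runs]
            est_all.append(est.to_numpy())
            true_all.append(s.true_amplitudes[cond].iloc[idx].to_numpy())
        E, T = np.vstack(est_all), np.vstack(true_all)
        rs = [np.corrcoef(T[:, j], E[:, j])[0, 1] for j in range(E.shape[1])]
        worst = min(worst, min(rs))
    assert worst > 0.40


def test_extract_roi_series_matches_brute_force():
    """5 mm sphere on a 2 mm grid: membership equals exhaustive check."""
    rng = np.random.default_rng(6)
    shape = (9, 9, 9, 5)
    data = rng.normal(size=shape)
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = [-8.0, -8.0, -8.0]
    spec = DEFAULT_ROIS[0].__class__("probe", "mentalizing", (0.0, 0.0, 0.0))
    series = extract_roi_series(data, affine, [spec])["probe"].to_numpy()
    picks = []
    for i in range(9):
        for j in range(9):
            for k in range(9):
                mm = affine @ np.array([i, j, k, 1.0])
                if (mm[:3] ** 2).sum() <= 25.0:
                    picks.append(data[i, j, k])
    assert len(picks) == 81  # 2 mm grid inside a 5 mm ball
    assert series == pytest.approx(np.mean(picks, axis=0), abs=1e-12)


def test_extract_roi_series_empty_sphere_names_roi():
    data = np.zeros((3, 3, 3, 2))
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    spec = DEFAULT_ROIS[0].__class__("far", "reward", (500.0, 0.0, 0.0))
    with pytest.raises(ValueError, match="far"):
        extract_roi_series(data, affine, [spec])
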