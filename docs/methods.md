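# Methods

`betaconn` implements a beta-series functional-connectivity analysis for
an event-related child fMRI task in which participants make predictions
about a live peer (Peer) or a story character (Character), crossed with
whether the prompt involves a mental state (Mental / Non-Mental).  The
package covers the full chain — task schedule, motion QC, trial-wise GLM
estimation, network connectivity, and group inference — together with a
synthetic-cohort generator that plants known effects so every stage can
be validated against ground truth.

## Task model

The design is 2 × 2 with four conditions (Peer Mental, Peer Non-Mental,
Character Mental, Character Non-Mental), 4 runs × 24 trials (6 per
condition per run, 96 trials in total).  A trial is an 8 s Guess period
(the response occurs inside it), a jittered fixation, a 2 s Feedback
period, and a jittered inter-trial fixation.  Runs open with 10 s and
close with 15 s of fixation.  Acquisition is TR = 1.25 s, 352 volumes
per run (440 s).

Jitters are drawn from a shifted exponential on [2, 6] s whose rate is
solved numerically so the truncated mean is 3.5 s.  Because the
acquisition length is fixed but the jitter draws are random, draws are
multiplicatively rescaled — then re-clipped to [2, 6] with the residual
spread over jitters that still have slack — so each run's schedule sums
to exactly 352 × 1.25 s (asserted to 1e-9 s).  A jittered fixation
follows every trial, including the last, ahead of the tail fixation;
with 48 jitters and a 175 s budget the realized mean jitter is 3.65 s.
Condition order is a uniformly random balanced permutation per run;
collinearity among the four condition regressors is checked post hoc
(warning at |r| ≥ 0.5; typical values at these defaults are ≈ 0.2).

## Motion QC

Framewise displacement is the sum of absolute backward differences of
the six rigid-body parameters, rotations converted to arc length on a
50 mm sphere (the conventional reference radius).  `fd[0] = 0`.
Volumes with FD > 1 mm are censored.  A run is dropped when fewer than
90% of volumes survive, when mean FD (computed over all volumes, before
censoring) exceeds 0.5 mm, when any condition's accuracy in the run is
below 50%, or when run accuracy is below 66.7%.  Subjects need at least
3 usable runs.  All triggered reasons are recorded, and exclusion is
monotone in censoring.  Rotations are assumed to be radians in input
files; a flag accepts degrees.

## Trial-wise GLM (least-squares-single)

Trial amplitudes are estimated with the LSS scheme: for each condition,
one GLM per trial (24 by default) whose design holds

* the target trial's regressor and one column aggregating the remaining
  same-condition trials;
* one aggregate Guess column per other condition and one column for all
  Feedback events;
* demeaned motion parameters and their backward-difference derivatives
  (first element 0, demeaned per run);
* one spike indicator per censored volume (censored frames are retained
  and absorbed rather than row-deleted);
* per-run Legendre polynomial baselines up to order 3 (a standard
  baseline complexity for ~440 s runs; configurable).

Task regressors are duration-modulated: a unit boxcar of length equal
to the trial's response time (8 s fallback when missing) convolved with
the canonical double-gamma HRF (peak shape 6, undershoot shape 16,
ratio 1/6, 32 s support, 0.05 s sampling grid), normalized by the
kernel integral so a sustained boxcar converges to amplitude 1.
Feedback uses a fixed 2 s boxcar.  Runs are concatenated with task
columns spanning runs and nuisance columns block-diagonal.  Solving is
least-squares with relative rank tolerance 1e-10; if the target column
is collinear with the rest of the design the trial's beta is set
missing with a warning (degenerate *nuisance* columns are harmless
under the minimum-norm solve and do not discard trials).

Two exactness properties anchor the implementation: when the model
spans the signal (noiseless, non-overlapping events, or equal
within-condition amplitudes) betas equal the generating amplitudes to
1e-6; on overlapping designs the iterated solver agrees with an
explicitly formed normal-equations solution to 1e-8.  With multiple
unequal same-condition trials, the aggregate column cannot represent
their amplitude differences, so even noiseless betas carry a small
leakage bias (order 1e-2 here) — an inherent property of LSS, not an
implementation artifact.  Because OLS is linear in the data, ROI-mode
estimation (averaging voxels first) is identical to averaging
voxel-wise betas; the package therefore works on ROI series by default
and supports voxel-mode NIfTI input as an option.

## Networks and connectivity

The default node set is 14 spherical ROIs of 5 mm radius at
meta-analytic MNI coordinates: 7 mentalizing-network nodes (dmPFC,
vmPFC, precuneus, bilateral TPJ, bilateral ATL) and 7 reward-network
nodes (L OFC, R vmPFC, ACC, bilateral ventral striatum, bilateral
amygdala), pairwise non-overlapping (center distance > 10 mm; overlap
is a warning so user-supplied sets can relax it).  Per condition, the
connectivity matrix is the Pearson correlation of ROI beta series
across trials.  Within-network connectivity is the mean of the
C(7,2) = 21 within pairs, between-network connectivity the mean of the
7 × 7 = 49 cross pairs (21 + 21 + 49 = C(14,2) = 91, a complete edge
partition).  Node strengths are each node's mean edge to same-network
and to other-network nodes.  Condition collapsing ("Peer",
"Character") is the equal-weight element-wise mean of the two
correlation matrices; raw r is averaged by default (connectivity is
reported in r units; a Fisher-z option exists but is off by default).

## Group inference

The central model is a linear mixed model with a single random
intercept per subject, REML-estimated, with mean connectivity (or RT,
accuracy, node strength) as outcome and fixed effects social,
mentalizing, age, social × age, plus gender, mean FD and IQ as
covariates of no interest (behaviour models omit mean FD).  Factors
are sum-coded (±0.5) and continuous covariates mean-centered, so each
single-df marginal Wald F is an average-effect test; interaction tests
are invariant to this coding.

Denominator degrees of freedom follow the grouping-level convention:
within-subject terms use `n_obs − n_subjects − p_within` and
subject-level terms `n_subjects − p_between − 1`.  With 50 subjects ×
4 conditions and three within-subject terms this yields F(1, 147) for
within terms and F(1, 45) for subject-level terms.  Two engines
produce the same numbers on balanced data: `mixedlm` (statsmodels
REML) and `split`, the closed-form within/between decomposition (OLS
on subject-demeaned data for within terms, OLS on subject means for
between terms), which is exactly REML when every subject contributes a
complete within-subject design and the variance estimate is interior.
The split engine is used for large simulation loops; their equivalence
is asserted in the test suite.  Singular mixed fits fall back to OLS
with a convergence flag.

Post-hoc analyses mirror the model battery: paired t on Peer vs
Character subject means, per-condition OLS age regressions (covariates
gender, mean FD, IQ), brain–behaviour models with social × RT (or
subjective-report) interactions on condition-collapsed connectivity,
per-condition partial correlations controlling age, Wilcoxon
signed-rank tests for the ordinal reports, one-tailed Spearman
correlations, and Benjamini–Hochberg FDR.  FDR families: the 28
node × strength interaction tests; the subjective-report effects
across 6 measures; and the three network-level models.  The Wilcoxon
statistic drops zero differences, average-ranks ties, and uses an
exact null distribution (rank-sum DP over doubled ranks, valid under
ties) for n ≤ 25, else a tie-corrected normal approximation with 0.5
continuity correction.  The age-quartile follow-up recomputes
empirical 25th/75th percentiles (linear interpolation) with strict
membership and runs two-tailed paired t-tests per group; the
motion-matched subsample utility greedily removes subjects until
|corr(age, mean FD)| < 0.05 or a target n (default 30) is reached.

## Synthetic cohort and what it does (not) emulate

Trial amplitudes per condition are multivariate normal over the 14
ROIs with unit mean and SD.  The correlation structure is
within-network 0.25 and between-network 0.10, chosen to reproduce the
qualitative ordering (within > between) that the within-vs-between
tests probe.  The Peer-minus-Character correlation difference grows
with age at `age_coupling` = 0.04 r/year (split symmetrically ±Δ/2
around the baseline and eigenvalue-clipped back to a valid correlation
matrix), and, in the Peer conditions only, tracks the subject's
age-independent RT deviation at `rt_conn_coupling` = −0.05 r/s —
magnitudes consistent with interaction effects detectable in a
50-child cohort without being unrealistically large.

Behaviour: RT = 2.04 s at the age midpoint, −0.10 s/year of age,
−0.08 s for Peer trials, between-subject SD 0.25 s, trial noise SD
0.45 s truncated to (0.2, 8] s; accuracy is Bernoulli at 90.17% with a
+0.025/year Character-specific slope.  Reports come from a latent
normal per measure and social level (locations/SDs set to the
questionnaire summary values; Perceived Difficulty is unshifted),
rounded and clipped to 1–5.  Ages are uniform on [8.18, 12.97] years;
gender is Bernoulli(0.6 male); IQ ~ N(100, 15).

BOLD = Σ amplitude × duration-modulated regressor + 0.5 × Feedback
response + Legendre drift (orders 1–3, coefficient SD 0.3) + AR(1)
noise (φ = 0.3, stationary SD 0.35 — voxel-scale noise of ~1 amplitude
unit averaged over the ≈ 8 voxels of a 5 mm sphere on a 2 mm grid) +
0.2 × FD-coupled component.  Motion is a random-walk drift plus white
jitter plus 1.2 mm spikes at probability 0.01/volume, which censors a
few percent of frames while leaving most runs usable.

A `beta` cohort mode skips BOLD synthesis and emits the amplitude
draws directly as beta series — the noiseless-recovery limit of the
pipeline — and is used for the 500-replicate null calibration of the
social × age test (rejection rate 0.05 ± 0.02 at α = 0.05) and the
50-replicate sign-recovery checks, at the cohort size the inference is
designed for (50 subjects).  At full-pipeline defaults, per-ROI
planted-vs-estimated amplitude correlation (pooled over 96 trials) was
calibrated once over 20 seeds (worst 0.445, median ≈ 0.76) and pinned
at a 0.40 floor as a regression test.

The generator does **not** emulate: anatomical images or spatial
preprocessing, slice timing, susceptibility distortion, physiological
noise structure beyond AR(1), non-Gaussian amplitude distributions,
learning/fatigue trends in behaviour, or the psychology of the peer
illusion.  Passing tests therefore demonstrate correctness of the
estimation and inference machinery under a plausible generative model,
not robustness to every property of real paediatric fMRI.

## Numerical choices and limitations

* Regressor grid 0.05 s; onsets rounded to the grid (≤ 25 ms error).
* Rank tolerance 1e-10 (relative) in all least-squares solves;
  pseudo-inverse covariance so degenerate covariates flag rather than
  crash.
* Exact Wilcoxon enumeration capped at n = 25 (DP size ≤ n(n+1)+1).
* The accuracy outcome is modelled as a per-cell proportion in a
  linear mixed model, not logistic regression.
* No AR-prewhitened GLS (the trial GLM is OLS), no
  Satterthwaite/Kenward–Roger df, no ordinal cumulative-link models
  for the reports, no graph metrics beyond mean strength.
* Alternative node sets (salience / mirror / motor) are supported as
  user-editable YAML; the shipped example file contains clearly
  labelled synthetic placeholder coordinates only.
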