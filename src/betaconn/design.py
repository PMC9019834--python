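"""Event-related task schedule generation.

The task is a 2 x 2 event-related design crossing social interaction
(Peer vs. Character) with mentalizing content (Mental vs. Non-Mental).
Each trial is a Guess period (nominally 8 s, during which the child
responds) followed, after a jittered fixation, by a 2 s Feedback period.
Runs open with a 10 s fixation and close with a 15 s fixation, and every
inter-event fixation is drawn from a shifted truncated exponential on
[2, 6] s with mean 3.5 s.  After drawing, jitters are rescaled so that
each run's schedule exactly fills the acquisition window
(``volumes_per_run * tr`` seconds).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CONDITIONS",
    "ConditionLabel",
    "TrialEvent",
    "TaskDesign",
    "SchedulingError",
    "generate_design",
    "design_from_trials",
    "truncated_exp_rate",
]

#: canonical condition names, in (social, mentalizing) factor order
CONDITIONS = (
    "Peer Mental",
    "Peer Non-Mental",
    "Character Mental",
    "Character Non-Mental",
)


class SchedulingError(ValueError):
    """Raised when the requested trial content cannot fit in the run."""


@dataclass(frozen=True)
class ConditionLabel:
    """One cell of the 2 x 2 design."""

    social: str  # "Peer" or "Character"
    mentalizing: str  # "Mental" or "Non-Mental"

    def __post_init__(self) -> None:
        if self.social not in ("Peer", "Character"):
            raise ValueError(f"unknown social level {self.social!r}")
        if self.mentalizing not in ("Mental", "Non-Mental"):
            raise ValueError(f"unknown mentalizing level {self.mentalizing!r}")

    @property
    def name(self) -> str:
        return f"{self.social} {self.mentalizing}"

    @classmethod
    def from_name(cls, name: str) -> "ConditionLabel":
        social, _, ment = name.partition(" ")
        return cls(social, ment)


@dataclass
class TrialEvent:
    """One trial: Guess period, mid jitter, Feedback period, ITI jitter."""

    run_index: int  # 1-based
    trial_index: int  # 1-based within run
    condition: str  # one of CONDITIONS
    guess_onset: float
    guess_duration: float = 8.0
    response_time: float | None = None
    mid_jitter: float = 3.5
    feedback_duration: float = 2.0
    iti_jitter: float = 3.5

    @property
    def feedback_onset(self) -> float:
        return self.guess_onset + self.guess_duration + self.mid_jitter

    @property
    def end(self) -> float:
        """Time at which the post-feedback ITI fixation finishes."""
        return self.feedback_onset + self.feedback_duration + self.iti_jitter

    @property
    def label(self) -> ConditionLabel:
        return ConditionLabel.from_name(self.condition)


@dataclass
class TaskDesign:
    trials: list[TrialEvent]
    tr: float = 1.25
    run_head_fixation: float = 10.0
    run_tail_fixation: float = 15.0
    volumes_per_run: int = 352
    n_runs: int = 4

    @property
    def run_duration(self) -> float:
        return self.volumes_per_run * self.tr

    @property
    def trials_per_run(self) -> int:
        return len(self.trials) // self.n_runs

    def run_trials(self, run_index: int) -> list[TrialEvent]:
        return [t for t in self.trials if t.run_index == run_index]

    def condition_trials(self, condition: str) -> list[TrialEvent]:
        return [t for t in self.trials if t.condition == condition]

    def validate(self) -> None:
        """Check schedule conservation, ordering and jitter bounds."""
        for r in range(1, self.n_runs + 1):
            trials = self.run_trials(r)
            if not trials:
                raise SchedulingError(f"run {r} has no trials")
            t = self.run_head_fixation
            for ev in trials:
                if not np.isclose(ev.guess_onset, t, atol=1e-9):
                    raise SchedulingError(
                        f"run {r}: trial {ev.trial_index} onset {ev.guess_onset} != {t}"
                    )
                t = ev.end
            total = t + self.run_tail_fixation
            if abs(total - self.run_duration) > 1e-9:
                raise SchedulingError(
                    f"run {r}: schedule sums to {total:.6f} s, "
                    f"expected {self.run_duration:.6f} s"
                )


@lru_cache(maxsize=None)
def truncated_exp_rate(span: float = 4.0, target_mean: float = 1.5) -> float:
    """Rate of an exponential truncated to [0, span] with the given mean.

    Solved numerically: the truncated mean is
    ``1/lam - span * exp(-span*lam) / (1 - exp(-span*lam))``.
    """
    if not 0 < target_mean < span / 2 * 2:
        raise ValueError("target mean must lie in (0, span)")

    def f(lam: float) -> float:
        e = np.exp(-span * lam)
        return 1.0 / lam - span * e / (1.0 - e) - target_mean

    return float(brentq(f, 1e-8, 50.0, xtol=1e-12))


def sample_jitters(
    n: int,
    rng: np.random.Generator,
    lo: float = 2.0,
    hi: float = 6.0,
    mean: float = 3.5,
) -> np.ndarray:
    """Draw n jitters from a shifted truncated exponential on [lo, hi]."""
    span = hi - lo
    lam = truncated_exp_rate(span, mean - lo)
    u = rng.random(n)
    # inverse CDF of exponential truncated to [0, span]
    x = -np.log1p(-u * (1.0 - np.exp(-span * lam))) / lam
    return lo + x


def _fill_budget(
    jitters: np.ndarray, total: float, lo: float = 2.0, hi: float = 6.0
) -> np.ndarray:
    """Rescale jitters so they sum exactly to `total` while staying in [lo, hi].

    Multiplicative rescale first; any clipping residual is spread over the
    jitters that still have slack (largest slack absorbs the final epsilon).
    """
    n = len(jitters)
    if not (n * lo - 1e-12 <= total <= n * hi + 1e-12):
        raise SchedulingError(
            f"jitter budget {total:.3f} s infeasible for {n} jitters in [{lo},{hi}]"
        )
    j = np.asarray(jitters, dtype=float).copy()
    j *= total / j.sum()
    j = np.clip(j, lo, hi)
    for _ in range(200):
        resid = total - j.sum()
        if abs(resid) < 1e-12:
            break
        room = (hi - j) if resid > 0 else (j - lo)
        movable = room > 1e-12
        if not movable.any():  # pragma: no cover - guarded by feasibility check
            raise SchedulingError("cannot absorb jitter residual")
        step = resid / movable.sum()
        j[movable] += step
        j = np.clip(j, lo, hi)
    # final exact correction on the jitter with the most slack
    resid = total - j.sum()
    k = int(np.argmax((hi - j) if resid > 0 else (j - lo)))
    j[k] += resid
    return j


def generate_design(
    n_runs: int = 4,
    trials_per_run: int = 24,
    tr: float = 1.25,
    seed: int | np.random.Generator | None = 0,
    volumes_per_run: int = 352,
    run_head_fixation: float = 10.0,
    run_tail_fixation: float = 15.0,
    guess_duration: float = 8.0,
    feedback_duration: float = 2.0,
    jitter_lo: float = 2.0,
    jitter_hi: float = 6.0,
    jitter_mean: float = 3.5,
) -> TaskDesign:
    """Generate a balanced, exactly-scheduled task design.

    Each run contains ``trials_per_run / 4`` trials of each condition in a
    uniformly random order, and the jittered fixations are rescaled so the
    run occupies exactly ``volumes_per_run * tr`` seconds.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if trials_per_run % len(CONDITIONS) != 0:
        raise ValueError(
            f"trials_per_run must be divisible by {len(CONDITIONS)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    run_seconds = volumes_per_run * tr
    content = (
        run_head_fixation
        + trials_per_run * (guess_duration + feedback_duration)
        + run_tail_fixation
    )
    budget = run_seconds - content  # total jitter time per run
    n_jit = 2 * trials_per_run  # mid + ITI jitter per trial
    if budget < n_jit * jitter_lo - 1e-12:
        raise SchedulingError(
            f"trial content ({content:.1f} s + minimum jitter) exceeds the "
            f"{run_seconds:.1f} s run"
        )

    per_cond = trials_per_run // len(CONDITIONS)
    trials: list[TrialEvent] = []
    for r in range(1, n_runs + 1):
        order = np.array(sum(([c] * per_cond for c in CONDITIONS), []))
        order = order[rng.permutation(trials_per_run)]
        raw = sample_jitters(n_jit, rng, jitter_lo, jitter_hi, jitter_mean)
        jit = _fill_budget(raw, budget, jitter_lo, jitter_hi)
        t = run_head_fixation
        for i, cond in enumerate(order):
            mid, iti = jit[2 * i], jit[2 * i + 1]
            ev = TrialEvent(
                run_index=r,
                trial_index=i + 1,
                condition=str(cond),
                guess_onset=t,
                guess_duration=guess_duration,
                mid_jitter=float(mid),
                feedback_duration=feedback_duration,
                iti_jitter=float(iti),
            )
            trials.append(ev)
            t = ev.end

    design = TaskDesign(
        trials=trials,
        tr=tr,
        run_head_fixation=run_head_fixation,
        run_tail_fixation=run_tail_fixation,
        volumes_per_run=volumes_per_run,
        n_runs=n_runs,
    )
    design.validate()
    return design


def design_from_trials(
    trials: Sequence[TrialEvent],
    tr: float = 1.25,
    volumes_per_run: int | None = None,
    n_runs: int | None = None,
    run_head_fixation: float = 10.0,
    run_tail_fixation: float = 15.0,
) -> TaskDesign:
    """Build a TaskDesign from explicit trial events (no schedule rescaling).

    Intended for hand-built designs (e.g. widely spaced trials for
    validation).  ``volumes_per_run`` defaults to the smallest volume count
    covering the last event plus the tail fixation.
    """
    trials = list(trials)
    if n_runs is None:
        n_runs = max(t.run_index for t in trials)
    if volumes_per_run is None:
        last = max(t.end for t in trials)
        volumes_per_run = int(np.ceil((last + run_tail_fixation) / tr))
    return TaskDesign(
        trials=trials,
        tr=tr,
        run_head_fixation=run_head_fixation,
        run_tail_fixation=run_tail_fixation,
        volumes_per_run=volumes_per_run,
        n_runs=n_runs,
    )
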