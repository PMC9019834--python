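"""Canonical haemodynamic response model and duration-modulated regressors.

Trial regressors follow the duration-modulated convention: a unit-height
boxcar whose length tracks the event (the child's response time for Guess
events, a fixed 2 s for Feedback) convolved with the canonical
double-gamma HRF, then normalized so a long plateau saturates at 1.  The
trial's GLM coefficient is therefore an amplitude in BOLD units,
comparable across trials of different duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HrfModel", "build_hrf", "make_trial_regressor", "RegressorGrid"]


@dataclass(frozen=True)
class HrfModel:
    """Double-gamma canonical HRF (SPM-style parameterization).

    h(t) ~ pdf_gamma(t; peak_shape, 1/peak_scale)
           - undershoot_ratio * pdf_gamma(t; undershoot_shape, 1/undershoot_scale)
    """

    peak_shape: float = 6.0
    peak_scale: float = 1.0
    undershoot_shape: float = 16.0
    undershoot_scale: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0  # kernel support, s
    dt: float = 0.05  # sampling step, s

    def __post_init__(self) -> None:
        if min(self.peak_shape, self.peak_scale, self.undershoot_shape,
               self.undershoot_scale) <= 0:
            raise ValueError("HRF shape parameters must be positive")
        if self.duration < 30.0:
            raise ValueError("HRF kernel must span at least 30 s")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def build_hrf(model: HrfModel = HrfModel()) -> np.ndarray:
    """Sample the double-gamma kernel at ``model.dt`` on [0, duration]."""
    from scipy.stats import gamma

    t = np.arange(0.0, model.duration + model.dt / 2, model.dt)
    peak = gamma.pdf(t, model.peak_shape, scale=model.peak_scale)
    under = gamma.pdf(t, model.undershoot_shape, scale=model.undershoot_scale)
    h = peak - model.undershoot_ratio * under
    integral = h.sum() * model.dt
    if integral <= 0:
        raise ValueError("HRF kernel must integrate to a positive value")
    return h


class RegressorGrid:
    """Fine-grid convolution workspace for one run.

    Events are laid down as boxcars on a grid of step ``hrf.dt``, convolved
    with the canonical kernel once, and sampled at volume acquisition
    times.  The plateau normalization divides by the kernel integral so an
    arbitrarily long boxcar converges to 1.
    """

    def __init__(self, n_volumes: int, tr: float, hrf: HrfModel = HrfModel()):
        if hrf.dt > tr:
            raise ValueError("HRF dt must not exceed the TR")
        self.n_volumes = int(n_volumes)
        self.tr = float(tr)
        self.hrf = hrf
        self.kernel = build_hrf(hrf)
        self.plateau = self.kernel.sum() * hrf.dt
        run_seconds = n_volumes * tr
        self.n_fine = int(np.ceil(run_seconds / hrf.dt)) + 1
        # indices of volume acquisition times on the fine grid
        vol_t = np.arange(n_volumes) * tr
        self.vol_idx = np.round(vol_t / hrf.dt).astype(int)

    def regressor(self, onset: float, duration: float) -> np.ndarray:
        """Duration-modulated response sampled at the run's volume times."""
        if duration <= 0:
            raise ValueError("event duration must be positive")
        if onset < 0 or onset >= self.n_volumes * self.tr:
            raise ValueError("event onset outside the run")
        dt = self.hrf.dt
        box = np.zeros(self.n_fine)
        i0 = int(round(onset / dt))
        i1 = min(int(round((onset + duration) / dt)), self.n_fine)
        if i1 <= i0:
            i1 = i0 + 1
        box[i0:i1] = 1.0
        conv = np.convolve(box, self.kernel)[: self.n_fine] * dt / self.plateau
        return conv[self.vol_idx]


def make_trial_regressor(
    onset: float,
    duration: float,
    n_volumes: int,
    tr: float,
    hrf: HrfModel = HrfModel(),
) -> np.ndarray:
    """One-off convenience wrapper around :class:`RegressorGrid`."""
    return RegressorGrid(n_volumes, tr, hrf).regressor(onset, duration)
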