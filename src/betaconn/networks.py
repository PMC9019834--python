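"""ROI node sets and beta-series network connectivity summaries.

The default node set is 14 spherical ROIs (5 mm radius): seven
mentalizing-network nodes (dmPFC, vmPFC, precuneus, bilateral TPJ,
bilateral ATL) and seven reward-network nodes (left OFC, right vmPFC,
ACC, bilateral ventral striatum, bilateral amygdala), placed at
meta-analytic MNI coordinates.  Connectivity is the Pearson correlation
of trial-wise beta series; network summaries are plain means over the
C(n,2) within-network pairs and the n_A x n_B between-network pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "RoiSpec",
    "ConnectivityMatrix",
    "NetworkSummary",
    "DEFAULT_ROIS",
    "check_non_overlap",
    "beta_corr_matrix",
    "within_network_mean",
    "between_network_mean",
    "node_strengths",
    "network_summary",
    "collapse_conditions",
    "fisher_z",
]


@dataclass(frozen=True)
class RoiSpec:
    name: str
    network: str
    mni_xyz: tuple[float, float, float]
    radius: float = 5.0


#: 14-node mentalizing + reward default node set (meta-analytic MNI mm).
DEFAULT_ROIS: tuple[RoiSpec, ...] = (
    RoiSpec("dmPFC", "mentalizing", (0, 53, 30)),
    RoiSpec("vmPFC", "mentalizing", (0, 48, -18)),
    RoiSpec("PC", "mentalizing", (0, -54, 44)),
    RoiSpec("L TPJ", "mentalizing", (-48, -56, 23)),
    RoiSpec("R TPJ", "mentalizing", (48, -56, 23)),
    RoiSpec("L ATL", "mentalizing", (-53, -12, -16)),
    RoiSpec("R ATL", "mentalizing", (53, -12, -16)),
    RoiSpec("L OFC", "reward", (-22, 36, -14)),
    RoiSpec("R vmPFC", "reward", (2, 58, -8)),
    RoiSpec("ACC", "reward", (2, 32, 16)),
    RoiSpec("L VS", "reward", (-12, 10, -8)),
    RoiSpec("R VS", "reward", (12, 10, -8)),
    RoiSpec("L Amygdala", "reward", (-20, -2, -14)),
    RoiSpec("R Amygdala", "reward", (24, -2, -18)),
)


def check_non_overlap(rois: tuple[RoiSpec, ...] | list[RoiSpec], warn: bool = True) -> bool:
    """Spheres must be pairwise non-overlapping (center distance > 2*radius)."""
    ok = True
    for a, b in combinations(rois, 2):
        d = float(np.linalg.norm(np.subtract(a.mni_xyz, b.mni_xyz)))
        if d <= a.radius + b.radius:
            ok = False
            if warn:
                warnings.warn(
                    f"ROI spheres overlap: {a.name} and {b.name} "
                    f"(center distance {d:.1f} mm)",
                    stacklevel=2,
                )
    return ok


@dataclass
class ConnectivityMatrix:
    r: pd.DataFrame  # ROI x ROI Pearson correlations, unit diagonal
    n_trials: int
    condition: str | None = None

    @property
    def labels(self) -> list[str]:
        return list(self.r.columns)


@dataclass
class NetworkSummary:
    within_mean: dict[str, float]
    between_mean: dict[tuple[str, str], float]
    node_within: dict[str, float]
    node_between: dict[str, float]


def beta_corr_matrix(beta: pd.DataFrame, condition: str | None = None) -> ConnectivityMatrix:
    """Pearson correlation of ROI beta series across trials.

    ``beta`` has one row per trial and one column per ROI.
    """
    n = len(beta)
    if n < 3:
        raise ValueError(f"need at least 3 trials to correlate (got {n})")
    vals = beta.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    if (sd == 0).any():
        bad = [c for c, s in zip(beta.columns, sd) if s == 0]
        raise ValueError(f"constant beta series for ROI(s): {', '.join(map(str, bad))}")
    r = np.corrcoef(vals, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(
        r=pd.DataFrame(r, index=beta.columns, columns=beta.columns),
        n_trials=n,
        condition=condition,
    )


def _members(rois, network: str) -> list[str]:
    names = [s.name for s in rois if s.network == network]
    if not names:
        raise KeyError(f"unknown network label {network!r}")
    return names


def within_network_mean(C: ConnectivityMatrix, rois, network: str) -> float:
    """Mean over the C(n,2) unordered within-network pairs."""
    names = _members(rois, network)
    if len(names) < 2:
        raise ValueError(f"network {network!r} has fewer than 2 nodes")
    sub = C.r.loc[names, names].to_numpy()
    iu = np.triu_indices(len(names), k=1)
    return float(sub[iu].mean())


def between_network_mean(C: ConnectivityMatrix, rois, net_a: str, net_b: str) -> float:
    """Mean over the n_A x n_B cross-network pairs."""
    if net_a == net_b:
        raise ValueError("between-network mean requires two distinct networks")
    a = _members(rois, net_a)
    b = _members(rois, net_b)
    return float(C.r.loc[a, b].to_numpy().mean())


def node_strengths(C: ConnectivityMatrix, rois) -> pd.DataFrame:
    """Per-node within- and between-network mean edge strength."""
    networks = sorted({s.network for s in rois})
    if len(networks) != 2:
        raise ValueError("node strengths defined for a two-network node set")
    rows = []
    for spec in rois:
        same = [s.name for s in rois if s.network == spec.network and s.name != spec.name]
        other = [s.name for s in rois if s.network != spec.network]
        if not same:
            raise ValueError(f"network {spec.network!r} is a singleton")
        rows.append(
            {
                "roi": spec.name,
                "network": spec.network,
                "within_strength": float(C.r.loc[spec.name, same].mean()),
                "between_strength": float(C.r.loc[spec.name, other].mean()),
            }
        )
    return pd.DataFrame(rows)


def network_summary(C: ConnectivityMatrix, rois) -> NetworkSummary:
    networks = sorted({s.network for s in rois})
    within = {n: within_network_mean(C, rois, n) for n in networks}
    between = {
        (a, b): between_network_mean(C, rois, a, b)
        for a, b in combinations(networks, 2)
    }
    ns = node_strengths(C, rois)
    return NetworkSummary(
        within_mean=within,
        between_mean=between,
        node_within=dict(zip(ns["roi"], ns["within_strength"])),
        node_between=dict(zip(ns["roi"], ns["between_strength"])),
    )


def collapse_conditions(
    matrices: list[ConnectivityMatrix], label: str | None = None
) -> ConnectivityMatrix:
    """Element-wise mean of correlation matrices (equal weight, raw r)."""
    if not matrices:
        raise ValueError("no matrices to collapse")
    cols = list(matrices[0].r.columns)
    for m in matrices[1:]:
        if list(m.r.columns) != cols:
            raise ValueError("mismatched node sets across matrices")
    mean_r = sum(m.r.to_numpy() for m in matrices) / len(matrices)
    return ConnectivityMatrix(
        r=pd.DataFrame(mean_r, index=cols, columns=cols),
        n_trials=min(m.n_trials for m in matrices),
        condition=label,
    )


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform (offered as an option; raw r is the default)."""
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
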