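"""Run configuration: thresholds, node sets, simulation truth, seeds.

All QC thresholds default to the values the pipeline is built around
(censor FD > 1 mm; drop runs with mean FD > 0.5 mm or < 90% volumes
remaining or any condition accuracy < 50% or run accuracy < 66.7%; keep
subjects with >= 3 usable runs).  Configs round-trip losslessly through
YAML or JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import GroundTruth
from .networks import DEFAULT_ROIS, RoiSpec, check_non_overlap
from .qc import QCThresholds

__all__ = ["RunConfig", "load_config", "dump_config", "load_node_set"]


@dataclass
class RunConfig:
    n_subjects: int = 50
    seed: int = 0
    mode: str = "bold"  # "bold" or "beta"
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    truth: GroundTruth = field(default_factory=GroundTruth)
    rois: tuple[RoiSpec, ...] = DEFAULT_ROIS
    poly_order: int = 3
    head_radius: float = 50.0
    fisher_z: bool = False

    def validate(self) -> None:
        t = self.thresholds
        if not (0 < t.min_volumes_frac <= 1 and 0 <= t.min_condition_acc <= 1
                and 0 <= t.min_run_acc <= 1):
            raise ValueError("QC threshold fractions must lie in [0, 1]")
        if t.fd_censor <= 0 or t.fd_mean_max <= 0:
            raise ValueError("FD thresholds must be positive")
        if not 1 <= t.min_usable_runs <= 4:
            raise ValueError("min_usable_runs must be in 1..4")
        if self.mode not in ("bold", "beta"):
            raise ValueError("mode must be 'bold' or 'beta'")
        check_non_overlap(self.rois)


def _to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["rois"] = [
        {"name": s.name, "network": s.network, "x": s.mni_xyz[0],
         "y": s.mni_xyz[1], "z": s.mni_xyz[2], "radius": s.radius}
        for s in cfg.rois
    ]
    return d


def _roi_from_dict(r: dict) -> RoiSpec:
    return RoiSpec(
        name=r["name"], network=r["network"],
        mni_xyz=(float(r["x"]), float(r["y"]), float(r["z"])),
        radius=float(r.get("radius", 5.0)),
    )


def _from_dict(d: dict) -> RunConfig:
    kwargs = dict(d)
    if "thresholds" in kwargs:
        kwargs["thresholds"] = QCThresholds(**kwargs["thresholds"])
    if "truth" in kwargs:
        t = dict(kwargs["truth"])
        if "age_range" in t:
            t["age_range"] = tuple(t["age_range"])
        if "reports" in t:
            t["reports"] = {
                k: (tuple(v[0]), tuple(v[1])) for k, v in t["reports"].items()
            }
        kwargs["truth"] = GroundTruth(**t)
    if "rois" in kwargs:
        kwargs["rois"] = tuple(_roi_from_dict(r) for r in kwargs["rois"])
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path: Path) -> None:
    path = Path(path)
    d = _to_dict(cfg)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=1))


def load_config(path: Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    cfg = _from_dict(d)
    cfg.validate()
    return cfg


def load_node_set(path: Path) -> tuple[RoiSpec, ...]:
    """Read a node-set file: a YAML/JSON list of name/network/x/y/z/radius."""
    path = Path(path)
    d = yaml.safe_load(path.read_text())
    rois = tuple(_roi_from_dict(r) for r in d)
    check_non_overlap(rois)
    return rois
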