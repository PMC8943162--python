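"""Run configuration: a single serializable record of every analysis knob."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .trajectory import SegmentDef


@dataclass
class RunConfig:
    """Everything a run needs, echoed verbatim into its output directory."""

    topology: str = ""
    trajectories: list[str] = field(default_factory=list)
    runs: dict[str, list[str]] = field(default_factory=dict)
    segments: list[dict] = field(default_factory=list)
    fit_segment: dict | None = None
    monomers: list[str] = field(default_factory=list)
    # mutual information
    eigenvalue_floor: float = 1e-8
    stride: int | None = None
    clip_negative: bool = True
    null_permutations: int = 0
    seed: int = 0
    # pocket
    pocket_cutoff: float = 11.0
    pocket_window_ns: float = 2.0
    pocket_residues: tuple[int, int] = (610, 667)
    # pore
    pore_axis: list[float] | None = None
    pore_z_step: float = 0.5
    pore_max_probe: float = 10.0
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.pocket_residues, list):
            cfg.pocket_residues = tuple(cfg.pocket_residues)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True))

    def segment_defs(self) -> list[SegmentDef]:
        return [SegmentDef(s["name"], s["chain_id"],
                           int(s["first_residue"]), int(s["last_residue"]))
                for s in self.segments]

    def fit_segment_def(self) -> SegmentDef | None:
        if self.fit_segment is None:
            return None
        s = self.fit_segment
        return SegmentDef(s["name"], s["chain_id"],
                          int(s["first_residue"]), int(s["last_residue"]))

    def config_hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
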