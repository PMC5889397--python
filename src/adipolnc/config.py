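"""Run configuration: every analysis threshold plus the simulation knobs.

Serialises losslessly to/from YAML; unknown keys are rejected so a typo in
a config file cannot silently fall back to a default.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synthetic import SimulationConfig, config_from_dict, config_to_dict


@dataclass
class AnalysisConfig:
    """All tunable thresholds of the pipeline with their study defaults."""

    min_coverage: float = 3.0
    min_length: int = 200
    min_exons: int = 2
    lnc_detect: float = 0.1
    mrna_detect: float = 1.0
    specificity_threshold: float = 0.1
    sweep_start: float = 0.1
    sweep_stop: float = 0.5
    sweep_step: float = 0.05
    window_bp: int = 500_000
    min_fold: float = 1.5
    min_shared_synteny: int = 2
    r_min_pairs: float = 0.3
    r_min_guilt: float = 0.7
    min_set_overlap: int = 3
    seed: int = 1
    outdir: str = "adipolnc_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = config_from_dict(self.simulation)
        # one seed drives everything, including the generator
        self.simulation.seed = self.seed

    @property
    def sweep_thresholds(self) -> list[float]:
        out = []
        t = self.sweep_start
        while t <= self.sweep_stop + 1e-9:
            out.append(round(t, 6))
            t += self.sweep_step
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = config_to_dict(self.simulation)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
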