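"""Declarative run configuration.

A single YAML file carries every tunable of a run -- migration model,
ladder composition, noise model, kinetic ground truth, integration and
qualification thresholds -- so that a run is reproducible from
(config, seed) alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .synthetic import KineticTruth, LadderSpec, MigrationModel, NoiseModel, SampleScenario


@dataclass
class StudyDesign:
    """Stability-study layout: temperatures (deg C) and pull timepoints (days)."""

    start_integrity: float = 80.0
    temperatures: tuple = (-20.0, 4.0, 25.0, 37.0, 45.0, 60.0)
    timepoints: tuple = (0.0, 4.0, 7.0, 14.0, 30.0, 60.0, 90.0)


@dataclass
class IntegrationSettings:
    marker_window: tuple = (15.0, 22.0)
    marker_halfwidth: float = 1.0
    snr_floor: float = 3.0


@dataclass
class QualificationSettings:
    lod_snr: float = 3.0
    loq_snr: float = 10.0
    linearity_concs: tuple = (2.5, 5.0, 7.5, 10.0, 12.5, 15.0)
    dilution_concs: tuple = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.5, 5.0, 10.0, 15.0)
    n_blanks: int = 3
    n_suitability: int = 6
    recovery_purity_high: float = 71.7
    recovery_purity_low: float = 22.9
    recovery_mix_fraction: float = 0.5


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulate/analyze/qualify/kinetics run."""

    seed: int = 0
    migration: MigrationModel = field(default_factory=MigrationModel)
    ladder: LadderSpec = field(default_factory=LadderSpec)
    noise: NoiseModel = field(default_factory=NoiseModel)
    kinetic_truth: KineticTruth = field(default_factory=KineticTruth)
    scenario: SampleScenario = field(default_factory=SampleScenario)
    study: StudyDesign = field(default_factory=StudyDesign)
    integration: IntegrationSettings = field(default_factory=IntegrationSettings)
    qualification: QualificationSettings = field(default_factory=QualificationSettings)

    def with_seed(self, seed: int | None) -> "RunConfig":
        return self if seed is None else replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def demo(cls) -> "RunConfig":
        """The packaged end-to-end demonstration configuration."""
        return cls()

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sections = {
            "migration": MigrationModel,
            "ladder": LadderSpec,
            "noise": NoiseModel,
            "kinetic_truth": KineticTruth,
            "scenario": SampleScenario,
            "study": StudyDesign,
            "integration": IntegrationSettings,
            "qualification": QualificationSettings,
        }
        kwargs: dict = {}
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        for key, typ in sections.items():
            if key in raw and raw[key] is not None:
                section = dict(raw[key])
                valid = {f.name for f in fields(typ)}
                unknown = set(section) - valid
                if unknown:
                    raise ValueError(f"unknown key(s) {sorted(unknown)} in '{key}'")
                for name, val in list(section.items()):
                    if isinstance(val, list):
                        section[name] = tuple(val)
                kwargs[key] = typ(**section)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )
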