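"""Structured run configuration with strict validation.

Configurations are plain mappings (usually loaded from YAML); unknown keys
are rejected up front so a typo cannot silently disable a stage. All
validation happens before any file is written.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .simulate import DOWNSAMPLE, XREPLACE


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


def _from_mapping(cls, data: Mapping[str, Any], context: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{context}: unknown key(s) {sorted(unknown)}; allowed: {sorted(names)}")
    return cls(**data)


@dataclass
class CallerDecl:
    """One caller's output table and how to read it."""

    name: str
    path: str
    score_column: str
    coords: str = "0-based"
    higher_is_better: bool = True
    chrom_col: str = "chrom"
    start_col: str = "start"
    end_col: str = "end"
    sample_col: str = "sample"

    def __post_init__(self) -> None:
        if self.coords not in ("0-based", "1-based"):
            raise ConfigError(f"caller {self.name!r}: unknown coords {self.coords!r}")


@dataclass
class SimulationSection:
    enabled: bool = True
    method: str = DOWNSAMPLE
    n_range: tuple[int, int] = (2, 10)
    size_range_targets: tuple[int, int] = (1, 5)
    seed: int = 0
    p_remove: float = 0.5
    cross_sample_disjoint: bool = False

    def __post_init__(self) -> None:
        if self.method not in (DOWNSAMPLE, XREPLACE):
            raise ConfigError(f"simulation.method must be downsample|xreplace, got {self.method!r}")
        self.n_range = tuple(self.n_range)  # type: ignore[assignment]
        self.size_range_targets = tuple(self.size_range_targets)  # type: ignore[assignment]


@dataclass
class EvaluationSection:
    overlap_frac: float = 0.0
    n_bins: int = 5
    size_by: str | None = None  # "bases" | "targets"
    size_range: tuple[float, float] | None = None
    combine: bool = True  # also evaluate union/intersection when >= 2 callers

    def __post_init__(self) -> None:
        if self.size_by is not None and self.size_by not in ("bases", "targets"):
            raise ConfigError(f"evaluation.size_by must be bases|targets, got {self.size_by!r}")
        if (self.size_by is None) != (self.size_range is None):
            raise ConfigError("evaluation.size_by and size_range must be given together")
        if self.size_range is not None:
            self.size_range = tuple(self.size_range)  # type: ignore[assignment]


@dataclass
class QcSection:
    bin_width: int = 5_000_000
    chrom_sizes: str | None = None  # two-column TSV; falls back to BAM header


@dataclass
class ToyCallerSection:
    enabled: bool = False
    z_threshold: float = 3.0


@dataclass
class RunConfig:
    """Full configuration of a simulate→evaluate→QC run."""

    output_dir: str
    targets: str
    bams: dict[str, str] = field(default_factory=dict)  # sample id -> BAM path
    sexes: dict[str, str] = field(default_factory=dict)  # sample id -> male|female
    truth: str | None = None  # truth TSV when simulation is disabled
    simulation: SimulationSection = field(default_factory=SimulationSection)
    callers: list[CallerDecl] = field(default_factory=list)
    toy_caller: ToyCallerSection = field(default_factory=ToyCallerSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)
    qc: QcSection = field(default_factory=QcSection)

    def validate(self) -> None:
        if not self.simulation.enabled and self.truth is None:
            raise ConfigError(
                "simulation is disabled and no truth file given: nothing to evaluate against"
            )
        if self.simulation.enabled and not self.bams:
            raise ConfigError("simulation requires input BAMs")
        if not self.callers and not self.toy_caller.enabled:
            raise ConfigError("no callers declared and toy caller disabled: nothing to evaluate")
        for sample, sex in self.sexes.items():
            if sex not in ("male", "female"):
                raise ConfigError(f"sample {sample!r}: sex must be male|female, got {sex!r}")
        names = [c.name for c in self.callers]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate caller names: {names}")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        sections = {
            "simulation": SimulationSection,
            "evaluation": EvaluationSection,
            "qc": QcSection,
            "toy_caller": ToyCallerSection,
        }
        for key, section_cls in sections.items():
            if key in data:
                data[key] = _from_mapping(section_cls, data[key], key)
        if "callers" in data:
            data["callers"] = [
                _from_mapping(CallerDecl, c, f"callers[{i}]") for i, c in enumerate(data["callers"])
            ]
        config = _from_mapping(cls, data, "run config")
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_yaml(self, path: str | Path) -> None:
        """Write the effective configuration with all defaults resolved."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
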