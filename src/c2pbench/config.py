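"""Declarative benchmark configuration (YAML in, effective snapshot out)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthesis import GenerationConfig

__all__ = ["SplitSpec", "BenchmarkConfig"]


@dataclass(frozen=True)
class SplitSpec:
    """One test split: how many phantoms, targets per phantom, and crop ratio."""

    name: str
    n_sources: int = 2
    targets_per_source: int = 50
    crop_ratio: float = 0.15

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_sources": self.n_sources,
            "targets_per_source": self.targets_per_source,
            "crop_ratio": self.crop_ratio,
        }


@dataclass
class BenchmarkConfig:
    """Everything one benchmark run needs, in one declarative object.

    The default splits reproduce the four-partiality test layout (5%, 10%,
    15%, 25%; two source organs with 50 targets each).
    """

    generation: GenerationConfig = field(default_factory=GenerationConfig)
    splits: list[SplitSpec] = field(
        default_factory=lambda: [
            SplitSpec("crop05", crop_ratio=0.05),
            SplitSpec("crop10", crop_ratio=0.10),
            SplitSpec("crop15", crop_ratio=0.15),
            SplitSpec("crop25", crop_ratio=0.25),
        ]
    )
    methods: dict = field(
        default_factory=lambda: {"icp": {}, "cpd": {}, "gmmreg": {}, "fpfh-ransac": {}}
    )
    out_dir: str = "bench_out"
    phantom_width: float = 200.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        names = [s.name for s in self.splits]
        if len(names) != len(set(names)):
            raise ValueError(f"split names must be unique, got {names}")

    def to_dict(self) -> dict:
        return {
            "generation": self.generation.to_dict(),
            "splits": [s.to_dict() for s in self.splits],
            "methods": self.methods,
            "out_dir": self.out_dir,
            "phantom_width": self.phantom_width,
            "log_level": self.log_level,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        kwargs = dict(d)
        if "generation" in kwargs:
            kwargs["generation"] = GenerationConfig.from_dict(kwargs["generation"])
        if "splits" in kwargs:
            kwargs["splits"] = [SplitSpec(**s) for s in kwargs["splits"]]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
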