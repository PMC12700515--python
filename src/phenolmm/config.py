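"""Pipeline configuration: one YAML/JSON document drives every stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .simulate import SimulationTruth


@dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end pipeline.

    All randomness flows from ``seed``; the simulation block populates a
    :class:`SimulationTruth`, the remaining blocks override feature,
    aggregation and analysis defaults.
    """

    seed: int = 0
    out_dir: str = "results"
    simulate: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    aggregate: dict = field(default_factory=dict)
    analyze: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ag = self.aggregate
        for key, default in (("min_wake_windows", 720), ("min_sleep_windows", 480), ("min_hours_per_day", 18.0)):
            v = ag.get(key, default)
            if not v > 0:
                raise ConfigError(f"aggregate.{key} must be positive, got {v}")
        alpha = self.analyze.get("alpha", 0.05)
        if not (0.0 < alpha < 1.0):
            raise ConfigError(f"analyze.alpha must lie in (0, 1), got {alpha}")
        f2 = self.analyze.get("f2_gate", 0.01)
        if f2 < 0:
            raise ConfigError(f"analyze.f2_gate must be >= 0, got {f2}")
        al = self.aggregate.get("alignment", "preceding")
        if al not in ("preceding", "same"):
            raise ConfigError(f"aggregate.alignment must be 'preceding' or 'same', got {al!r}")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ConfigError("seed must be an integer")

    def truth(self) -> SimulationTruth:
        d = dict(self.simulate)
        d.setdefault("seed", self.seed)
        return SimulationTruth.from_dict(d)

    def digest(self) -> str:
        """Stable hash of the configuration, stamped on every artifact."""
        blob = json.dumps(
            {
                "seed": self.seed,
                "simulate": self.simulate,
                "features": self.features,
                "aggregate": self.aggregate,
                "analyze": self.analyze,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, seed: int | None = None, out_dir: str | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
        kwargs = {
            "seed": raw.get("seed", 0),
            "out_dir": raw.get("out_dir", "results"),
            "simulate": raw.get("simulate", {}) or {},
            "features": raw.get("features", {}) or {},
            "aggregate": raw.get("aggregate", {}) or {},
            "analyze": raw.get("analyze", {}) or {},
        }
        if seed is not None:
            kwargs["seed"] = seed
        if out_dir is not None:
            kwargs["out_dir"] = out_dir
        return cls(**kwargs)
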