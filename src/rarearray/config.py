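"""Pipeline configuration: paths, tunables, stage toggles.

Configuration files are YAML with three top-level sections (``inputs``,
``params``, ``stages``) plus ``output_dir`` and ``seed``. Unknown keys are
rejected anywhere, and the resolved configuration is written beside the
outputs of every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineParams", "StageToggles", "PipelineConfig"]


@dataclass
class PipelineParams:
    epsilon: float = 1.0
    prior_center: float = 3.0
    prior_var: float = 0.25
    prior_weight: float = 2.0
    confidence_threshold: float = 0.95
    d_max: float = 1.0
    shift_threshold: float = 0.5
    min_plate_n: int = 8
    t_upper: float = 1.72
    t_lower: float = -2.0
    npv_fraction: float = 0.0135


@dataclass
class StageToggles:
    rarehet: bool = True
    advnorm: bool = True
    concordance: bool = True
    screening: bool = True


@dataclass
class PipelineConfig:
    inputs: dict[str, str]
    output_dir: str
    seed: int
    params: PipelineParams = field(default_factory=PipelineParams)
    stages: StageToggles = field(default_factory=StageToggles)

    _INPUT_KEYS = {
        "intensities",
        "manifest",
        "annotation",
        "ref_maf",
        "gold_standard",
        "truth_dir",
        "panels",
    }
    _REQUIRED_INPUTS = {"intensities", "manifest", "annotation"}

    def validate(self) -> None:
        unknown = set(self.inputs) - self._INPUT_KEYS
        if unknown:
            raise ValueError(f"unknown input keys: {sorted(unknown)}")
        missing = self._REQUIRED_INPUTS - set(self.inputs)
        if missing:
            raise ValueError(f"missing required inputs: {sorted(missing)}")
        if self.stages.concordance and "ref_maf" not in self.inputs:
            raise ValueError("concordance stage enabled but no ref_maf input")
        if self.stages.screening and not (
            "gold_standard" in self.inputs or "truth_dir" in self.inputs
        ):
            raise ValueError(
                "screening stage enabled but neither gold_standard nor truth_dir given"
            )

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        known_top = {"inputs", "output_dir", "seed", "params", "stages"}
        unknown = set(raw) - known_top
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for section, klass in (("params", PipelineParams), ("stages", StageToggles)):
            data = raw.get(section) or {}
            fields = {f for f in klass.__dataclass_fields__}  # type: ignore[attr-defined]
            bad = set(data) - fields
            if bad:
                raise ValueError(f"unknown {section} keys: {sorted(bad)}")
            raw[section] = klass(**data)
        cfg = cls(
            inputs={k: str(v) for k, v in (raw.get("inputs") or {}).items()},
            output_dir=str(raw["output_dir"]),
            seed=int(raw["seed"]),
            params=raw.get("params", PipelineParams()),
            stages=raw.get("stages", StageToggles()),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} is not a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return {
            "inputs": dict(self.inputs),
            "output_dir": self.output_dir,
            "seed": self.seed,
            "params": asdict(self.params),
            "stages": asdict(self.stages),
        }

    def write_resolved(self, path=None) -> Path:
        path = Path(path) if path else Path(self.output_dir) / "resolved_config.yaml"
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path
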