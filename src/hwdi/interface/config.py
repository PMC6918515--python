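"""Pipeline configuration: a dataclass mirroring the YAML config schema.

The master ``seed`` drives every stochastic stage through fixed offsets:
the generator uses ``seed``, missingness injection ``seed + 1``, and
imputation ``seed + 2`` (each state then derives its own per-dataset
streams from that).
"""

from __future__ import annotations

import hashlib

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from ..imputation import ImputationSpec
from ..synthetic_data import GeneratorConfig, MissingnessSpec

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    #: Path to a microdata file, or None to use the synthetic generator.
    input_path: str | None = None
    generator: GeneratorConfig | None = None
    missingness: MissingnessSpec | None = None
    guideline_path: str | None = None
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    weighted_percentile: bool = False
    adjusted_means: bool = True
    at_covariate_means: bool = False
    missing_threshold: float = 0.5
    m_comparisons: int = 1
    top_k: int = 5
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.input_path is None and self.generator is None:
            self.generator = GeneratorConfig()
        # Master seed propagates to stage seeds by fixed offsets.
        if self.generator is not None:
            self.generator = replace(self.generator, seed=self.seed)
        if self.missingness is not None:
            self.missingness = replace(self.missingness, seed=self.seed + 1)
        self.imputation = replace(self.imputation, seed=self.seed + 2)

    def validate(self) -> None:
        if self.input_path is not None and not Path(self.input_path).exists():
            raise FileNotFoundError(f"input_path not found: {self.input_path}")
        if self.guideline_path is not None and not Path(self.guideline_path).exists():
            raise FileNotFoundError(f"guideline_path not found: {self.guideline_path}")
        if self.generator is not None:
            self.generator.validate()
        if self.missingness is not None:
            self.missingness.validate()
        self.imputation.validate()
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.m_comparisons < 1:
            raise ValueError("m_comparisons must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d and d["generator"] is not None:
            g = dict(d["generator"])
            if "states" in g:
                g["states"] = tuple(g["states"])
            if "bmi_income_gradient" in g:
                g["bmi_income_gradient"] = tuple(g["bmi_income_gradient"])
            if "household_size_dist" in g:
                g["household_size_dist"] = {
                    tuple(int(x) for x in str(k).split(",")): v
                    for k, v in g["household_size_dist"].items()
                }
            d["generator"] = GeneratorConfig(**g)
        if "missingness" in d and d["missingness"] is not None:
            d["missingness"] = MissingnessSpec(**d["missingness"])
        if "imputation" in d and d["imputation"] is not None:
            d["imputation"] = ImputationSpec(**d["imputation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Short stable digest of the full configuration (for output headers)."""
        payload = repr(asdict(self))  # dataclass field order is fixed; repr is deterministic
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
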