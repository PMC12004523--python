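"""Schema-validated pipeline configuration.

The configuration mirrors the pipeline stages: a simulation section (the
synthetic study conditions), a modeling section (CV, oversampling, the
random-forest grid and the BEDROC weight), and a funnel section (triage
thresholds).  Unknown keys are rejected, and a config round-trips through
YAML/JSON losslessly.

Defaults in the modeling section are the protocol constants (1000 trees,
seed 42, the five-value ``max_features`` grid, Butina floor 0.3, BEDROC
alpha 20); the simulation section defaults to a desk-scale demo dataset.
"""

from __future__ import annotations

from typing import List, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field


class SimulationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_balanced: int = 180
    n_imbalanced: int = 180
    label_noise: float = Field(0.1, ge=0.0, lt=0.5)
    planted_rule: str = "c1cncn1"
    n_scaffolds: int = 10
    library_decoys: int = 500
    library_planted: int = 10
    motif_decoy_fraction: float = Field(0.3, ge=0.0, le=1.0)
    seed: int = 1


class ModelingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha: float = Field(20.0, gt=0.0)
    grid: List[Union[None, str, float]] = [None, "sqrt", 0.2, 0.4, 0.8]
    k_folds: int = Field(5, ge=2)
    similarity_floor: float = Field(0.3, ge=0.0, le=1.0)
    test_fraction: float = Field(0.2, gt=0.0, lt=1.0)
    n_estimators: int = Field(1000, ge=1)
    oversample_mode: str = "continuous"
    seed: int = 42


class FunnelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    top_n: int = Field(10000, ge=1)
    p_min: float = Field(0.7, ge=0.0, le=1.0)
    novelty_max_sim: float = Field(0.7, ge=0.0, le=1.0)
    diversity_sim: float = Field(0.6, ge=0.0, le=1.0)
    rotatable_bond_max: int = Field(8, ge=0)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    simulation: SimulationSection = SimulationSection()
    modeling: ModelingSection = ModelingSection()
    funnel: FunnelSection = FunnelSection()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: Optional[str] = None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text
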