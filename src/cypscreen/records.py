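"""Core record types shared across the pipeline.

A :class:`CompoundRecord` carries one molecule through curation, featurization,
modeling and screening; reports (:class:`CurationReport`, :class:`FunnelReport`)
are the audit trail the pipeline emits alongside its outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Optional


class Source(str, Enum):
    """Where a record's activity annotation comes from.

    ``POTENCY`` records carry a continuous pIC50-like value (unitless
    -log10 molar scale); ``SCORE`` records carry a 0-100 integer assay
    score; ``LIBRARY`` records are unlabeled screening compounds.
    """

    POTENCY = "potency_source"
    SCORE = "score_source"
    LIBRARY = "library"


class Label(str, Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    EXCLUDED = "excluded"
    UNLABELED = "unlabeled"


@dataclass
class CompoundRecord:
    compound_id: str
    smiles_raw: str
    source: Source = Source.LIBRARY
    activity_value: Optional[float] = None
    smiles_std: Optional[str] = None
    label: Label = Label.UNLABELED

    def to_dict(self) -> dict:
        d = asdict(self)
        d["source"] = self.source.value
        d["label"] = self.label.value
        return d


@dataclass
class StageCount:
    """One curation stage: how many records entered, survived, and why
    the rest were rejected."""

    name: str
    n_in: int
    n_out: int
    rejection_reasons: dict = field(default_factory=dict)

    def reconciles(self) -> bool:
        return sum(self.rejection_reasons.values()) == self.n_in - self.n_out


@dataclass
class CurationReport:
    stages: list = field(default_factory=list)

    @property
    def stage_names(self) -> list:
        return [s.name for s in self.stages]

    def add(self, name: str, n_in: int, n_out: int, reasons: dict) -> None:
        self.stages.append(StageCount(name, n_in, n_out, dict(reasons)))

    def validate(self) -> None:
        prev_out = None
        for s in self.stages:
            if not s.reconciles():
                raise ValueError(f"stage {s.name!r} does not reconcile")
            if s.n_out > s.n_in:
                raise ValueError(f"stage {s.name!r} count increased")
            if prev_out is not None and s.n_in != prev_out:
                raise ValueError(f"stage {s.name!r} input != previous output")
            prev_out = s.n_out

    def to_json(self) -> str:
        return json.dumps(
            {
                "stages": [
                    {
                        "name": s.name,
                        "n_in": s.n_in,
                        "n_out": s.n_out,
                        "rejection_reasons": s.rejection_reasons,
                    }
                    for s in self.stages
                ]
            },
            indent=2,
        )
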