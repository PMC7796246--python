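"""Validated run configuration (YAML/JSON) for the command-line interface.

The schema is strict: unknown keys are rejected before any computation, so
a typo in a threshold name fails fast instead of silently running with a
default.  Each block maps onto the corresponding parameter object.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import phenotype as ph
from . import score as sc
from . import segment as seg
from . import simulate as sim


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimBlock(_Strict):
    seed: int = 0
    core_diameter_px: int = 900
    pixel_size_um: float = 0.5
    n_cells: int = 400
    tumour_fraction: float = 0.5
    n_nests: int = 3
    tps_true: float = Field(30.0, ge=0, le=100)
    macrophage_fraction: float = Field(0.1, ge=0, le=1)
    tcell_fraction: float = Field(0.1, ge=0, le=1)
    intratumoural_immune_fraction: float = Field(0.4, ge=0, le=1)
    pdl1_pos_prob_macrophage: float = Field(0.5, ge=0, le=1)
    pdl1_pos_prob_tcell: float = Field(0.2, ge=0, le=1)
    background_level: float = Field(0.05, ge=0)
    noise_sd: float = Field(0.05, ge=0)
    crosstalk: list[list[float]] | None = None
    section_jitter_px: float = Field(2.0, ge=0)
    section_dropout_prob: float = Field(0.05, ge=0, le=1)
    nucleus_radius_px: float = 6.0
    dab_od_level: float = 0.3
    pdl1_bernoulli: bool = False

    def to_params(self, seed: int | None = None) -> sim.SimParams:
        d = self.model_dump()
        if d["crosstalk"] is None:
            d.pop("crosstalk")
        else:
            d["crosstalk"] = np.asarray(d["crosstalk"], float)
        if seed is not None:
            d["seed"] = seed
        return sim.SimParams(**d)


class SegmentationBlock(_Strict):
    smoothing_sigma_px: float = 1.5
    dapi_threshold: float | str = "auto"
    min_nucleus_area_px: int = 10
    cell_expansion_um: float = 5.0
    h_maxima_px: float = 2.0

    def to_params(self) -> seg.SegmentationParams:
        return seg.SegmentationParams(**self.model_dump())


class RuleBlock(_Strict):
    label: str
    channel: str
    compartment: str = "cell"
    threshold: float = 0.2
    comparator: str = ">="

    def to_rule(self) -> ph.PhenotypeRule:
        return ph.PhenotypeRule(**self.model_dump())


def _default_rules() -> list[RuleBlock]:
    return [
        RuleBlock(label="tcell", channel="CD8"),
        RuleBlock(label="macrophage", channel="CD68"),
        RuleBlock(label="tumour", channel="CK"),
    ]


class CascadeBlock(_Strict):
    lineage_rules: list[RuleBlock] = Field(default_factory=_default_rules)
    pdl1_rule: RuleBlock = Field(
        default_factory=lambda: RuleBlock(label="pdl1", channel="PDL1", threshold=0.10)
    )
    pdl1_scope: str = "ck_positive_only"
    tumour_label: str = "tumour"

    def to_config(self) -> ph.CascadeConfig:
        return ph.CascadeConfig(
            [r.to_rule() for r in self.lineage_rules],
            self.pdl1_rule.to_rule(),
            self.pdl1_scope,
            self.tumour_label,
        )


class ScoringBlock(_Strict):
    dab_od_threshold: float = Field(0.15, ge=0)
    low_cut: float = 1.0
    high_cut: float = 50.0

    def to_config(self) -> sc.ScoringConfig:
        return sc.ScoringConfig(
            self.dab_od_threshold, sc.CategoryScheme(self.low_cut, self.high_cut)
        )


class RunConfig(_Strict):
    """Top-level run configuration: one block per pipeline stage."""

    sim: SimBlock = Field(default_factory=SimBlock)
    segmentation: SegmentationBlock = Field(default_factory=SegmentationBlock)
    cascade: CascadeBlock = Field(default_factory=CascadeBlock)
    scoring: ScoringBlock = Field(default_factory=ScoringBlock)
    out_dir: str = "pdl1dia-out"
    seeds: list[int] = Field(default_factory=lambda: [0])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
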