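"""PD-L1 tumour proportion score (TPS) and clinical category.

TPS = 100 × (PD-L1+ CK+ tumour cells) / (all CK+ tumour cells).  The three
clinical categories <1%, 1–49% and ≥50% drive immunotherapy eligibility;
here they are the bins [0,1), [1,50) and [50,100] — a score of exactly 50
falls in the high-expression category, following standard TPS practice.
Cores with no CK+ cells are flagged non-evaluable rather than scored 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CAT_LOW = "<1%"
CAT_MID = "1–49%"
CAT_HIGH = "≥50%"
NON_EVALUABLE = "non-evaluable"


@dataclass(frozen=True)
class CategoryScheme:
    """Three clinical bins partitioning [0, 100] at two cut points."""

    low_cut: float = 1.0
    high_cut: float = 50.0
    labels: tuple[str, str, str] = (CAT_LOW, CAT_MID, CAT_HIGH)

    def __post_init__(self):
        if not 0.0 < self.low_cut < self.high_cut < 100.0:
            raise ValueError("cuts must satisfy 0 < low_cut < high_cut < 100")


@dataclass(frozen=True)
class ScoringConfig:
    """DAB positivity threshold (optical density) and category scheme."""

    dab_od_threshold: float = 0.15
    scheme: CategoryScheme = field(default_factory=CategoryScheme)

    def __post_init__(self):
        if self.dab_od_threshold < 0:
            raise ValueError("dab_od_threshold must be non-negative")


@dataclass
class CoreScore:
    """Per-core counts, TPS and clinical category for one modality."""

    core_id: str
    modality: str  # "mif" or "dab"
    n_cells: int
    n_ck: int
    n_ck_pdl1: int
    n_cd68: int = 0
    n_cd8: int = 0
    tps: float | None = None
    category: str = NON_EVALUABLE

    @property
    def evaluable(self) -> bool:
        return self.tps is not None

    def to_dict(self) -> dict:
        return {
            "core_id": self.core_id, "modality": self.modality,
            "n_cells": self.n_cells, "n_ck": self.n_ck, "n_ck_pdl1": self.n_ck_pdl1,
            "n_cd68": self.n_cd68, "n_cd8": self.n_cd8,
            "tps": self.tps, "category": self.category,
        }


def clinical_category(tps: float, scheme: CategoryScheme | None = None) -> str:
    """Map a TPS in [0, 100] to its clinical category."""
    scheme = scheme or CategoryScheme()
    if not 0.0 <= tps <= 100.0:
        raise ValueError(f"TPS must be in [0, 100], got {tps}")
    if tps < scheme.low_cut:
        return scheme.labels[0]
    if tps < scheme.high_cut:
        return scheme.labels[1]
    return scheme.labels[2]


def tumour_proportion_score(
    table: pd.DataFrame,
    core_id: str = "core",
    modality: str = "mif",
    scheme: CategoryScheme | None = None,
    tumour_label: str = "tumour",
) -> CoreScore:
    """Score a classified cell table: percent of CK+ tumour cells that are PD-L1+.

    Only cells whose phenotype equals ``tumour_label`` enter numerator and
    denominator; PD-L1+ macrophages and T-cells are counted but ignored by
    the score.  With zero CK+ cells the core is non-evaluable.
    """
    if "phenotype" not in table.columns:
        raise ValueError("table is not classified: no 'phenotype' column")
    is_ck = table["phenotype"] == tumour_label
    n_ck = int(is_ck.sum())
    if "pdl1_call" in table.columns:
        calls = table.loc[is_ck, "pdl1_call"].fillna(False).astype(bool)
        n_pos = int(calls.sum())
    else:
        n_pos = 0
    score = CoreScore(
        core_id=core_id, modality=modality,
        n_cells=len(table), n_ck=n_ck, n_ck_pdl1=n_pos,
        n_cd68=int((table["phenotype"] == "macrophage").sum()),
        n_cd8=int((table["phenotype"] == "tcell").sum()),
    )
    if n_ck > 0:
        score.tps = 100.0 * n_pos / n_ck
        score.category = clinical_category(score.tps, scheme)
    return score


def naive_tumour_proportion_score(
    table: pd.DataFrame,
    core_id: str = "core",
    scheme: CategoryScheme | None = None,
    tumour_label: str = "tumour",
) -> CoreScore:
    """Score a table produced by the naive PD-L1-first ordering.

    Numerator = PD-L1+ cells inside the tumour region regardless of lineage
    (the ``naive_numerator`` column); denominator = CK+ tumour-classified
    cells, the same denominator as the optimised cascade, so the comparison
    isolates the numerator inflation.
    """
    if "naive_numerator" not in table.columns:
        raise ValueError("table lacks 'naive_numerator'; run naive_pdl1_first first")
    is_ck = table["phenotype"] == tumour_label
    n_ck = int(is_ck.sum())
    n_pos = int(table["naive_numerator"].sum())
    score = CoreScore(
        core_id=core_id, modality="mif-naive",
        n_cells=len(table), n_ck=n_ck, n_ck_pdl1=n_pos,
        n_cd68=int((table["phenotype"] == "macrophage").sum()),
        n_cd8=int((table["phenotype"] == "tcell").sum()),
    )
    if n_ck > 0:
        # the naive numerator can exceed the denominator on pathological cores
        score.tps = min(100.0, 100.0 * n_pos / n_ck)
        score.category = clinical_category(score.tps, scheme)
    return score


def score_dab(
    table: pd.DataFrame,
    config: ScoringConfig | None = None,
    core_id: str = "core",
    tumour_col: str = "tumour_class",
    od_col: str = "dab_od_nucleus",
) -> CoreScore:
    """Score a chromogenic PD-L1 section.

    A positive tumour cell is one assigned to the tumour compartment whose
    mean DAB optical density is at or above the threshold (default 0.15).
    """
    config = config or ScoringConfig()
    if od_col not in table.columns:
        raise ValueError(f"table lacks DAB optical-density column {od_col!r}")
    if tumour_col not in table.columns:
        raise ValueError(f"table lacks tumour/stroma column {tumour_col!r}")
    is_tum = table[tumour_col].astype(bool)
    n_ck = int(is_tum.sum())
    n_pos = int((is_tum & (table[od_col] >= config.dab_od_threshold)).sum())
    score = CoreScore(
        core_id=core_id, modality="dab",
        n_cells=len(table), n_ck=n_ck, n_ck_pdl1=n_pos,
    )
    if n_ck > 0:
        score.tps = 100.0 * n_pos / n_ck
        score.category = clinical_category(score.tps, config.scheme)
    return score


def scores_to_frame(scores: list[CoreScore]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in scores])
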