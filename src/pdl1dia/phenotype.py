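"""Sequential phenotype gating of measured cells.

Each detected cell is assigned exactly one lineage by applying threshold
rules in a configurable order: the first rule whose comparator passes wins,
and unmatched cells fall through to ``"other"``.  Order matters because
immune cells sit inside CK+ tumour nests and pick up neighbouring signal,
so the optimised cascade gates CD8, then CD68, and only then CK, before
PD-L1 is evaluated within the CK+ tumour cells.  A deliberately naive
ordering that gates PD-L1 first — and therefore counts PD-L1+ immune cells
inside tumour regions into the numerator — is provided to quantify how much
it inflates the tumour proportion score.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

_COMPARATORS = {">=": operator.ge, ">": operator.gt, "<=": operator.le, "<": operator.lt}


@dataclass(frozen=True)
class PhenotypeRule:
    """One threshold rule: cells whose measured intensity passes are positive."""

    label: str
    channel: str
    compartment: str = "cell"  # "nucleus" or "cell"
    threshold: float = 0.2
    comparator: str = ">="

    def __post_init__(self):
        if self.compartment not in ("nucleus", "cell"):
            raise ValueError(f"compartment must be 'nucleus' or 'cell', got {self.compartment!r}")
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")

    @property
    def column(self) -> str:
        return f"{self.channel}_{self.compartment}"

    def apply(self, table: pd.DataFrame) -> pd.Series:
        if self.column not in table.columns:
            raise KeyError(
                f"rule {self.label!r} needs channel measurement {self.column!r}, "
                "which is not in the cell table"
            )
        return _COMPARATORS[self.comparator](table[self.column], self.threshold)


def _default_lineage_rules() -> list[PhenotypeRule]:
    return [
        PhenotypeRule("tcell", "CD8", "cell", 0.2),
        PhenotypeRule("macrophage", "CD68", "cell", 0.2),
        PhenotypeRule("tumour", "CK", "cell", 0.2),
    ]


def _default_pdl1_rule() -> PhenotypeRule:
    return PhenotypeRule("pdl1", "PDL1", "cell", 0.10)


@dataclass
class CascadeConfig:
    """Ordered lineage rules plus the PD-L1 rule and its scope.

    The default order (CD8 → CD68 → CK-tumour, PD-L1 scored on CK+ cells
    only) is the optimised sequence: immune cells are removed before the
    tumour class is formed, so PD-L1+ macrophages and T-cells inside the
    nests cannot enter the tumour score.
    """

    lineage_rules: list[PhenotypeRule] = field(default_factory=_default_lineage_rules)
    pdl1_rule: PhenotypeRule = field(default_factory=_default_pdl1_rule)
    pdl1_scope: str = "ck_positive_only"  # or "all_cells"
    tumour_label: str = "tumour"
    fallback_label: str = "other"

    def __post_init__(self):
        labels = [r.label for r in self.lineage_rules]
        if len(set(labels)) != len(labels):
            raise ValueError(f"lineage rule labels must be unique, got {labels}")
        if self.pdl1_scope not in ("ck_positive_only", "all_cells"):
            raise ValueError(f"pdl1_scope must be 'ck_positive_only' or 'all_cells'")

    def reordered(self, order: list[str]) -> "CascadeConfig":
        """Same rules, permuted lineage order (labels must match exactly)."""
        by_label = {r.label: r for r in self.lineage_rules}
        if set(order) != set(by_label):
            raise ValueError(f"order {order} does not match rule labels {sorted(by_label)}")
        return CascadeConfig(
            [by_label[lab] for lab in order], self.pdl1_rule,
            self.pdl1_scope, self.tumour_label, self.fallback_label,
        )


def classify_cells(table: pd.DataFrame, config: CascadeConfig | None = None) -> pd.DataFrame:
    """Assign one lineage per cell by first-match-wins sequential gating.

    Returns a copy of the table with ``phenotype`` set and ``pdl1_call``
    (nullable boolean) defined only for cells inside the PD-L1 scope.
    """
    config = config or CascadeConfig()
    out = table.copy()
    phenotype = pd.Series(config.fallback_label, index=out.index, dtype=object)
    unassigned = pd.Series(True, index=out.index)
    for rule in config.lineage_rules:
        hit = rule.apply(out) & unassigned
        phenotype[hit] = rule.label
        unassigned &= ~hit
    out["phenotype"] = phenotype

    pdl1_pos = config.pdl1_rule.apply(out)
    in_scope = (
        phenotype == config.tumour_label
        if config.pdl1_scope == "ck_positive_only"
        else pd.Series(True, index=out.index)
    )
    out["pdl1_call"] = pd.Series(pd.NA, index=out.index, dtype="boolean")
    out.loc[in_scope, "pdl1_call"] = pdl1_pos[in_scope]
    return out


def points_in_nests(xs, ys, nests: list[np.ndarray] | list[Polygon]) -> np.ndarray:
    """Vectorised point-in-polygon test against the union of nest outlines."""
    polys = [n if isinstance(n, Polygon) else Polygon(n) for n in nests]
    if not polys:
        return np.zeros(len(np.atleast_1d(xs)), dtype=bool)
    union = shapely.unary_union(polys)
    shapely.prepare(union)
    return shapely.contains_xy(union, np.asarray(xs, float), np.asarray(ys, float))


def naive_pdl1_first(
    table: pd.DataFrame,
    config: CascadeConfig | None = None,
    nests: list[np.ndarray] | None = None,
    tumour_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Gate PD-L1 before lineage assignment (the inflation-prone ordering).

    PD-L1 is evaluated on every cell first; a cell enters the score
    numerator if it is PD-L1+ and lies inside the tumour region (nest
    polygons, or a binary mask indexed at the centroid).  Lineages are then
    assigned as usual but are *not* used to exclude immune cells from the
    numerator, so PD-L1+ intratumoural macrophages and T-cells inflate the
    score.  Adds ``pdl1_call`` (defined for every cell), ``in_tumour_region``
    and ``naive_numerator`` columns.
    """
    config = config or CascadeConfig()
    if nests is None and tumour_mask is None:
        raise ValueError("naive ordering needs a tumour region: pass nests or tumour_mask")
    out = classify_cells(table, config)
    out["pdl1_call"] = config.pdl1_rule.apply(out).astype("boolean")
    if nests is not None:
        inside = points_in_nests(out["x"].to_numpy(), out["y"].to_numpy(), nests)
    else:
        iy = np.clip(np.round(out["y"].to_numpy()).astype(int), 0, tumour_mask.shape[0] - 1)
        ix = np.clip(np.round(out["x"].to_numpy()).astype(int), 0, tumour_mask.shape[1] - 1)
        inside = tumour_mask[iy, ix].astype(bool)
    out["in_tumour_region"] = inside
    out["naive_numerator"] = out["pdl1_call"].fillna(False).to_numpy(bool) & inside
    return out


def auto_threshold(values, method: str = "otsu") -> float:
    """Data-driven cut between the negative and positive intensity modes.

    ``otsu`` maximises between-class variance; ``gmm2`` fits a two-component
    Gaussian mixture and returns the midpoint of the component means.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 or np.unique(values).size < 2:
        raise ValueError("auto_threshold needs at least two distinct values")
    if method == "otsu":
        # histogram Otsu, taking the midpoint of the argmax plateau: for
        # well-separated modes the between-class variance is flat across the
        # whole gap, and the plateau centre is the natural cut
        counts, edges = np.histogram(values, bins=256)
        mids = 0.5 * (edges[:-1] + edges[1:])
        w0 = np.cumsum(counts)[:-1]
        w1 = values.size - w0
        mu0 = np.cumsum(counts * mids)[:-1] / np.where(w0 == 0, 1, w0)
        mu1 = (np.sum(counts * mids) - np.cumsum(counts * mids)[:-1]) / np.where(w1 == 0, 1, w1)
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
        best = np.flatnonzero(sigma_b >= sigma_b.max() * (1 - 1e-12))
        return float(mids[(best[0] + best[-1]) // 2])
    if method == "gmm2":
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(n_components=2, random_state=0, n_init=3)
        gm.fit(values.reshape(-1, 1))
        return float(np.mean(np.sort(gm.means_.ravel())))
    raise ValueError(f"unknown method {method!r}; expected 'otsu' or 'gmm2'")
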