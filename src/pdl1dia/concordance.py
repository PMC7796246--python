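"""Agreement between paired per-core PD-L1 scores.

Compares two scoring paths per core — fluorescence vs chromogenic, or the
optimised vs naive gating order — with squared Pearson correlation, Spearman
rank correlation (mid-ranks for ties), and categorical concordance on the
clinical scale: the 3×3 cross-tabulation, the concordant percentage, and the
split of discordances into overcalls by either side.  Also hosts the two
simulation experiments: the gating-order inflation experiment and the
serial-section per-marker cell-count correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import phenotype as ph
from . import pipeline
from . import score as sc
from . import segment as seg
from . import simulate as sim


@dataclass
class PairedScores:
    """Per-core score pairs from two modalities (or orderings) a and b."""

    frame: pd.DataFrame  # columns: core_id, score_a, score_b, category_a, category_b
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self):
        need = {"core_id", "score_a", "score_b", "category_a", "category_b"}
        missing = need - set(self.frame.columns)
        if missing:
            raise ValueError(f"paired-score frame missing columns {sorted(missing)}")
        if self.frame["core_id"].duplicated().any():
            raise ValueError("duplicate core_id in paired scores")

    @classmethod
    def from_scores(cls, a: list[sc.CoreScore], b: list[sc.CoreScore],
                    label_a: str = "a", label_b: str = "b") -> "PairedScores":
        bm = {s.core_id: s for s in b}
        rows = []
        for s in a:
            if s.core_id not in bm:
                continue
            t = bm[s.core_id]
            rows.append({"core_id": s.core_id, "score_a": s.tps, "score_b": t.tps,
                         "category_a": s.category, "category_b": t.category})
        return cls(pd.DataFrame(rows), label_a, label_b)

    def evaluable(self) -> pd.DataFrame:
        """Pairs where both scores exist; non-evaluable cores drop out pairwise."""
        f = self.frame
        return f[f["score_a"].notna() & f["score_b"].notna()]

    def swapped(self) -> "PairedScores":
        f = self.frame.rename(columns={
            "score_a": "score_b", "score_b": "score_a",
            "category_a": "category_b", "category_b": "category_a",
        })
        return PairedScores(f, self.label_b, self.label_a)


def r_squared(pairs: PairedScores) -> float:
    """Squared Pearson correlation of the paired scores."""
    f = pairs.evaluable()
    if len(f) < 3:
        raise ValueError(f"need at least 3 evaluable pairs, got {len(f)}")
    a = f["score_a"].to_numpy(float)
    b = f["score_b"].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: one side has zero variance")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def spearman_rho(pairs: PairedScores) -> float:
    """Spearman rank correlation with mid-ranks for ties."""
    f = pairs.evaluable()
    if len(f) < 3:
        raise ValueError(f"need at least 3 evaluable pairs, got {len(f)}")
    a = f["score_a"].to_numpy(float)
    b = f["score_b"].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation undefined: one side has zero variance")
    return float(stats.spearmanr(a, b).statistic)


@dataclass
class ConcordanceReport:
    """Categorical agreement between two modalities on the clinical scale."""

    label_a: str
    label_b: str
    n_pairs: int
    n_excluded: int
    crosstab: pd.DataFrame  # rows = a categories, cols = b categories
    n_concordant: int
    pct_concordant: float
    overcalls_a: int
    overcalls_b: int
    discordant: pd.DataFrame  # core_id, category_a, category_b, overcall_by, flag
    r_squared: float | None = None
    spearman_rho: float | None = None
    manual_flags: dict = field(default_factory=dict)

    @property
    def n_discordant(self) -> int:
        return self.n_pairs - self.n_concordant

    @property
    def pct_discordant(self) -> float:
        return _pct(self.n_discordant, self.n_pairs)

    def to_dict(self) -> dict:
        return {
            "labels": [self.label_a, self.label_b],
            "n_pairs": self.n_pairs,
            "n_excluded_non_evaluable": self.n_excluded,
            "crosstab": {str(r): {str(c): int(v) for c, v in row.items()}
                         for r, row in self.crosstab.iterrows()},
            "n_concordant": self.n_concordant,
            "pct_concordant": self.pct_concordant,
            "n_discordant": self.n_discordant,
            "pct_discordant": self.pct_discordant,
            f"overcalls_{self.label_a}": self.overcalls_a,
            f"overcalls_{self.label_b}": self.overcalls_b,
            "discordant_cores": self.discordant.to_dict(orient="records"),
            "r_squared": self.r_squared,
            "spearman_rho": self.spearman_rho,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def to_text(self) -> str:
        lines = [
            f"Categorical concordance: {self.label_a} vs {self.label_b}",
            f"  pairs compared: {self.n_pairs} ({self.n_excluded} non-evaluable excluded)",
            f"  concordant: {self.n_concordant}/{self.n_pairs} = {self.pct_concordant}%",
            f"  discordant: {self.n_discordant}/{self.n_pairs} = {self.pct_discordant}%",
            f"  overcalls by {self.label_a}: {self.overcalls_a}; by {self.label_b}: {self.overcalls_b}",
        ]
        if self.r_squared is not None:
            lines.append(f"  R^2 = {self.r_squared:.4f}, Spearman rho = {self.spearman_rho:.4f}")
        lines.append("  cross-tabulation (rows = %s):" % self.label_a)
        lines.append(self.crosstab.to_string())
        return "\n".join(lines)


def _pct(num: int, den: int) -> float:
    """Percentage to 1 decimal (round-half-even)."""
    return float(round(100.0 * num / den, 1))


def categorical_concordance(
    pairs: PairedScores,
    scheme: sc.CategoryScheme | None = None,
    with_correlation: bool = True,
    manual_flags: dict | None = None,
) -> ConcordanceReport:
    """Cross-tabulate paired clinical categories and split the discordances.

    An overcall by a modality is a pair where that modality's category is
    the higher of the two.  ``manual_flags`` is a pass-through of core_id →
    free-text review flags for cores whose ground truth is hard to discern.
    """
    scheme = scheme or sc.CategoryScheme()
    if len(pairs.frame) == 0:
        raise ValueError("no pairs to compare")
    f = pairs.evaluable()
    if len(f) == 0:
        raise ValueError("no evaluable pairs to compare")
    n_excluded = len(pairs.frame) - len(f)
    cats = list(scheme.labels)
    order = {c: i for i, c in enumerate(cats)}
    ct = pd.crosstab(f["category_a"], f["category_b"]).reindex(
        index=cats, columns=cats, fill_value=0
    )
    ct.index.name = pairs.label_a
    ct.columns.name = pairs.label_b
    n = len(f)
    n_conc = int(np.trace(ct.to_numpy()))
    ia = f["category_a"].map(order)
    ib = f["category_b"].map(order)
    over_a = int((ia > ib).sum())
    over_b = int((ib > ia).sum())
    disc = f[ia != ib][["core_id", "score_a", "score_b", "category_a", "category_b"]].copy()
    disc["overcall_by"] = np.where(
        ia[disc.index] > ib[disc.index], pairs.label_a, pairs.label_b
    )
    flags = manual_flags or {}
    disc["flag"] = disc["core_id"].map(flags).fillna("")
    r2 = rho = None
    if with_correlation:
        try:
            r2 = r_squared(pairs)
            rho = spearman_rho(pairs)
        except ValueError:
            pass
    return ConcordanceReport(
        label_a=pairs.label_a, label_b=pairs.label_b,
        n_pairs=n, n_excluded=n_excluded, crosstab=ct,
        n_concordant=n_conc, pct_concordant=_pct(n_conc, n),
        overcalls_a=over_a, overcalls_b=over_b,
        discordant=disc.reset_index(drop=True),
        r_squared=r2, spearman_rho=rho, manual_flags=flags,
    )


# ---------------------------------------------------------------------------
# simulation experiments


def parameter_recovery_experiment(
    n_cores: int,
    params: sim.SimParams,
    seg_params: seg.SegmentationParams | None = None,
    cascade: ph.CascadeConfig | None = None,
    base_seed: int = 0,
    tps_range: tuple[float, float] = (2.0, 95.0),
) -> pd.DataFrame:
    """Full-pipeline recovery of the true tumour proportion score.

    Each core draws its true TPS uniformly from ``tps_range`` (quota mode,
    so the target is exact), is rendered at the default noise level, and is
    scored through the complete fluorescence path.  Returns per-core true
    and measured TPS and the absolute error in percentage points.
    """
    rng = np.random.default_rng([int(base_seed), 23])
    rows = []
    for i in range(n_cores):
        tps = float(rng.uniform(*tps_range))
        p = params.replace(seed=int(base_seed) * 99991 + i, tps_true=tps)
        truth = sim.generate_core(p)
        _, score = pipeline.analyse_mif(truth, seg_params, cascade, core_id=f"core{i}")
        rows.append({
            "core": i,
            "tps_true": truth.true_tps(),
            "tps_measured": score.tps,
            "abs_error_pp": abs(score.tps - truth.true_tps()),
        })
    return pd.DataFrame(rows)


def modality_concordance_experiment(
    n_cores: int,
    params: sim.SimParams,
    seg_params: seg.SegmentationParams | None = None,
    cascade: ph.CascadeConfig | None = None,
    scoring: sc.ScoringConfig | None = None,
    base_seed: int = 0,
) -> ConcordanceReport:
    """Paired mIF-vs-DAB scoring of a synthetic cohort.

    True TPS values are spread across the three clinical categories, and the
    immune infiltrate varies core to core (fraction, intratumoural split and
    PD-L1 positivity drawn per core), as in a real cohort — cores combining
    a near-zero tumour score with a PD-L1-rich intratumoural infiltrate are
    the ones the chromogenic path overcalls.  The chromogenic slide is an
    emulated serial section of each core.  Returns the full concordance
    report (crosstab, concordant percent, overcall split, R², Spearman ρ).
    """
    rng = np.random.default_rng([int(base_seed), 29])
    scheme = (scoring or sc.ScoringConfig()).scheme
    mif_scores, dab_scores = [], []
    for i in range(n_cores):
        # cohort spread: a third of cores in each clinical category
        band = i % 3
        tps = float((0.0, rng.uniform(5, 45), rng.uniform(55, 95))[band])
        p = params.replace(
            seed=int(base_seed) * 99989 + i,
            tps_true=tps,
            macrophage_fraction=float(rng.uniform(0.05, 0.15)),
            tcell_fraction=float(rng.uniform(0.05, 0.15)),
            intratumoural_immune_fraction=float(rng.uniform(0.1, 0.7)),
            pdl1_pos_prob_macrophage=float(rng.uniform(0.0, 0.6)),
            pdl1_pos_prob_tcell=float(rng.uniform(0.0, 0.3)),
        )
        truth = sim.generate_core(p)
        _, ms = pipeline.analyse_mif(truth, seg_params, cascade, scheme, core_id=f"core{i}")
        _, ds = pipeline.analyse_dab(truth, "PDL1", seg_params, scoring, core_id=f"core{i}")
        mif_scores.append(ms)
        dab_scores.append(ds)
    pairs = PairedScores.from_scores(mif_scores, dab_scores, "mif", "dab")
    return categorical_concordance(pairs, scheme)


def order_effect_experiment(
    seeds,
    params: sim.SimParams,
    seg_params: seg.SegmentationParams | None = None,
    cascade: ph.CascadeConfig | None = None,
    scheme: sc.CategoryScheme | None = None,
) -> pd.DataFrame:
    """Quantify score inflation under the naive PD-L1-first gating order.

    For each seed, one core is generated and analysed twice from the same
    rendered stack: once with the optimised cascade and once with PD-L1
    gated first.  Returns one row per seed with the true TPS, both measured
    scores, their clinical categories, and whether the naive order shifted
    the category upward.
    """
    cascade = cascade or ph.CascadeConfig()
    rows = []
    for s in seeds:
        p = params.replace(seed=int(s))
        truth = sim.generate_core(p)
        stack = sim.render_channels(truth)
        _, cas = pipeline.analyse_mif(truth, seg_params, cascade, scheme,
                                      core_id=f"core{s}", stack=stack)
        _, nai = pipeline.analyse_mif_naive(truth, seg_params, cascade, scheme,
                                            core_id=f"core{s}", stack=stack)
        rows.append({
            "seed": int(s),
            "tps_true": truth.true_tps(),
            "cascade_tps": cas.tps,
            "naive_tps": nai.tps,
            "cascade_category": cas.category,
            "naive_category": nai.category,
            "inflation": (nai.tps - cas.tps) if cas.evaluable and nai.evaluable else np.nan,
            "category_shift": cas.evaluable and nai.evaluable and nai.category != cas.category,
        })
    return pd.DataFrame(rows)


def serial_section_experiment(
    n_rois: int,
    params: sim.SimParams,
    seg_params: seg.SegmentationParams | None = None,
    markers=("PDL1", "CK", "CD68", "CD8"),
    base_seed: int = 0,
    n_cells_range: tuple[int, int] = (120, 400),
    dab_threshold: float = 0.15,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-marker positive-cell-count correlation across emulated serial sections.

    Mimics comparing matched regions of interest between a chromogenic slide
    and the corresponding single fluorescence channel: each ROI is one
    synthetic core; the fluorescence count is the number of segmented cells
    whose marker intensity passes the phenotype threshold, and the
    chromogenic count is the number of DAB-positive cells detected on an
    emulated adjacent section.  ROI cellularity varies across the stated
    range so the correlation spans a realistic dynamic range.  Returns the
    per-ROI count table and the per-marker R².
    """
    seg_params = seg_params or seg.SegmentationParams()
    rng = np.random.default_rng([int(base_seed), 17])
    rules = {
        "CK": ph.PhenotypeRule("ck", "CK", "cell", 0.2),
        "CD68": ph.PhenotypeRule("cd68", "CD68", "cell", 0.2),
        "CD8": ph.PhenotypeRule("cd8", "CD8", "cell", 0.2),
        "PDL1": ph.PhenotypeRule("pdl1", "PDL1", "cell", 0.10),
    }
    rows = []
    for i in range(n_rois):
        n_cells = int(rng.integers(*n_cells_range))
        p = params.replace(seed=int(base_seed) * 100003 + i, n_cells=n_cells)
        truth = sim.generate_core(p)
        stack = sim.render_channels(truth)
        _, table = pipeline.segment_and_measure(stack, seg_params)
        row = {"roi": i, "n_cells_true": n_cells, "n_detected_mif": len(table)}
        for m in markers:
            row[f"{m}_mif_count"] = int(rules[m].apply(table).sum())
        # chromogenic side: one single-marker DAB slide per marker, each an
        # emulated adjacent section of the same core
        section = sim.emulate_serial_section(truth)
        for m in markers:
            hdab = sim.render_hdab(section, m)
            od_h, od_d = seg.deconvolve_hdab(hdab)
            nuclei = seg.detect_nuclei(od_h, seg_params)
            labels = seg.expand_cells(nuclei, p.pixel_size_um, seg_params)
            dab_table = seg.measure_cells(labels, dab_od={"dab_od": od_d})
            row[f"{m}_dab_count"] = pipeline.dab_positive_count(dab_table, dab_threshold)
        rows.append(row)
    frame = pd.DataFrame(rows)
    r2 = {}
    for m in markers:
        pairs = PairedScores(
            pd.DataFrame({
                "core_id": frame["roi"],
                "score_a": frame[f"{m}_mif_count"].astype(float),
                "score_b": frame[f"{m}_dab_count"].astype(float),
                "category_a": "", "category_b": "",
            }),
            "mif", "dab",
        )
        r2[m] = r_squared(pairs)
    return frame, r2
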