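"""Paired-score agreement statistics against brute-force definitional oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdl1dia import (
    PairedScores,
    categorical_concordance,
    clinical_category,
    r_squared,
    spearman_rho,
)


def pairs_from(a, b, categorise=False):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return PairedScores(pd.DataFrame({
        "core_id": [f"c{i}" for i in range(len(a))],
        "score_a": a,
        "score_b": b,
        "category_a": [clinical_category(v) for v in a] if categorise else "",
        "category_b": [clinical_category(v) for v in b] if categorise else "",
    }))


def pearson_oracle(x, y):
    """Pearson r from the definition: centred cross-moments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def midrank_oracle(v):
    """Mid-ranks by explicit enumeration: rank = mean position of equal values."""
    v = np.asarray(v, float)
    return np.array([(np.sum(v < x) + 1 + np.sum(v <= x)) / 2 for x in v])


class TestRSquared:
    def test_exact_line_gives_one(self):
        assert r_squared(pairs_from([1, 2, 3, 4], [2, 4, 6, 8])) == pytest.approx(1.0)

    def test_matches_definitional_oracle(self):
        a, b = [1, 2, 3, 4], [1, 3, 2, 4]
        assert r_squared(pairs_from(a, b)) == pytest.approx(pearson_oracle(a, b) ** 2, abs=1e-12)

    def test_constant_side_rejected(self):
        with pytest.raises(ValueError):
            r_squared(pairs_from([1, 2, 3], [5, 5, 5]))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            r_squared(pairs_from([1, 2], [1, 2]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_oracle_equivalence_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 21)
        a = rng.uniform(0, 100, n).round(1)  # rounding induces occasional ties
        b = rng.uniform(0, 100, n).round(1)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return
        pairs = pairs_from(a, b)
        assert r_squared(pairs) == pytest.approx(pearson_oracle(a, b) ** 2, abs=1e-12)
        assert spearman_rho(pairs) == pytest.approx(
            pearson_oracle(midrank_oracle(a), midrank_oracle(b)), abs=1e-12)


class TestSpearman:
    def test_monotone_is_one(self):
        assert spearman_rho(pairs_from([1, 5, 20, 80], [2, 3, 50, 99])) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        assert spearman_rho(pairs_from([1, 2, 3, 4], [9, 7, 5, 3])) == pytest.approx(-1.0)

    def test_ties_use_midranks(self):
        a = [1, 2, 2, 3, 4, 5]
        b = [1, 3, 2, 4, 5, 6]
        expected = pearson_oracle(midrank_oracle(a), midrank_oracle(b))
        assert spearman_rho(pairs_from(a, b)) == pytest.approx(expected, abs=1e-12)


class TestCategoricalConcordance:
    def test_printed_contingency_arithmetic(self):
        # 320 paired cores, 303 same category, 12 overcalls by b, 5 by a
        a = ["<1%"] * 100 + ["1–49%"] * 120 + ["≥50%"] * 100
        b = list(a)
        for i in range(12):  # b overcalls
            b[i] = "1–49%"
        for i in range(100, 105):  # a overcalls relative to b
            b[i] = "<1%"
        frame = pd.DataFrame({
            "core_id": range(320), "score_a": 10.0, "score_b": 10.0,
            "category_a": a, "category_b": b,
        })
        rep = categorical_concordance(PairedScores(frame, "mif", "dab"),
                                      with_correlation=False)
        assert rep.n_concordant == 303
        assert rep.pct_concordant == 94.7
        assert rep.pct_discordant == 5.3
        assert rep.overcalls_b == 12 and rep.overcalls_a == 5
        assert round(100 * rep.overcalls_b / rep.n_discordant, 1) == 70.6

    def test_all_concordant(self):
        pairs = pairs_from([0.5, 25, 75], [0.7, 30, 60], categorise=True)
        rep = categorical_concordance(pairs)
        assert rep.pct_concordant == 100.0
        assert rep.overcalls_a == rep.overcalls_b == 0

    def test_internal_consistency_invariants(self):
        rng = np.random.default_rng(3)
        pairs = pairs_from(rng.uniform(0, 100, 60), rng.uniform(0, 100, 60),
                           categorise=True)
        rep = categorical_concordance(pairs)
        assert rep.n_concordant == np.trace(rep.crosstab.to_numpy())
        assert rep.overcalls_a + rep.overcalls_b == rep.n_pairs - rep.n_concordant
        assert rep.pct_concordant == round(100 * rep.n_concordant / rep.n_pairs, 1)
        assert rep.crosstab.to_numpy().sum() == rep.n_pairs

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(5)
        pairs = pairs_from(rng.uniform(0, 100, 40), rng.uniform(0, 100, 40),
                           categorise=True)
        rep = categorical_concordance(pairs)
        swp = categorical_concordance(pairs.swapped())
        assert rep.pct_concordant == swp.pct_concordant
        assert rep.r_squared == pytest.approx(swp.r_squared, abs=1e-12)
        assert rep.spearman_rho == pytest.approx(swp.spearman_rho, abs=1e-12)
        assert (rep.overcalls_a, rep.overcalls_b) == (swp.overcalls_b, swp.overcalls_a)

    def test_non_evaluable_excluded_pairwise(self):
        frame = pd.DataFrame({
            "core_id": ["a", "b", "c", "d"],
            "score_a": [10.0, None, 60.0, 20.0],
            "score_b": [12.0, 15.0, 55.0, 25.0],
            "category_a": ["1–49%", "non-evaluable", "≥50%", "1–49%"],
            "category_b": ["1–49%", "1–49%", "≥50%", "1–49%"],
        })
        rep = categorical_concordance(PairedScores(frame), with_correlation=False)
        assert rep.n_pairs == 3
        assert rep.n_excluded == 1

    def test_duplicate_core_ids_rejected(self):
        frame = pd.DataFrame({
            "core_id": ["a", "a"], "score_a": [1.0, 2.0], "score_b": [1.0, 2.0],
            "category_a": ["<1%", "<1%"], "category_b": ["<1%", "<1%"],
        })
        with pytest.raises(ValueError):
            PairedScores(frame)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            categorical_concordance(PairedScores(pd.DataFrame(
                columns=["core_id", "score_a", "score_b", "category_a", "category_b"])))

    def test_report_roundtrips_to_json(self):
        pairs = pairs_from([0.5, 25, 75, 30], [0.7, 30, 60, 55], categorise=True)
        rep = categorical_concordance(pairs)
        import json

        d = json.loads(rep.to_json())
        assert d["n_pairs"] == 4
        assert d["pct_concordant"] == rep.pct_concordant
        assert "crosstab" in d and len(d["discordant_cores"]) == rep.n_discordant
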