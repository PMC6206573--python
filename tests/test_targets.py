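"""Binomial target prioritisation: tail oracle, GS/CS scoring, selections."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from formulanet import datasets, synthetic, targets as tg


def exact_binomial_tail(k: int, n: int, p: Fraction) -> Fraction:
    """Exact-rational enumeration of P(X >= k) for X ~ Binomial(n, p)."""
    from math import comb

    return sum(
        Fraction(comb(n, m)) * p**m * (1 - p) ** (n - m) for m in range(k, n + 1)
    )


class TestBinomialTail:
    def test_trivial_bounds(self):
        assert tg.binomial_tail(0, 5, 0.3) == 1.0
        assert tg.binomial_tail(7, 7, 1.0) == 1.0
        with pytest.raises(ValueError):
            tg.binomial_tail(8, 7, 0.5)

    def test_small_case_against_enumeration(self):
        expected = exact_binomial_tail(3, 10, Fraction(1, 10))
        assert float(expected) == pytest.approx(0.070190, abs=1e-6)
        assert tg.binomial_tail(3, 10, 0.1) == pytest.approx(float(expected), abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        n=st.integers(1, 20),
        k_frac=st.floats(0.0, 1.0),
        num=st.integers(0, 10),
    )
    def test_matches_exact_rational_oracle(self, n, k_frac, num):
        k = int(round(k_frac * n))
        p = Fraction(num, 10)
        expected = float(exact_binomial_tail(k, n, p))
        assert tg.binomial_tail(k, n, float(p)) == pytest.approx(expected, abs=1e-12)


class TestScoreTargets:
    def test_uniform_profile_yields_no_core_targets(self):
        rows = [
            {"compound_id": f"C{i}", "gene": f"G{i}", "herb": ""} for i in range(40)
        ]
        table = tg.InteractionTable(pd.DataFrame(rows))
        scores = tg.score_targets(table)
        assert (scores["gs"] == 0).all()
        assert tg.select_core_targets(scores) == frozenset()

    def test_gs_formula_and_gate(self, planted_profile):
        table, _ = planted_profile
        scores = tg.score_targets(table, alpha=0.05)
        sig = scores["adj_pvalue"] <= 0.05
        recomputed = -np.log10(scores["adj_pvalue"]) / scores["rank"]
        assert np.allclose(scores.loc[sig, "gs"], recomputed[sig], rtol=1e-12)
        assert (scores.loc[~sig, "gs"] == 0).all()
        # hand value: adjusted p of 0.001 at rank 2 gives GS = 1.5
        assert -np.log10(0.001) / 2 == pytest.approx(1.5)

    def test_bh_adjustment_invariants(self, planted_profile):
        table, _ = planted_profile
        scores = tg.score_targets(table)
        assert (scores["adj_pvalue"] >= scores["pvalue"] - 1e-15).all()
        order = scores.sort_values("pvalue")
        assert order["adj_pvalue"].is_monotonic_increasing

    def test_planted_recovery(self, planted_profile):
        table, truth = planted_profile
        core = tg.select_core_targets(tg.score_targets(table))
        planted = truth.planted_core_targets
        precision = len(core & planted) / len(core)
        recall = len(core & planted) / len(planted)
        assert precision >= 0.9
        assert recall >= 0.8

    def test_null_false_positive_rate(self):
        """Without planted targets the GS > 0 fraction stays near alpha."""
        fractions = []
        for seed in range(50):
            frame, _ = synthetic.gen_compound_targets(100, 300, n_core=0, seed=seed)
            scores = tg.score_targets(tg.InteractionTable(frame))
            fractions.append(float((scores["gs"] > 0).mean()))
        assert np.mean(fractions) <= 0.05 + 3 * np.std(fractions)

    def test_empty_table_rejected(self):
        table = tg.InteractionTable(pd.DataFrame(columns=["compound_id", "gene"]))
        with pytest.raises(ValueError):
            tg.score_targets(table)


class TestScoreCompounds:
    def make_table(self):
        rows = [
            ("A", "T1"), ("A", "T2"), ("A", "T3"),
            ("B", "T2"),
            ("C", "T4"),
        ]
        return tg.InteractionTable(
            pd.DataFrame([{"compound_id": c, "gene": g} for c, g in rows])
        )

    def make_scores(self):
        return pd.DataFrame(
            {"gene": ["T1", "T2", "T3", "T4"], "gs": [3.0, 0.0, 1.5, 0.0]}
        )

    def test_cs_is_mean_gs(self):
        cs = tg.score_compounds(self.make_table(), self.make_scores())
        by_id = cs.set_index("compound_id")["cs"]
        assert by_id["A"] == pytest.approx(1.5)
        assert by_id["B"] == pytest.approx(0.0)
        assert by_id["C"] == pytest.approx(0.0)

    def test_row_order_invariance(self):
        table = self.make_table()
        shuffled = tg.InteractionTable(
            table.frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
        )
        a = tg.score_compounds(table, self.make_scores())
        b = tg.score_compounds(shuffled, self.make_scores())
        pd.testing.assert_frame_equal(a, b)

    def test_missing_gene_is_named(self):
        scores = self.make_scores().iloc[:2]
        with pytest.raises(KeyError, match="T3|T4"):
            tg.score_compounds(self.make_table(), scores)


class TestRepresentativeCompounds:
    def test_prefix_keeps_non_contributing_compounds(self):
        table = tg.InteractionTable(
            pd.DataFrame(
                [
                    {"compound_id": "C1", "gene": "T1"},
                    {"compound_id": "C1", "gene": "T2"},
                    {"compound_id": "C2", "gene": "T1"},
                    {"compound_id": "C3", "gene": "T3"},
                ]
            )
        )
        cs = pd.DataFrame({"compound_id": ["C1", "C2", "C3"], "cs": [3.0, 2.0, 1.0]})
        prefix = tg.select_representative_compounds(cs, table, {"T1", "T2", "T3"})
        assert prefix == ["C1", "C2", "C3"]

    def test_top_compound_covering_everything(self):
        table = tg.InteractionTable(
            pd.DataFrame([{"compound_id": "C1", "gene": "T1"},
                          {"compound_id": "C2", "gene": "T1"}])
        )
        cs = pd.DataFrame({"compound_id": ["C1", "C2"], "cs": [2.0, 1.0]})
        assert tg.select_representative_compounds(cs, table, {"T1"}) == ["C1"]

    def test_empty_core_gives_empty_prefix(self):
        table = tg.InteractionTable(pd.DataFrame([{"compound_id": "C1", "gene": "T1"}]))
        cs = pd.DataFrame({"compound_id": ["C1"], "cs": [1.0]})
        assert tg.select_representative_compounds(cs, table, set()) == []

    def test_uncoverable_core_lists_missing_genes(self):
        table = tg.InteractionTable(pd.DataFrame([{"compound_id": "C1", "gene": "T1"}]))
        cs = pd.DataFrame({"compound_id": ["C1"], "cs": [1.0]})
        with pytest.raises(ValueError, match="T9"):
            tg.select_representative_compounds(cs, table, {"T1", "T9"})


class TestHerbTargets:
    def test_truncation_to_available_genes(self):
        rows = [{"compound_id": f"C{i}", "gene": f"T{i % 5}", "herb": "BX"} for i in range(20)]
        table = tg.InteractionTable(pd.DataFrame(rows))
        assert len(tg.herb_core_targets(table, "BX", top_n=30)) <= 5

    def test_identical_subtables_give_identical_sets(self):
        rows = []
        for herb in ("BX", "GJ"):
            rows += [
                {"compound_id": f"{herb}_C{i}", "gene": f"T{i % 4}", "herb": herb}
                for i in range(16)
            ]
        table = tg.InteractionTable(pd.DataFrame(rows))
        assert tg.herb_core_targets(table, "BX") == tg.herb_core_targets(table, "GJ")

    def test_unknown_herb_rejected(self):
        table = tg.InteractionTable(
            pd.DataFrame([{"compound_id": "C1", "gene": "T1", "herb": "BX"}])
        )
        with pytest.raises(KeyError):
            tg.herb_core_targets(table, "ZZ")


class TestTargetOverlap:
    def test_published_drug_target_overlap_counts(self):
        """The formula's core targets share 8/6/3 genes with colitis, DM and
        GC drug targets (16 distinct in total)."""
        core = datasets.load_core_targets()
        by_disease = datasets.drug_targets_by_disease()
        counts = {d: tg.target_overlap(core, genes)[1] for d, genes in by_disease.items()}
        assert counts == {"colitis": 8, "DM": 6, "GC": 3}
        pooled = frozenset().union(*by_disease.values())
        assert tg.target_overlap(core, pooled)[1] == 16

    def test_disjoint_and_identity(self):
        assert tg.target_overlap({"A"}, {"B"})[1] == 0
        common, n = tg.target_overlap({"tnf", "IL6"}, {"TNF", "il6"})
        assert common == {"TNF", "IL6"} and n == 2
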