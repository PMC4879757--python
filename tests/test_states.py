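"""State calls, multi-class counting, co-occurrence permutation test, verdict."""

import numpy as np
import pandas as pd
import pytest

import polcoherence as pc
from polcoherence.exceptions import ParameterError, ValidationError

from conftest import random_matrix


def matrix_from_columns(cols: dict) -> pc.ExpressionMatrix:
    genes = list(cols)
    vals = np.column_stack([np.asarray(cols[g], dtype=float) for g in genes])
    return pc.ExpressionMatrix(vals, [f"c{i+1}" for i in range(vals.shape[0])], genes)


class TestCallStates:
    def test_classes_hit_at_very_high_tier(self, panel):
        m = matrix_from_columns({"Arg1": [150.0], "Tnf": [120.0], "Il4ra": [0.0]})
        (prof,) = pc.call_states(m, panel, tier=100.0)
        assert prof.classes_hit == {"M(IL4)", "M(LPS,IFNγ)"}
        assert prof.calls == {("Arg1", "M(IL4)"), ("Tnf", "M(LPS,IFNγ)")}

    def test_tier_comparison_is_strict(self, panel):
        m = matrix_from_columns({"Arg1": [100.0], "Tnf": [50.0]})
        (prof,) = pc.call_states(m, panel, tier=100.0)
        assert prof.calls == frozenset()

    def test_no_panel_genes_errors(self, panel):
        m = matrix_from_columns({"Xyz": [1.0], "Abc": [2.0]})
        with pytest.raises(ValidationError):
            pc.call_states(m, panel, tier=100.0)

    def test_aggregated_calls_match_positive_fraction(self, panel):
        m = random_matrix(seed=31, n_cells=25, n_genes=3)
        m = pc.ExpressionMatrix(m.values, m.cell_ids, ["Arg1", "Tnf", "Il4ra"])
        profiles = pc.call_states(m, panel, tier=0.1)
        for gene in m.gene_ids:
            n_calls = sum(
                any(g == gene for g, _ in p.calls) for p in profiles)
            assert n_calls == pc.positive_fraction(m, gene, 0.1, mode="gt").n_positive


class TestCountMulticlass:
    def _profiles(self, panel):
        m = matrix_from_columns(
            {"Arg1": [150.0, 150.0, 0.0], "Tnf": [120.0, 0.0, 0.0]})
        return pc.call_states(m, panel, tier=100.0)

    def test_brute_force_toy(self, panel):
        profiles = self._profiles(panel)
        # cell1 hits 2 classes, cell2 hits 1, cell3 hits 0
        assert pc.count_multiclass_cells(profiles, 2) == (1, pytest.approx(1 / 3))

    def test_all_zero_matrix(self, panel):
        m = matrix_from_columns({"Arg1": [0.0, 0.0], "Tnf": [0.0, 0.0]})
        count, frac = pc.count_multiclass_cells(pc.call_states(m, panel, 100.0), 2)
        assert (count, frac) == (0, 0.0)

    def test_min_classes_below_two_rejected(self, panel):
        with pytest.raises(ParameterError):
            pc.count_multiclass_cells(self._profiles(panel), 1)

    def test_non_increasing_in_min_classes_and_tier(self, panel):
        ds = pc.generate(pc.SimulationConfig(scenario="mixed", n_cells=60, seed=7))
        counts_by_tier = []
        for tier in (0.1, 1.0, 10.0, 100.0):
            profiles = pc.call_states(ds.matrix, panel, tier)
            by_k = [pc.count_multiclass_cells(profiles, k)[0] for k in (2, 3, 4)]
            assert by_k == sorted(by_k, reverse=True)
            counts_by_tier.append(by_k[0])
        assert counts_by_tier == sorted(counts_by_tier, reverse=True)


class TestCooccurrencePermutation:
    def test_perfect_exclusivity_detected(self, two_gene_panel):
        m = matrix_from_columns(
            {"a": [200.0] * 10 + [0.0] * 10, "b": [0.0] * 10 + [200.0] * 10})
        df = pc.cooccurrence_permutation(m, two_gene_panel, 100.0,
                                         n_perm=999, seed=0)
        row = df.iloc[0]
        assert row["n11"] == 0
        assert row["odds_ratio"] < 1
        assert row["perm_p"] <= 0.05

    def test_all_zero_gene_gives_corrected_or_and_p_one(self, two_gene_panel):
        m = matrix_from_columns(
            {"a": [200.0] * 10 + [0.0] * 10, "b": [0.0] * 20})
        df = pc.cooccurrence_permutation(m, two_gene_panel, 100.0,
                                         n_perm=99, seed=0)
        row = df.iloc[0]
        # counts (0,10,0,10) with +0.5 everywhere: OR = (0.5*10.5)/(10.5*0.5)
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["perm_p"] == 1.0

    def test_contingency_counts_sum_to_total(self, panel):
        ds = pc.generate(pc.SimulationConfig(scenario="mixed", n_cells=30, seed=2))
        df = pc.cooccurrence_permutation(ds.matrix, panel, 100.0, n_perm=99, seed=3)
        assert (df[["n11", "n10", "n01", "n00"]].sum(axis=1) == 30).all()
        assert (df["class_a"] != df["class_b"]).all()
        assert ((df["perm_p"] > 0) & (df["perm_p"] <= 1)).all()

    def test_same_seed_reproduces_exactly(self, panel):
        ds = pc.generate(pc.SimulationConfig(scenario="mixed", n_cells=40, seed=4))
        a = pc.cooccurrence_permutation(ds.matrix, panel, 100.0, n_perm=199, seed=11)
        b = pc.cooccurrence_permutation(ds.matrix, panel, 100.0, n_perm=199, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_invariant_to_cell_relabeling(self, panel):
        ds = pc.generate(pc.SimulationConfig(scenario="mixed", n_cells=40, seed=5))
        m = ds.matrix
        relabeled = pc.ExpressionMatrix(
            m.values, [f"x{i}" for i in range(m.n_cells)], m.gene_ids)
        a = pc.cooccurrence_permutation(m, panel, 100.0, n_perm=199, seed=12)
        b = pc.cooccurrence_permutation(relabeled, panel, 100.0, n_perm=199, seed=12)
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_errors(self):
        panel1 = pc.MarkerPanel({"a": "M(IL4)", "b": "M(IL4)"})
        m = matrix_from_columns({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        with pytest.raises(ValidationError):
            pc.cooccurrence_permutation(m, panel1, 0.5, n_perm=99, seed=0)

    def test_too_few_permutations_rejected(self, two_gene_panel):
        m = matrix_from_columns({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        with pytest.raises(ParameterError):
            pc.cooccurrence_permutation(m, two_gene_panel, 0.5, n_perm=10, seed=0)


class TestVerdict:
    def _row(self, perm_p, odds_ratio):
        return {"gene_a": "a", "class_a": "M(IL4)", "gene_b": "b",
                "class_b": "M(LPS,IFNγ)", "n11": 1, "n10": 1, "n01": 1, "n00": 1,
                "odds_ratio": odds_ratio, "log_odds_ratio": np.log(odds_ratio),
                "perm_p": perm_p, "n_permutations": 999}

    def test_single_pair_is_too_little_evidence(self):
        df = pd.DataFrame([self._row(0.2, 0.5)])
        assert pc.admixture_vs_mixed_verdict(df).verdict == "indeterminate"

    def test_exclusive_pairs_give_admixture(self):
        df = pd.DataFrame([self._row(0.001, 0.1)] * 12)
        v = pc.admixture_vs_mixed_verdict(df)
        assert v.verdict == "admixture-like"
        assert v.exclusive_significant_fraction == 1.0

    def test_chance_level_pairs_give_mixed_state(self):
        df = pd.DataFrame([self._row(0.6, 1.1)] * 12)
        assert pc.admixture_vs_mixed_verdict(df).verdict == "mixed-state-like"

    def test_intermediate_fraction_is_indeterminate(self):
        df = pd.DataFrame([self._row(0.001, 0.1)] * 3 + [self._row(0.6, 1.0)] * 9)
        assert pc.admixture_vs_mixed_verdict(df).verdict == "indeterminate"

    def test_empty_input_errors(self):
        with pytest.raises(ValidationError):
            pc.admixture_vs_mixed_verdict(pd.DataFrame())


def test_mixed_scenario_odds_ratios_center_on_one(panel):
    """Across-class odds ratios under independent activation have median
    within [0.8, 1.25] at n_cells = 1000."""
    ds = pc.generate(pc.SimulationConfig(scenario="mixed", n_cells=1000, seed=17))
    df = pc.cooccurrence_permutation(ds.matrix, panel, 100.0, n_perm=99, seed=18)
    assert 0.8 <= df["odds_ratio"].median() <= 1.25
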