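"""Pairwise regressions, positivity splits and predictability tests."""

import numpy as np
import pytest

import polcoherence as pc
from polcoherence.exceptions import DegenerateInputError, ValidationError

from conftest import random_matrix


def matrix_from_columns(cols: dict) -> pc.ExpressionMatrix:
    genes = list(cols)
    vals = np.column_stack([np.asarray(cols[g], dtype=float) for g in genes])
    return pc.ExpressionMatrix(vals, [f"c{i+1}" for i in range(vals.shape[0])], genes)


class TestPairRegression:
    def test_exact_linear_relation(self):
        m = matrix_from_columns({"a": [1, 2, 3], "b": [2, 4, 6]})
        r = pc.pair_regression(m, "a", "b")
        assert r.r_squared == pytest.approx(1.0)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(0.0)

    def test_zero_covariance_gives_zero_r_squared(self):
        # hand evaluation: cov(a,b) = E[ab] - E[a]E[b] = 2/3 - 1*(2/3) = 0
        m = matrix_from_columns({"a": [0, 1, 2], "b": [1, 0, 1]})
        assert pc.pair_regression(m, "a", "b").r_squared == pytest.approx(0.0)

    def test_constant_gene_is_degenerate_and_named(self):
        m = matrix_from_columns({"a": [1, 2, 3], "b": [5, 5, 5]})
        with pytest.raises(DegenerateInputError, match="b"):
            pc.pair_regression(m, "a", "b")

    def test_r_squared_symmetric_in_gene_order(self):
        m = random_matrix(seed=9, n_cells=20, n_genes=2)
        ab = pc.pair_regression(m, "g0", "g1").r_squared
        ba = pc.pair_regression(m, "g1", "g0").r_squared
        assert ab == pytest.approx(ba)

    def test_r_squared_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(4)
        a = rng.lognormal(0, 1, 25)
        b = rng.lognormal(0, 1, 25)
        m1 = matrix_from_columns({"a": a, "b": b})
        m2 = matrix_from_columns({"a": 3.5 * a + 7.0, "b": b})
        r1 = pc.pair_regression(m1, "a", "b").r_squared
        r2 = pc.pair_regression(m2, "a", "b").r_squared
        assert r1 == pytest.approx(r2)

    def test_log_scale_mode_changes_fit(self):
        rng = np.random.default_rng(5)
        a = rng.lognormal(2, 2, 30)
        b = a ** 1.5
        m = matrix_from_columns({"a": a, "b": b})
        lin = pc.pair_regression(m, "a", "b", scale="linear")
        log = pc.pair_regression(m, "a", "b", scale="log10p")
        assert log.scale == "log10p"
        assert log.r_squared > lin.r_squared  # power law linearises on log scale


class TestSplitByPositivity:
    def test_three_way_partition(self):
        m = matrix_from_columns({"g": [0.0, 0.05, 0.5, 5.0]})
        pos, neg, exc = pc.split_by_positivity(m, "g")
        assert (pos, neg, exc) == (["c4"], ["c1", "c2"], ["c3"])

    def test_all_above_positive_tier(self):
        m = matrix_from_columns({"g": [2.0, 3.0, 4.0]})
        pos, neg, exc = pc.split_by_positivity(m, "g")
        assert pos == ["c1", "c2", "c3"] and neg == [] and exc == []

    def test_all_zero(self):
        m = matrix_from_columns({"g": [0.0, 0.0, 0.0]})
        pos, neg, exc = pc.split_by_positivity(m, "g")
        assert pos == [] and len(neg) == 3

    def test_sets_partition_all_cells(self):
        m = random_matrix(seed=13, n_cells=40, n_genes=1)
        pos, neg, exc = pc.split_by_positivity(m, "g0")
        assert sorted(pos + neg + exc) == sorted(m.cell_ids)


class TestPredictabilityTest:
    def test_identical_response_distributions(self):
        m = matrix_from_columns(
            {"pred": [5.0, 5.0, 0.0, 0.0], "resp": [1.0, 2.0, 1.0, 2.0]})
        r = pc.predictability_test(m, "pred", "resp")
        assert r.applicable and r.p_value == 1.0
        assert r.mean_response_positive == r.mean_response_negative

    def test_exact_two_vs_two(self):
        m = matrix_from_columns(
            {"pred": [5.0, 5.0, 0.0, 0.0], "resp": [10.0, 20.0, 1.0, 2.0]})
        r = pc.predictability_test(m, "pred", "resp")
        assert r.p_value == pytest.approx(1 / 3)
        assert (r.n_positive, r.n_negative) == (2, 2)

    def test_predictor_expressed_everywhere_not_applicable(self):
        m = matrix_from_columns({"pred": [5.0, 6.0, 7.0], "resp": [1.0, 2.0, 3.0]})
        r = pc.predictability_test(m, "pred", "resp")
        assert r.applicable is False and r.p_value is None

    def test_intermediate_band_counted_not_tested(self):
        m = matrix_from_columns(
            {"pred": [5.0, 0.5, 0.0, 0.0], "resp": [1.0, 2.0, 3.0, 4.0]})
        r = pc.predictability_test(m, "pred", "resp")
        assert r.excluded_intermediate == 1
        assert r.n_positive + r.n_negative + r.excluded_intermediate == 4


class TestCoherenceScreen:
    def test_all_pairs_of_three_genes(self, panel):
        m = random_matrix(seed=21, n_cells=10, n_genes=3)
        m = pc.ExpressionMatrix(m.values, m.cell_ids, ["Arg1", "Tnf", "Il4ra"])
        df = pc.coherence_screen(m, panel, pairs="all")
        assert len(df) == 3  # C(3,2)

    def test_same_class_genes_give_empty_across_class_table(self, panel):
        m = random_matrix(seed=22, n_cells=10, n_genes=2)
        m = pc.ExpressionMatrix(m.values, m.cell_ids, ["Arg1", "Mrc1"])
        df = pc.coherence_screen(m, panel, pairs="across_class")
        assert len(df) == 0

    def test_single_panel_gene_errors(self, panel):
        m = random_matrix(seed=23, n_cells=10, n_genes=1)
        m = pc.ExpressionMatrix(m.values, m.cell_ids, ["Arg1"])
        with pytest.raises(ValidationError):
            pc.coherence_screen(m, panel)

    def test_degenerate_pairs_skipped(self, panel):
        vals = np.column_stack([np.arange(1.0, 11.0), np.full(10, 2.0),
                                np.arange(10.0, 0.0, -1.0)])
        m = pc.ExpressionMatrix(vals, [f"c{i}" for i in range(10)],
                                ["Arg1", "Tnf", "Il4ra"])
        df = pc.coherence_screen(m, panel, pairs="all")
        assert len(df) == 1  # only (Arg1, Il4ra) survives: Tnf is constant
        assert set(df[["gene_a", "gene_b"]].iloc[0]) == {"Arg1", "Il4ra"}

    def test_fdr_flag_adds_monotone_q_values(self, panel):
        m = random_matrix(seed=24, n_cells=30, n_genes=6)
        m = pc.ExpressionMatrix(m.values, m.cell_ids,
                                ["Arg1", "Mrc1", "Tnf", "Il1b", "Il4ra", "Cxcl3"])
        df = pc.coherence_screen(m, panel, pairs="all", fdr=True)
        assert "q_value" in df.columns
        assert (df["q_value"] >= df["p_value"] - 1e-12).all()

    def test_admixture_across_class_pairs_anticorrelated(self, panel):
        """Under a two-class admixture every across-class pair slopes down and
        its r² exceeds the median r² of an independent-marker null."""
        ds = pc.generate(pc.SimulationConfig(
            scenario="admixture", n_cells=100, seed=42,
            class_proportions={"M(IL4)": 0.5, "M(LPS,IFNγ)": 0.5}))
        df = pc.coherence_screen(ds.matrix, panel, pairs="across_class",
                                 scale="log10p")
        il4_lps = df[df["class_a"].isin(["M(IL4)", "M(LPS,IFNγ)"])
                     & df["class_b"].isin(["M(IL4)", "M(LPS,IFNγ)"])]
        null = pc.generate(pc.SimulationConfig(scenario="null", n_cells=100, seed=43))
        null_df = pc.coherence_screen(null.matrix, panel, pairs="across_class",
                                      scale="log10p")
        assert (il4_lps["slope"] < 0).all()
        assert (il4_lps["r_squared"] > null_df["r_squared"].median()).all()


def test_null_across_class_r_squared_median_below_0_1(panel):
    """Independent markers at the study's cell count stay in the near-zero
    r² regime: median across-class r² < 0.1 in every one of 100 seeds."""
    medians = []
    for seed in range(100):
        ds = pc.generate(pc.SimulationConfig(scenario="null", n_cells=45, seed=seed))
        df = pc.coherence_screen(ds.matrix, panel, pairs="across_class")
        medians.append(df["r_squared"].median())
    assert max(medians) < 0.1
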