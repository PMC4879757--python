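"""Replicated simulation studies over the synthetic scenarios.

These are the package's standard self-checks: type-I calibration of the
co-occurrence permutation test, calibration of the randomized-PCA null,
verdict accuracy under the two competing population hypotheses, and the
multi-class co-expression regime under mixed activation. Every study
derives its per-replicate seeds from a single master seed, so results are
reproducible end to end.
"""

from __future__ import annotations

import numpy as np

from .datatypes import ExpressionMatrix, Thresholds
from .simulate import SimulationConfig, generate
from .states import (admixture_vs_mixed_verdict, call_states,
                     cooccurrence_permutation, count_multiclass_cells)
from .structure import randomized_pca_null

__all__ = [
    "replicate_seeds",
    "cooccurrence_rejection_rate",
    "pca_null_median_p",
    "verdict_accuracy",
    "mixed_multiclass_fractions",
]


def replicate_seeds(master_seed: int, n: int, stream: int = 0) -> np.ndarray:
    """n reproducible per-replicate seeds (< 2**31) from one master seed."""
    rng = np.random.default_rng([master_seed, stream])
    return rng.integers(0, 2**31 - 1, size=2 * n).reshape(n, 2)


def cooccurrence_rejection_rate(
    n_replicates: int = 200,
    n_cells: int = 45,
    tier: float | None = None,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the co-occurrence test at level ``alpha``.

    Across-class marker calls under the ``mixed`` scenario are independent
    by construction, so every pair is a true null. The default tier is the
    positive tier (TPM > 1), where activation_prob 0.5 puts marker
    positivity near 50 % — margins near n/2 give the permutation null of a
    2×2 table its maximal support at small n, the regime in which a
    rejection-rate calibration is informative (sparser margins make the
    add-one permutation p conservative; see the methods note).
    """
    tier = Thresholds().positive_tpm if tier is None else tier
    rates = []
    for gen_seed, perm_seed in replicate_seeds(seed, n_replicates):
        ds = generate(SimulationConfig(scenario="mixed", n_cells=n_cells,
                                       seed=int(gen_seed)))
        cooc = cooccurrence_permutation(ds.matrix, ds.config.resolved_panel(),
                                        tier=tier, n_perm=n_perm,
                                        seed=int(perm_seed))
        rates.append(float((cooc["perm_p"] < alpha).mean()))
    return float(np.mean(rates))


def pca_null_median_p(
    n_seeds: int = 50,
    n_cells: int = 45,
    n_shuffles: int = 99,
    seed: int = 0,
) -> float:
    """Median randomized-PCA p-value on data that is itself a null draw.

    Each replicate takes an admixture draw (real structure), destroys it
    with a single within-gene permutation — producing a draw from the null
    — and checks that ``randomized_pca_null`` then sees nothing: the
    p-values should be uniform on the grid, median ≈ 0.5.
    """
    ps = []
    for gen_seed, perm_seed in replicate_seeds(seed, n_seeds, stream=1):
        ds = generate(SimulationConfig(scenario="admixture", n_cells=n_cells,
                                       seed=int(gen_seed)))
        panel = ds.config.resolved_panel()
        sub = ds.matrix.subset_genes(panel.genes)
        rng = np.random.default_rng(int(perm_seed))
        vals = rng.permuted(sub.values, axis=0)
        m = ExpressionMatrix(vals, sub.cell_ids, sub.gene_ids)
        scan = randomized_pca_null(m, n_shuffles=n_shuffles,
                                   seed=int(perm_seed) // 2 + 1)
        ps.append(scan.pc1_excess_p)
    return float(np.median(ps))


def verdict_accuracy(
    scenario: str,
    n_replicates: int = 100,
    n_cells: int = 200,
    tier: float = 100.0,
    n_perm: int = 499,
    seed: int = 0,
) -> float:
    """Fraction of replicates on which the pipeline verdict matches the
    generating hypothesis ("admixture-like" for admixture data,
    "mixed-state-like" for mixed data)."""
    expected = {"admixture": "admixture-like", "mixed": "mixed-state-like"}[scenario]
    stream = {"admixture": 2, "mixed": 3}[scenario]
    hits = 0
    for gen_seed, perm_seed in replicate_seeds(seed, n_replicates, stream=stream):
        ds = generate(SimulationConfig(scenario=scenario, n_cells=n_cells,
                                       seed=int(gen_seed)))
        cooc = cooccurrence_permutation(ds.matrix, ds.config.resolved_panel(),
                                        tier=tier, n_perm=n_perm,
                                        seed=int(perm_seed))
        if admixture_vs_mixed_verdict(cooc).verdict == expected:
            hits += 1
    return hits / n_replicates


def mixed_multiclass_fractions(
    n_replicates: int = 100,
    n_cells: int = 45,
    tier: float = 100.0,
    min_classes: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Per-replicate fraction of cells spanning ≥ min_classes classes under
    independent mixed activation at the study's cell count."""
    fracs = []
    for gen_seed, _ in replicate_seeds(seed, n_replicates, stream=4):
        ds = generate(SimulationConfig(scenario="mixed", n_cells=n_cells,
                                       seed=int(gen_seed)))
        profiles = call_states(ds.matrix, ds.config.resolved_panel(), tier)
        fracs.append(count_multiclass_cells(profiles, min_classes)[1])
    return np.asarray(fracs)
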