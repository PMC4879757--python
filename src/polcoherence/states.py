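"""Combinatorial activation-state calls and the co-occurrence permutation test.

A cell's *state profile* at a TPM tier is the set of panel markers it
expresses above the tier, projected onto polarization classes. Counting
cells whose profile spans two or more classes quantifies mixed activation.

"No more likely than at random" is formalised as a permutation test: each
gene's values are independently permuted across cells, which preserves
every gene's marginal distribution while destroying cross-gene structure
(the same null used for the randomized-order PCA comparison). Association
per across-class pair is the 2×2 odds ratio at the tier; two-sided testing
on |log OR| detects both mutual exclusivity (the admixture signature) and
excess co-occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, MarkerPanel
from .exceptions import ParameterError, ValidationError

__all__ = [
    "StateProfile",
    "VerdictSummary",
    "call_states",
    "count_multiclass_cells",
    "cooccurrence_permutation",
    "admixture_vs_mixed_verdict",
]


@dataclass(frozen=True)
class StateProfile:
    """Per-cell (gene, class) calls above a tier, and the classes they span."""

    cell_id: str
    calls: frozenset  # of (gene, class) pairs
    tier: float

    @property
    def classes_hit(self) -> frozenset:
        return frozenset(cls for _, cls in self.calls)


@dataclass(frozen=True)
class VerdictSummary:
    verdict: str  # "admixture-like" | "mixed-state-like" | "indeterminate"
    median_log_odds_ratio: float
    exclusive_significant_fraction: float
    n_pairs: int
    alpha: float


def call_states(
    m: ExpressionMatrix, panel: MarkerPanel, tier: float
) -> list[StateProfile]:
    """One profile per cell; a (gene, class) call requires TPM strictly > tier."""
    genes = [g for g in panel.genes if m.has_gene(g)]
    if not genes:
        raise ValidationError("no panel genes present in the matrix")
    sub = m.subset_genes(genes)
    hits = sub.values > tier
    profiles = []
    for i, cell in enumerate(sub.cell_ids):
        calls = frozenset(
            (g, panel.class_of(g)) for j, g in enumerate(genes) if hits[i, j]
        )
        profiles.append(StateProfile(cell, calls, float(tier)))
    return profiles


def count_multiclass_cells(
    profiles: list[StateProfile], min_classes: int = 2
) -> tuple[int, float]:
    """(count, fraction) of cells whose calls span ≥ ``min_classes`` classes."""
    if min_classes < 2:
        raise ParameterError("min_classes must be >= 2")
    if not profiles:
        raise ValidationError("no state profiles supplied")
    n = sum(1 for p in profiles if len(p.classes_hit) >= min_classes)
    return n, n / len(profiles)


def _odds_ratios(n11, n10, n01, n00):
    """Haldane-Anscombe: add 0.5 to every cell only when any cell is zero."""
    n11, n10, n01, n00 = (np.asarray(a, dtype=float) for a in (n11, n10, n01, n00))
    zero = (n11 == 0) | (n10 == 0) | (n01 == 0) | (n00 == 0)
    c = np.where(zero, 0.5, 0.0)
    return ((n11 + c) * (n00 + c)) / ((n10 + c) * (n01 + c))


def cooccurrence_permutation(
    m: ExpressionMatrix,
    panel: MarkerPanel,
    tier: float,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation test of across-class marker co-occurrence at a TPM tier.

    For every unordered pair of panel genes from *different* classes,
    builds the 2×2 contingency of positivity (TPM > tier), computes the
    odds ratio (Haldane-Anscombe 0.5 correction only when a cell count is
    zero), and compares |log OR| against ``n_perm`` within-gene
    permutations of the expression values. p-values use the add-one
    convention (1 + #extreme) / (n_perm + 1) and so are never zero.

    Returns a DataFrame with one row per pair: gene/class labels, the four
    counts, ``odds_ratio``, ``log_odds_ratio``, ``perm_p``, ``n_permutations``.
    """
    if n_perm < 99:
        raise ParameterError("n_perm must be >= 99")
    genes = [g for g in panel.genes if m.has_gene(g)]
    classes = {panel.class_of(g) for g in genes}
    if len(classes) < 2:
        raise ValidationError(
            "co-occurrence needs panel genes from at least 2 classes in the matrix"
        )
    sub = m.subset_genes(genes)
    B = sub.values > tier  # cells × genes boolean
    n_cells, n_genes = B.shape
    margins = B.sum(axis=0)

    pair_idx = [
        (i, j)
        for i, j in combinations(range(n_genes), 2)
        if panel.class_of(genes[i]) != panel.class_of(genes[j])
    ]
    if not pair_idx:
        raise ValidationError("no across-class gene pairs available")
    ii = np.array([i for i, _ in pair_idx])
    jj = np.array([j for _, j in pair_idx])

    co = (B.astype(np.int64).T @ B.astype(np.int64))  # genes × genes co-positivity
    n11 = co[ii, jj]
    n10 = margins[ii] - n11
    n01 = margins[jj] - n11
    n00 = n_cells - n11 - n10 - n01
    obs_or = _odds_ratios(n11, n10, n01, n00)
    obs_abs_log = np.abs(np.log(obs_or))

    # Null: permute every gene's column independently, n_perm times at once.
    rng = np.random.default_rng(seed)
    perm = np.broadcast_to(B, (n_perm, n_cells, n_genes)).copy()
    rng.permuted(perm, axis=1, out=perm)
    P = perm.astype(np.int64)
    co_p = np.einsum("pcg,pch->pgh", P, P)  # n_perm × genes × genes
    p11 = co_p[:, ii, jj]
    p10 = margins[ii][None, :] - p11
    p01 = margins[jj][None, :] - p11
    p00 = n_cells - p11 - p10 - p01
    perm_abs_log = np.abs(np.log(_odds_ratios(p11, p10, p01, p00)))
    n_extreme = (perm_abs_log >= obs_abs_log[None, :] - 1e-12).sum(axis=0)
    perm_p = (1.0 + n_extreme) / (n_perm + 1.0)

    return pd.DataFrame(
        {
            "gene_a": [genes[i] for i in ii],
            "class_a": [panel.class_of(genes[i]) for i in ii],
            "gene_b": [genes[j] for j in jj],
            "class_b": [panel.class_of(genes[j]) for j in jj],
            "n11": n11, "n10": n10, "n01": n01, "n00": n00,
            "odds_ratio": obs_or,
            "log_odds_ratio": np.log(obs_or),
            "perm_p": perm_p,
            "n_permutations": n_perm,
        }
    )


def admixture_vs_mixed_verdict(
    results: pd.DataFrame,
    alpha: float = 0.05,
    admixture_fraction: float = 0.5,
    mixed_fraction: float = 0.1,
    min_pairs: int = 10,
) -> VerdictSummary:
    """Summarise pairwise co-occurrence tests into a population-level verdict.

    The admixture hypothesis (mixture of singly-polarized cells) predicts
    widespread significant mutual exclusivity (OR < 1) across classes; the
    mixed-state hypothesis predicts chance-level co-occurrence. The verdict
    is "admixture-like" when the fraction of pairs with ``perm_p < alpha``
    and ``odds_ratio < 1`` exceeds ``admixture_fraction``,
    "mixed-state-like" when it is below ``mixed_fraction``, otherwise
    "indeterminate". Fewer than ``min_pairs`` pair tests is too little
    evidence for a population-level claim and yields "indeterminate"
    regardless of the fraction. Thresholds are package conventions and
    configurable.
    """
    if results is None or len(results) == 0:
        raise ValidationError("no across-class pair results to summarise")
    sig_excl = (results["perm_p"] < alpha) & (results["odds_ratio"] < 1.0)
    frac = float(sig_excl.mean())
    if len(results) < min_pairs:
        verdict = "indeterminate"
    elif frac > admixture_fraction:
        verdict = "admixture-like"
    elif frac < mixed_fraction:
        verdict = "mixed-state-like"
    else:
        verdict = "indeterminate"
    return VerdictSummary(
        verdict=verdict,
        median_log_odds_ratio=float(np.median(results["log_odds_ratio"])),
        exclusive_significant_fraction=frac,
        n_pairs=len(results),
        alpha=alpha,
    )
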