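"""Model/Results facade over the full polarization-coherence analysis.

``PolarizationCoherence`` bundles an expression matrix, a marker panel,
thresholds and (optionally) a QC table; ``fit()`` runs the whole pipeline
— QC filtering, detectability, the pairwise coherence screen, the
co-occurrence permutation test, multi-class state counting, the
randomized-PCA structure scan — and returns a
``PolarizationCoherenceResults`` object carrying the estimates, their
permutation p-values and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .coherence import coherence_screen
from .datatypes import CellQCRecord, ExpressionMatrix, MarkerPanel, Thresholds
from .exceptions import ValidationError
from .qc import detectable_genes, filter_cells, positive_fraction
from .states import (VerdictSummary, admixture_vs_mixed_verdict, call_states,
                     cooccurrence_permutation, count_multiclass_cells)
from .structure import StructureScanResult, randomized_pca_null, subset_scan

__all__ = ["PolarizationCoherence", "PolarizationCoherenceResults"]


class PolarizationCoherence:
    """Polarization-coherence model for a single-cell TPM matrix.

    Parameters
    ----------
    matrix
        Cells × genes TPM matrix.
    panel
        Marker panel (gene → polarization class); shipped default if None.
    thresholds
        Graded TPM tiers and QC cut-offs.
    qc
        Optional per-cell QC records; when given, cells failing QC are
        removed before analysis.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        panel: MarkerPanel | None = None,
        thresholds: Thresholds | None = None,
        qc: Sequence[CellQCRecord] | None = None,
    ) -> None:
        self.panel = panel if panel is not None else pio.default_marker_panel()
        self.thresholds = thresholds or Thresholds()
        self.qc = list(qc) if qc is not None else None
        if self.qc is not None:
            kept = filter_cells(self.qc, self.thresholds)
            kept_in_matrix = [c for c in matrix.cell_ids if c in set(kept)]
            if not kept_in_matrix:
                raise ValidationError("no cells pass QC")
            matrix = matrix.subset_cells(kept_in_matrix)
        self.matrix = matrix

    @classmethod
    def from_files(
        cls,
        matrix_path,
        panel_path=None,
        qc_path=None,
        matrix_format: str = "tsv",
        thresholds: Thresholds | None = None,
    ) -> "PolarizationCoherence":
        matrix = pio.load_expression_matrix(matrix_path, format=matrix_format)
        panel = pio.load_marker_panel(panel_path) if panel_path else None
        qc = pio.load_qc_table(qc_path) if qc_path else None
        return cls(matrix, panel=panel, thresholds=thresholds, qc=qc)

    def fit(
        self,
        tier: float | None = None,
        min_classes: int = 2,
        pairs: str = "across_class",
        scale: str = "linear",
        n_permutations: int = 999,
        n_shuffles: int = 99,
        seed: int | None = None,
    ) -> "PolarizationCoherenceResults":
        """Run the full analysis; ``tier`` defaults to the very-high tier."""
        th = self.thresholds
        tier = th.very_high_tpm if tier is None else tier
        m, panel = self.matrix, self.panel
        present = [g for g in panel.genes if m.has_gene(g)]

        detection = pd.DataFrame(
            [
                {
                    "gene": g,
                    "class": panel.class_of(g),
                    "tier": name,
                    "threshold": cut,
                    "fraction_positive": positive_fraction(m, g, cut, th)
                    .fraction_positive,
                }
                for g in present
                for name, cut in th.tiers.items()
            ]
        )
        screen = coherence_screen(m, panel, pairs=pairs, scale=scale, th=th)
        cooc = cooccurrence_permutation(
            m, panel, tier=tier, n_perm=n_permutations, seed=seed)
        verdict = admixture_vs_mixed_verdict(cooc)
        profiles = call_states(m, panel, tier=tier)
        n_multi, frac_multi = count_multiclass_cells(profiles, min_classes)
        structure = randomized_pca_null(
            m, genes=present, n_shuffles=n_shuffles, seed=seed)
        return PolarizationCoherenceResults(
            model=self,
            tier=tier,
            min_classes=min_classes,
            n_detectable_genes=len(detectable_genes(m, th)),
            detection=detection,
            coherence=screen,
            cooccurrence=cooc,
            verdict=verdict,
            state_profiles=profiles,
            n_multiclass=n_multi,
            fraction_multiclass=frac_multi,
            structure=structure,
        )


@dataclass
class PolarizationCoherenceResults:
    """Fitted results; tables are pandas DataFrames."""

    model: PolarizationCoherence
    tier: float
    min_classes: int
    n_detectable_genes: int
    detection: pd.DataFrame
    coherence: pd.DataFrame
    cooccurrence: pd.DataFrame
    verdict: VerdictSummary
    state_profiles: list = field(repr=False, default_factory=list)
    n_multiclass: int = 0
    fraction_multiclass: float = 0.0
    structure: StructureScanResult | None = None

    def summary(self) -> str:
        m = self.model.matrix
        v = self.verdict
        lines = [
            "Polarization-coherence analysis",
            "=" * 47,
            f"cells analysed                 {m.n_cells}",
            f"panel genes in matrix          "
            f"{sum(m.has_gene(g) for g in self.model.panel.genes)}"
            f"/{len(self.model.panel)}",
            f"detectable genes               {self.n_detectable_genes}",
            f"co-expression tier (TPM >)     {self.tier:g}",
            f"cells spanning >={self.min_classes} classes     "
            f"{self.n_multiclass}/{m.n_cells}"
            f" ({100 * self.fraction_multiclass:.1f}%)",
            "-" * 47,
            f"across-class pairs tested      {v.n_pairs}",
            f"median log odds ratio          {v.median_log_odds_ratio:+.3f}",
            f"signif. exclusive pairs        "
            f"{100 * v.exclusive_significant_fraction:.1f}% (alpha={v.alpha})",
            f"median across-class r^2        "
            f"{self.coherence['r_squared'].median():.4f}"
            if len(self.coherence) else "median across-class r^2        n/a",
        ]
        if self.structure is not None and self.structure.pc1_excess_p is not None:
            lines.append(
                f"PC1 vs randomized-order null   p = {self.structure.pc1_excess_p:.3f}")
        lines += ["-" * 47, f"verdict: {v.verdict}"]
        return "\n".join(lines)

    def scree_table(self) -> pd.DataFrame:
        """Per-component real vs null variance-explained proportions."""
        s = self.structure
        if s is None or s.real_profile is None:
            raise ValidationError("no structure scan in these results")
        nulls = np.array([p.variance_explained for p in s.null_profiles])
        return pd.DataFrame(
            {
                "component": np.arange(1, s.real_profile.n_components + 1),
                "real_proportion": s.real_profile.variance_explained,
                "null_mean": nulls.mean(axis=0),
                "null_q95": np.quantile(nulls, 0.95, axis=0),
            }
        )

    def plot_scree(self, ax=None):
        """Scree plot of real vs randomized-order variance explained."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.scree_table()
        ax.plot(t["component"], t["real_proportion"], "o-", label="observed")
        ax.plot(t["component"], t["null_mean"], "s--", label="randomized order")
        ax.fill_between(t["component"], 0, t["null_q95"], alpha=0.2,
                        label="null 95th pct")
        ax.set_xlabel("principal component")
        ax.set_ylabel("variance explained")
        ax.legend()
        return ax
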