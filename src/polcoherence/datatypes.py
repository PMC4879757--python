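"""Core data containers: expression matrix, QC records, marker panel, thresholds.

The expression scale throughout is TPM (transcripts per million) — a
length- and depth-normalised abundance that is non-negative and, in
single-cell data, spans four to five orders of magnitude with exact zeros
(dropout). Matrices are oriented cells-in-rows, genes-in-columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "CLASS_LABELS",
    "ExpressionMatrix",
    "CellQCRecord",
    "MarkerPanel",
    "Thresholds",
]

#: The four macrophage polarization classes, named by their prototypical
#: in-vitro inducing stimulus.
CLASS_LABELS: tuple[str, ...] = ("M(IL4)", "M(LPS,IFNγ)", "M(IL10)", "M(IC)")


class ExpressionMatrix:
    """Cells × genes matrix of non-negative TPM values.

    Parameters
    ----------
    values : array-like, shape (n_cells, n_genes)
        TPM values; must be finite and >= 0.
    cell_ids, gene_ids : sequence of str
        Unique row / column identifiers.
    """

    def __init__(
        self,
        values: np.ndarray | Sequence[Sequence[float]],
        cell_ids: Sequence[str],
        gene_ids: Sequence[str],
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        cell_ids = [str(c) for c in cell_ids]
        gene_ids = [str(g) for g in gene_ids]
        if values.shape != (len(cell_ids), len(gene_ids)):
            raise ValidationError(
                f"shape {values.shape} does not match {len(cell_ids)} cells "
                f"× {len(gene_ids)} genes"
            )
        if len(set(cell_ids)) != len(cell_ids):
            raise ValidationError("duplicate cell identifiers")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValidationError("duplicate gene identifiers")
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values must be finite (no NaN/inf)")
        if np.any(values < 0):
            raise ValidationError("negative expression value; TPM must be >= 0")
        self._values = values
        self._cell_ids = list(cell_ids)
        self._gene_ids = list(gene_ids)
        self._gene_index = {g: j for j, g in enumerate(gene_ids)}
        self._cell_index = {c: i for i, c in enumerate(cell_ids)}

    # ------------------------------------------------------------------ basic
    @property
    def values(self) -> np.ndarray:
        return self._values

    @property
    def cell_ids(self) -> list[str]:
        return list(self._cell_ids)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._gene_ids)

    @property
    def n_cells(self) -> int:
        return self._values.shape[0]

    @property
    def n_genes(self) -> int:
        return self._values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self._values.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.n_cells} cells × {self.n_genes} genes)"

    # -------------------------------------------------------------- accessors
    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def gene_values(self, gene: str) -> np.ndarray:
        """TPM vector of one gene across cells; absence is a data defect."""
        try:
            j = self._gene_index[gene]
        except KeyError:
            raise ValidationError(f"gene {gene!r} is not in the matrix") from None
        return self._values[:, j]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self._gene_index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing}")
        idx = [self._gene_index[g] for g in genes]
        return ExpressionMatrix(self._values[:, idx], self._cell_ids, genes)

    def subset_cells(self, cells: Iterable[str]) -> "ExpressionMatrix":
        cells = list(cells)
        missing = [c for c in cells if c not in self._cell_index]
        if missing:
            raise ValidationError(f"cells not in matrix: {missing}")
        idx = [self._cell_index[c] for c in cells]
        return ExpressionMatrix(self._values[idx, :], cells, self._gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._values, index=pd.Index(self._cell_ids, name="cell_id"),
            columns=self._gene_ids,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)),
                   list(df.columns.astype(str)))


@dataclass(frozen=True)
class CellQCRecord:
    """Per-cell sequencing QC metrics (inputs; alignment itself is out of scope)."""

    cell_id: str
    aligned_reads: float
    mapped_fraction: float

    def __post_init__(self) -> None:
        if self.aligned_reads < 0:
            raise ValidationError(
                f"{self.cell_id}: aligned_reads must be >= 0, got {self.aligned_reads}"
            )
        if not 0.0 <= self.mapped_fraction <= 1.0:
            raise ValidationError(
                f"{self.cell_id}: mapped_fraction must lie in [0, 1], "
                f"got {self.mapped_fraction}"
            )


class MarkerPanel:
    """Mapping gene symbol → polarization class, with a consensus-set flag.

    Gene symbols are matched case-sensitively by default; ``normalize=True``
    applies the mouse capitalise-first convention on construction (off by
    default because silent case-folding hides data errors).
    """

    def __init__(
        self,
        entries: Mapping[str, str] | Sequence[tuple[str, str]],
        consensus: Iterable[str] = (),
        normalize: bool = False,
    ) -> None:
        if isinstance(entries, Mapping):
            items = list(entries.items())
        else:
            items = list(entries)
        if normalize:
            items = [(g.capitalize(), c) for g, c in items]
            consensus = [g.capitalize() for g in consensus]
        seen: dict[str, str] = {}
        for gene, cls in items:
            if gene in seen:
                raise ValidationError(f"gene {gene!r} appears more than once in panel")
            if cls not in CLASS_LABELS:
                raise ValidationError(
                    f"unknown polarization class {cls!r} for gene {gene!r}; "
                    f"expected one of {CLASS_LABELS}"
                )
            seen[gene] = cls
        self._entries = seen
        self._consensus = frozenset(consensus)
        unknown = self._consensus - set(seen)
        if unknown:
            raise ValidationError(f"consensus genes not in panel: {sorted(unknown)}")

    @property
    def genes(self) -> list[str]:
        return list(self._entries)

    @property
    def classes(self) -> list[str]:
        """Distinct class labels present, in canonical order."""
        present = set(self._entries.values())
        return [c for c in CLASS_LABELS if c in present]

    def class_of(self, gene: str) -> str:
        try:
            return self._entries[gene]
        except KeyError:
            raise ValidationError(f"gene {gene!r} is not in the panel") from None

    def is_consensus(self, gene: str) -> bool:
        self.class_of(gene)  # raises if absent
        return gene in self._consensus

    def genes_of_class(self, cls: str) -> list[str]:
        return [g for g, c in self._entries.items() if c == cls]

    def consensus_subset(self) -> "MarkerPanel":
        return MarkerPanel(
            {g: c for g, c in self._entries.items() if g in self._consensus},
            consensus=self._consensus,
        )

    def items(self):
        return self._entries.items()

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self._entries

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MarkerPanel({len(self)} genes, {len(self.classes)} classes)"


@dataclass
class Thresholds:
    """Graded TPM cut-offs and cell-level QC cut-offs.

    The four expression tiers (detectable 0.1, positive 1, high 10,
    very-high 100 TPM) grade marker expression from barely measurable to
    extreme; ``detectable_cell_fraction`` is the fraction of cells a gene
    must exceed the detectable tier in to count as detectably expressed.
    QC keeps cells with at least ``min_aligned_reads`` aligned reads and at
    least ``min_mapped_fraction`` of reads mapped.
    """

    detectable_tpm: float = 0.1
    positive_tpm: float = 1.0
    high_tpm: float = 10.0
    very_high_tpm: float = 100.0
    detectable_cell_fraction: float = 0.5
    min_aligned_reads: float = 1e6
    min_mapped_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.detectable_tpm < self.positive_tpm
                < self.high_tpm < self.very_high_tpm):
            raise ValidationError(
                "TPM tiers must satisfy 0 < detectable < positive < high < very_high"
            )
        if not 0 < self.detectable_cell_fraction < 1:
            raise ValidationError("detectable_cell_fraction must lie in (0, 1)")

    @property
    def tiers(self) -> dict[str, float]:
        return {
            "detectable": self.detectable_tpm,
            "positive": self.positive_tpm,
            "high": self.high_tpm,
            "very_high": self.very_high_tpm,
        }
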