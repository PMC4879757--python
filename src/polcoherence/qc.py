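"""Cell-level QC filtering, gene detectability and graded positivity.

QC keeps cells meeting both sequencing-depth criteria (the exclusion rule
removes cells with *fewer than* the minimum, so boundary values pass).
Detectability asks whether a gene exceeds the detectable tier (TPM > 0.1)
in strictly more than half the cells; positivity fractions are reported at
any of the graded tiers. The coverage-association check tests whether
cells with exact-zero expression of a gene have systematically lower read
coverage — i.e. whether zeros look like undersampling rather than biology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import CellQCRecord, ExpressionMatrix, Thresholds
from .exceptions import ParameterError, ValidationError
from .stats import mann_whitney_u

__all__ = [
    "DetectionSummary",
    "CoverageAssociationResult",
    "filter_cells",
    "detectable_genes",
    "positive_fraction",
    "coverage_association",
]


@dataclass(frozen=True)
class DetectionSummary:
    """Positivity of one gene at one TPM cut-off."""

    gene: str
    threshold: float
    n_positive: int
    n_cells: int
    mode: str  # "gt" (strict >) or "ge" (>=)

    @property
    def fraction_positive(self) -> float:
        return self.n_positive / self.n_cells


@dataclass(frozen=True)
class CoverageAssociationResult:
    """Mann-Whitney comparison of aligned reads, zero- vs nonzero-expression cells."""

    gene: str
    n_zero_cells: int
    n_nonzero_cells: int
    u_statistic: float | None
    p_value: float | None
    applicable: bool


def filter_cells(
    qc: Sequence[CellQCRecord], th: Thresholds | None = None
) -> list[str]:
    """Identifiers of cells passing both QC criteria, in input order.

    A cell is kept when ``aligned_reads >= th.min_aligned_reads`` and
    ``mapped_fraction >= th.min_mapped_fraction``.
    """
    th = th or Thresholds()
    qc = list(qc)
    if not qc:
        raise ValidationError("QC table is empty")
    return [
        r.cell_id
        for r in qc
        if r.aligned_reads >= th.min_aligned_reads
        and r.mapped_fraction >= th.min_mapped_fraction
    ]


def detectable_genes(m: ExpressionMatrix, th: Thresholds | None = None) -> list[str]:
    """Genes with TPM > detectable tier in strictly more than half the cells.

    Both inequalities are strict: a gene at exactly the tier in a cell does
    not count, and a gene detected in exactly 50 % of cells is excluded.
    """
    th = th or Thresholds()
    if m.n_cells < 1:
        raise ValidationError("matrix has no cells")
    frac = (m.values > th.detectable_tpm).mean(axis=0)
    return [g for g, f in zip(m.gene_ids, frac) if f > th.detectable_cell_fraction]


def positive_fraction(
    m: ExpressionMatrix,
    gene: str,
    threshold: float,
    th: Thresholds | None = None,
    mode: str | None = None,
) -> DetectionSummary:
    """Fraction of cells positive for ``gene`` at ``threshold`` TPM.

    The comparison defaults to strict ``>`` except at the high tier
    (TPM ≥ 10), mirroring how the tiers are conventionally written; pass
    ``mode="gt"`` or ``mode="ge"`` to override.
    """
    th = th or Thresholds()
    if mode is None:
        mode = "ge" if threshold == th.high_tpm else "gt"
    if mode not in ("gt", "ge"):
        raise ParameterError(f"mode must be 'gt' or 'ge', got {mode!r}")
    v = m.gene_values(gene)
    n_pos = int(np.sum(v >= threshold) if mode == "ge" else np.sum(v > threshold))
    return DetectionSummary(gene, float(threshold), n_pos, m.n_cells, mode)


def coverage_association(
    m: ExpressionMatrix,
    qc: Sequence[CellQCRecord],
    gene: str,
) -> CoverageAssociationResult:
    """Are zero-expression cells for ``gene`` the low-coverage cells?

    Splits cells into exact-zero vs nonzero expressors and compares their
    aligned-read counts by a two-sided Mann-Whitney U test (exact
    enumeration when both groups have ≤ 8 cells). When either group is
    empty no test is possible and ``applicable`` is False.
    """
    reads = {r.cell_id: r.aligned_reads for r in qc}
    missing = [c for c in m.cell_ids if c not in reads]
    if missing:
        raise ValidationError(f"cells without QC records: {missing}")
    v = m.gene_values(gene)
    zero_mask = v == 0
    zero_reads = np.array([reads[c] for c, z in zip(m.cell_ids, zero_mask) if z])
    nonzero_reads = np.array([reads[c] for c, z in zip(m.cell_ids, zero_mask) if not z])
    if len(zero_reads) == 0 or len(nonzero_reads) == 0:
        return CoverageAssociationResult(
            gene, int(zero_mask.sum()), int((~zero_mask).sum()), None, None, False
        )
    u, p = mann_whitney_u(zero_reads, nonzero_reads)
    return CoverageAssociationResult(
        gene, len(zero_reads), len(nonzero_reads), u, p, True
    )
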