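"""Pairwise coherence of polarization markers.

If a cell population were an admixture of singly-polarized subsets, the
expression of two markers of the same class should rise and fall together
(high r²) and markers of different classes should be mutually exclusive.
This module measures that: ordinary least-squares regression / r² for gene
pairs, and the positivity-split predictability test — does being positive
for one marker (TPM > 1) predict the level of another, assessed by a
two-sided Mann-Whitney U test between positive and negative cells?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ExpressionMatrix, MarkerPanel, Thresholds
from .exceptions import DegenerateInputError, ParameterError, ValidationError
from .stats import mann_whitney_u

__all__ = [
    "PairRegressionResult",
    "PredictabilityResult",
    "pair_regression",
    "split_by_positivity",
    "predictability_test",
    "coherence_screen",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairRegressionResult:
    gene_a: str
    gene_b: str
    r_squared: float
    slope: float
    intercept: float
    p_value: float
    n_cells: int
    scale: str


@dataclass(frozen=True)
class PredictabilityResult:
    predictor: str
    response: str
    n_positive: int
    n_negative: int
    excluded_intermediate: int
    mean_response_positive: float | None
    mean_response_negative: float | None
    u_statistic: float | None
    p_value: float | None
    applicable: bool


def _transform(v: np.ndarray, scale: str) -> np.ndarray:
    if scale == "linear":
        return v
    if scale == "log10p":
        return np.log10(v + 1.0)
    raise ParameterError(f"scale must be 'linear' or 'log10p', got {scale!r}")


def pair_regression(
    m: ExpressionMatrix, gene_a: str, gene_b: str, scale: str = "linear"
) -> PairRegressionResult:
    """OLS of ``gene_b`` on ``gene_a``; r² is the squared Pearson correlation.

    ``scale="log10p"`` applies log10(TPM + 1) to both genes first. Either
    gene having zero variance makes the regression undefined and raises
    :class:`DegenerateInputError` naming the offending gene.
    """
    a = _transform(m.gene_values(gene_a), scale)
    b = _transform(m.gene_values(gene_b), scale)
    if len(a) < 3:
        raise ValidationError("pair regression needs at least 3 cells")
    for g, v in ((gene_a, a), (gene_b, b)):
        if np.ptp(v) == 0:
            raise DegenerateInputError(f"gene {g!r} has zero variance")
    fit = sps.linregress(a, b)
    return PairRegressionResult(
        gene_a=gene_a,
        gene_b=gene_b,
        r_squared=float(fit.rvalue) ** 2,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n_cells=len(a),
        scale=scale,
    )


def split_by_positivity(
    m: ExpressionMatrix, gene: str, th: Thresholds | None = None
) -> tuple[list[str], list[str], list[str]]:
    """Partition cells into (positive, negative, excluded) for ``gene``.

    Positive: TPM > positive tier (1). Negative: TPM ≤ detectable tier
    (0.1), covering true non-expressors. The ambiguous band
    (detectable, positive] is excluded rather than silently mislabelled;
    the three sets partition all cells.
    """
    th = th or Thresholds()
    v = m.gene_values(gene)
    pos, neg, exc = [], [], []
    for cell, x in zip(m.cell_ids, v):
        if x > th.positive_tpm:
            pos.append(cell)
        elif x <= th.detectable_tpm:
            neg.append(cell)
        else:
            exc.append(cell)
    return pos, neg, exc


def predictability_test(
    m: ExpressionMatrix,
    predictor: str,
    response: str,
    th: Thresholds | None = None,
) -> PredictabilityResult:
    """Does positivity for ``predictor`` predict the level of ``response``?

    Two-sided Mann-Whitney U on the response TPM between predictor-positive
    and predictor-negative cells (same engine as the coverage check). If
    either group is empty the result is flagged not-applicable instead of
    raising.
    """
    pos, neg, exc = split_by_positivity(m, predictor, th)
    resp = dict(zip(m.cell_ids, m.gene_values(response)))
    if not pos or not neg:
        return PredictabilityResult(
            predictor, response, len(pos), len(neg), len(exc),
            float(np.mean([resp[c] for c in pos])) if pos else None,
            float(np.mean([resp[c] for c in neg])) if neg else None,
            None, None, False,
        )
    rp = np.array([resp[c] for c in pos])
    rn = np.array([resp[c] for c in neg])
    u, p = mann_whitney_u(rp, rn)
    return PredictabilityResult(
        predictor, response, len(pos), len(neg), len(exc),
        float(rp.mean()), float(rn.mean()), u, p, True,
    )


def coherence_screen(
    m: ExpressionMatrix,
    panel: MarkerPanel,
    pairs: str = "all",
    scale: str = "linear",
    th: Thresholds | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Pairwise regressions over panel genes present in the matrix.

    Parameters
    ----------
    pairs
        ``"within_class"``, ``"across_class"`` or ``"all"`` — which
        unordered gene pairs to regress, by their class labels.
    fdr
        Add a Benjamini-Hochberg ``q_value`` column.

    Degenerate pairs (zero-variance gene) are skipped with a logged reason.
    """
    if pairs not in ("within_class", "across_class", "all"):
        raise ParameterError(f"invalid pair selection {pairs!r}")
    present = [g for g in panel.genes if m.has_gene(g)]
    if len(present) < 2:
        raise ValidationError("need at least 2 panel genes present in the matrix")
    rows = []
    for ga, gb in combinations(present, 2):
        ca, cb = panel.class_of(ga), panel.class_of(gb)
        if pairs == "within_class" and ca != cb:
            continue
        if pairs == "across_class" and ca == cb:
            continue
        try:
            r = pair_regression(m, ga, gb, scale=scale)
        except DegenerateInputError as exc:
            logger.info("skipping pair (%s, %s): %s", ga, gb, exc)
            continue
        rows.append(
            {
                "gene_a": ga, "class_a": ca, "gene_b": gb, "class_b": cb,
                "r_squared": r.r_squared, "slope": r.slope,
                "intercept": r.intercept, "p_value": r.p_value, "n": r.n_cells,
            }
        )
    cols = ["gene_a", "class_a", "gene_b", "class_b", "r_squared", "slope",
            "intercept", "p_value", "n"]
    df = pd.DataFrame(rows, columns=cols)
    if fdr and len(df):
        df["q_value"] = sps.false_discovery_control(df["p_value"], method="bh")
    return df
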