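"""Population-structure scan: PCA scree vs a randomized-order null, and a
hierarchical-clustering subset scan.

If a cell population contained discrete polarized subsets, PCA of the
marker submatrix would concentrate variance on the leading component and
hierarchical clustering would find well-separated groups. Both are judged
against a null in which each gene's values are independently permuted
across cells — preserving per-gene marginals exactly while destroying all
cross-gene correlation.

Because TPM spans 4-5 orders of magnitude, raw-scale PCA is dominated by a
handful of extreme genes; the default preprocessing is log10(TPM + 1)
followed by per-gene standardization (``log10p_zscore``), with ``raw`` and
``log10p`` selectable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .datatypes import ExpressionMatrix
from .exceptions import DegenerateInputError, ParameterError, ValidationError

__all__ = [
    "PcaProfile",
    "StructureScanResult",
    "top_variable_genes",
    "pca_profile",
    "randomized_pca_null",
    "subset_scan",
]

#: Mean-silhouette convention above which a clustering cut counts as an
#: "apparent subset"; a package convention, flagged as such in reports.
SILHOUETTE_THRESHOLD = 0.25


@dataclass(frozen=True)
class PcaProfile:
    variance_explained: np.ndarray  # proportions, non-increasing, sum <= 1
    n_components: int
    preprocessing: str
    genes_used: tuple[str, ...]


@dataclass
class StructureScanResult:
    real_profile: PcaProfile | None = None
    null_profiles: list[PcaProfile] = field(default_factory=list)
    pc1_excess_p: float | None = None
    subset_score: float | None = None
    subset_best_k: int | None = None
    subset_detected: bool | None = None


def top_variable_genes(m: ExpressionMatrix, fraction: float) -> list[str]:
    """Top ⌈fraction · n_genes⌉ genes by variance of log10(TPM + 1).

    Ties at the cut boundary are broken lexicographically (smaller gene
    symbol kept), so the selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must lie in (0, 1], got {fraction}")
    log_vals = np.log10(m.values + 1.0)
    variances = log_vals.var(axis=0)
    k = math.ceil(fraction * m.n_genes)
    order = sorted(zip(m.gene_ids, variances), key=lambda gv: (-gv[1], gv[0]))
    return [g for g, _ in order[:k]]


def _preprocess(values: np.ndarray, preprocessing: str) -> np.ndarray:
    if preprocessing == "raw":
        return values.astype(float)
    if preprocessing == "log10p":
        return np.log10(values + 1.0)
    if preprocessing == "log10p_zscore":
        x = np.log10(values + 1.0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0  # zero-variance genes are dropped upstream
        return (x - x.mean(axis=0)) / sd
    raise ParameterError(
        f"preprocessing must be raw|log10p|log10p_zscore, got {preprocessing!r}"
    )


def _prepared_submatrix(
    m: ExpressionMatrix, genes: list[str], preprocessing: str
) -> tuple[np.ndarray, list[str]]:
    if len(genes) < 2:
        raise ValidationError("need at least 2 genes")
    if m.n_cells < 3:
        raise ValidationError("need at least 3 cells")
    sub = m.subset_genes(genes)
    keep = np.ptp(sub.values, axis=0) > 0
    if not keep.any():
        raise DegenerateInputError("all selected genes have zero variance")
    if not keep.all():
        dropped = [g for g, k in zip(sub.gene_ids, keep) if not k]
        warnings.warn(f"dropping zero-variance genes: {dropped}", stacklevel=3)
    kept = [g for g, k in zip(sub.gene_ids, keep) if k]
    if len(kept) < 2:
        raise ValidationError("fewer than 2 genes with nonzero variance")
    return _preprocess(sub.values[:, keep], preprocessing), kept


def _scree(x: np.ndarray, preprocessing: str, genes: list[str]) -> PcaProfile:
    n_comp = min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp)
    pca.fit(x)
    return PcaProfile(
        variance_explained=pca.explained_variance_ratio_.copy(),
        n_components=n_comp,
        preprocessing=preprocessing,
        genes_used=tuple(genes),
    )


def pca_profile(
    m: ExpressionMatrix,
    genes: list[str] | None = None,
    preprocessing: str = "log10p_zscore",
) -> PcaProfile:
    """Scree profile (variance-explained proportions) of the gene submatrix.

    ``min(n_cells − 1, n_genes)`` components are reported; zero-variance
    genes are dropped with a warning, and an all-zero-variance selection
    raises.
    """
    genes = genes if genes is not None else m.gene_ids
    x, kept = _prepared_submatrix(m, list(genes), preprocessing)
    return _scree(x, preprocessing, kept)


def randomized_pca_null(
    m: ExpressionMatrix,
    genes: list[str] | None = None,
    n_shuffles: int = 99,
    seed: int | None = None,
    preprocessing: str = "log10p_zscore",
    shuffle: str = "within_gene",
) -> StructureScanResult:
    """Compare the real PC1 proportion against randomized-order data.

    ``shuffle="within_gene"`` (default) permutes each gene's values across
    cells independently; ``"global"`` shuffles the entire flattened matrix.
    ``pc1_excess_p`` = (1 + #{nulls with PC1 ≥ real PC1}) / (n_shuffles + 1).
    """
    if n_shuffles < 19:
        raise ParameterError("n_shuffles must be >= 19")
    if shuffle not in ("within_gene", "global"):
        raise ParameterError(f"shuffle must be within_gene|global, got {shuffle!r}")
    genes = genes if genes is not None else m.gene_ids
    x, kept = _prepared_submatrix(m, list(genes), preprocessing)
    real = _scree(x, preprocessing, kept)
    rng = np.random.default_rng(seed)
    nulls: list[PcaProfile] = []
    exceed = 0
    for _ in range(n_shuffles):
        if shuffle == "within_gene":
            xs = rng.permuted(x, axis=0)  # each column independently
        else:
            xs = rng.permutation(x.ravel()).reshape(x.shape)
        prof = _scree(xs, preprocessing, kept)
        nulls.append(prof)
        if prof.variance_explained[0] >= real.variance_explained[0]:
            exceed += 1
    return StructureScanResult(
        real_profile=real,
        null_profiles=nulls,
        pc1_excess_p=(1.0 + exceed) / (n_shuffles + 1.0),
    )


def subset_scan(
    m: ExpressionMatrix,
    genes: list[str] | None = None,
    max_k: int = 6,
    preprocessing: str = "log10p_zscore",
    silhouette_threshold: float = SILHOUETTE_THRESHOLD,
) -> StructureScanResult:
    """Hierarchical-clustering scan for discrete cell subsets.

    Average-linkage clustering on Euclidean distances of the preprocessed
    submatrix; cuts at k = 2..max_k are scored by mean silhouette and the
    best cut decides ``subset_detected``.
    """
    if max_k < 2:
        raise ParameterError("max_k must be >= 2")
    if m.n_cells < 4:
        raise ValidationError("subset scan needs at least 4 cells")
    genes = genes if genes is not None else m.gene_ids
    x, _ = _prepared_submatrix(m, list(genes), preprocessing)
    Z = linkage(x, method="average", metric="euclidean")
    best_score, best_k = -1.0, None
    for k in range(2, min(max_k, m.n_cells - 1) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = float(silhouette_score(x, labels, metric="euclidean"))
        if score > best_score:
            best_score, best_k = score, k
    if best_k is None:
        raise DegenerateInputError("no clustering cut produced >= 2 groups")
    return StructureScanResult(
        subset_score=best_score,
        subset_best_k=best_k,
        subset_detected=best_score > silhouette_threshold,
    )
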