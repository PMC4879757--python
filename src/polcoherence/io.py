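"""Readers and writers for expression matrices, QC tables and marker panels.

Formats
-------
TSV matrix
    First column ``cell_id``, remaining columns gene symbols, tab-delimited,
    UTF-8, cells in rows.
MatrixMarket (MTX)
    Stored genes × cells (community convention) and transposed on load;
    sidecar files ``genes.tsv`` and ``barcodes.tsv`` carry row/column names,
    one identifier per line.
Marker panel
    TSV with header ``gene<TAB>class<TAB>consensus`` (consensus ∈ {0, 1}).
QC table
    TSV with columns ``cell_id``, ``aligned_reads``, ``mapped_fraction``.

Round-trips through either matrix format preserve values to full float64
precision.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import CellQCRecord, ExpressionMatrix, MarkerPanel
from .exceptions import FormatError, ValidationError

__all__ = [
    "load_expression_matrix",
    "write_expression_matrix",
    "load_marker_panel",
    "default_marker_panel",
    "write_marker_panel",
    "load_qc_table",
    "write_qc_table",
]


# ----------------------------------------------------------------- matrices
def load_expression_matrix(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read a cells × genes TPM matrix.

    Parameters
    ----------
    path
        TSV file, or (for ``format="mtx"``) the ``.mtx`` file whose directory
        also holds ``genes.tsv`` and ``barcodes.tsv``.
    format
        ``"tsv"`` or ``"mtx"``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "tsv":
        return _load_tsv(path)
    if format == "mtx":
        return _load_mtx(path)
    raise FormatError(f"unknown matrix format {format!r}; expected 'tsv' or 'mtx'")


def _load_tsv(path: Path) -> ExpressionMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    # pandas would silently rename duplicate columns; catch them up front
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"{path}: duplicate column identifiers {dupes}")
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2 or df.columns[0] != "cell_id":
        raise FormatError(
            f"{path}: expected first column 'cell_id' followed by gene columns"
        )
    df = df.set_index("cell_id")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionMatrix(values, list(df.index), list(df.columns))


def _read_names(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing {what} sidecar file: {path}")
    names = [ln.split("\t")[0].strip() for ln in
             path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    return names


def _load_mtx(path: Path) -> ExpressionMatrix:
    genes = _read_names(path.parent / "genes.tsv", "gene-name")
    cells = _read_names(path.parent / "barcodes.tsv", "cell-barcode")
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"{path}: MTX declares {mat.shape[0]}×{mat.shape[1]} (genes × cells) "
            f"but sidecars list {len(genes)} genes and {len(cells)} barcodes"
        )
    return ExpressionMatrix(mat.T, cells, genes)


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, format: str = "tsv"
) -> None:
    """Write a matrix in TSV (cells × genes) or MTX (genes × cells + sidecars)."""
    path = Path(path)
    if format == "tsv":
        m.to_frame().to_csv(path, sep="\t")
    elif format == "mtx":
        coo = scipy.sparse.coo_matrix(m.values.T)
        # precision=17 → 17 significant digits: exact float64 round-trip
        scipy.io.mmwrite(str(path), coo, precision=17)
        (path.parent / "genes.tsv").write_text(
            "".join(g + "\n" for g in m.gene_ids), encoding="utf-8")
        (path.parent / "barcodes.tsv").write_text(
            "".join(c + "\n" for c in m.cell_ids), encoding="utf-8")
    else:
        raise FormatError(f"unknown matrix format {format!r}")


# -------------------------------------------------------------------- panels
def load_marker_panel(path: str | Path, normalize: bool = False) -> MarkerPanel:
    """Read a marker panel TSV (``gene<TAB>class<TAB>consensus``)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "class"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: panel needs columns {sorted(required)}")
    consensus: list[str] = []
    if "consensus" in df.columns:
        flags = df["consensus"].astype(str).str.strip()
        bad = ~flags.isin({"0", "1"})
        if bad.any():
            raise FormatError(f"{path}: consensus column must be 0 or 1")
        consensus = list(df.loc[flags == "1", "gene"])
    entries = list(zip(df["gene"].astype(str), df["class"].astype(str)))
    return MarkerPanel(entries, consensus=consensus, normalize=normalize)


def default_marker_panel() -> MarkerPanel:
    """The shipped panel: the marker genes with explicit class assignments.

    Covers all four classes — M(IL4) wound-healing, M(LPS,IFNγ)
    inflammatory, M(IL10) regulatory and M(IC) immune-complex markers — and
    is user-replaceable by any panel file in the same format (the full
    74-gene panel can be supplied that way).
    """
    with importlib.resources.as_file(
        importlib.resources.files("polcoherence.data") / "default_panel.tsv"
    ) as p:
        return load_marker_panel(p)


def write_marker_panel(panel: MarkerPanel, path: str | Path) -> None:
    rows = [
        {"gene": g, "class": c, "consensus": int(panel.is_consensus(g))}
        for g, c in panel.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- QC tables
def load_qc_table(path: str | Path) -> list[CellQCRecord]:
    """Read per-cell QC metrics; one :class:`CellQCRecord` per row."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    required = ["cell_id", "aligned_reads", "mapped_fraction"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: QC table missing columns {missing}")
    if df["cell_id"].duplicated().any():
        dupes = sorted(df.loc[df["cell_id"].duplicated(), "cell_id"].unique())
        raise ValidationError(f"duplicated cell ids in QC table: {dupes}")
    return [
        CellQCRecord(str(r.cell_id), float(r.aligned_reads), float(r.mapped_fraction))
        for r in df.itertuples(index=False)
    ]


def write_qc_table(records: Sequence[CellQCRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"cell_id": r.cell_id, "aligned_reads": r.aligned_reads,
             "mapped_fraction": r.mapped_fraction}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
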