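"""Seeded synthetic-data generator for the competing population hypotheses.

Three scenarios formalise what a mixed bulk polarization signature could
mean at single-cell resolution:

``admixture``
    Each cell is polarized to exactly one class; its own class's markers
    are drawn from a high lognormal, every other class's markers from a
    low lognormal. Predicts mutual exclusivity of cross-class markers.
``mixed``
    Each cell independently activates each class (probability
    ``activation_prob``); markers of active classes are high, others low.
    Cross-class co-occurrence is exactly chance level.
``null``
    No activation at all — every marker low. Used for calibration.

Markers and background genes are lognormal — reproducing the 4-5
order-of-magnitude spread of single-cell TPM — with entry-wise dropout
(exact zeros) applied after sampling. The default high mean (ln 200)
places active markers above the very-high tier (TPM > 100) most of the
time. All draws flow from one seeded generator: same config + seed ⇒
bit-identical output.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .datatypes import CellQCRecord, ExpressionMatrix, MarkerPanel
from .exceptions import ParameterError
from .io import default_marker_panel, write_expression_matrix, write_qc_table

__all__ = ["SimulationConfig", "SimulatedDataset", "generate", "generate_qc",
           "fixture_suite"]

SCENARIOS = ("admixture", "mixed", "null")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults emulate the 45-cell study regime."""

    scenario: str = "mixed"
    n_cells: int = 45
    panel: MarkerPanel | None = None  # None → shipped default panel
    n_background_genes: int = 500
    class_proportions: Mapping[str, float] | None = None  # admixture; None → equal
    activation_prob: float = 0.5  # mixed
    mu_high: float = math.log(200.0)  # log-scale mean, active markers
    mu_low: float = math.log(0.5)  # log-scale mean, inactive markers/background
    sigma: float = 1.0  # log-scale sd
    dropout_prob: float = 0.2  # entry-wise exact-zero probability
    qc_fail_fraction: float = 0.3  # fraction of cells generated to fail QC
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ParameterError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        for name in ("activation_prob", "dropout_prob", "qc_fail_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.sigma < 0:
            raise ParameterError("sigma must be >= 0")
        if self.mu_high <= self.mu_low:
            raise ParameterError("mu_high must exceed mu_low")
        if self.class_proportions is not None:
            total = sum(self.class_proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ParameterError(
                    f"class_proportions must sum to 1, got {total}")

    def resolved_panel(self) -> MarkerPanel:
        return self.panel if self.panel is not None else default_marker_panel()


@dataclass(frozen=True)
class SimulatedDataset:
    matrix: ExpressionMatrix
    qc: list[CellQCRecord]
    true_labels: list  # per-cell class label (admixture) or active-class frozenset
    config: SimulationConfig


def _largest_remainder_counts(
    proportions: Mapping[str, float], classes: list[str], n: int
) -> dict[str, int]:
    """Deterministic integer allocation of n cells to classes."""
    quotas = {c: proportions[c] * n for c in classes}
    counts = {c: int(math.floor(quotas[c])) for c in classes}
    short = n - sum(counts.values())
    by_remainder = sorted(
        classes, key=lambda c: (-(quotas[c] - counts[c]), classes.index(c)))
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


def generate(config: SimulationConfig) -> SimulatedDataset:
    """Draw one synthetic dataset (matrix + QC table + true labels)."""
    panel = config.resolved_panel()
    classes = panel.classes
    rng = np.random.default_rng(config.seed)
    marker_genes = panel.genes
    bg_genes = [f"BG{i:04d}" for i in range(config.n_background_genes)]
    gene_ids = marker_genes + bg_genes
    cell_ids = [f"cell{i:03d}" for i in range(config.n_cells)]
    n, g = config.n_cells, len(gene_ids)

    # Which (cell, marker) entries are "active" (drawn from the high regime)
    active = np.zeros((n, len(marker_genes)), dtype=bool)
    gene_class = np.array([classes.index(panel.class_of(m)) for m in marker_genes])
    if config.scenario == "admixture":
        props = (config.class_proportions
                 or {c: 1.0 / len(classes) for c in classes})
        unknown = set(props) - set(classes)
        if unknown:
            raise ParameterError(f"proportions for classes not in panel: {unknown}")
        alloc_classes = [c for c in classes if c in props]
        counts = _largest_remainder_counts(props, alloc_classes, n)
        labels = [c for c in alloc_classes for _ in range(counts.get(c, 0))]
        labels = [labels[i] for i in rng.permutation(n)]
        cell_class = np.array([classes.index(c) for c in labels])
        active = gene_class[None, :] == cell_class[:, None]
        true_labels: list = labels
    elif config.scenario == "mixed":
        act = rng.random((n, len(classes))) < config.activation_prob
        active = act[:, gene_class]
        true_labels = [
            frozenset(c for k, c in enumerate(classes) if act[i, k])
            for i in range(n)
        ]
    else:  # null
        true_labels = [frozenset() for _ in range(n)]

    mu = np.full((n, g), config.mu_low)
    mu[:, : len(marker_genes)][active] = config.mu_high
    z = rng.standard_normal((n, g))
    values = np.exp(mu + config.sigma * z)
    if config.dropout_prob > 0:
        values[rng.random((n, g)) < config.dropout_prob] = 0.0

    matrix = ExpressionMatrix(values, cell_ids, gene_ids)
    return SimulatedDataset(matrix, generate_qc(config), true_labels, config)


def generate_qc(config: SimulationConfig) -> list[CellQCRecord]:
    """Per-cell QC metrics calibrated so the standard filter removes
    ``ceil(qc_fail_fraction · n_cells)`` cells.

    Failing cells violate exactly one criterion, alternating between too
    few aligned reads and too low a mapped fraction; passing cells clear
    both thresholds with margin. Seeded independently of the expression
    draw so matrix and QC generation can be reproduced separately.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_cells
    n_fail = math.ceil(config.qc_fail_fraction * n - 1e-9)
    fail_idx = set(rng.permutation(n)[:n_fail].tolist())
    records = []
    fail_rank = 0
    for i in range(n):
        if i in fail_idx:
            if fail_rank % 2 == 0:  # too few aligned reads
                reads = rng.uniform(1e5, 9e5)
                mapped = rng.uniform(0.6, 0.95)
            else:  # too low mapped fraction
                reads = rng.uniform(2e6, 8e6)
                mapped = rng.uniform(0.05, 0.45)
            fail_rank += 1
        else:
            reads = rng.uniform(2e6, 8e6)
            mapped = rng.uniform(0.6, 0.95)
        records.append(CellQCRecord(f"cell{i:03d}", float(reads), float(mapped)))
    return records


def _labels_text(ds: SimulatedDataset) -> str:
    lines = ["cell_id\tlabel"]
    for cell, lab in zip(ds.matrix.cell_ids, ds.true_labels):
        if isinstance(lab, frozenset):
            lab = ";".join(sorted(lab))
        lines.append(f"{cell}\t{lab}")
    return "\n".join(lines) + "\n"


def fixture_suite(out_dir: str | Path, seed: int = 0) -> dict:
    """Write one small dataset per scenario (TSV + MTX + labels + manifest).

    Output is byte-identical for the same seed. Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "scenarios": {}}
    for scenario in SCENARIOS:
        ds = generate(SimulationConfig(scenario=scenario, seed=seed))
        sub = out_dir / scenario
        sub.mkdir(exist_ok=True)
        write_expression_matrix(ds.matrix, sub / "matrix.tsv", format="tsv")
        write_expression_matrix(ds.matrix, sub / "matrix.mtx", format="mtx")
        write_qc_table(ds.qc, sub / "qc.tsv")
        (sub / "labels.tsv").write_text(_labels_text(ds), encoding="utf-8")
        digest = hashlib.sha256(
            (sub / "matrix.tsv").read_bytes()).hexdigest()
        manifest["scenarios"][scenario] = {
            "n_cells": ds.matrix.n_cells,
            "n_genes": ds.matrix.n_genes,
            "matrix_tsv_sha256": digest,
            "files": ["matrix.tsv", "matrix.mtx", "genes.tsv", "barcodes.tsv",
                      "qc.tsv", "labels.tsv"],
        }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return manifest
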