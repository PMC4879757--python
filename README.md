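# polcoherence

Single-cell polarization-coherence analysis for macrophage marker panels.

## The problem

Bulk profiling of monocyte-derived macrophages in injured tissue routinely
shows "mixed" polarization signatures — classical/inflammatory
M(LPS,IFNγ) markers such as *Il1b* and *Tnf* alongside
alternative/wound-healing M(IL4) markers such as *Arg1* and *Mrc1*. At the
population level this is ambiguous between two hypotheses:

- **Admixture** — the population is a mixture of singly-polarized subsets.
  Within a cell, markers of different classes should then be *mutually
  exclusive*, and markers of the same class should rise and fall together.
- **Mixed state** — individual cells genuinely co-express programs of
  several classes. Cross-class co-occurrence within cells should then be
  *no rarer than chance*.

Single-cell TPM matrices can separate these, but only with explicit
statistics. `polcoherence` provides them as a tested pipeline for anyone
analysing threshold-based marker panels in small single-cell data sets:
cell-level QC, graded positivity, pairwise coherence, permutation nulls,
and combinatorial co-expression-state counting — plus a seeded synthetic
generator that emulates both hypotheses so every stage is testable without
any external download.

## The statistics at the core

For genes *g*, *h* in a panel mapping genes to classes
{M(IL4), M(LPS,IFNγ), M(IL10), M(IC)} and a TPM tier *t* (graded tiers
0.1 / 1 / 10 / 100):

- **Positivity / detectability** — fraction of cells with TPM > *t*
  (the high tier 10 uses ≥); a gene is *detectable* if TPM > 0.1 in
  strictly more than 50 % of cells.
- **Pairwise coherence** — OLS of *h* on *g*; r² = squared Pearson
  correlation; plus a positivity-split test: cells with *g* > 1 TPM vs
  cells with *g* ≤ 0.1 TPM, two-sided Mann-Whitney U on the level of *h*
  (exact enumeration when both groups ≤ 8).
- **Co-occurrence test** — for each across-class pair, the 2×2 table of
  positivity at tier *t*; odds ratio OR (Haldane-Anscombe 0.5 only when a
  cell count is 0); null built by independently permuting each gene's
  values across cells, which preserves marginals and destroys cross-gene
  structure; p = (1 + #{|log OR*| ≥ |log OR|}) / (n_perm + 1).
- **Verdict** — fraction of across-class pairs with p < 0.05 and OR < 1:
  above 0.5 ⇒ "admixture-like", below 0.1 ⇒ "mixed-state-like"
  (≥ 10 pairs required; thresholds configurable).
- **Structure scan** — PCA scree of the marker submatrix
  (log10(TPM+1), per-gene z-score) against the same randomized-order
  null, and an average-linkage hierarchical clustering scan scored by
  mean silhouette.
- **State counting** — a cell's state profile at tier *t* is the set of
  (gene, class) calls with TPM > *t*; multi-class cells are those whose
  calls span ≥ k distinct classes.

## Worked example

```python
import polcoherence as pc

# a 45-cell data set under the mixed-activation hypothesis
ds = pc.generate(pc.SimulationConfig(scenario="mixed", n_cells=45, seed=7))

model = pc.PolarizationCoherence(ds.matrix)          # shipped default panel
res = model.fit(n_permutations=999, n_shuffles=99, seed=7)
print(res.summary())
```

```
Polarization-coherence analysis
===============================================
cells analysed                 45
panel genes in matrix          20/20
detectable genes               520
co-expression tier (TPM >)     100
cells spanning >=2 classes     24/45 (53.3%)
-----------------------------------------------
across-class pairs tested      138
median log odds ratio          +0.000
signif. exclusive pairs        0.0% (alpha=0.05)
median across-class r^2        0.0065
PC1 vs randomized-order null   p = 0.010
-----------------------------------------------
verdict: mixed-state-like
```

Reading this: a majority of cells (53.3 %) co-express markers of at least
two distinct polarization classes above the very-high tier (TPM > 100),
across-class marker pairs show essentially no linear relationship
(median r² ≈ 0.007), and no pair is significantly mutually exclusive —
expressing one class's marker does not predict repression of another's,
so the population looks mixed-state, not admixed. (The PC1 line says the
marker matrix has *some* correlation structure relative to the
randomized-order null — here the within-class co-activation the generator
builds in — which is compatible with either hypothesis; exclusivity is
what separates them.)

The same analyses are available as a CLI
(`polcoherence qc|detect|coherence|states|structure|simulate`), each
subcommand emitting TSV + JSON reports, e.g.

```sh
polcoherence simulate --scenario admixture --n-cells 45 --seed 7 --out-dir sim/
polcoherence states --matrix sim/matrix.tsv --tier 100 --n-perm 999 --seed 7 --out-dir out/
```

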