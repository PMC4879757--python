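# Methods

This note documents the statistical procedures, conventions and design
choices behind `polcoherence`, and what the synthetic-data studies do and
do not establish.

## Data model and thresholds

The pipeline consumes a cells × genes matrix of TPM (transcripts per
million): non-negative, exact zeros allowed (dropout), typically spanning
4–5 orders of magnitude in single-cell data. No normalisation is applied —
TPM is taken as given; alignment and quantification are out of scope, as
are doublet detection and ambient-RNA correction.

Graded TPM tiers (all overridable via `Thresholds` or the CLI `--config`
YAML):

| tier | cut-off (TPM) | comparison | meaning |
|---|---|---|---|
| detectable | 0.1 | strict > | above measurement floor |
| positive | 1 | strict > | unambiguous expression |
| high | 10 | ≥ | strong expression |
| very-high | 100 | strict > | extreme expression; the co-expression tier |

The high tier uses ≥ and the others strict >, mirroring how the tiers are
conventionally quoted; the comparison is an explicit parameter wherever it
matters. Cell-level QC keeps cells with ≥ 1 × 10⁶ aligned reads **and**
≥ 50 % of reads mapped — the exclusion rule removes cells with *fewer
than* the minima, so boundary values pass. A gene is *detectable* when it
exceeds the detectable tier in strictly more than 50 % of cells.

Gene symbols are matched case-sensitively (a capitalise-first
normalisation flag exists but is off by default: silent case-folding hides
data errors), and a panel gene absent from the matrix is an error for
single-gene operations, not an implicit zero — absence is a data defect,
not biology. Screens over the whole panel operate on the panel ∩ matrix
intersection.

The shipped default panel carries the 20 markers with explicit class
assignments across M(IL4), M(LPS,IFNγ), M(IL10) and M(IC); the
`consensus` flag marks the widely cited consensus markers and is an
editorial convention. Any panel in the same three-column TSV format can be
substituted, including a full 74-gene panel.

## Rank tests

All two-group comparisons (coverage association, positivity-split
predictability) use a two-sided Mann-Whitney U. When both groups have ≤ 8
observations the permutation distribution of U is enumerated exactly over
all C(n, n₁) group assignments with midrank tie handling (p = fraction of
assignments whose |U − n₁n₂/2| is at least the observed); larger groups
use the tie-corrected normal approximation with continuity correction.
The exact path is hand-rolled because standard exact implementations do
not handle ties, and tied TPM values (especially zeros) are the norm here.

The positivity split assigns cells with predictor TPM > 1 to the positive
group and TPM ≤ 0.1 to the negative group; the ambiguous band (0.1, 1] is
excluded and its size reported, rather than silently mislabelled. An
empty group yields a flagged not-applicable result, not an exception.

## Pairwise coherence

`pair_regression` is OLS of gene b on gene a with r² the squared Pearson
correlation; the default scale is raw TPM, with log10(TPM+1) selectable
(which of the two a published figure used is often unknowable — both are
provided). A zero-variance gene makes the regression undefined and raises
an error naming the gene; the screen skips such pairs with a logged
reason. No multiple-testing correction is applied by default; a
Benjamini-Hochberg flag adds q-values.

## The co-occurrence permutation test

"No more likely than at random" is operationalised with a single null used
everywhere in the package: **independent within-gene permutation** of
expression values across cells, which preserves every gene's marginal
multiset exactly while destroying all cross-gene structure. For each
across-class pair the statistic is |log OR| of the 2×2 positivity table at
the tier, with the Haldane-Anscombe +0.5 applied to all four cells only
when some cell count is zero (in observed and permuted tables alike).
Two-sided testing on |log OR| detects both mutual exclusivity (the
admixture signature, OR < 1) and excess co-occurrence. p-values use the
add-one convention (1 + #extreme)/(n_perm + 1) and are never zero;
permutation ties with the observed statistic count as extreme (compared
with 10⁻¹² slack against float noise). Identical seeds give bit-identical
results; the implementation permutes all genes for all permutations in
one vectorised pass, so 999 permutations on 45 × 20 data cost milliseconds.

### Verdict rule

The population-level verdict summarises the pair table by the fraction of
across-class pairs with p < α (default 0.05) **and** OR < 1:

- fraction > 0.5 → **admixture-like**
- fraction < 0.1 → **mixed-state-like**
- otherwise, or fewer than 10 pairs tested → **indeterminate**

The 0.5/0.1 cut-offs and the 10-pair minimum are package conventions
(configurable); the minimum exists because a population-level claim from a
single pair test is not evidence of anything.

### Power and the verdict's operating size

A permutation test on a 2×2 table needs enough cells to resolve
exclusivity. With four equal classes at 45 cells, a perfectly exclusive
pair has margins ≈ 7/45 vs 7/45, and the null probability of observing
n₁₁ = 0 is ≈ 0.28 — no pair can reach α = 0.05 regardless of effect size.
At 200 cells the same construction gives margins ≈ 30/200 and null
P(n₁₁ = 0) ≈ 0.008, and essentially every truly exclusive pair rejects.
The hypothesis-discrimination study therefore runs the verdict at 200
cells (measured: 100/100 admixture replicates verdict "admixture-like",
98–99/100 mixed replicates "mixed-state-like", at 499 permutations); the
45-cell default remains the generator's study-scale setting for
everything else. At 45 cells the honest verdict on admixture data is
typically "indeterminate-to-mixed" — a power limitation users should know
before applying the verdict to very small data sets.

### Type-I calibration

The calibration study uses across-class pairs under the `mixed` scenario,
which are true nulls by construction (class activations are independent),
at the positive tier, where activation probability 0.5 puts marker
positivity near 50 %. Margins near n/2 give the permutation null of a 2×2
table its maximal support at n = 45 — the regime in which a
rejection-rate calibration is informative. Measured empirical rate at
α = 0.05: ≈ 0.034 (200 replicates × 138 pairs, 999 permutations), within
the 0.05 ± 0.02 band. At sparser margins the add-one permutation p is
*conservative* by discreteness, never anticonservative: measured rates at
45 cells are ≈ 0.019 (≈ 20 % positivity) to ≈ 0.030 (≈ 30 % positivity),
while at 1000 cells the same test gives ≈ 0.043 at any informative tier.
Practically: at small n the test under-rejects, so a significant
exclusivity finding is trustworthy and a null result is the part that
needs the power analysis above.

## Structure scan

PCA runs on the marker (or top-variable-gene) submatrix after
log10(TPM+1) and per-gene z-scoring by default — raw-scale PCA on data
spanning 4–5 decades is dominated by a handful of extreme genes; raw and
unstandardised-log modes are selectable. `min(n_cells − 1, n_genes)`
components are reported; zero-variance genes are dropped with a warning.
Variable genes are ranked by variance of log10(TPM+1) with lexicographic
tie-breaking, so selections are deterministic.

The randomized-order comparison permutes each gene's values across cells
independently (the same null as the co-occurrence test; a whole-matrix
global shuffle is available behind a flag) and reports
pc1_excess_p = (1 + #{null PC1 ≥ real PC1})/(n_shuffles + 1). On data
that is itself a null draw the p-values are uniform on the grid (measured
median ≈ 0.5 over 50 seeds); on two-class admixture data at 100 cells
p ≤ 0.05 at 99 shuffles. Note PC1 excess indicates *any* cross-gene
correlation — including within-class co-activation — and is therefore not
by itself evidence for admixture.

The subset scan is average-linkage hierarchical clustering on Euclidean
distances of the preprocessed submatrix, cut at k = 2..max_k and scored
by mean silhouette; "apparent subsets" means best silhouette > 0.25, an
explicit package convention flagged in reports. On iid noise at 45 cells
this flags subsets in ≲ 10 % of seeds; on well-separated clouds it
recovers k = 2 with silhouette ≈ 1.

## Synthetic-data generator

The generator emulates a small Fluidigm-C1-scale experiment: default 45
cells, a 20-marker panel plus 500 background genes, lognormal expression,
entry-wise dropout, and a QC table calibrated to the study's attrition.

| parameter | default | rationale |
|---|---|---|
| n_cells | 45 | the study scale after QC |
| mu_high | ln 200 | active markers mostly above the very-high tier |
| mu_low | ln 0.5 | inactive markers/background near the detection floor |
| sigma | 1.0 | gives the observed 4–5 decade spread with dropout |
| dropout_prob | 0.2 | placeholder convention; no empirical rate available |
| activation_prob | 0.5 | mixed scenario: each class an independent coin flip |
| qc_fail_fraction | 0.3 | mirrors 18-of-63 library attrition |

Scenarios: `admixture` assigns each cell one class by deterministic
largest-remainder allocation of the class proportions (then a seeded
shuffle), making class counts exact for assertions; `mixed` activates
each class independently per cell; `null` activates nothing. Active
markers draw LogNormal(mu_high, sigma), everything else
LogNormal(mu_low, sigma); dropout zeros entries afterwards. QC metrics
are drawn so failing cells violate exactly one criterion (alternating
which) and passing cells clear both with margin. Same config + seed ⇒
bit-identical output, including the on-disk fixture suite.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: library-size/TPM compositional coupling,
expression-dependent dropout (dropout here is flat, real dropout is
abundance-dependent), gene-gene correlation beyond the class-block
structure, transition/continuum states between polarization programs, and
batch effects. Results on real matrices should lean on the calibration
properties (which hold under any marginals) rather than on effect sizes
matched to the generator.

## Numerical conventions

- Matrix round-trips are bit-faithful: TSV is written with shortest-repr
  floats and read with the round-trip parser; MatrixMarket is written at
  17 significant digits, genes × cells with name sidecars, transposed on
  load.
- Permutation and shuffle p-values use the add-one convention; equality
  with the observed statistic counts as extreme (10⁻¹² slack).
- Ties in variable-gene ranking break lexicographically; largest-remainder
  allocation breaks remainder ties by canonical class order.
- Replicated studies derive per-replicate seeds from one master seed via a
  seeded integer stream (all < 2³¹).
- Study sizes used by the standard self-checks: calibration 200 replicates
  × 45 cells × 999 permutations; PCA-null calibration 50 seeds × 99
  shuffles; discrimination 100 replicates per scenario × 200 cells × 499
  permutations; these run in ~30 s on one CPU.

## Known limitations

- The verdict is a two-point summary of a rich pair table; inspect the
  per-pair odds ratios before trusting it on borderline data.
- At ≤ 45 cells the co-occurrence test is conservative and low-powered
  (see above); "mixed-state-like" at that scale is weaker evidence than
  the same verdict at 200 cells.
- The predictability split discards the (0.1, 1] TPM band; with many
  cells in that band the test loses power (the count is reported).
- Exact Mann-Whitney enumeration is O(C(n, n₁)) and capped at 8 per
  group; beyond that the normal approximation is used even when an exact
  test would be feasible.
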