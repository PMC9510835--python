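# Methods

## Scope and data model

The package implements a case/control biomarker-discovery funnel for
bulk expression data: genes × samples log2-scale matrix (assumed already
normalized), a phenotype table with groups `AS`/`HC`, optional batch
labels and an optional 0–10 severity score for cases. Probe-level
preprocessing (RMA of CEL files) is out of scope; a GEO series-matrix
reader and a probe-collapse step (max-variance probe by default, mean as
an option) connect the pipeline to real deposits.

## Synthetic data: what it emulates and what it does not

The generator follows a single-latent-factor-per-module model:

    x[g,s] = mu_g + lambda * f_m(s) + delta * 1[g disc.] * 1[s case]
             + b(batch(s)) + eps,    eps ~ N(0, noise_sd^2)

with one standard-normal factor per module and per sample. Trait linkage
has two separate ground truths by design: a *module-level* shift (the
factor of trait-linked modules gains `factor_trait_shift` in cases,
default 1.0) and a *gene-level* shift (`trait_effect`, default 1.5 log2
units, on the discriminative genes). This keeps module–trait selection
and DE screening distinguishable recovery targets. Discriminative genes
alternate between trait-linked-module members and background genes so
both kinds of DE truth exist.

Defaults mirror a whole-blood microarray cohort: 52 cases + 20 controls,
2000 genes, four planted modules of 100 genes, loading 0.8, unit noise,
60 discriminative genes, no missingness or batches unless requested.
Severity exists for cases only (as a 10-cm VAS-style score would),
generated as `coupling ×` mean standardized driver expression plus noise,
affinely rescaled into [0, 10].

What the generator does *not* emulate: heavy-tailed intensity noise,
correlated probe effects, mean–variance coupling, nested module
structure, and realistic protein-interaction topology (the planted graph
is Erdős–Rényi plus boosted-degree hubs). Passing recovery tests
therefore demonstrates that each algorithm recovers the structure it is
designed for, not that it is robust to every artifact of real arrays.

## Preprocessing

Missing cells are imputed gene-wise (classical KNNimpute orientation:
neighbors are genes, Euclidean distance over shared observed samples,
k = 10), delegated to scikit-learn's `KNNImputer` with genes as rows;
observed values are never altered, making the step idempotent. Batch
adjustment is a per-gene location adjustment — every batch mean is moved
to the gene's grand mean — not empirical-Bayes ComBat: ComBat's
shrinkage buys little over plain location adjustment for the additive
batch offsets the generator plants, and the exact adjustment removes
them completely.
A consequence worth knowing: after adjustment the between-batch F
statistic is ~0 (below the batch-free null), because a degree of freedom
has been spent equalizing the means. The variance filter keeps the top
25% of genes by sample variance (denominator n − 1, ties broken by gene
id). Pipeline order is fixed: impute → batch adjust → filter, with DE
run on the unfiltered (imputed, adjusted) matrix and the network built
on the filtered one.

## Co-expression network

Unsigned adjacency a = |cor|^beta (signed variant available). The
scale-free fit index bins connectivities into 10 equal-width bins and
regresses log10(frequency) on log10(mean k); the index is
−sign(slope)·R², so a decaying power law scores +1. The scan chooses the
smallest power in 1..20 reaching 0.9, falling back to the maximizing
power with a warning. On strongly modular synthetic data no power may
reach 0.9 (the connectivity distribution is bimodal rather than
scale-free); the fallback then tends to very high powers, which weakens
topological overlap — a known behavior to keep in mind when simulating
strong signal.

TOM follows the standard unsigned formula with TOM_ii = 1. Module
detection clusters 1 − TOM by average linkage with a static cut at
height 0.995; clusters below 30 genes become `grey`. Because a high
power compresses every TOM value toward zero (pushing all merges above
any fixed cut), the detector falls back — only when the static cut
yields no module at all — to cutting at the largest gap in the upper
linkage heights, which separates cohesive blocks from the background
independently of the overall scale. This replaces the
dynamic hybrid tree cut of the reference WGCNA implementation: the
static cut plus eigengene merging (merge when eigengene dissimilarity
1 − cor < 0.25, iterated to a fixed point) is simpler, fully
deterministic, and its correctness is defined by the recovery tests
(planted-module ARI = 1.0 at loading 0.9/noise 0.5 across seeds).
Module colors follow the conventional vocabulary in decreasing size
order; `grey` is reserved for unassigned genes but is eligible for
module–trait selection like any module (flagged in the output table).

Eigengenes are unit-norm first right-singular vectors of the
gene-standardized module submatrix, sign-anchored to correlate
non-negatively with the module mean profile. Module–trait correlation is
Pearson r against the 0/1 case indicator with Student-t p-values
(df = n − 2); selection cutoff |r| ≥ 0.3. Gene significance GS =
|cor(gene, trait)| and module membership MM = cor(gene, eigengene) are
reported with per-module cor(|MM|, GS).

Module preservation is a permutation Z of mean intramodular adjacency:
observed mean within-module adjacency versus the null of same-size
uniformly drawn gene sets (100 permutations). This is a deliberately
lighter statistic than the reference modulePreservation Z-summary; it
flags cohesive modules (planted modules score far above same-run null
modules; pure-noise "modules" stay within |Z| < 3).

## Differential expression

Moderated t with the standard hierarchical variance model. The prior is
fitted by moment matching on log variances: trigamma(d0/2) = var(e) −
trigamma(d_g/2) solved by bracketed root finding (d0 = ∞ when the
observed spread does not exceed sampling noise, then s0² is the mean
variance). Filters are strict: adjusted P < 0.01 and |log2FC| > 1 — the
fold-change cut is interpreted on the log2 scale (a natural-scale
|FC| > 1 would exclude nothing). Calibration is verified: type-I rate
0.048 at nominal 0.05 under the null; (d0 = 4, s0² = 1) recovered within
1%/0.2% at 20 000 genes.

Power note: at the half-cohort size 26 + 10 and unit noise, the
fold-change estimate has standard error ≈ 0.372, so jointly requiring
|log2FC| > 1 and BH-0.01 leaves per-gene power ≈ 0.67 for a pure 1.5-unit
shift; measured recall of planted DE genes is ≈ 0.75 (false-discovery
proportion ≈ 0.03). Recall above 0.8 needs either larger effects,
module-correlated signal on top of the shift, or the full cohort.

## GSEA

Signal-to-noise ranking with the classic floor (sd ≥ 0.2·|mean|, then
0.2 if still zero), weighted KS running sum (weight p = 1 by default,
p = 0 exposed), ES = extremum of the walk, leading edge on the extremum
side. Significance by permutation with the add-one rule, so p ≥
1/(n_perm + 1): phenotype mode re-ranks under shuffled labels (requires
≥ 7 per group, else auto-switches to gene-set mode), gene-set mode draws
random member sets on the fixed ranking. Run per selected module, the
ranked universe is restricted to the module's genes and the top-10 sets
by p are reported. No NES or cross-set FDR — reporting uses the nominal
P < 0.05 cut only. Null gene-set-mode p-values are uniform (Kolmogorov
distance ≈ 0.04 at 100 sets × 500 permutations).

## Hub ranking

The twelve centralities follow the cytoHubba-style definitions, all
oriented so larger = more central: harmonic Closeness and reciprocal
Eccentricity handle disconnected graphs (unreachable pairs contribute
zero); Radiality uses the component diameter; Stress counts shortest
paths through a node; MNC/DMNC use the largest connected component of
the neighbor-induced subgraph (DMNC exponent fixed at 1.7); MCC sums
(|C| − 1)! over maximal cliques; BottleNeck counts BFS-tree roots for
which the node gates more than a quarter of the component, with the
tree made deterministic by a smallest-parent-id rule (this makes the
score reproducible but — unavoidably — label-dependent on ties); EPC is
a seeded Monte Carlo with edge-keep probability 0.5, the natural choice
for unweighted graphs. All deterministic measures are verified against
brute-force path/clique enumeration on every non-isomorphic graph with
up to 6 nodes, and EPC against exact edge-subset enumeration.

Consensus rule: top ceil(0.25·n) per measure (ties by node id), hub ⇔
present in ≥ 5 of the 12 lists ("more than 4", read strictly).

## SVM-RFE

Ranking uses a linear SVM (C = 1) because the weight vector w — and
hence the |w|² elimination criterion — exists only for linear decision
functions; the CV classifier kernel is configurable (linear default,
RBF available) for users who prefer a nonlinear classifier once the
ranking is fixed (an RBF SVM has no per-feature weight vector, so it
cannot drive the elimination itself).
Features are standardized inside each training fold only (verified: test
folds cannot influence the scalers). Elimination is one feature per
iteration, ties removed larger-index-first. The CV curve uses stratified
5-fold splits with a seeded shuffle; k* is the smallest k attaining the
minimum mean error.

Selection behavior worth knowing: because the ranking is computed once
on all samples before cross-validation (the classic SVM-RFE protocol,
which trades a little optimism for a single stable ranking), top-k
prefixes often separate every fold perfectly on clean synthetic data;
the error curve then plateaus at exactly 0 and the smallest-k tie rule
makes k* small. The selected signature is consequently high-precision
but deliberately parsimonious — recall against a large planted set is
bounded by k*, and the recovery report therefore also states recall
restricted to the candidates that entered the selection stage.

## Evaluation

AUC = Mann–Whitney U/(n1·n2) with half-credit ties; two-sided p from the
tie-corrected normal approximation (fully tied data → p = 1). Group
differences by one-way ANOVA (two-group F equals t², verified to 1e-10).
Severity correlations are Pearson over cases with non-missing scores
only. Recovery metrics: adjusted Rand index between detected colors and
planted module indices computed over planted-module genes (background
genes have no true module and are excluded on the truth side), plus
precision/recall of the DE, hub and key-gene sets against their planted
counterparts.

## Numerical and design choices

- All randomness flows from a single seed through named sub-seeds
  (SeedSequence), so re-running a stage with a different seed leaves the
  others bit-identical; all seeds stay below 2^31.
- Ties are broken deterministically everywhere (gene/node id
  lexicographic; larger feature index first in RFE).
- Missing-value tokens accepted on input: empty, `NA`, `NaN`, `null`
  (case-insensitive). Readers fail loudly with line numbers rather than
  coercing.
- Degenerate inputs are contracts, not crashes: single batch → identity
  with a notice; all-correlated matrix → the soft-threshold scan raises
  a degeneracy error; whole-universe gene set → ES = 1 with a warning;
  sets absent from the universe are skipped with a notice.
- Problem sizes in the test-bed runs (560-gene module recovery, 500-gene
  trait scans, 2000 × 72 pipeline, 20 000-gene prior recovery) were
  chosen to make every planted structure identifiable while keeping a
  full run of the suite and the acceptance script interactive.

## Known limitations

- Single-dataset analysis only: no multi-cohort consensus modules, no
  block-wise decomposition for very large gene sets (> ~20 k genes will
  be slow and memory-hungry since TOM is dense).
- Batch handling is location-only; scale or latent batch effects need an
  external tool before import.
- The module detector's static cut is tuned for well-separated factor
  modules; overlapping or nested modules will merge or fragment.
- GSEA reports nominal p-values only; multiple-collection control is the
  caller's responsibility.
- The severity model is linear in standardized expression; threshold or
  saturating dose–response relationships are not simulated.
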