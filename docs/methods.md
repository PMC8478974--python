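# Methods

This note documents the models behind each module, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Synthetic atlas generator

The generator (`eyeatlas.synthetic`) produces counts whose mean
structure is assembled in four layers, all recorded in `GroundTruth`:

1. **Low-rank background.** A non-negative amplitude matrix (background
   gene rows drawn Gamma(shape 2, scale 1) per pattern) times a
   pattern×type weight matrix in which each pattern prefers one type;
   weight columns are scaled to a common sum so a flat amplitude row
   yields the same base mean in every type.
2. **Planted genes at a constant baseline.** TFs, their target blocks,
   markers and ligand/receptor genes all sit at the *expected*
   background level (shape × rank). Because their baseline is constant
   across types, a multiplicative boost of `marker_fold` (default 4)
   translates directly into an in-type/out-type mean ratio of ≈ 4 after
   library-size effects cancel.
3. **Balanced activation.** TF module blocks (default: one block per
   cell type) switch on in one type each; a TF's own gene and its
   targets are boosted there. Spreading exactly one block, one marker
   set and a similar share of ligand/receptor boosts over every type
   keeps the per-type boost mass balanced, so per-type library
   normalization does not distort the planted fold changes.
4. **Progenitor flattening.** The first type's *background* profile is
   mixed toward its expected level with weight `potency_flatten`
   (default 0.7). Only background rows are flattened: planted rows are
   already flat, and leaving them untouched preserves both the marker
   folds and the column mass. The resulting higher-entropy profile is
   what makes the progenitor score highest on network entropy (SR).

Counts are gamma-Poisson (negative binomial with one global dispersion,
default 0.25) around cell-specific log-normal library sizes (log-mean
8.5 ≈ 5000 counts, log-sd 0.35), then thinned by independent dropout
(default rate 0.2). These defaults sit in the range typical of
droplet-based single-cell RNA-seq at moderate depth. Additional species
reuse the amplitude rows of the ortholog-shared gene fraction (default
0.7) and draw fresh background rows for the remainder; their gene order
is shuffled and identifiers carry a species prefix, so every
cross-species operation is forced through the explicit two-column
ortholog map.

**What the generator does not emulate:** batch and donor effects,
ambient RNA, doublets, realistic gene-length or GC biases, gene–gene
correlation beyond the planted low-rank/TF structure, and realistic
gene names. Tests passing on this generator therefore demonstrate that
each method recovers the structure it targets under clean, overdispersed,
dropout-thinned counts — not that it is robust to every artefact of
real tissue data.

## Marker detection

One-sided rank-sum test per gene (group greater than rest). Totals of
≤ 12 cells are handled by exhaustive enumeration of label splits on
midranks, which is exact under ties; larger samples use the
tie-corrected normal approximation *without* continuity correction, so
swapping the groups maps p to 1 − p exactly. A gene tied across every
cell carries no information and reports p = 0.5 (the statistic at its
null mean) rather than the degenerate enumeration value. The effect
size is avg_log2FC = log2((mean_in + 1)/(mean_out + 1)) on
back-transformed (expm1) normalized values — the +1-pseudocount
convention common in single-cell practice. Defaults p < 0.01,
|avg_log2FC| > 0.25; p-values are reported raw (no multiplicity
adjustment) with an optional Benjamini–Hochberg flag in the enrichment
table only.

## Clustering

`cluster_cells` is a deliberately conventional stack — dispersion-ranked
highly variable genes, PCA, kNN graph, Leiden communities — standing in
for "unsupervised graph clustering"; scanpy provides every step, and
the seed fixes PCA initialisation, neighbour graph and community
detection. Degenerate input (no varying gene) returns a single cluster
without touching the graph machinery.

## Diffusion imputation

Adaptive-bandwidth kernel exp(−(d/σᵢ)^decay) with σᵢ the distance to the
ka-th neighbour, symmetrised by summation, then row-normalised; the
imputed matrix is the operator's t-th power applied to cell profiles.
Defaults k = 15, ka = 4, decay = 2, t = 3, n_pcs = 20, chosen as
moderate smoothing for datasets of 10²–10⁴ cells; all are recorded in
the operator's parameter sidecar because no single setting suits every
dataset. Imputation runs on log-normalized values since its consumers
(co-expression, combined TF scores) are correlation-based and therefore
scale-sensitive. Each imputed value is a convex combination of observed
values of the same gene, so per-gene ranges can only shrink. Exact
row-identity for duplicated cells holds on the full affinity graph; with
kNN truncation, third cells may tie-break their neighbour lists
arbitrarily between duplicates, which perturbs incoming edges — an
inherent property of kNN graphs, not of the kernel.

## Regulons and TF modules

Regulon inference keeps the co-expression stage only: per TF, the top
`n_targets` positively associated genes by Spearman correlation (or
extra-trees importance in `method="trees"`). Motif-based pruning is
replaced by the positive-association filter; this is a stand-in, and
regulons here are "co-expression regulons".

Activity is the rank-AUC: genes ranked per cell by expression
descending, ties broken by one seeded global gene permutation
(deterministic and unbiased across cells), and the target-set recovery
curve integrated over the top ⌈top_frac·n_genes⌉ ranks, normalized by
the best achievable curve. Because only ranks enter, any monotone
per-cell transform of expression leaves activity unchanged.

The combined TF score is the equal-weight sum of the z-scored activity
and z-scored imputed TF expression, re-standardized per TF; the weight
is exposed because no canonical combination exists. Modules come from
average-linkage clustering of 1 − r on the TF×TF Pearson matrix. When
the module count is not given, the tree cut is chosen to maximize the
total within-module pairwise correlation *in excess of* a floor
(`min_intra_r`, default 0.3), over clusters of at least `min_size`
(default 3) TFs. The excess form matters: maximizing the mean picks a
single tightest cluster, and maximizing the raw total merges blocks
across weakly positive cross-correlations; penalizing each pair by the
floor does neither, and the floor also guarantees that mutually
independent TFs yield no modules. Conservation across species is the
Pearson correlation of a TF's per-type mean combined score across
explicitly matched cell types (at least three, else the correlation is
meaningless), with the ortholog map as a required input.

## Patterns

`learn_patterns` is deterministic multiplicative-update NMF minimizing
squared reconstruction error, seeded initialisation, with the objective
asserted non-increasing at every iteration and convergence at relative
change < 1e-6 (or 500 iterations). It is written in-package rather than
delegated because the contract includes the per-iteration objective
trace and the L1-amplitude normalization semantics. The Bayesian sparse
factorization used for single-cell pattern discovery is replaced by
this deterministic NMF with the same non-negativity semantics; pattern
counts are a config parameter. Projection fixes the (ortholog-mapped,
re-normalized) amplitudes and solves one non-negative least squares per
cell; mapping under 50% of amplitude genes warns, under 10% errors.
Pattern–cell-type correlation is Pearson against one-hot type
indicators (point-biserial), matching the heat-map semantics of
pattern/type association.

## Signalling

Probability = (L̄·R̄)/(kh + L̄·R̄) with Tukey trimeans as robust
cluster summaries; kh (default 0.5) sets the half-saturation point on
the product scale. The permutation null shuffles cluster labels over
cells, one shared stream for all scores, and
p = (1 + #{perm ≥ obs})/(1 + n_perm), so the minimal attainable p is
1/(n_perm + 1) and a pair with a zero summary is automatically p = 1.
Network aggregation sums significant-pair probabilities per directed
cluster edge by default; mean and max reducers are available because
the choice of reducer is presentational.

## Scoring

Gene-set scores subtract the mean of expression-bin-matched control
genes (n_bins 24, n_ctrl 100 per set gene, sampled with replacement
when a bin is small), giving a null expectation of zero by
construction. Cell-cycle phase is the argmax of the S and G2M scores
when positive, else G1. Potency SR uses the expression-weighted
transition rows pᵢⱼ = xⱼAᵢⱼ/(Ax)ᵢ, whose stationary distribution has
the closed form πᵢ ∝ xᵢ(Ax)ᵢ by detailed balance; the entropy rate is
normalized by log λ_max(A), so a complete graph under uniform
expression scores exactly 1. A pseudocount of 1e-3 on network genes
prevents zero transition rows; the network itself is a mandatory input
(no interaction network is bundled). Potency states fit a 1-D Gaussian
mixture on logit(SR) with the component count chosen by BIC over 1–3,
accepting a more complex mixture only when BIC improves by at least 6
(the conventional "positive evidence" gap; without the margin, clean
two-component data can flip to three components on sub-unit BIC
differences). The over-representation test is the upper-tail
(cumulative) hypergeometric, exact by construction.

## Problem sizes and determinism

The test-suite and acceptance script run on atlases of 300–3000 cells
and 500–2000 genes, sizes at which every stage completes in seconds to
a few minutes on one CPU while leaving the planted effects (fold 4,
10-gene markers, 4-TF modules) comfortably recoverable. Every stochastic
step — generation, permutation nulls, NMF initialisation, mixture fits,
rank tie-breaking — takes an explicit seed, and identical seeds give
bit-identical outputs.

## Known limitations

* Regulon inference is purely co-expression-based; it cannot separate
  the targets of TFs activated in the same cell type.
* The clustering stack is one sensible default, not a benchmarked
  choice; resolution remains data-dependent.
* Ligand–receptor scoring handles single-gene ligands and receptors
  only (no multi-subunit complexes) and no spatial constraints.
* SR potency depends on the supplied network; different networks give
  different absolute values, and only the within-dataset ordering is
  interpretable.
* Imputed values are smoothed, not rescaled to original quantiles;
  downstream analyses treating them as counts would be biased.
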