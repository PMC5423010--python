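# Methods

This note documents the statistical model, the numerical conventions, and the
design choices behind the package, in the spirit of a model reference rather
than a tutorial.

## Sponge-pair model and its assumptions

The inference treats a ceRNA pair as a putative sponge interaction when the
pair (i) lies in the disease gene list, (ii) shares significantly many
validated miRNA regulators, (iii) shows a similar miRNA regulation pattern,
and (iv) is positively co-expressed. The assumptions worth keeping in mind:

- Expression is taken as analysis-ready (normalized / log-scale); no
  transformation or imputation is applied, and missing values are rejected.
  Duplicate gene rows are collapsed by averaging at read time.
- Regulator evidence comes solely from the supplied miRNA–target edge list;
  no sequence-based target prediction is done. Swapping a validated edge list
  for a predicted one is a pure input change.
- Pearson correlation is assumed adequate for monotone linear co-expression;
  its p-value uses the exact t-transform `t = r√((n−2)/(1−r²))` on n−2
  degrees of freedom, two-sided.
- Raw (uncorrected) per-pair cutoffs are used by design: p < 0.01 for the
  sharing test and the correlation test. No multiple-testing correction is
  applied across candidate pairs, matching the method's published operating
  point.

### The sharing test

For *M* miRNAs in the dataset, of which *N* regulate ceRNA_i and *K* regulate
ceRNA_j, the probability of sharing at least the observed *x* regulators by
chance is the upper-tail hypergeometric probability. The implementation
delegates to `scipy.stats.hypergeom.sf(x−1, M, N, K)`; the test suite pins it
against exact rational-arithmetic enumeration over the entire grid M ≤ 15 at
1e-12.

### Regulation-pattern scores

Both scores operate on the correlation vectors of the *shared* miRNAs only.
The cosine score is the ordinary cosine similarity of the signed correlation
vectors. The collaboration score uses absolute correlations with
square-roots-of-sums denominators:

    Col(i, j) = Σ_k AC_ik AC_jk / (√(Σ_k AC_ik) · √(Σ_k AC_jk))

This is intentionally *not* a cosine (the denominator is not a norm). For
AC ∈ [0,1] it is bounded by 1 via Cauchy–Schwarz together with a² ≤ a, which
the property tests exercise. It deliberately over-weights many weak shared
regulators ("excessive" estimate), while the cosine is conservative; their
mean, Sim, balances the two. Sign of the miRNA–ceRNA correlations is not
filtered anywhere: C may be positive or negative, and AC = |C|.

### Thresholds and tie handling

Defaults: ≥ 3 shared miRNAs; hypergeometric p < 0.01 (strict); Sim ≥ 0.5
(inclusive — the published cutoff is described as a moderate value, and the
boundary is included); correlation r > 0 strictly with p < 0.01 strict.
Candidacy is gated on the shared-miRNA count only, so a pair excluded by the
disease list still appears in the audit output with its condition-(i) flag
false; accepted edges require all four flags. Passing the whole gene universe
as the disease list disables condition (i). Pairs whose pattern scores are
undefined (all-zero correlation vector) are flagged with a reason, never
silently dropped.

## Motif semantics

The two 4-node motif types encode "a sponge pair co-regulates a PPI". The
link from a sponge to a protein is an lncRNA-target edge for lncRNA sponges;
an mRNA sponge *is* its protein node, so its links are its own PPI edges —
the only reading that keeps both motifs at exactly four pairwise-distinct
nodes for mixed sponge kinds. In type A the two links land on the two
distinct parties of one PPI; in type B both land on one shared protein that
must itself have a PPI partner q, and each distinct q is a distinct match.
Matches are canonicalized (sponge pair ordered lexicographically, first
protein attached to the first sponge), so swapping the symmetric roles does
not duplicate a match, while genuinely different edge realizations on the
same node set are distinct matches. A subgraph realizing both patterns yields
one match per pattern. The matcher is a fixed-pattern enumerator, not a
general subgraph-isomorphism engine; it is verified against brute-force
4-subset scanning on random typed networks.

## Topology conventions

- Degrees and path lengths treat all edges as undirected and untyped.
- Characteristic path length averages shortest paths over *reachable*
  unordered pairs, excluding unreachable ones (logged), so it stays finite on
  multi-component networks.
- Power-law goodness of fit is the R² of an ordinary least-squares line on
  the raw log10 frequency spectrum (no binning, no complementary CDF, no
  maximum-likelihood exponent), the convention consistent with reporting a
  single R² for a scale-free claim. Zero frequencies are skipped; values ≤ 0
  are a domain error; a flat spectrum returns slope 0 with R² = 0 rather than
  an undefined ratio.
- Hubs are the top ⌈fraction × n⌉ nodes by degree, default fraction 0.10,
  ties broken lexicographically (the rounding rule is not published; ceiling
  was chosen and is configurable only through the fraction).

## Markov clustering

MCL is implemented natively on the dense column-stochastic matrix:
unit-weight adjacency with unit self-loops, column normalization, then
expansion (matrix power 2) alternating with inflation (elementwise power 2.0
followed by re-normalization), pruning entries below 1e-5, until the maximum
entry change falls below 1e-6 or 100 iterations. Clusters are read off as
attractor-connected components; nodes attracted by several systems go to the
lowest-index attractor, so the output is a deterministic partition. These are
MCL's canonical defaults; the published analysis names the algorithm without
parameters, and all of them are exposed in the configuration. Edge types are
ignored during clustering. The minimum module size is 4 — the size of one
motif.

## Module classification

Per module, features are the expression rows of its measured genes
(protein-only nodes have no expression and are excluded); observations are
the labeled samples. The classifier is pinned explicitly for reproducibility
across ecosystems: RBF-kernel SVM with cost 1 and kernel width 1/n_features,
features standardized to zero mean and unit variance *within each training
fold*, stratified 10-fold assignment from a recorded seed. Whether the
original analysis standardized features is unpublished; within-fold
standardization was chosen to avoid test-set leakage and is documented here.
ACC is the pooled out-of-fold correct fraction. AUC is computed from the
pooled out-of-fold decision values via the Mann–Whitney rank formulation
(average ranks under ties); pooling a single ROC rather than averaging
per-fold AUCs was chosen for stability at ~144-sample scale, and the tests
verify the rank form equals trapezoidal ROC integration. OPI = (AUC+ACC)/2;
a module is a signature when ACC and AUC both exceed 0.9 (strict).

Over-representation analysis reuses the same upper-tail hypergeometric test
(universe = measured genes), adjusts across all tested terms with
Benjamini–Hochberg, and reports terms with adjusted p below 0.01 by default.

## Synthetic data: what it emulates and what it does not

Each planted pair (A, B) receives a dedicated, disjoint block of shared
miRNA regulators and expression `A = −w·Σ_k mir_k + ε`, likewise B, with
w = 1 (reg_strength) and ε ~ N(0, 0.3²) by default. Negative regulation
makes |C| large for every shared miRNA and makes A and B positively
correlated — the canonical ceRNA mechanism; with the defaults the expected
per-regulator correlation is ≈ −0.49, Sim ≈ 0.75 and corr(A,B) ≈ 0.98, which
is what makes near-perfect recovery the correct outcome rather than a lucky
one. Background ceRNAs get at most two incidental regulators, so no
background pair can reach the 3-shared-miRNA gate; disjoint regulator blocks
make the ground truth unambiguous. Defaults: 100 miRNAs, 30 lncRNAs, 120
mRNAs, 72+72 samples, 20 planted pairs, 4 shared miRNAs per pair (100 miRNAs
being the smallest round count that accommodates 20 disjoint 4-regulator
blocks with headroom for incidental background regulators). The protein
layer wires every pair into exactly one type-A and one type-B motif through
dedicated proteins, plus random background PPIs. Differential modules are
disjoint sets of background mRNAs whose tumor columns are shifted by
+delta = 3 (three within-group standard deviations — a strongly but not
degenerately separable signature on the log-expression scale).

What this does **not** emulate: count-distribution properties of real
RNA-seq (heteroscedasticity, library-size effects), correlated background
co-expression, hub-dominated scale-free topologies of curated interaction
databases, overlapping regulator programs, or label noise. Passing the
recovery tests therefore demonstrates correctness of the statistical
machinery under its own model, not expected performance on real cohort-scale
data, where edge counts, path lengths, R² values and module counts depend on
the specific expression matrices and database versions used.

## Numerical and degenerate-input choices

- Undirected edges are stored with endpoints in lexicographic order; all set
  operations use this canonical form. Self-loops are dropped on read with a
  logged count.
- Correlations of constant vectors, all-zero cosine inputs and zero-sum
  collaboration inputs raise typed errors; callers convert them to flagged,
  auditable rejections.
- r is clamped to [−1, 1] before the t-transform; |r| = 1 maps to p = 0.
- The expression reader parses floats with round-trip precision, so a
  write/read cycle is bit-identical.
- MCL columns that prune to zero are re-anchored on their own node; MCL
  non-convergence at the iteration cap yields clusters from the final state
  with a warning.
- Module evaluation requires at least two measured genes and at least
  `folds` samples per class; violations raise rather than degrade silently.

## Problem sizes in the test suite

The acceptance checks run the generator at its default conditions (72+72
samples, 20 planted pairs) over 10 seeds, the motif brute-force comparison on
100 random networks of up to 30 nodes, the hypergeometric enumeration over
the full M ≤ 15 grid, and the permutation null with 100 relabelings; unit
tests use smaller seeded bundles. These sizes are the package's own test
design: large enough to exercise every code path and the stochastic claims,
small enough to run routinely.

## Known limitations

- The number of inferred interactions is threshold-dependent by design
  (parametric method); the audit output exists so users can re-filter.
- Condition (i) requires a caller-supplied disease list; lncRNA and gene
  lists are concatenated by the caller.
- No pseudogene/circRNA sponges, no ID conversion, no database retrieval,
  no survival analysis ("prognostication" here is tumor/normal
  classification), and no maximum-likelihood power-law estimation.
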