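# Methods

## Overview

`gbanet` turns gene-set expansion into supervised classification on a
molecular network. The working assumption is guilt-by-association: genes
that participate in the same process or disease occupy overlapping network
neighborhoods. The classifier therefore never sees curated pathway features —
its features *are* the network, under one of three representations — and its
genome-wide scores measure how much each gene's connectivity pattern
resembles that of the input set.

## Identifier handling

All computation happens in Entrez space. Conversion is table-driven
(3-column TSV: alias, namespace, entrez); symbols match case-insensitively,
Ensembl and Entrez IDs case-sensitively. An alias resolving to several
Entrez IDs is reported as *ambiguous* and excluded from the positive set
rather than resolved arbitrarily — a silent wrong choice would contaminate
training labels. Two aliases resolving to the same gene collapse to the
first occurrence (the label set is a set); such collapses are reported in
their own bucket so the output buckets always partition the de-duplicated
input.

## Network canonicalization

Networks are undirected and weighted. On load: edges are symmetrized,
duplicate pairs keep the **maximum** weight (deterministic and
order-invariant, unlike keep-first/keep-last), self-loops are dropped and
counted, and nodes — defined as edge endpoints, so no isolates — are ordered
by ascending numeric Entrez ID. The canonical order fixes all matrix layouts,
making every downstream artifact byte-reproducible. Edge weights are used as
given; no rescaling is applied.

## Feature representations

**Adjacency.** `X = W` with zero diagonal. Purely local signal; the weight
vector of the trained model lives in gene space (one coefficient per gene).

**Influence.** The random-walk-with-restart kernel
`F = α (I − (1−α)P)⁻¹`, `P = D⁻¹W` (row-normalized; the random-walk, not
symmetric, normalization). `F[i, j]` is the stationary probability that a
walk restarting at *i* with probability α is found at *j*; each row sums
to 1 by the geometric-series identity, and mass never crosses connected
components because `I − (1−α)P` is block-diagonal over components — the
kernel is computed by one global linear solve, never an explicit inverse.
Default α = 0.85 (exposed as `--restart`): a standard choice that keeps the
kernel local enough to be discriminative while still integrating multi-hop
structure. The diagonal of `F` is non-decreasing in α; α = 1 gives the
identity.

**Embedding.** node2vec with conventional defaults: dimension 128, walk
length 80, 10 walks per node, window 10, p = q = 1, 5 epochs (test fixtures
use dimension 16 and shorter walks). Second-order biased walks are generated
exactly per the algorithm (unnormalized step weight `w/p` back to the
previous node, `w` to common neighbors, `w/q` outward); with p = q = 1 this
reduces to the first-order weighted walk, which is verified empirically
against the transition matrix. The skip-gram-with-negative-sampling trainer
is a compact numpy implementation: fixed context window, 5 negatives per
pair drawn from the unigram^(3/4) distribution, linearly decaying learning
rate (0.025 → 0), mini-batched SGD with scatter-add updates. Everything —
walk generation, pair shuffling, negative draws, weight initialization —
flows from a single `numpy.random.default_rng(seed)`, so one seed plus the
parameter fingerprint determines the matrix bitwise.

Each feature matrix carries a fingerprint string of its representation,
network and every construction parameter; models refuse to score features
with a mismatched fingerprint, preventing accidental cross-representation
scoring.

## Label selection

Positives = user genes ∩ network nodes (an empty intersection is an error —
there is nothing to learn from). Negatives start from the collection
universe ∩ network nodes minus the positives; each collection set is tested
for overlap with the positives by a one-sided hypergeometric tail, with the
universe of the test being the collection universe restricted to network
nodes (labels only ever apply to network genes, and the draw is likewise the
positives inside that universe). Sets with p < α (default 0.05, unadjusted,
configurable) have **all** their members removed from the negative pool;
removed genes become unused, not negatives. Unadjusted α is deliberate: the
cost of a false negative label (a disease gene marked N) far exceeds the
cost of discarding a harmless set, so the test errs toward exclusion.
Shrinking α monotonically grows the negative pool.

## Classifier, evaluation, prediction

l2-penalized logistic regression, inverse regularization C = 1 (objective
`C Σ log(1+e^{−y(w·x+b)}) + ‖w‖²/2`, intercept unpenalized), lbfgs with
tolerance 1e-6 — deterministic given inputs. Only P and N rows enter the
fit. With ≥ 15 positives, stratified 3-fold cross-validation (shuffled with
a recorded seed, default 42) reports auPRC, auROC and P@topK with K = the
held-out fold's positive count; below 15 positives fold metrics are too
unstable to be useful and CV is skipped, which is reported as absent rather
than zero. The final model scores all genes — P, N and U — in one pass;
ranks break probability ties by ascending numeric Entrez. Display tables
truncate to the top 500 rows; the full table is always written alongside.

## Model-similarity interpretation

The corpus builder runs the *identical* pipeline per collection set
(positive selection → negative selection → training) under one shared
settings fingerprint; sets with fewer than 10 in-network genes are skipped
(below that, the fit is dominated by the prior and its weights are mostly
noise; configurable). Similarity is the cosine of raw weight vectors,
intercepts excluded: cosine is scale-invariant (models trained on different
class balances differ mainly in scale) and the intercept encodes the class
prior, not connectivity structure. The metric is a single pluggable
function. A corpus entry trained on exactly the user's positives under the
same settings is the user's own model and must rank first with similarity 1;
this is asserted in the acceptance suite. Similarity ties break
lexicographically by set id.

## Subgraph export

Vertex-induced subgraph over the selected genes (top-n by rank, or all genes
above a probability threshold; their intersection when both are given —
the stricter, reproducible reading), hard-capped at 50 nodes; induced edges
below the edge-weight threshold are dropped while nodes are kept. Output is
JSON node-link and GraphML; layout and interaction are viewer concerns.

## Synthetic data

The generator is a stochastic block model: blocks are functional modules,
with independent Bernoulli edges at `p_within` inside and `p_between`
across blocks and uniform weights on [0.5, 1.0] (a score-like range).
Defaults — two blocks of 50 genes, `p_within` 0.3, `p_between` 0.01, an
8-set collection with set sizes 10–30 and 10 % membership noise in the
block-aligned sets — define the standard benchmark condition: dense enough
that a module is learnable, sparse enough that recovery is not trivial.
Genes carry Entrez-style IDs from 900000001 upward (far above the real
Entrez range); isolated genes are re-wired with one within-block edge so
network invariants hold. Collections mix block-aligned sets (which trip the
overlap-exclusion rule) with uniform random sets (clean negatives); the
collection uses its own seed stream so it does not perturb the network draw.

What the SBM does *not* emulate: the heavy-tailed degree distributions,
weight calibration and study bias of real interactome databases. Passing the
planted-module benchmark shows the pipeline recovers community-structured
association signal; it does not certify performance on any particular real
network.

**Planted-recovery benchmark.** Block 0 is the true module; 30 % of its
genes are hidden, the rest train the model, and the hidden genes' positions
are read from the prediction table. Ranks are taken among *candidate*
(non-positive) genes: training positives occupy the table's top by
construction, so genome-wide ranks of held-out genes would measure the
positives' count, not recovery. Reported are the mean held-out candidate
rank and top-decile recall (random baseline 0.1), averaged over 5 seeds,
per representation. With ~65 candidates and 15 held-out genes the top
decile holds 6 slots, capping recall at 0.4 — both deterministic
representations reach that cap under default conditions.

## Numerical choices and degenerate inputs

- Influence entries are clipped at 0 to scrub `-0.0` and round-off below
  machine epsilon; agreement with a 3000-term series oracle is at 1e-8 or
  better (observed ~1e-15 at fixture scale).
- Hypergeometric tails come from `scipy.stats.hypergeom.sf`; the test
  suite's oracle enumerates the tail with exact binomial coefficients.
- Degenerate cases raise typed errors rather than guessing: empty gene list,
  no positives in the network, single-class training set, empty negative
  pool after exclusion, empty corpus, fingerprint mismatches.
- Problem sizes in tests and the acceptance script (networks of 10–100
  genes, one 1000-gene run for the display caps) were chosen so every oracle
  comparison is exact or near-exact while the whole suite runs in seconds;
  the algorithms themselves are size-agnostic.

## Known limitations

- The embedding trainer is mini-batched rather than per-pair sequential SGD;
  embeddings are deterministic and high-quality at fixture scale but are not
  numerically interchangeable with other node2vec implementations.
- Corpus building is sequential; real-scale corpora (thousands of sets on
  genome-scale networks) would need caching and parallelism beyond scope.
- One-to-many alias mappings are reported, never auto-resolved; users must
  disambiguate manually.
- The hypergeometric overlap test treats sets independently (no multiple-
  testing adjustment); with very large collections α may warrant tightening.
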