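# gbanet

Network-based gene classification for expanding and interpreting gene sets.

Experimentally derived gene lists — from differential expression, screens,
association studies — are noisy and incomplete, and say nothing about how the
genes relate to the rest of the genome. `gbanet` addresses this by
guilt-by-association supervised learning on a molecular network: given a
weighted undirected gene network, a user gene set and a gene-set collection
to draw negatives from, it trains a custom classifier whose features are the
network connections themselves, scores **every** gene in the network for
association with the input set, interprets the trained model by comparing it
to a corpus of models pre-trained on known gene sets, and exports the
top-gene subgraph for visualization.

## The model

Genes present in the network and in the user set are **positives** (P).
**Negatives** (N) are the collection's genes present in the network, minus
the positives, minus every member of any collection set whose overlap with
the positives is significant under a one-sided hypergeometric test
(p < α, default α = 0.05): such sets plausibly describe the same biology and
their genes are unsafe negatives. Everything else is **unused** (U) — not
trained on, but still scored.

The classifier is l2-regularized logistic regression with inverse
regularization C = 1, fit on P vs N rows of one of three feature
representations of the network `W`:

- **adjacency** — `X = W`, the raw connection weights;
- **influence** — a random-walk-with-restart kernel
  `F = α (I − (1−α) P)⁻¹` with `P = D⁻¹W` and restart probability
  α (default 0.85); each row of `F` is a probability distribution capturing
  multi-hop proximity;
- **embedding** — node2vec: second-order biased random walks + skip-gram
  with negative sampling, giving a d-dimensional vector per gene
  (default d = 128).

Every gene receives `p(gene) = σ(w·x + b)`, ranked into a table with
`Probability`, `Training-Label` (P/N/U), `Known/Novel` (Known = training
positive) and `Rank`. With ≥ 15 positives the model is evaluated by
stratified 3-fold cross-validation (auPRC, auROC, P@topK).

For interpretation, a corpus of models is pre-trained on a collection of
known gene sets under the *same* network, representation and negative
collection, and ranked by cosine similarity between weight vectors. A known
set can rank highly even with zero gene overlap, as long as the two sets
occupy similar network neighborhoods.

## Worked example

No downloads are needed: the `simulate` command generates a synthetic
network with planted functional modules (a stochastic block model), a
gene-set collection and an ID map.

```bash
gbanet simulate --seed 3 --out data
# wrote network (100 genes, 771 edges), collection and id map to data

# take the genes of one known module set as the "user" list (as symbols)
grep '^BLOCK0' data/collection.gmt | cut -f3- | tr '\t' '\n' \
  | sed 's/^/SYM/' > module_genes.txt

gbanet run --genes module_genes.txt --network data/network.tsv \
  --id-map data/id_map.tsv --negative-collection data/collection.gmt \
  --corpus-collection data/collection.gmt --feature influence \
  --seed 11 --jobname-prefix demo_ --out results
# results written to results/demo_ihXEKLSb (archive: results/demo_ihXEKLSb.zip)
```

The run log records 25 positives and 54 negatives, with the set `BLOCK0`
excluded from the negative pool (it overlaps the positives, being the input
itself). Cross-validation (25 ≥ 15 positives, 3 folds) reports

```
auPRC 0.630   auROC 0.817   P@topK 0.560
```

The prediction table (`predictions_top.tsv`) is led by training positives,
and the first *Novel* genes are exactly held-back members of the planted
module — the guilt-by-association signal at work:

```
Entrez      Symbol        Probability  Training-Label  Known/Novel  Rank
900000022   SYM900000022  0.4241       P               Known        1
...
900000018   SYM900000018  0.3322       U               Novel        26
900000032   SYM900000032  0.3264       U               Novel        27
900000035   SYM900000035  0.3260       U               Novel        28
```

Model interpretation (`model_similarities.tsv`) ranks the pre-trained corpus
by weight-vector cosine similarity; the model pre-trained on the same module
set is, as it must be, the nearest one:

```
ID      Name            Similarity  Rank
BLOCK0  module block 0  1.0000      1
RAND2   random set 2    0.1602      2
RAND1   random set 1    0.0897      3
```

`top_subgraph.json` / `.graphml` hold the induced subgraph of the 50
top-ranked genes for any graph viewer. All outputs are also archived into a
single zip per job.

## CLI

`validate`, `simulate`, `run`, `build-corpus`, `interpret`, `graph` — see
`gbanet COMMAND --help`. Exit codes: 0 ok, 1 user error, 2 internal error.
Every run writes its resolved configuration (`job_config.yaml`), which
reproduces the run bit-for-bit for the deterministic representations.
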