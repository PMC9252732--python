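"""Synthetic networks, gene-set collections and ID maps.

Everything the pipeline consumes can be generated here, so the full method is
testable without downloading any real network or annotation database.  The
network generator is a stochastic block model (SBM): genes fall into blocks
("functional modules") with dense within-block and sparse between-block
wiring.  Guilt-by-association — the premise that network neighbors share
function — is exactly the signal the classifier exploits, so an SBM with a
planted module is the natural stand-in for a real functional network.

Synthetic genes get Entrez-style numeric IDs starting at 900000001, far above
the real Entrez range.  Collections mix block-aligned sets (which exercise
the overlap-exclusion rule) with random sets (clean negative sources).  The
planted-recovery benchmark hides a fraction of one module's genes, trains on
the rest and measures how well the hidden genes are re-ranked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .features import build_features
from .id_mapping import IdMappingTable
from .labels import GeneSet, GeneSetCollection, select_negatives
from .model import predict_all, train
from .network import GeneNetwork, from_edges

logger = logging.getLogger(__name__)

FIRST_SYNTHETIC_ENTREZ = 900_000_001


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic world.

    Defaults describe the standard benchmark condition: two 50-gene modules
    with within-block edge probability 0.3 and between-block probability
    0.01, uniform edge weights, an 8-set collection and 10% label noise in
    block-aligned sets.
    """

    n_blocks: int = 2
    block_sizes: tuple[int, ...] = (50, 50)
    p_within: float = 0.3
    p_between: float = 0.01
    weight_distribution: tuple[float, float] = (0.5, 1.0)
    n_sets: int = 8
    set_size_range: tuple[int, int] = (10, 30)
    noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_sizes) != self.n_blocks:
            raise ParameterError("block_sizes length must equal n_blocks")
        for p in (self.p_within, self.p_between):
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"edge probability {p} outside [0, 1]")
        if any(s < 2 for s in self.block_sizes):
            raise ParameterError("blocks need >= 2 genes to be wireable")
        if not (0.0 <= self.noise <= 1.0):
            raise ParameterError(f"noise {self.noise} outside [0, 1]")

    @property
    def n_genes(self) -> int:
        return sum(self.block_sizes)


def _gene_ids(spec: SyntheticSpec) -> list[str]:
    return [str(FIRST_SYNTHETIC_ENTREZ + i) for i in range(spec.n_genes)]


def block_assignment(spec: SyntheticSpec) -> dict[str, int]:
    """Gene ID -> block index, in generation order."""
    genes = _gene_ids(spec)
    out: dict[str, int] = {}
    pos = 0
    for b, size in enumerate(spec.block_sizes):
        for g in genes[pos : pos + size]:
            out[g] = b
        pos += size
    return out


def generate_network(spec: SyntheticSpec) -> GeneNetwork:
    """Draw an SBM network; identical spec (incl. seed) gives an identical
    network.  Genes left isolated by the draw are re-wired with one
    within-block edge so that every gene is an edge endpoint."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec)
    blocks = block_assignment(spec)
    lo, hi = spec.weight_distribution
    raw: list[tuple[str, str, float]] = []
    touched: set[str] = set()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            same = blocks[genes[i]] == blocks[genes[j]]
            prob = spec.p_within if same else spec.p_between
            if rng.random() < prob:
                w = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
                raw.append((genes[i], genes[j], w))
                touched.update((genes[i], genes[j]))
    # re-wire isolated genes with one within-block edge
    for g in genes:
        if g in touched:
            continue
        mates = [m for m in genes if m != g and blocks[m] == blocks[g]]
        if not mates:
            raise ParameterError(f"block of gene {g} too small to re-wire")
        mate = mates[int(rng.integers(len(mates)))]
        w = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        raw.append((g, mate, w))
        touched.update((g, mate))
    return from_edges(f"sbm_seed{spec.seed}", raw)


def generate_collection(
    network: GeneNetwork, spec: SyntheticSpec, name: str = "synthetic_collection"
) -> GeneSetCollection:
    """Sample a gene-set collection over the network's genes.

    One block-aligned set per block comes first (members drawn from the
    block, with a ``noise`` fraction replaced by out-of-block genes) —
    these significantly overlap any block-derived positive set and exercise
    the exclusion rule.  The remainder are uniform random sets, providing
    clean negatives.  A dedicated seed stream (spec.seed + 1) keeps the
    collection independent of the network draw.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = list(network.nodes)
    blocks = block_assignment(spec)
    lo, hi = spec.set_size_range
    sets: list[GeneSet] = []
    for b in range(spec.n_blocks):
        block_genes = [g for g in genes if blocks.get(g) == b]
        others = [g for g in genes if blocks.get(g) != b]
        size = min(int(rng.integers(lo, hi + 1)), len(block_genes))
        members = list(rng.choice(block_genes, size=size, replace=False))
        n_noise = int(round(spec.noise * size))
        if n_noise and others:
            swap_out = rng.choice(size, size=n_noise, replace=False)
            noise_genes = rng.choice(others, size=n_noise, replace=False)
            for k, g in zip(swap_out, noise_genes):
                members[k] = g
        sets.append(GeneSet(id=f"BLOCK{b}", name=f"module block {b}", members=frozenset(members)))
    for k in range(max(0, spec.n_sets - spec.n_blocks)):
        size = min(int(rng.integers(lo, hi + 1)), len(genes))
        members = rng.choice(genes, size=size, replace=False)
        sets.append(GeneSet(id=f"RAND{k}", name=f"random set {k}", members=frozenset(members)))
    return GeneSetCollection(name, tuple(sets))


def generate_id_map(network: GeneNetwork) -> IdMappingTable:
    """Alias table covering every network gene in all namespaces.

    Each Entrez ID ``E`` gets a symbol ``SYM<E>``, an Ensembl gene ID
    ``ENSG<E padded>`` and itself as an Entrez alias.
    """
    records: list[tuple[str, str, str]] = []
    for g in network.nodes:
        records.append((g, "entrez", g))
        records.append((f"SYM{g}", "symbol", g))
        records.append((f"ENSG{int(g):011d}", "ensembl_gene", g))
    return IdMappingTable(records)


@dataclass(frozen=True)
class RecoveryReport:
    """Held-out planted-module recovery, per representation."""

    representation: str
    seeds: tuple[int, ...]
    mean_heldout_rank: float | None
    top_decile_recall: float | None
    per_seed_recall: tuple[float, ...] = field(default_factory=tuple)
    n_genes: int = 0


def planted_recovery_benchmark(
    spec: SyntheticSpec,
    held_out_fraction: float = 0.3,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    representations: Sequence[str] = ("adjacency", "influence"),
    alpha: float = 0.05,
    feature_params: dict | None = None,
) -> dict[str, RecoveryReport]:
    """Hide a fraction of the planted module and measure its recovery.

    For each seed: draw a network, designate block 0 as the true module,
    hide ``held_out_fraction`` of its genes, train on the remainder (with
    negatives from the generated collection) and record where the hidden
    genes land in the prediction table.  Ranks are taken among *candidate*
    genes only (training positives excluded): the positives occupy the top
    of any well-fit table by construction, and the scientific question is
    how the hidden module genes fare against the rest of the genome.
    Reports the mean held-out candidate rank and the top-decile recall
    (fraction of hidden genes within the top 10% of candidates), averaged
    over seeds; a uniformly random ranking gives recall 0.1.  With
    ``held_out_fraction = 0`` there is nothing to recover and the metrics
    are reported as absent (None).
    """
    if not (0.0 <= held_out_fraction < 1.0):
        raise ParameterError(f"held_out_fraction {held_out_fraction} outside [0, 1)")
    feature_params = feature_params or {}
    reports: dict[str, RecoveryReport] = {}
    for representation in representations:
        ranks_all: list[float] = []
        recalls: list[float] = []
        n_genes = 0
        for seed in seeds:
            local = replace(spec, seed=int(seed))
            net = generate_network(local)
            blocks = block_assignment(local)
            module = sorted(g for g in net.nodes if blocks.get(g) == 0)
            rng = np.random.default_rng(int(seed) + 10_000)
            n_hold = int(round(held_out_fraction * len(module)))
            if n_hold == 0:
                continue
            held_out = set(rng.choice(module, size=n_hold, replace=False))
            visible = frozenset(set(module) - held_out)
            collection = generate_collection(net, local)
            labels = select_negatives(visible, collection, net, alpha=alpha)
            feats = build_features(net, representation, **feature_params)
            mdl = train(feats, labels)
            table = predict_all(mdl, feats, labels)
            candidates = table[table["Training-Label"] != "P"].reset_index(drop=True)
            rank_of = {g: r + 1 for r, g in enumerate(candidates["Entrez"])}
            n_genes = len(candidates)
            cutoff = max(1, n_genes // 10)
            held_ranks = [rank_of[g] for g in held_out]
            ranks_all.extend(held_ranks)
            recalls.append(float(np.mean([r <= cutoff for r in held_ranks])))
        if not ranks_all:
            reports[representation] = RecoveryReport(
                representation, tuple(int(s) for s in seeds), None, None, (), n_genes
            )
        else:
            reports[representation] = RecoveryReport(
                representation,
                tuple(int(s) for s in seeds),
                float(np.mean(ranks_all)),
                float(np.mean(recalls)),
                tuple(recalls),
                n_genes,
            )
    return reports
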