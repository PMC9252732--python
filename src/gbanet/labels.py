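"""Training-label selection: positives, negatives and unused genes.

The classifier needs three disjoint gene partitions over the network:

* **Positives (P)** — the user's genes that mapped to Entrez and are present
  in the chosen network.
* **Negatives (N)** — genes drawn from a gene-set collection (e.g. a
  process/pathway or disease collection) that show no evidence of association
  with the positive set.  Starting from every collection gene present in the
  network, the positives themselves are removed, and then every member of any
  collection set that *significantly overlaps* the positive set is removed:
  such sets plausibly describe the same biology, so their genes are unsafe
  negatives.  Significance is a one-sided hypergeometric tail test at level
  ``alpha`` (default 0.05, unadjusted), with the test universe being the
  collection universe restricted to network nodes.
* **Unused (U)** — everything else.  Unused genes take no part in training
  but are still scored by the final model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .errors import EmptyInputError, ParseError
from .network import GeneNetwork

logger = logging.getLogger(__name__)

DEFAULT_OVERLAP_ALPHA = 0.05


@dataclass(frozen=True)
class GeneSet:
    id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.id!r} has no members")


@dataclass(frozen=True)
class GeneSetCollection:
    """A named list of gene sets (as read from a GMT file)."""

    collection_name: str
    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sets]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate set ids in collection")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.members
        return frozenset(out)


def load_gmt(path: str | Path, collection_name: str | None = None) -> GeneSetCollection:
    """Read a GMT file: ``set_id <TAB> description <TAB> member ...`` per line."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            members = frozenset(f.strip() for f in fields[2:] if f.strip())
            if not members:
                raise ParseError(f"{path}:{lineno}: set {fields[0]!r} has no members")
            sets.append(GeneSet(id=fields[0], name=fields[1], members=members))
    if not sets:
        raise EmptyInputError(f"GMT file {path} contains no sets")
    return GeneSetCollection(collection_name or path.stem, tuple(sets))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection.sets:
            members = "\t".join(sorted(s.members))
            fh.write(f"{s.id}\t{s.name}\t{members}\n")


@dataclass(frozen=True)
class LabeledSets:
    """Disjoint P/N/U partition of the network node set."""

    positives: frozenset[str]
    negatives: frozenset[str]
    unused: frozenset[str]
    excluded_sets: tuple[tuple[str, int, float], ...] = field(default_factory=tuple)
    collection_name: str = ""

    def label_of(self, gene: str) -> str:
        if gene in self.positives:
            return "P"
        if gene in self.negatives:
            return "N"
        return "U"


def select_positives(user_genes: Iterable[str], network: GeneNetwork) -> frozenset[str]:
    """Positives are the user's Entrez genes that are present in the network."""
    user = set(user_genes)
    positives = user & network.node_set
    dropped = len(user) - len(positives)
    if dropped:
        logger.info(
            "%d user gene(s) absent from network %s and dropped", dropped, network.name
        )
    if not positives:
        raise EmptyInputError(
            f"no positives: none of the {len(user)} user genes are in network "
            f"{network.name!r}; the model cannot train"
        )
    return frozenset(positives)


def overlap_pvalue(n_universe: int, n_set: int, n_pos: int, n_overlap: int) -> float:
    """One-sided hypergeometric tail P(X >= n_overlap).

    ``X`` is the overlap between a random ``n_pos``-subset of the universe
    and a fixed set of size ``n_set``.
    """
    return float(hypergeom.sf(n_overlap - 1, n_universe, n_set, n_pos))


def select_negatives(
    positives: frozenset[str],
    collection: GeneSetCollection,
    network: GeneNetwork,
    alpha: float = DEFAULT_OVERLAP_ALPHA,
) -> LabeledSets:
    """Choose negatives from the collection, excluding sets that overlap P.

    Candidate negatives are every collection gene present in the network,
    minus the positives.  For each set ``S`` the one-sided hypergeometric
    tail probability of observing ``|S ∩ P|`` overlapping genes is computed
    over the universe ``collection.universe ∩ network nodes``; when
    ``p < alpha`` all of ``S``'s members are removed from the candidates and
    ``S`` is recorded in ``excluded_sets``.  Removed genes become unused,
    not negatives.
    """
    if not positives:
        raise EmptyInputError("positive set is empty")
    nodes = network.node_set
    universe = collection.universe & nodes
    if not universe:
        raise EmptyInputError(
            f"collection {collection.collection_name!r} shares no genes with "
            f"network {network.name!r}"
        )
    pos_in_universe = positives & universe
    candidates = set(universe) - positives

    excluded: list[tuple[str, int, float]] = []
    for s in collection.sets:
        set_in_universe = s.members & universe
        overlap = len(set_in_universe & pos_in_universe)
        pval = overlap_pvalue(
            len(universe), len(set_in_universe), len(pos_in_universe), overlap
        )
        if pval < alpha:
            excluded.append((s.id, overlap, pval))
            candidates -= s.members
    if excluded:
        logger.info(
            "excluded %d set(s) significantly overlapping the positives: %s",
            len(excluded), ", ".join(e[0] for e in excluded),
        )
    if not candidates:
        raise EmptyInputError(
            "no negatives remain after overlap exclusion; try a different "
            "gene-set collection or a larger alpha"
        )
    negatives = frozenset(candidates)
    unused = frozenset(nodes - positives - negatives)
    return LabeledSets(
        positives=positives,
        negatives=negatives,
        unused=unused,
        excluded_sets=tuple(excluded),
        collection_name=collection.collection_name,
    )


def build_labels(
    user_genes: Iterable[str],
    collection: GeneSetCollection,
    network: GeneNetwork,
    alpha: float = DEFAULT_OVERLAP_ALPHA,
) -> LabeledSets:
    """Convenience wrapper: select_positives then select_negatives."""
    positives = select_positives(user_genes, network)
    return select_negatives(positives, collection, network, alpha=alpha)


def write_labels(labels: LabeledSets, path: str | Path) -> None:
    """TSV with one gene per row and its training label."""
    with open(path, "w") as fh:
        fh.write("entrez\tlabel\n")
        for label, genes in (
            ("P", labels.positives), ("N", labels.negatives), ("U", labels.unused)
        ):
            for g in sorted(genes, key=lambda x: (not x.isdigit(), int(x) if x.isdigit() else 0, x)):
                fh.write(f"{g}\t{label}\n")
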