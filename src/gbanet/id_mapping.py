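"""Gene identifier conversion into Entrez space.

All downstream stages (networks, gene-set collections, pre-trained model
corpora) operate on NCBI Entrez IDs, so the first step of any analysis is to
convert a user's gene list — which may mix Gene Symbols, Ensembl gene /
protein / transcript IDs and Entrez IDs — into Entrez space.  Conversion is
entirely table-driven (no live database queries): a 3-column TSV maps each
alias to its Entrez ID(s).

An alias that resolves to more than one Entrez ID is *ambiguous* and is
reported rather than silently resolved, because an arbitrary choice would
contaminate the positive training set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import EmptyInputError, ParseError
from .network import GeneNetwork

logger = logging.getLogger(__name__)

NAMESPACES = ("symbol", "ensembl_gene", "ensembl_protein", "ensembl_transcript", "entrez")
#: namespaces matched without regard to letter case
_CASE_INSENSITIVE = frozenset({"symbol"})


@dataclass
class IdMappingTable:
    """Alias → Entrez lookup table.

    ``records`` holds ``(alias, namespace, entrez)`` triples; an alias may
    legitimately map to several Entrez IDs (the ambiguity is preserved, not
    collapsed).
    """

    records: list[tuple[str, str, str]]
    _lookup: dict[tuple[str, str], list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lookup: dict[tuple[str, str], list[str]] = {}
        for alias, ns, entrez in self.records:
            key_alias = alias.casefold() if ns in _CASE_INSENSITIVE else alias
            lookup.setdefault((key_alias, ns), [])
            if entrez not in lookup[(key_alias, ns)]:
                lookup[(key_alias, ns)].append(entrez)
        self._lookup = lookup

    def candidates(self, alias: str) -> list[str]:
        """All Entrez IDs the alias can resolve to, across namespaces.

        Symbols match case-insensitively; Ensembl and Entrez IDs match
        case-sensitively.  Order is deterministic (table order, de-duplicated).
        """
        out: list[str] = []
        for ns in NAMESPACES:
            key = alias.casefold() if ns in _CASE_INSENSITIVE else alias
            for entrez in self._lookup.get((key, ns), []):
                if entrez not in out:
                    out.append(entrez)
        return out


def load_id_map(path: str | Path) -> IdMappingTable:
    """Read an alias table from TSV: columns ``alias  namespace  entrez``,
    header required."""
    path = Path(path)
    records: list[tuple[str, str, str]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}:1: missing header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            alias, ns, entrez = (f.strip() for f in fields)
            if ns not in NAMESPACES:
                raise ParseError(f"{path}:{lineno}: unknown namespace {ns!r}")
            if not entrez.isdigit():
                raise ParseError(f"{path}:{lineno}: entrez {entrez!r} is not a digit string")
            records.append((alias, ns, entrez))
    return IdMappingTable(records)


def write_id_map(table: IdMappingTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("alias\tnamespace\tentrez\n")
        for alias, ns, entrez in table.records:
            fh.write(f"{alias}\t{ns}\t{entrez}\n")


@dataclass
class ConversionResult:
    """Outcome of converting a raw gene list to Entrez space.

    ``mapped``, ``unmapped``, ``ambiguous`` and ``collapsed`` together
    partition the de-duplicated input, preserving input order.  ``collapsed``
    holds aliases whose (unique) Entrez ID was already claimed by an earlier
    alias — the label set is a set, so they add nothing.
    """

    mapped: list[tuple[str, str]]
    unmapped: list[str]
    ambiguous: list[tuple[str, list[str]]]
    collapsed: list[tuple[str, str]] = field(default_factory=list)

    @property
    def entrez_ids(self) -> list[str]:
        return [e for _, e in self.mapped]


def read_gene_list(path: str | Path) -> list[str]:
    """Read a newline- or comma-separated plain-text gene list."""
    text = Path(path).read_text()
    return [tok for chunk in text.splitlines() for tok in chunk.split(",") if tok.strip()]


def convert_ids(raw_ids: Sequence[str], table: IdMappingTable) -> ConversionResult:
    """Convert raw identifiers to Entrez IDs via the mapping table.

    Duplicate inputs are collapsed to their first occurrence (logged);
    aliases with no table entry land in ``unmapped``; aliases with several
    candidate Entrez IDs land in ``ambiguous``.
    """
    cleaned: list[str] = []
    seen: set[str] = set()
    n_dup = 0
    for raw in raw_ids:
        tok = raw.strip()
        if not tok:
            continue
        if tok in seen:
            n_dup += 1
            continue
        seen.add(tok)
        cleaned.append(tok)
    if n_dup:
        logger.info("collapsed %d duplicate input identifier(s)", n_dup)
    if not cleaned:
        raise EmptyInputError("no genes supplied")

    result = ConversionResult(mapped=[], unmapped=[], ambiguous=[])
    claimed: set[str] = set()
    for alias in cleaned:
        cand = table.candidates(alias)
        if not cand:
            result.unmapped.append(alias)
        elif len(cand) > 1:
            result.ambiguous.append((alias, cand))
        elif cand[0] in claimed:
            result.collapsed.append((alias, cand[0]))
        else:
            claimed.add(cand[0])
            result.mapped.append((alias, cand[0]))
    return result


@dataclass
class OverlapSummary:
    """Per-network coverage of a converted gene set."""

    per_network: list[tuple[str, int, int, float]]  # (name, n_input, n_in_net, fraction)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_network,
            columns=["network", "n_input_mapped", "n_in_network", "fraction_in_network"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_frame().to_dict(orient="records"), indent=2))


def summarize_overlap(entrez_ids: Iterable[str], networks: Sequence[GeneNetwork]) -> OverlapSummary:
    """Count how many converted genes are present in each candidate network.

    The summary guides the choice of network: a gene absent from the chosen
    network cannot serve as a training positive.
    """
    ids = set(entrez_ids)
    rows = []
    for net in networks:
        n_in = len(ids & net.node_set)
        frac = n_in / len(ids) if ids else 0.0
        rows.append((net.name, len(ids), n_in, frac))
    return OverlapSummary(rows)
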