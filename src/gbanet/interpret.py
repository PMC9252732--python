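"""Model interpretation by similarity to a corpus of pre-trained models.

Instead of gene-set enrichment on the prediction list, the trained model
itself is interpreted: a corpus of models is pre-trained on known gene sets
(e.g. biological processes or diseases) under *exactly* the same network,
feature representation and negative-selection collection as the user's model,
and the corpus entries are ranked by the cosine similarity of their weight
vectors to the user model's weights (intercepts excluded).  Two models are
similar when they respond to the same patterns of network connectivity — a
known set can rank highly even if it shares few or no genes with the user's
input, as long as the two sets occupy overlapping network neighborhoods.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FingerprintMismatchError
from .features import FeatureMatrix
from .labels import GeneSetCollection, select_negatives, select_positives
from .model import TrainedModel, train
from .network import GeneNetwork

logger = logging.getLogger(__name__)

DEFAULT_MIN_POSITIVES = 10


@dataclass
class ModelCorpus:
    """Pre-trained models over a gene-set collection, sharing one settings
    fingerprint (network + representation + negative collection)."""

    entries: list[tuple[str, str, TrainedModel]]  # (set_id, set_name, model)
    feature_fingerprint: str

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate set ids in corpus")

    def __len__(self) -> int:
        return len(self.entries)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"feature_fingerprint": self.feature_fingerprint, "entries": []}
        for k, (set_id, set_name, mdl) in enumerate(self.entries):
            fname = f"model_{k:05d}.json"
            mdl.save(directory / fname)
            manifest["entries"].append({"set_id": set_id, "set_name": set_name, "file": fname})
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "ModelCorpus":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        entries = [
            (e["set_id"], e["set_name"], TrainedModel.load(directory / e["file"]))
            for e in manifest["entries"]
        ]
        return cls(entries=entries, feature_fingerprint=manifest["feature_fingerprint"])


def build_corpus(
    collection: GeneSetCollection,
    features: FeatureMatrix,
    network: GeneNetwork,
    negative_collection: GeneSetCollection,
    alpha: float = 0.05,
    min_positives: int = DEFAULT_MIN_POSITIVES,
    inverse_reg: float = 1.0,
) -> ModelCorpus:
    """Train one model per collection set, exactly as a user set would be.

    Each set's members become the user genes of a full pipeline run
    (positive selection -> negative selection -> training).  Sets with fewer
    than ``min_positives`` in-network genes are skipped (too few positives to
    learn from); skips are logged.
    """
    entries: list[tuple[str, str, TrainedModel]] = []
    for s in collection.sets:
        in_network = s.members & network.node_set
        if len(in_network) < min_positives:
            logger.info(
                "corpus: skipping %s (%d in-network genes < %d)",
                s.id, len(in_network), min_positives,
            )
            continue
        try:
            positives = select_positives(s.members, network)
            labels = select_negatives(positives, negative_collection, network, alpha=alpha)
            mdl = train(features, labels, inverse_reg=inverse_reg,
                        settings={"set_id": s.id, "collection": collection.collection_name})
        except EmptyInputError as exc:
            logger.info("corpus: skipping %s (%s)", s.id, exc)
            continue
        entries.append((s.id, s.name, mdl))
    if not entries:
        raise EmptyInputError(
            f"no trainable sets in collection {collection.collection_name!r} "
            f"(floor: {min_positives} in-network genes)"
        )
    return ModelCorpus(entries=entries, feature_fingerprint=features.params_fingerprint)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of two weight vectors; scale-invariant, in [-1, 1]."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def rank_similar(user_model: TrainedModel, corpus: ModelCorpus) -> pd.DataFrame:
    """Rank corpus entries by weight-vector cosine similarity to the user model.

    Returns the full table (columns ID, Name, Similarity, Rank) sorted by
    similarity descending with ties broken lexicographically by set id.
    """
    if user_model.feature_fingerprint != corpus.feature_fingerprint:
        raise FingerprintMismatchError(
            "user model and corpus were built under different feature settings:\n"
            f"  model:  {user_model.feature_fingerprint}\n"
            f"  corpus: {corpus.feature_fingerprint}"
        )
    rows = [
        (set_id, set_name, cosine_similarity(user_model.weights, mdl.weights))
        for set_id, set_name, mdl in corpus.entries
    ]
    rows.sort(key=lambda r: (-r[2], r[0]))
    table = pd.DataFrame(rows, columns=["ID", "Name", "Similarity"])
    table["Rank"] = np.arange(1, len(table) + 1)
    return table


def write_similarity_table(table: pd.DataFrame, path: str | Path, fmt: str = "tsv") -> None:
    if fmt == "tsv":
        table.to_csv(path, sep="\t", index=False)
    else:
        Path(path).write_text(table.to_json(orient="records", indent=2))
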