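"""Network feature representations for the classifier.

Three representations of a :class:`~gbanet.network.GeneNetwork` are supported,
each yielding one feature vector per gene:

``adjacency``
    The raw connections: row *i* is the weighted adjacency row of gene *i*
    (diagonal zero).  Local, sparse signal.

``influence``
    A random-walk-with-restart (RWR) diffusion kernel.  With row-normalized
    transition matrix ``P[i, j] = w_ij / deg(i)`` and restart probability
    ``alpha``, the kernel is the stationary visiting distribution of a walk
    that restarts at its origin with probability ``alpha`` each step::

        F = alpha * (I - (1 - alpha) * P)^{-1}

    Each row of ``F`` is a probability distribution (sums to 1), capturing
    multi-hop proximity rather than only direct edges.

``embedding``
    node2vec: second-order biased random walks (return parameter ``p``,
    in-out parameter ``q``) generate sentence-like node sequences, and a
    skip-gram model with negative sampling places each node in a
    ``dim``-dimensional vector space where nearby nodes have similar vectors.
    The skip-gram trainer is implemented here directly in numpy so that the
    whole pipeline is deterministic under a single integer seed.

Every matrix carries a ``params_fingerprint`` string encoding the network,
representation and all construction parameters; models refuse to score
feature matrices whose fingerprint differs from the one they were trained on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .errors import ParameterError
from .network import GeneNetwork

logger = logging.getLogger(__name__)

REPRESENTATIONS = ("adjacency", "influence", "embedding")

DEFAULT_RESTART_PROB = 0.85
DEFAULT_EMBEDDING = dict(
    dim=128, walk_length=80, walks_per_node=10, window=10, p=1.0, q=1.0, epochs=5
)


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-gene feature vectors under one representation.

    ``genes`` matches the canonical node order of the source network;
    ``values`` is an ``n_genes x n_features`` dense array with no non-finite
    entries.
    """

    representation: str
    genes: tuple[str, ...]
    values: np.ndarray
    params_fingerprint: str

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]


def _fingerprint(network: GeneNetwork, representation: str, **params) -> str:
    items = "|".join(f"{k}={params[k]}" for k in sorted(params))
    return f"{representation}|network={network.name}|n={network.n_nodes}|{items}"


def adjacency_features(network: GeneNetwork) -> FeatureMatrix:
    """Features are the connections in the original network: ``X = W``."""
    values = network.adjacency().toarray().astype(float)
    return FeatureMatrix(
        representation="adjacency",
        genes=network.nodes,
        values=values,
        params_fingerprint=_fingerprint(network, "adjacency"),
    )


def transition_matrix(network: GeneNetwork) -> np.ndarray:
    """Row-normalized random-walk transition matrix ``P = D^{-1} W``."""
    adj = network.adjacency().toarray().astype(float)
    deg = adj.sum(axis=1)
    return adj / deg[:, None]


def influence_features(
    network: GeneNetwork, restart_prob: float = DEFAULT_RESTART_PROB
) -> FeatureMatrix:
    """Random-walk-with-restart diffusion kernel.

    Solves ``(I - (1 - alpha) P) F = alpha I`` as one linear system; because
    ``P`` has no entries between connected components the system is block
    diagonal and walk mass stays within each component.  Every row of the
    result sums to 1 and all entries are non-negative.
    """
    if not (0.0 < restart_prob <= 1.0):
        raise ParameterError(f"restart_prob must be in (0, 1], got {restart_prob}")
    alpha = restart_prob
    n = network.n_nodes
    system = np.eye(n) - (1.0 - alpha) * transition_matrix(network)
    values = scipy.linalg.solve(system, alpha * np.eye(n))
    np.clip(values, 0.0, None, out=values)  # scrub -0.0 / tiny negative round-off
    return FeatureMatrix(
        representation="influence",
        genes=network.nodes,
        values=values,
        params_fingerprint=_fingerprint(network, "influence", restart_prob=restart_prob),
    )


# ---------------------------------------------------------------------------
# node2vec embedding
# ---------------------------------------------------------------------------


def _neighbor_arrays(network: GeneNetwork):
    """CSR-style neighbor lists: per node, sorted neighbor indices + weights."""
    adj = network.adjacency().tocsr()
    nbrs, wts = [], []
    for i in range(network.n_nodes):
        start, end = adj.indptr[i], adj.indptr[i + 1]
        order = np.argsort(adj.indices[start:end])
        nbrs.append(adj.indices[start:end][order])
        wts.append(adj.data[start:end][order].astype(float))
    return nbrs, wts


def generate_walks(
    network: GeneNetwork,
    walk_length: int,
    walks_per_node: int,
    p: float,
    q: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Second-order biased random walks (the node2vec walk model).

    From edge ``(t, v)`` the unnormalized probability of stepping to ``x`` is
    ``w(v, x) / p`` if ``x == t``, ``w(v, x)`` if ``x`` is a neighbor of
    ``t``, and ``w(v, x) / q`` otherwise.  ``p = q = 1`` recovers the
    first-order weighted walk.
    """
    nbrs, wts = _neighbor_arrays(network)
    nbr_sets = [set(a.tolist()) for a in nbrs]
    walks: list[np.ndarray] = []
    for _ in range(walks_per_node):
        order = rng.permutation(network.n_nodes)
        for start in order:
            walk = [int(start)]
            while len(walk) < walk_length:
                v = walk[-1]
                cand, w = nbrs[v], wts[v]
                if len(cand) == 0:
                    break
                if len(walk) == 1 or (p == 1.0 and q == 1.0):
                    probs = w / w.sum()
                else:
                    t = walk[-2]
                    bias = np.where(
                        cand == t,
                        1.0 / p,
                        np.fromiter(
                            (1.0 if x in nbr_sets[t] else 1.0 / q for x in cand),
                            dtype=float,
                            count=len(cand),
                        ),
                    )
                    probs = w * bias
                    probs /= probs.sum()
                walk.append(int(rng.choice(cand, p=probs)))
            walks.append(np.asarray(walk, dtype=np.int64))
    return walks


def _skipgram_pairs(walks: list[np.ndarray], window: int) -> np.ndarray:
    """All (center, context) pairs within the fixed window, as an (m, 2) array."""
    pairs = []
    for walk in walks:
        L = len(walk)
        for pos in range(L):
            lo, hi = max(0, pos - window), min(L, pos + window + 1)
            for ctx in range(lo, hi):
                if ctx != pos:
                    pairs.append((walk[pos], walk[ctx]))
    return np.asarray(pairs, dtype=np.int64)


def _train_sgns(
    n_nodes: int,
    pairs: np.ndarray,
    counts: np.ndarray,
    dim: int,
    epochs: int,
    rng: np.random.Generator,
    n_negative: int = 5,
    lr0: float = 0.025,
    batch: int = 2048,
) -> np.ndarray:
    """Skip-gram with negative sampling, mini-batched SGD in numpy.

    Negatives are drawn from the unigram distribution raised to 3/4 (the
    standard smoothing).  The learning rate decays linearly over batches.
    Returns the input (center) vectors, the conventional node embedding.
    """
    noise = counts.astype(float) ** 0.75
    noise /= noise.sum()
    win = (rng.random((n_nodes, dim)) - 0.5) / dim
    wout = np.zeros((n_nodes, dim))

    m = len(pairs)
    n_batches_total = epochs * max(1, (m + batch - 1) // batch)
    step = 0
    for _ in range(epochs):
        perm = rng.permutation(m)
        for lo in range(0, m, batch):
            idx = perm[lo : lo + batch]
            centers, contexts = pairs[idx, 0], pairs[idx, 1]
            negs = rng.choice(n_nodes, size=(len(idx), n_negative), p=noise)
            lr = lr0 * max(1.0 - step / n_batches_total, 1e-4)
            step += 1

            vc = win[centers]  # (b, d)
            # positive examples
            uo = wout[contexts]
            score = 1.0 / (1.0 + np.exp(-np.einsum("bd,bd->b", vc, uo)))
            g = (score - 1.0)[:, None]  # d loss / d score
            grad_vc = g * uo
            np.add.at(wout, contexts, -lr * g * vc)
            # negative examples
            un = wout[negs]  # (b, k, d)
            nscore = 1.0 / (1.0 + np.exp(-np.einsum("bd,bkd->bk", vc, un)))
            grad_vc += np.einsum("bk,bkd->bd", nscore, un)
            np.add.at(
                wout,
                negs.ravel(),
                (-lr * nscore[..., None] * vc[:, None, :]).reshape(-1, dim),
            )
            np.add.at(win, centers, -lr * grad_vc)
    return win


def embedding_features(
    network: GeneNetwork,
    dim: int = DEFAULT_EMBEDDING["dim"],
    walk_length: int = DEFAULT_EMBEDDING["walk_length"],
    walks_per_node: int = DEFAULT_EMBEDDING["walks_per_node"],
    window: int = DEFAULT_EMBEDDING["window"],
    p: float = DEFAULT_EMBEDDING["p"],
    q: float = DEFAULT_EMBEDDING["q"],
    epochs: int = DEFAULT_EMBEDDING["epochs"],
    seed: int = 0,
) -> FeatureMatrix:
    """node2vec embedding of the network.

    Identical ``seed`` and parameters give a bitwise-identical matrix.  A
    warning is emitted when ``dim`` exceeds the node count (the embedding is
    then over-parameterized but still valid).
    """
    for pname, val in [
        ("dim", dim), ("walk_length", walk_length), ("walks_per_node", walks_per_node),
        ("window", window), ("p", p), ("q", q), ("epochs", epochs),
    ]:
        if val <= 0:
            raise ParameterError(f"{pname} must be positive, got {val}")
    if dim < 2:
        raise ParameterError(f"dim must be >= 2, got {dim}")
    if network.n_nodes < dim:
        warnings.warn(
            f"embedding dim {dim} exceeds node count {network.n_nodes}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    walks = generate_walks(network, walk_length, walks_per_node, p, q, rng)
    pairs = _skipgram_pairs(walks, window)
    counts = np.bincount(
        np.concatenate(walks), minlength=network.n_nodes
    )
    values = _train_sgns(network.n_nodes, pairs, counts, dim, epochs, rng)
    return FeatureMatrix(
        representation="embedding",
        genes=network.nodes,
        values=values,
        params_fingerprint=_fingerprint(
            network, "embedding",
            dim=dim, walk_length=walk_length, walks_per_node=walks_per_node,
            window=window, p=p, q=q, epochs=epochs, seed=seed,
        ),
    )


def build_features(network: GeneNetwork, representation: str, **params) -> FeatureMatrix:
    """Dispatch on representation name; unknown names raise ParameterError."""
    if representation == "adjacency":
        return adjacency_features(network)
    if representation == "influence":
        return influence_features(network, **params)
    if representation == "embedding":
        return embedding_features(network, **params)
    raise ParameterError(
        f"unknown representation {representation!r}; choose from {REPRESENTATIONS}"
    )
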