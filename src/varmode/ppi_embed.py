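"""Protein-interaction-network embedding via biased random walks + skip-gram.

Second-order (node2vec-style) random walks over a weighted undirected
graph, followed by skip-gram training with negative sampling, compress the
network into a fixed 64-dimensional vector per protein.  Edge weights are
interaction confidences rescaled to (0, 1] and act as walk-transition
weights.  The walk bias follows the return parameter ``p`` and in-out
parameter ``q``: from previous node t at current node v, the unnormalized
probability of stepping to x is w(v,x) * 1/p if x == t, * 1 if x neighbors
t, * 1/q otherwise.  Defaults (p=q=1, walk length 80, 10 walks per node,
window 10, 5 negatives, 5 epochs) are the standard node2vec settings; the
output dimension is fixed at 64 by default.

The skip-gram trainer is a compact vectorized SGD implementation
(minibatched, deterministic under a fixed seed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "read_edge_list",
    "write_embedding",
    "build_graph",
    "generate_walks",
    "embed",
    "embed_graph",
]

EMBEDDING_DIM = 64


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = ["node_a", "node_b", "weight"]
    if list(df.columns[:3]) != expected:
        df.columns = expected + list(df.columns[3:])
    return df


def build_graph(edges: pd.DataFrame) -> nx.Graph:
    """Weighted undirected graph from a 3-column edge list."""
    if len(edges) == 0:
        raise ValueError("empty edge list")
    g = nx.Graph()
    for a, b, w in edges.itertuples(index=False):
        if a == b:
            continue  # no self-loops
        w = float(w)
        if w <= 0:
            raise ValueError("edge weights must be positive")
        g.add_edge(a, b, weight=w)
    return g


def generate_walks(
    graph: nx.Graph,
    p: float = 1.0,
    q: float = 1.0,
    walk_length: int = 80,
    walks_per_node: int = 10,
    rng: np.random.Generator | None = None,
) -> list[list]:
    """Second-order biased random walks starting at every node.

    Isolated nodes yield single-node walks.  Node order is sorted for
    determinism under a fixed rng.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if rng is None:
        rng = np.random.default_rng(0)

    nodes = sorted(graph.nodes())
    nbrs = {
        v: (
            np.array(sorted(graph.neighbors(v)), dtype=object),
            np.array([graph[v][u]["weight"] for u in sorted(graph.neighbors(v))]),
        )
        for v in nodes
    }
    nbr_sets = {v: set(graph.neighbors(v)) for v in nodes}

    walks = []
    for _ in range(walks_per_node):
        for start in nodes:
            walk = [start]
            while len(walk) < walk_length:
                v = walk[-1]
                neighbors, weights = nbrs[v]
                if len(neighbors) == 0:
                    break
                if len(walk) == 1:
                    probs = weights / weights.sum()
                else:
                    t = walk[-2]
                    bias = np.ones(len(neighbors))
                    for i, x in enumerate(neighbors):
                        if x == t:
                            bias[i] = 1.0 / p
                        elif x in nbr_sets[t]:
                            bias[i] = 1.0
                        else:
                            bias[i] = 1.0 / q
                    w = weights * bias
                    probs = w / w.sum()
                walk.append(neighbors[rng.choice(len(neighbors), p=probs)])
            walks.append(walk)
    return walks


def _skipgram_pairs(walks: list[list], index: dict, window: int) -> np.ndarray:
    pairs = []
    for walk in walks:
        ids = [index[w] for w in walk]
        L = len(ids)
        for i in range(L):
            lo, hi = max(0, i - window), min(L, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((ids[i], ids[j]))
    return np.array(pairs, dtype=np.int64)


def embed(
    walks: list[list],
    dim: int = EMBEDDING_DIM,
    window: int = 10,
    epochs: int = 5,
    negative: int = 5,
    lr: float = 0.025,
    batch_size: int = 1024,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Skip-gram with negative sampling over walk corpora.

    Returns a mapping from node to its ``dim``-vector (input embedding).
    Deterministic under a fixed rng.  Vectors are not normalized.
    """
    if not walks:
        raise ValueError("no walks supplied")
    if rng is None:
        rng = np.random.default_rng(0)

    vocab = sorted({node for walk in walks for node in walk})
    if len(vocab) < 2:
        raise ValueError("vocabulary must contain at least 2 nodes")
    index = {node: i for i, node in enumerate(vocab)}
    V = len(vocab)

    counts = np.zeros(V)
    for walk in walks:
        for node in walk:
            counts[index[node]] += 1
    noise = counts ** 0.75
    noise /= noise.sum()

    pairs = _skipgram_pairs(walks, index, window)
    if len(pairs) == 0:
        # Walks of length 1 only: return random small vectors.
        return {v: (rng.random(dim) - 0.5) / dim for v in vocab}

    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))

    total_batches = epochs * int(np.ceil(len(pairs) / batch_size))
    batch_no = 0
    for _ in range(epochs):
        order = rng.permutation(len(pairs))
        for s in range(0, len(pairs), batch_size):
            batch = pairs[order[s: s + batch_size]]
            alpha = max(lr * (1 - batch_no / total_batches), lr * 1e-2)
            batch_no += 1
            c, o = batch[:, 0], batch[:, 1]
            neg = rng.choice(V, size=(len(batch), negative), p=noise)

            vc = W_in[c]                                   # (B, d)
            targets = np.concatenate([o[:, None], neg], axis=1)  # (B, 1+neg)
            vt = W_out[targets]                            # (B, 1+neg, d)
            score = np.einsum("bd,bkd->bk", vc, vt)
            sig = 1.0 / (1.0 + np.exp(-score))
            label = np.zeros_like(sig)
            label[:, 0] = 1.0
            g = (label - sig) * alpha                      # (B, 1+neg)

            grad_c = np.einsum("bk,bkd->bd", g, vt)
            grad_t = g[..., None] * vc[:, None, :]
            np.add.at(W_in, c, grad_c)
            np.add.at(W_out, targets.ravel(), grad_t.reshape(-1, dim))

    return {v: W_in[index[v]].copy() for v in vocab}


def embed_graph(
    graph: nx.Graph,
    dim: int = EMBEDDING_DIM,
    p: float = 1.0,
    q: float = 1.0,
    walk_length: int = 80,
    walks_per_node: int = 10,
    window: int = 10,
    epochs: int = 5,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Walks + skip-gram in one call."""
    rng = np.random.default_rng(seed)
    walks = generate_walks(
        graph, p=p, q=q, walk_length=walk_length,
        walks_per_node=walks_per_node, rng=rng,
    )
    return embed(walks, dim=dim, window=window, epochs=epochs, rng=rng)


def write_embedding(embedding: dict[str, np.ndarray], path) -> None:
    dim = len(next(iter(embedding.values())))
    df = pd.DataFrame(
        [[k, *v] for k, v in sorted(embedding.items())],
        columns=["protein"] + [f"e{i + 1}" for i in range(dim)],
    )
    df.to_csv(path, sep="\t", index=False)
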