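"""Embed an interaction network and check that structure is preserved.

Generates a two-community planted-partition graph, embeds it with biased
random walks + skip-gram, and compares cosine similarity within and
between the known communities: proteins interacting with the same
partners should receive nearby vectors.
"""

import numpy as np

from varmode.ppi_embed import build_graph, embed_graph
from varmode.simulate import gen_ppi

edges, membership = gen_ppi(15, 2, p_in=0.5, p_out=0.03, seed=1)
graph = build_graph(edges)
print(f"graph: {graph.number_of_nodes()} proteins, {graph.number_of_edges()} edges")

embedding = embed_graph(graph, dim=64, walk_length=30, walks_per_node=8,
                        window=5, epochs=3, seed=0)
nodes = sorted(embedding)
E = np.array([embedding[n] for n in nodes])
E /= np.linalg.norm(E, axis=1, keepdims=True)
labels = np.array([membership[n] for n in nodes])
S = E @ E.T
intra = (S[np.ix_(labels == 0, labels == 0)].mean()
         + S[np.ix_(labels == 1, labels == 1)].mean()) / 2
inter = S[np.ix_(labels == 0, labels == 1)].mean()
print(f"embedding dimension: {E.shape[1]}")
print(f"mean cosine similarity within communities:  {intra:.3f}")
print(f"mean cosine similarity between communities: {inter:.3f}")
print("A clear intra > inter gap means the 64-dimensional vectors encode "
      "each protein's place in the network.")
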