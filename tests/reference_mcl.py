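"""Independent reference implementation of Markov clustering.

Deliberately written as a second, separate route for cross-checking the
package's MCL: dense matrices without pruning, convergence judged by
idempotence of the whole matrix, and clusters read out as connected
components of the binarised limit matrix.  Shares no code with the
implementation under test.
"""

from __future__ import annotations

import networkx as nx
import numpy as np


def reference_mcl(
    nodes: list[str],
    weighted_edges: list[tuple[str, str, float]],
    inflation: float,
    max_iter: int = 200,
) -> list[set[str]]:
    order = sorted(nodes)
    pos = {v: i for i, v in enumerate(order)}
    n = len(order)
    a = np.eye(n)
    for u, v, w in weighted_edges:
        a[pos[u], pos[v]] = w
        a[pos[v], pos[u]] = w
    m = a / a.sum(axis=0)
    for _ in range(max_iter):
        m = m @ m
        m = m**inflation
        m = m / m.sum(axis=0)
        if np.allclose(m @ m, m, atol=1e-12):
            break
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > 1e-7)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return [
        {order[i] for i in comp} for comp in nx.connected_components(support)
    ]


def planted_partition_graph(
    n_blocks: int,
    block_size: int,
    p_in: float,
    p_out: float,
    seed: int,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Unweighted (unit-weight) planted-partition benchmark graph."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{b:02d}_{i:02d}" for b in range(n_blocks) for i in range(block_size)]
    block = {v: int(v[1:3]) for v in nodes}
    edges = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            p = p_in if block[u] == block[v] else p_out
            if rng.random() < p:
                edges.append((u, v, 1.0))
    return nodes, edges
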