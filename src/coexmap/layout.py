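"""Deterministic force-directed graph layout in three dimensions.

A Fruchterman-Reingold layout with the attractive force along each edge
scaled linearly by its correlation weight: strongly coexpressed probe
pairs are pulled closer than weakly coexpressed ones.  Positions start
seeded-uniform in the unit cube and displacements are capped by a
temperature that cools linearly to zero, so the result is reproducible
given the seed.
"""

from __future__ import annotations

import numpy as np

from .network import CorrelationGraph

__all__ = ["fr_layout"]


def fr_layout(
    g: CorrelationGraph,
    iterations: int = 100,
    seed: int = 0,
    include_isolated: bool = True,
) -> dict[str, tuple[float, float, float]]:
    """3-D Fruchterman-Reingold coordinates for every graph node.

    Repulsion acts between all node pairs (force ~ k^2/d), attraction
    along edges (force ~ w * d^2/k) with the edge weight w scaling the
    pull; k is the ideal pairwise distance for the node count.  A single
    node is placed at the origin.
    """
    nodes = g.nodes
    if include_isolated:
        nodes = sorted(set(nodes) | set(g.isolated))
    if not nodes:
        raise ValueError("graph has no nodes to lay out")
    n = len(nodes)
    if n == 1:
        return {nodes[0]: (0.0, 0.0, 0.0)}
    index = {v: i for i, v in enumerate(nodes)}
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, 1.0, size=(n, 3))
    weights = np.zeros((n, n), dtype=float)
    for (a, b), w in g.edges.items():
        i, j = index[a], index[b]
        weights[i, j] = w
        weights[j, i] = w
    k = (1.0 / n) ** (1.0 / 3.0)  # ideal distance for unit-cube volume
    t0 = 0.1
    for it in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, 1e-9)
        unit = delta / dist[:, :, None]
        repulse = (k * k) / dist
        attract = weights * (dist * dist) / k
        force = (repulse - attract)[:, :, None] * unit
        disp = force.sum(axis=1)
        length = np.linalg.norm(disp, axis=1, keepdims=True)
        length = np.maximum(length, 1e-9)
        temperature = t0 * (1.0 - it / iterations)
        pos = pos + disp / length * np.minimum(length, temperature)
    pos = pos - pos.mean(axis=0)
    return {v: tuple(float(x) for x in pos[index[v]]) for v in nodes}
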