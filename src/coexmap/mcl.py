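"""Weighted Markov clustering (MCL) of coexpression graphs.

MCL simulates random flow through a graph: a column-stochastic transition
matrix is alternately *expanded* (squared, letting flow spread) and
*inflated* (raised entrywise to a power > 1 and renormalised, boosting
strong currents and starving weak ones).  The process converges to a
sparse idempotent-like limit whose attractor systems are read off as
clusters.  The inflation exponent sets cluster granularity; 2.2 is the
default used throughout for highly structured expression graphs.

Clusters are named by relative size: the largest cluster is "Cluster 1".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import probe_symbol
from .network import CorrelationGraph

__all__ = ["MclParams", "ClusterSet", "mcl_cluster", "cluster_sizes"]


@dataclass
class MclParams:
    """Tuning knobs of the MCL iteration.

    Attributes
    ----------
    inflation
        Entrywise power applied after each expansion; must exceed 1.
        Larger values yield smaller, tighter clusters.
    self_loop_weight
        Weight of the self-loop added to every node before
        normalisation; canonical MCL uses 1.
    prune_below
        Matrix entries below this value are zeroed (then columns
        renormalised) to keep the flow matrix sparse in effect.
    max_iterations
        Hard cap on expansion/inflation rounds.
    convergence_tol
        Iteration stops once the max absolute entry change falls below
        this tolerance.
    """

    inflation: float = 2.2
    self_loop_weight: float = 1.0
    prune_below: float = 1e-5
    max_iterations: int = 100
    convergence_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.inflation > 1:
            raise ValueError("inflation must be > 1")
        if self.self_loop_weight < 0:
            raise ValueError("self_loop_weight must be >= 0")
        if not self.prune_below < 1:
            raise ValueError("prune_below must be < 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


@dataclass
class ClusterSet:
    """Size-ranked partition of graph nodes.

    ``clusters`` is ordered by size descending (ties broken by the
    lexicographically smallest member), so ``names[0] == "Cluster 1"``
    is the largest.  ``unassigned`` holds isolated nodes when singleton
    clusters are not kept.
    """

    clusters: list[list[str]]
    unassigned: list[str] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for members in self.clusters:
            for m in members:
                if m in seen:
                    raise ValueError(f"node {m!r} appears in more than one cluster")
                seen.add(m)
        overlap = seen & set(self.unassigned)
        if overlap:
            raise ValueError(f"nodes both clustered and unassigned: {sorted(overlap)[:3]}")
        sizes = [len(c) for c in self.clusters]
        if sizes != sorted(sizes, reverse=True):
            raise ValueError("clusters must be sorted by size, largest first")

    @property
    def names(self) -> list[str]:
        return [f"Cluster {i + 1}" for i in range(len(self.clusters))]

    def as_mapping(self) -> dict[str, list[str]]:
        return dict(zip(self.names, self.clusters))

    def labels(self) -> dict[str, int]:
        """Node -> 0-based cluster rank, for partition comparisons."""
        out: dict[str, int] = {}
        for k, members in enumerate(self.clusters):
            for m in members:
                out[m] = k
        return out

    def universe(self) -> set[str]:
        return set(self.labels()) | set(self.unassigned)


def _rank_clusters(groups: list[list[str]]) -> list[list[str]]:
    groups = [sorted(g) for g in groups]
    return sorted(groups, key=lambda g: (-len(g), g[0]))


def mcl_cluster(
    g: CorrelationGraph,
    params: MclParams | None = None,
    keep_singletons: bool = True,
) -> ClusterSet:
    """Cluster a weighted coexpression graph with MCL.

    The adjacency matrix (edge weights, plus self-loops of
    ``params.self_loop_weight``) is column-normalised and iterated:
    expansion (matrix squaring), inflation (entrywise power and column
    renormalisation) and pruning of entries below ``params.prune_below``,
    until the largest entrywise change drops under
    ``params.convergence_tol``.  Clusters are the attractor systems of
    the limit matrix: rows with a positive diagonal are attractors,
    attractors connected through residual flow form one system, and each
    remaining node joins the system it flows into.  A node reachable
    from several systems joins the larger cluster; exact ties go to the
    cluster containing the lexicographically smallest node.

    Non-convergence within ``max_iterations`` is reported via a warning
    and the ``converged`` flag, not an exception.

    Isolated nodes of ``g`` become singleton clusters when
    ``keep_singletons`` is true, otherwise they are listed as
    ``unassigned``.
    """
    if params is None:
        params = MclParams()
    nodes = g.nodes
    if not nodes and not g.isolated:
        raise ValueError("graph has no nodes")
    converged = True
    groups: list[list[str]] = []
    if nodes:
        index = {v: i for i, v in enumerate(nodes)}
        n = len(nodes)
        adj = np.zeros((n, n), dtype=float)
        for (a, b), w in g.edges.items():
            i, j = index[a], index[b]
            adj[i, j] = w
            adj[j, i] = w
        adj[np.diag_indices(n)] = params.self_loop_weight
        m = _normalise_columns(adj)
        for _ in range(params.max_iterations):
            expanded = m @ m
            inflated = _normalise_columns(np.power(expanded, params.inflation))
            inflated[inflated < params.prune_below] = 0.0
            inflated = _normalise_columns(inflated)
            delta = np.max(np.abs(inflated - m))
            m = inflated
            if delta < params.convergence_tol:
                break
        else:
            converged = False
            warnings.warn(
                f"MCL did not converge within {params.max_iterations} iterations; "
                "returning the current clustering",
                RuntimeWarning,
                stacklevel=2,
            )
        groups = _interpret_limit(m, nodes)
    clusters = groups
    unassigned: list[str] = []
    if keep_singletons:
        clusters = clusters + [[v] for v in g.isolated]
    else:
        unassigned = sorted(g.isolated)
    return ClusterSet(
        clusters=_rank_clusters(clusters),
        unassigned=unassigned,
        converged=converged,
    )


def _normalise_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    # columns emptied by pruning keep a unit self-loop so flow is conserved
    dead = sums == 0.0
    if np.any(dead):
        m = m.copy()
        idx = np.nonzero(dead)[0]
        m[idx, idx] = 1.0
        sums = m.sum(axis=0)
    return m / sums


def _interpret_limit(m: np.ndarray, nodes: list[str]) -> list[list[str]]:
    """Read attractor systems out of the (near-)idempotent limit matrix."""
    eps = 1e-9
    n = len(nodes)
    diag = np.diagonal(m)
    attractors = np.nonzero(diag > eps)[0]
    if attractors.size == 0:
        # fully degenerate flow: fall back to connected components
        attractors = np.arange(n)
    # attractors sharing residual flow belong to one attractor system
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    att_set = set(attractors.tolist())
    for a in attractors:
        flow = np.nonzero(m[a, :] > eps)[0]
        for b in flow:
            if b in att_set:
                union(int(a), int(b))
        flow_in = np.nonzero(m[:, a] > eps)[0]
        for b in flow_in:
            if b in att_set:
                union(int(a), int(b))
    systems: dict[int, list[int]] = {}
    for a in attractors:
        systems.setdefault(find(int(a)), []).append(int(a))
    # assign every node to the system(s) it flows into
    membership: dict[int, set[int]] = {root: set(mem) for root, mem in systems.items()}
    ambiguous: list[tuple[int, list[int]]] = []
    for j in range(n):
        if j in att_set:
            continue
        roots = {find(int(a)) for a in attractors if m[a, j] > eps}
        if not roots:
            # no resolvable flow (numerically starved column): own singleton
            membership.setdefault(-j - 1, set()).add(j)
        elif len(roots) == 1:
            membership[roots.pop()].add(j)
        else:
            ambiguous.append((j, sorted(roots)))
    # overlapping nodes join the larger cluster; ties go to the cluster
    # holding the lexicographically smallest node id
    for j, roots in ambiguous:
        best = max(
            roots,
            key=lambda r: (len(membership[r]), _min_name(membership[r], nodes)),
        )
        membership[best].add(j)
    return [[nodes[i] for i in mem] for mem in membership.values()]


class _ReverseStr(str):
    """Orders lexicographically smaller strings as larger, for use in max()."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def _min_name(members: set[int], nodes: list[str]) -> "_ReverseStr":
    return _ReverseStr(min(nodes[i] for i in members))


def cluster_sizes(cs: ClusterSet) -> list[tuple[str, int, int]]:
    """Per-cluster (name, probeset count, distinct gene count).

    Gene counts collapse ``SYMBOL|PROBESET`` identifiers to their symbol;
    probes lacking a symbol each count as their own gene.
    """
    out: list[tuple[str, int, int]] = []
    for name, members in zip(cs.names, cs.clusters):
        genes = {probe_symbol(m) for m in members}
        out.append((name, len(members), len(genes)))
    return out
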