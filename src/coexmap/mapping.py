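"""Hypergeometric overlap testing between clusterings and gene sets.

Conservation mapping asks whether a "core signature" — a cluster from
the merged mean-correlation network — is over-represented in some
cluster of an independently analysed dataset.  Every (signature, target
cluster) pair is scored with a one-sided Fisher/hypergeometric test over
the universe of identifiers observable in both analyses, p-values are
adjusted jointly (Benjamini-Hochberg by default), and each signature is
reported with its best-matching target cluster.

The same machinery drives generic gene-set enrichment of clusters
against a GMT collection, with probe identifiers collapsed to gene
symbols first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, probe_symbol
from .mcl import ClusterSet

__all__ = [
    "EnrichmentResult",
    "ConservationTable",
    "fisher_overlap",
    "adjust_pvalues",
    "map_signatures",
    "enrich_gene_sets",
]


@dataclass
class EnrichmentResult:
    """Overlap statistics for one (query, set) pair.

    ``k`` of the ``n`` query members fall in the set of size ``K`` drawn
    from a universe of ``N`` identifiers.
    """

    query_name: str
    set_name: str
    k: int
    n: int
    K: int
    N: int
    odds_ratio: float
    p_raw: float
    p_adjusted: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) <= self.N):
            raise ValueError(
                f"inconsistent overlap counts k={self.k} n={self.n} "
                f"K={self.K} N={self.N}"
            )


@dataclass
class ConservationTable:
    """Best target-cluster match per core signature, plus the full table."""

    best: dict[str, EnrichmentResult]
    all_results: list[EnrichmentResult]
    unmapped: list[str]

    def significant(self, alpha: float) -> dict[str, EnrichmentResult]:
        return {
            name: res
            for name, res in self.best.items()
            if res.p_adjusted < alpha
        }


def fisher_overlap(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """One-sided over-representation test of a k-element overlap.

    Returns ``(odds_ratio, p_raw)`` where ``p_raw = P(X >= k)`` for
    ``X ~ Hypergeometric(N, K, n)``.  The odds ratio comes from the 2x2
    table with a 0.5 Haldane correction applied when any cell is zero.
    """
    if not (0 <= k <= min(n, K) and max(n, K) <= N):
        raise ValueError(
            f"require 0 <= k <= min(n, K) and n, K <= N, got k={k} n={n} K={K} N={N}"
        )
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(1.0, max(p, 0.0))
    a = k
    b = K - k
    c = n - k
    d = N - K - n + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return float(odds), p


def adjust_pvalues(ps: Sequence[float], method: str = "bh") -> list[float]:
    """Multiple-testing adjustment (Benjamini-Hochberg or Bonferroni).

    Output order matches input order.
    """
    ps = list(ps)
    if not ps:
        return []
    for p in ps:
        if not (0 < p <= 1):
            raise ValueError(f"p-value {p} outside (0, 1]")
    key = method.lower()
    if key in ("bh", "fdr_bh", "benjamini-hochberg"):
        sm_method = "fdr_bh"
    elif key == "bonferroni":
        sm_method = "bonferroni"
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    _, adjusted, _, _ = multipletests(ps, method=sm_method)
    return [float(p) for p in adjusted]


def _overlap_tests(
    queries: dict[str, set[str]],
    targets: dict[str, set[str]],
    universe: set[str],
    method: str,
) -> list[EnrichmentResult]:
    results: list[EnrichmentResult] = []
    N = len(universe)
    for qname, qset in queries.items():
        n = len(qset)
        for tname, tset in targets.items():
            K = len(tset)
            k = len(qset & tset)
            odds, p = fisher_overlap(k, n, K, N)
            results.append(
                EnrichmentResult(
                    query_name=qname,
                    set_name=tname,
                    k=k,
                    n=n,
                    K=K,
                    N=N,
                    odds_ratio=odds,
                    p_raw=p,
                )
            )
    if results:
        adjusted = adjust_pvalues([r.p_raw for r in results], method=method)
        for r, pa in zip(results, adjusted):
            r.p_adjusted = pa
    return results


def _restrict(named_sets: dict[str, Iterable[str]], universe: set[str]) -> tuple[dict[str, set[str]], list[str]]:
    kept: dict[str, set[str]] = {}
    dropped: list[str] = []
    for name, members in named_sets.items():
        inter = set(members) & universe
        if inter:
            kept[name] = inter
        else:
            dropped.append(name)
    return kept, dropped


def map_signatures(
    core: ClusterSet,
    target: ClusterSet,
    universe: Iterable[str],
    method: str = "bh",
    min_cluster_size: int = 1,
) -> ConservationTable:
    """Map core-signature clusters onto the clusters of another dataset.

    Clusters on both sides are first intersected with ``universe`` (the
    probe identifiers observable in both analyses).  Every remaining
    (core, target) pair is Fisher-tested; adjustment is joint across all
    pairs.  Each core signature is reported with the target cluster
    attaining the minimal adjusted p-value (ties broken by raw p, then
    larger overlap, then target name).  Core clusters emptied by the
    universe intersection are reported as unmapped, with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    core_sets = {
        name: members
        for name, members in core.as_mapping().items()
        if len(members) >= min_cluster_size
    }
    target_sets = {
        name: members
        for name, members in target.as_mapping().items()
        if len(members) >= min_cluster_size
    }
    queries, unmapped = _restrict(core_sets, universe)
    targets, _ = _restrict(target_sets, universe)
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} core signature(s) have no members in the shared "
            f"universe and were skipped: {unmapped[:5]}",
            RuntimeWarning,
            stacklevel=2,
        )
    results = _overlap_tests(queries, targets, universe, method)
    best: dict[str, EnrichmentResult] = {}
    for r in results:
        cur = best.get(r.query_name)
        if cur is None or (r.p_adjusted, r.p_raw, -r.k, r.set_name) < (
            cur.p_adjusted,
            cur.p_raw,
            -cur.k,
            cur.set_name,
        ):
            best[r.query_name] = r
    return ConservationTable(best=best, all_results=results, unmapped=unmapped)


def enrich_gene_sets(
    cs: ClusterSet,
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
    method: str = "bh",
) -> list[EnrichmentResult]:
    """Gene-level enrichment of clusters against a GMT collection.

    Probe identifiers are collapsed to gene symbols before testing.  The
    universe defaults to all symbols present in the clustering; an
    explicit universe (probe or gene identifiers) may be supplied and is
    likewise collapsed to symbols.
    """
    if universe is None:
        uni = {probe_symbol(p) for p in cs.universe()}
    else:
        uni = {probe_symbol(p) for p in universe}
    if not uni:
        raise ValueError("universe must be non-empty")
    queries_raw = {
        name: {probe_symbol(m) for m in members}
        for name, members in cs.as_mapping().items()
    }
    queries, _ = _restrict(queries_raw, uni)
    sets, _ = _restrict(dict(collection.sets), uni)
    return _overlap_tests(queries, sets, uni, method)
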