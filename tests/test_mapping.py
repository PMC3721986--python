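import math
from math import comb

import numpy as np
import pytest

from coexmap import (
    ClusterSet,
    GeneSetCollection,
    adjust_pvalues,
    enrich_gene_sets,
    fisher_overlap,
    map_signatures,
)


def enumerated_tail(k, n, K, N):
    """P(X >= k) for X ~ Hypergeom(N, K, n), by direct summation."""
    return sum(
        comb(K, j) * comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
        if n - j <= N - K
    ) / comb(N, n)


class TestFisherOverlap:
    def test_zero_overlap_has_p_one(self):
        _, p = fisher_overlap(0, 5, 5, 20)
        assert p == pytest.approx(1.0)

    def test_complete_overlap_matches_enumeration(self):
        _, p = fisher_overlap(5, 5, 5, 10)
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_partial_overlap_matches_direct_sum(self):
        _, p = fisher_overlap(2, 3, 4, 10)
        assert p == pytest.approx(40 / 120, rel=1e-12)

    def test_matches_enumeration_exhaustively_small_universes(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        _, p = fisher_overlap(k, n, K, N)
                        assert p == pytest.approx(
                            enumerated_tail(k, n, K, N), rel=1e-9, abs=1e-12
                        ), (k, n, K, N)

    def test_p_strictly_decreases_in_k(self):
        ps = [fisher_overlap(k, 10, 10, 50)[1] for k in range(11)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_bound_violations_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap(6, 5, 10, 20)
        with pytest.raises(ValueError):
            fisher_overlap(2, 5, 30, 20)

    def test_odds_ratio_with_haldane_correction(self):
        odds, _ = fisher_overlap(5, 5, 5, 10)  # zero cells -> 0.5 correction
        assert math.isfinite(odds) and odds > 1
        odds2, _ = fisher_overlap(3, 5, 5, 12)
        assert odds2 == pytest.approx((3 * 5) / (2 * 2))


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.037]) == [pytest.approx(0.037)]

    def test_bh_step_up_hand_example(self):
        assert adjust_pvalues([0.01, 0.02, 0.03], "bh") == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_bonferroni_multiplies_and_caps(self):
        assert adjust_pvalues([0.01, 0.5], "bonferroni") == pytest.approx([0.02, 1.0])

    def test_order_preserved(self):
        ps = [0.04, 0.001, 0.2, 0.01]
        adj = adjust_pvalues(ps, "bh")
        assert np.argmin(adj) == 1

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(1)
        ps = rng.uniform(1e-6, 1, size=50).tolist()
        for method in ("bh", "bonferroni"):
            for raw, adj in zip(ps, adjust_pvalues(ps, method)):
                assert adj >= raw - 1e-15

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.0, 0.5])
        with pytest.raises(ValueError):
            adjust_pvalues([1.5])


def random_partition(ids, rng, low=150, high=250):
    ids = list(ids)
    rng.shuffle(ids)
    clusters, i = [], 0
    while i < len(ids):
        size = int(rng.integers(low, high + 1))
        clusters.append(ids[i : i + size])
        i += size
    clusters = [c for c in clusters if len(c) >= low // 2]
    return ClusterSet(
        clusters=sorted([sorted(c) for c in clusters], key=lambda c: (-len(c), c[0]))
    )


class TestMapSignatures:
    def test_self_mapping_is_perfect(self):
        cs = ClusterSet(clusters=[["A", "B", "C"], ["D", "E"]])
        table = map_signatures(cs, cs, universe={"A", "B", "C", "D", "E"})
        for name, members in cs.as_mapping().items():
            best = table.best[name]
            assert best.set_name == name
            assert best.k == best.n == len(members)

    def test_null_partitions_show_no_significant_match(self):
        rng = np.random.default_rng(11)
        ids = [f"P{i:04d}" for i in range(1000)]
        core = random_partition(ids, rng, 80, 120)
        target = random_partition(ids, rng, 80, 120)
        table = map_signatures(core, target, universe=set(ids))
        assert min(r.p_adjusted for r in table.all_results) > 0.01

    def test_cluster_outside_universe_is_unmapped_with_warning(self):
        core = ClusterSet(clusters=[["A", "B"], ["X", "Y"]])
        target = ClusterSet(clusters=[["A", "B", "C"]])
        with pytest.warns(RuntimeWarning, match="universe"):
            table = map_signatures(core, target, universe={"A", "B", "C"})
        assert table.unmapped == ["Cluster 2"]
        assert set(table.best) == {"Cluster 1"}

    def test_empty_universe_rejected(self):
        cs = ClusterSet(clusters=[["A"]])
        with pytest.raises(ValueError):
            map_signatures(cs, cs, universe=set())

    def test_adjustment_is_joint_across_all_pairs(self):
        cs = ClusterSet(clusters=[["A", "B"], ["C", "D"]])
        table = map_signatures(cs, cs, universe={"A", "B", "C", "D"})
        raw = sorted(r.p_raw for r in table.all_results)
        adj = adjust_pvalues([r.p_raw for r in table.all_results])
        assert sorted(adj) == sorted(r.p_adjusted for r in table.all_results)
        assert len(table.all_results) == 4  # 2 core x 2 target
        assert raw[0] <= adj[0]


class TestEnrichGeneSets:
    def test_exact_set_is_top_hit(self):
        cs = ClusterSet(
            clusters=[
                ["CD14|1_at", "CD163|2_at", "CSF1R|3_at"],
                ["COL1A1|4_at", "FN1|5_at"],
            ]
        )
        coll = GeneSetCollection(
            sets={"macrophage": ["CD14", "CD163", "CSF1R"], "ecm": ["COL1A1", "FN1"]}
        )
        results = enrich_gene_sets(cs, coll)
        best = {}
        for r in results:
            if r.query_name not in best or r.p_raw < best[r.query_name].p_raw:
                best[r.query_name] = r
        assert best["Cluster 1"].set_name == "macrophage"
        assert best["Cluster 2"].set_name == "ecm"

    def test_empty_collection_gives_empty_result(self):
        cs = ClusterSet(clusters=[["A|1", "B|2"]])
        assert enrich_gene_sets(cs, GeneSetCollection(sets={})) == []

    def test_probe_ids_collapse_to_genes(self):
        # two probesets of one gene count once at gene level
        cs = ClusterSet(clusters=[["HBA1|1_at", "HBA1|2_at", "HBB|3_at"]])
        coll = GeneSetCollection(sets={"haemoglobin": ["HBA1", "HBB"]})
        (r,) = [
            r for r in enrich_gene_sets(cs, coll) if r.set_name == "haemoglobin"
        ]
        assert r.k == 2 and r.n == 2

    def test_recovered_programs_hit_their_truth_sets(self, benchmark_dataset):
        from coexmap import build_graph, correlation_matrix, mcl_cluster, truth_gene_sets

        matrix, truth = benchmark_dataset
        cs = mcl_cluster(build_graph(correlation_matrix(matrix), 0.7))
        results = enrich_gene_sets(
            cs, truth_gene_sets(truth), universe=matrix.row_ids
        )
        for name, members in cs.as_mapping().items():
            if len(members) < 20:
                continue
            majority = {truth.probe_program(m) for m in members}
            assert len(majority) == 1
            (program,) = majority
            hits = [r for r in results if r.query_name == name]
            top = min(hits, key=lambda r: (r.p_adjusted, r.p_raw))
            assert top.set_name == program
            assert top.p_adjusted < 1e-10
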