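import math

import numpy as np
import pytest

from coexmap import (
    CorrelationMatrix,
    ExpressionMatrix,
    build_graph,
    correlation_matrix,
    mean_pearson,
    pearson_correlation,
    select_threshold,
)
from coexmap.network import default_threshold_grid, included_fraction


def brute_force_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


class TestPearsonCorrelation:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),
        ],
    )
    def test_hand_evaluated_values(self, x, y, expected):
        assert pearson_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pearson_correlation([1, 2, 3], [1, 2, 3, 4])

    def test_zero_variance_is_undefined(self):
        assert math.isnan(pearson_correlation([5, 5, 5], [1, 2, 3]))

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.uniform(0, 100, size=15)
            y = rng.uniform(0, 100, size=15)
            assert pearson_correlation(x, y) == pytest.approx(
                brute_force_pearson(list(x), list(y)), abs=1e-12
            )


class TestCorrelationMatrix:
    def _matrix(self, values):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(
            row_ids=[f"P{i}" for i in range(values.shape[0])],
            sample_ids=[f"S{j}" for j in range(values.shape[1])],
            values=values,
        )

    def test_identical_rows_correlate_perfectly(self):
        m = self._matrix([[1, 2, 3, 4], [1, 2, 3, 4]])
        c = correlation_matrix(m)
        assert c.r[0, 1] == pytest.approx(1.0)

    def test_constant_probe_rows_are_undefined(self):
        m = self._matrix([[5, 5, 5, 5], [1, 2, 3, 4], [4, 3, 2, 1]])
        c = correlation_matrix(m)
        assert np.isnan(c.r[0, 1]) and np.isnan(c.r[2, 0])
        assert np.isfinite(c.r[1, 2])

    def test_matches_per_pair_oracle(self):
        rng = np.random.default_rng(10)
        m = self._matrix(rng.uniform(0, 50, size=(10, 20)))
        c = correlation_matrix(m)
        for i in range(10):
            for j in range(i + 1, 10):
                expected = pearson_correlation(m.values[i], m.values[j])
                assert c.r[i, j] == pytest.approx(expected, abs=1e-10)
                assert c.r[j, i] == pytest.approx(expected, abs=1e-10)

    def test_block_size_does_not_change_results(self):
        rng = np.random.default_rng(11)
        m = self._matrix(rng.uniform(0, 50, size=(50, 30)))
        full = correlation_matrix(m, block_size=4096).r
        for bs in (1, 7, 50):
            np.testing.assert_allclose(
                correlation_matrix(m, block_size=bs).r, full, atol=1e-12
            )

    def test_matches_brute_force_oracle_50x30(self):
        rng = np.random.default_rng(12)
        m = self._matrix(rng.uniform(0, 100, size=(50, 30)))
        c = correlation_matrix(m)
        for i in range(0, 50, 7):
            for j in range(i + 1, 50, 5):
                expected = brute_force_pearson(list(m.values[i]), list(m.values[j]))
                assert c.r[i, j] == pytest.approx(expected, abs=1e-10)


def _corr_from_pairs(ids, pairs):
    n = len(ids)
    r = np.eye(n)
    index = {v: i for i, v in enumerate(ids)}
    for (a, b), w in pairs.items():
        r[index[a], index[b]] = w
        r[index[b], index[a]] = w
    return CorrelationMatrix(ids=list(ids), r=r)


class TestBuildGraph:
    def test_enumerated_thresholding(self):
        c = _corr_from_pairs("ABC", {("A", "B"): 0.9, ("A", "C"): 0.5, ("B", "C"): 0.7})
        g = build_graph(c, 0.65)
        assert set(g.edges) == {("A", "B"), ("B", "C")}
        assert g.nodes == ["A", "B", "C"]
        assert g.isolated == []

    def test_threshold_above_max_gives_empty_graph(self):
        c = _corr_from_pairs("AB", {("A", "B"): 0.7})
        g = build_graph(c, 0.71)
        assert g.n_edges == 0
        assert g.isolated == ["A", "B"]

    def test_negative_correlations_never_form_edges(self):
        c = _corr_from_pairs("AB", {("A", "B"): -0.95})
        g = build_graph(c, 0.6)
        assert g.n_edges == 0

    def test_undefined_entries_never_form_edges(self):
        c = _corr_from_pairs("ABC", {("A", "B"): np.nan, ("A", "C"): 0.8})
        g = build_graph(c, 0.6)
        assert set(g.edges) == {("A", "C")}

    def test_nonpositive_threshold_rejected(self):
        c = _corr_from_pairs("AB", {("A", "B"): 0.7})
        with pytest.raises(ValueError):
            build_graph(c, 0.0)

    def test_monotone_nesting_across_thresholds(self, benchmark_dataset):
        matrix, _ = benchmark_dataset
        c = correlation_matrix(matrix)
        edge_sets = [set(build_graph(c, t).edges) for t in (0.6, 0.7, 0.8)]
        assert edge_sets[2] <= edge_sets[1] <= edge_sets[0]


class TestSelectThreshold:
    def test_enumerated_example_with_tie_break(self):
        c = _corr_from_pairs("ABCD", {("A", "B"): 0.85, ("C", "D"): 0.65})
        # fractions: 1.0 at 0.6, 0.5 at 0.7, 0.5 at 0.8 -> tie broken low
        assert select_threshold(c, 0.5, [0.6, 0.7, 0.8]) == 0.7

    def test_full_tie_returns_lowest_grid_value(self):
        c = _corr_from_pairs("ABC", {("A", "B"): 0.99, ("A", "C"): 0.99, ("B", "C"): 0.99})
        assert select_threshold(c, 1.0, [0.6, 0.7, 0.8]) == 0.6

    def test_deviation_is_minimal_over_grid(self):
        from coexmap import MixtureConfig, simulate_tumor_dataset

        matrix, _ = simulate_tumor_dataset(MixtureConfig(seed=3, noise_sigma=0.3))
        c = correlation_matrix(matrix)
        grid = default_threshold_grid()
        r_sel = select_threshold(c, 0.40, grid)
        best_dev = abs(included_fraction(c, r_sel) - 0.40)
        for t in grid:
            assert best_dev <= abs(included_fraction(c, t) - 0.40) + 1e-12

    def test_empty_matrix_rejected(self):
        c = CorrelationMatrix(ids=[], r=np.zeros((0, 0)))
        with pytest.raises(ValueError, match="empty"):
            select_threshold(c)


class TestMeanPearson:
    def test_arithmetic_mean_of_entries(self):
        cs = [
            _corr_from_pairs("AB", {("A", "B"): w}) for w in (0.8, 0.6, 0.7)
        ]
        merged = mean_pearson(cs)
        assert merged.r[0, 1] == pytest.approx(0.7)

    def test_single_input_is_identity(self):
        c = _corr_from_pairs("AB", {("A", "B"): 0.42})
        np.testing.assert_array_equal(mean_pearson([c]).r, c.r)

    def test_undefined_anywhere_is_undefined_in_mean(self):
        cs = [
            _corr_from_pairs("AB", {("A", "B"): 0.9}),
            _corr_from_pairs("AB", {("A", "B"): np.nan}),
        ]
        assert np.isnan(mean_pearson(cs).r[0, 1])

    def test_mean_bounded_by_min_and_max(self):
        rng = np.random.default_rng(8)
        ids = [f"P{i}" for i in range(20)]
        cs = []
        for seed in range(3):
            m = ExpressionMatrix(
                row_ids=ids,
                sample_ids=[f"S{j}" for j in range(15)],
                values=np.random.default_rng(seed).uniform(0, 10, size=(20, 15)),
            )
            cs.append(correlation_matrix(m))
        merged = mean_pearson(cs)
        stack = np.stack([c.r for c in cs])
        assert np.all(merged.r >= stack.min(axis=0) - 1e-12)
        assert np.all(merged.r <= stack.max(axis=0) + 1e-12)

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError, match="identical id list"):
            mean_pearson(
                [_corr_from_pairs("AB", {}), _corr_from_pairs("AC", {})]
            )
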