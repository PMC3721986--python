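import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # reference oracles

from coexmap import ExpressionMatrix, MixtureConfig, Program, simulate_tumor_dataset


def brute_force_ari(labels_a: list, labels_b: list) -> float:
    """Adjusted Rand index straight from the pair-counting definition."""
    assert len(labels_a) == len(labels_b)
    n = len(labels_a)
    same_a = same_b = same_both = 0
    for i in range(n):
        for j in range(i + 1, n):
            a = labels_a[i] == labels_a[j]
            b = labels_b[i] == labels_b[j]
            same_a += a
            same_b += b
            same_both += a and b
    pairs = n * (n - 1) // 2
    expected = same_a * same_b / pairs if pairs else 0.0
    max_index = (same_a + same_b) / 2
    if max_index == expected:
        return 1.0
    return (same_both - expected) / (max_index - expected)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    return ExpressionMatrix(
        row_ids=[f"G{i}|{1000 + i}_at" for i in range(10)],
        sample_ids=[f"S{j}" for j in range(20)],
        values=rng.gamma(2.0, 50.0, size=(10, 20)),
    )


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The standard recovery benchmark: 3 cell-type programs, housekeeping."""
    cfg = MixtureConfig(
        n_samples=150,
        programs=[
            Program("CT1", 50),
            Program("CT2", 50),
            Program("CT3", 50),
            Program("HK", 20, kind="housekeeping"),
        ],
        noise_sigma=0.15,
        seed=1,
    )
    return simulate_tumor_dataset(cfg)
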