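"""Synthetic tumour transcriptomes as mixtures of cell-type programs.

Bulk tumour biopsies are mixtures: the macrophage content, T-cell
infiltrate, stromal fraction and mitotic index differ from tumour to
tumour, so genes expressed specifically by one cell type (or driven by
one pathway) rise and fall together across samples.  The generator
reproduces exactly that structure with known ground truth:

* per sample, cell-type proportions are drawn from a Dirichlet, so
  programs are compositionally (negatively) coupled, as stromal and
  tumour fractions are in real biopsies;
* *activity* programs (a cell-cycle analogue) follow an independent
  Beta(2, 2) activity level, decoupled from composition;
* *housekeeping* genes track a constant level — only noise varies;
* *dataset-specific* programs model tumour-type-private biology that
  should not survive a cross-dataset meta-analysis;
* each gene carries a log-normal amplitude, emits 1-3 probesets with
  probe-specific gains, and all noise is multiplicative log-normal, on
  the natural scale throughout.

Gene value for gene g of cell-type program k in sample j:
``b_g * (c0 + p_kj) * exp(eps)`` with ``eps ~ N(0, sigma^2)``, baseline
``c0 = 0.05`` and ``b_g ~ LogNormal(ln 100, 0.5)``.  Probe value:
``gain_p * gene_value * exp(eta)`` with ``gain_p ~ LogNormal(0, 0.2)``
and ``eta ~ N(0, (sigma/2)^2)``.  Everything is deterministic given the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "Program",
    "MixtureConfig",
    "MixtureTruth",
    "simulate_tumor_dataset",
    "simulate_multi_datasets",
    "truth_gene_sets",
]

BASELINE_OFFSET = 0.05  # background signal when a cell type is absent
AMPLITUDE_LOG_MEAN = float(np.log(100.0))
AMPLITUDE_LOG_SD = 0.5
PROBE_GAIN_LOG_SD = 0.2

PROGRAM_KINDS = ("cell_type", "activity", "housekeeping", "dataset_specific")


@dataclass(frozen=True)
class Program:
    name: str
    n_genes: int
    kind: str = "cell_type"

    def __post_init__(self) -> None:
        if self.kind not in PROGRAM_KINDS:
            raise ValueError(f"unknown program kind {self.kind!r}")
        if self.n_genes < 1:
            raise ValueError("each program needs at least one gene")
        if not self.name:
            raise ValueError("program name must be non-empty")


@dataclass
class MixtureConfig:
    """Study design of one simulated dataset.

    ``dirichlet_alpha`` (one entry per cell-type program) controls how
    variable the cellular composition is across tumours; all-ones gives
    broadly varying mixtures.  ``noise_sigma`` is the standard deviation
    of the log-scale multiplicative gene noise.  ``probe_reps`` is the
    distribution of probesets per gene over {1, 2, 3}.
    """

    n_samples: int = 150
    programs: list[Program] = field(
        default_factory=lambda: [
            Program("CT1", 50),
            Program("CT2", 50),
            Program("CT3", 50),
            Program("HK", 20, kind="housekeeping"),
        ]
    )
    dirichlet_alpha: list[float] | None = None
    noise_sigma: float = 0.15
    probe_reps: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        kinds = [p.kind for p in self.programs]
        if "cell_type" not in kinds:
            raise ValueError("at least one cell_type program is required")
        names = [p.name for p in self.programs]
        if len(set(names)) != len(names):
            raise ValueError("program names must be unique")
        n_ct = kinds.count("cell_type")
        if self.dirichlet_alpha is None:
            self.dirichlet_alpha = [1.0] * n_ct
        if len(self.dirichlet_alpha) != n_ct:
            raise ValueError(
                f"dirichlet_alpha has {len(self.dirichlet_alpha)} entries for "
                f"{n_ct} cell_type programs"
            )
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha entries must be positive")
        if set(self.probe_reps) - {1, 2, 3}:
            raise ValueError("probe_reps support must lie in {1, 2, 3}")
        total = sum(self.probe_reps.values())
        if total <= 0:
            raise ValueError("probe_reps probabilities must sum to > 0")

    def by_kind(self, kind: str) -> list[Program]:
        return [p for p in self.programs if p.kind == kind]


@dataclass
class MixtureTruth:
    """Ground truth of one simulated dataset.

    ``proportions`` rows (samples x cell-type programs) sum to one;
    ``activities`` are the Beta-distributed per-sample activity levels;
    ``specific_levels`` the abundances of dataset-specific programs.
    """

    gene_program: dict[str, str]
    probe_gene: dict[str, str]
    proportions: "np.ndarray"
    proportion_names: list[str]
    activities: "np.ndarray"
    activity_names: list[str]
    specific_levels: "np.ndarray"
    specific_names: list[str]

    def __post_init__(self) -> None:
        if self.proportions.size:
            sums = self.proportions.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValueError("cell-type proportions must sum to 1 per sample")
        for probe, gene in self.probe_gene.items():
            if gene not in self.gene_program:
                raise ValueError(f"probe {probe!r} maps to unknown gene {gene!r}")

    def probe_program(self, probe_id: str) -> str:
        return self.gene_program[self.probe_gene[probe_id]]

    def shared_programs(self) -> set[str]:
        """Program names that belong in the cross-dataset signature truth."""
        specific = set(self.specific_names)
        return {p for p in set(self.gene_program.values()) if p not in specific}


def _gene_names(program: Program) -> list[str]:
    return [f"{program.name}G{i + 1:03d}" for i in range(program.n_genes)]


def _assign_probes(
    genes: Sequence[str],
    probe_reps: dict[int, float],
    rng: np.random.Generator,
    start: int,
) -> tuple[dict[str, list[str]], int]:
    """Draw probesets-per-gene and mint ``SYMBOL|NNNNN_at`` probe ids."""
    support = sorted(probe_reps)
    probs = np.array([probe_reps[k] for k in support], dtype=float)
    probs /= probs.sum()
    counts = rng.choice(support, size=len(genes), p=probs)
    probe_map: dict[str, list[str]] = {}
    counter = start
    for gene, c in zip(genes, counts):
        probe_map[gene] = [f"{gene}|{counter + k:05d}_at" for k in range(int(c))]
        counter += int(c)
    return probe_map, counter


def simulate_tumor_dataset(
    cfg: MixtureConfig,
    probe_map: dict[str, list[str]] | None = None,
) -> tuple[ExpressionMatrix, MixtureTruth]:
    """Generate one dataset plus its ground truth.

    ``probe_map`` (gene -> probe ids) may be supplied to pin the probe
    universe of shared genes across datasets; genes missing from it get
    freshly minted probes.
    """
    rng = np.random.default_rng(cfg.seed)
    ct_programs = cfg.by_kind("cell_type")
    act_programs = cfg.by_kind("activity")
    hk_programs = cfg.by_kind("housekeeping")
    spec_programs = cfg.by_kind("dataset_specific")

    n = cfg.n_samples
    proportions = rng.dirichlet(np.asarray(cfg.dirichlet_alpha, dtype=float), size=n)
    activities = (
        rng.beta(2.0, 2.0, size=(n, len(act_programs)))
        if act_programs
        else np.zeros((n, 0))
    )
    if spec_programs:
        # compositional draw over (specific programs + silent remainder):
        # specific programs vary in [0,1] and are mutually anti-correlated
        # like true cell-type fractions, while the cell_type proportions
        # keep their own sum-to-one closure.
        spec_levels = rng.dirichlet(
            np.ones(len(spec_programs) + 1), size=n
        )[:, : len(spec_programs)]
    else:
        spec_levels = np.zeros((n, 0))

    # per-sample driving level for every program, in config order
    drivers: dict[str, np.ndarray] = {}
    for k, p in enumerate(ct_programs):
        drivers[p.name] = proportions[:, k]
    for k, p in enumerate(act_programs):
        drivers[p.name] = activities[:, k]
    for p in hk_programs:
        drivers[p.name] = np.ones(n)
    for k, p in enumerate(spec_programs):
        drivers[p.name] = spec_levels[:, k]

    gene_program: dict[str, str] = {}
    all_genes: list[str] = []
    for p in cfg.programs:
        for g in _gene_names(p):
            gene_program[g] = p.name
            all_genes.append(g)

    full_probe_map: dict[str, list[str]] = {}
    missing = [g for g in all_genes if probe_map is None or g not in probe_map]
    if probe_map is not None:
        for g in all_genes:
            if g in probe_map:
                full_probe_map[g] = list(probe_map[g])
    start = 10000
    if full_probe_map:
        taken = max(
            int(pid.split("|", 1)[1].split("_", 1)[0])
            for pids in full_probe_map.values()
            for pid in pids
        )
        start = taken + 1
    minted, _ = _assign_probes(missing, cfg.probe_reps, rng, start)
    full_probe_map.update(minted)

    sigma = cfg.noise_sigma
    probe_ids: list[str] = []
    probe_gene: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for p in cfg.programs:
        level = drivers[p.name]
        for g in _gene_names(p):
            b_g = rng.lognormal(AMPLITUDE_LOG_MEAN, AMPLITUDE_LOG_SD)
            eps = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
            gene_value = b_g * (BASELINE_OFFSET + level) * np.exp(eps)
            for pid in full_probe_map[g]:
                gain = rng.lognormal(0.0, PROBE_GAIN_LOG_SD)
                eta = (
                    rng.normal(0.0, sigma / 2.0, size=n)
                    if sigma > 0
                    else np.zeros(n)
                )
                probe_ids.append(pid)
                probe_gene[pid] = g
                rows.append(gain * gene_value * np.exp(eta))

    matrix = ExpressionMatrix(
        row_ids=probe_ids,
        sample_ids=[f"S{j + 1:03d}" for j in range(n)],
        values=np.vstack(rows),
    )
    truth = MixtureTruth(
        gene_program=gene_program,
        probe_gene=probe_gene,
        proportions=proportions,
        proportion_names=[p.name for p in ct_programs],
        activities=activities,
        activity_names=[p.name for p in act_programs],
        specific_levels=spec_levels,
        specific_names=[p.name for p in spec_programs],
    )
    return matrix, truth


def simulate_multi_datasets(
    shared: MixtureConfig,
    n_datasets: int,
    specific_programs_per_dataset: int = 0,
    genes_per_specific_program: int = 40,
    seed: int = 0,
) -> list[tuple[ExpressionMatrix, MixtureTruth]]:
    """Generate several datasets sharing the same cell-type programs.

    Every dataset carries the shared programs (identical gene membership
    and probe universe, independent proportions and noise) plus its own
    dataset-specific programs with disjoint gene sets, standing in for
    tumour-type-private biology.
    """
    if n_datasets < 2:
        raise ValueError("need at least 2 datasets")
    if specific_programs_per_dataset < 0:
        raise ValueError("specific_programs_per_dataset must be >= 0")
    master = np.random.default_rng(seed)
    shared_genes: list[str] = []
    for p in shared.programs:
        shared_genes.extend(_gene_names(p))
    shared_probe_map, _ = _assign_probes(shared_genes, shared.probe_reps, master, 10000)

    shared_names = {p.name for p in shared.programs}
    datasets: list[tuple[ExpressionMatrix, MixtureTruth]] = []
    for d in range(n_datasets):
        specific = [
            Program(
                f"DS{d + 1}SPEC{s + 1}",
                genes_per_specific_program,
                kind="dataset_specific",
            )
            for s in range(specific_programs_per_dataset)
        ]
        for p in specific:
            if p.name in shared_names:
                raise ValueError(
                    f"dataset-specific program {p.name!r} collides with a "
                    "shared program name"
                )
        cfg = replace(
            shared,
            programs=list(shared.programs) + specific,
            dirichlet_alpha=list(shared.dirichlet_alpha or []),
            seed=int(master.integers(0, 2**31 - 1)),
        )
        datasets.append(simulate_tumor_dataset(cfg, probe_map=shared_probe_map))
    return datasets


def truth_gene_sets(truth: MixtureTruth, level: str = "gene") -> GeneSetCollection:
    """Ground-truth program membership as a gene-set collection.

    ``level`` selects gene symbols (``"gene"``) or probe identifiers
    (``"probe"``) as set members.
    """
    sets: dict[str, list[str]] = {}
    if level == "gene":
        for gene, prog in truth.gene_program.items():
            sets.setdefault(prog, []).append(gene)
    elif level == "probe":
        for probe, gene in truth.probe_gene.items():
            sets.setdefault(truth.gene_program[gene], []).append(probe)
    else:
        raise ValueError("level must be 'gene' or 'probe'")
    return GeneSetCollection(
        sets={name: sorted(members) for name, members in sorted(sets.items())},
        descriptions={name: "simulated ground-truth program" for name in sets},
    )
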