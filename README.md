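# coexmap

Coexpression-network dissection of heterogeneous tumour transcriptomes.

## The problem

A tumour biopsy is never a pure population of cancer cells. Macrophages,
T cells, fibroblasts, endothelium and adipocytes are all present, and their
proportions differ from biopsy to biopsy. In a bulk expression profile this
heterogeneity is usually treated as a nuisance; `coexmap` exploits it. If the
macrophage fraction Φ varies across tumours, every macrophage-specific gene
rises and falls with Φ, so macrophage genes are strongly *correlated with each
other* across samples — without anyone having to sort the cells. The same
holds for pathway activity: the mitotic index drives coordinated variation of
cell-cycle genes.

`coexmap` turns this premise into a pipeline for transcriptomics researchers
working with large (n ≳ 100) tumour cohorts:

1. **Correlation graph** — all-pairs Pearson *r* between probesets on
   natural-scale normalised intensities; an edge for each pair with
   *r* ≥ *r*_min (default 0.6, or a grid scan choosing the threshold whose
   node inclusion is closest to 40% of probesets).
2. **Markov clustering (MCL)** — a from-scratch weighted MCL (expansion,
   inflation at 2.2, pruning) partitions the graph into coexpression modules;
   clusters are named by size, largest first.
3. **Meta-network** — probesets are intersected across cohorts, the
   entrywise *mean* Pearson correlation is computed, and the merged graph is
   clustered: only relationships conserved across cohorts survive, yielding
   "core signatures" (macrophage, T cell, ECM, cell cycle, …).
4. **Conservation mapping** — each core signature is tested for
   over-representation in the clusters of an independent dataset with a
   one-sided Fisher/hypergeometric test, Benjamini–Hochberg adjusted across
   all cluster pairs.
5. **Simulator** — tumour-like datasets as Dirichlet mixtures of cell-type
   programs with multiplicative log-normal noise, multiple probesets per
   gene and full ground truth, so every stage is testable without downloads.

A deterministic 3-D Fruchterman–Reingold layout is included for export and
visualisation of the graphs.

## Worked example

```python
from coexmap import (MixtureConfig, PipelineConfig, simulate_tumor_dataset,
                     correlation_matrix, build_graph, mcl_cluster, MclParams,
                     cluster_sizes)

# 150 tumours, three cell-type programs of 50 genes plus 20 housekeeping genes
matrix, truth = simulate_tumor_dataset(MixtureConfig(seed=1))
graph = build_graph(correlation_matrix(matrix), r_min=0.7)
clusters = mcl_cluster(graph, MclParams(inflation=2.2))
for name, n_probes, n_genes in cluster_sizes(clusters)[:3]:
    print(name, n_probes, n_genes)
```

prints

```
Cluster 1 78 50
Cluster 2 78 50
Cluster 3 73 50
```

— the three largest clusters each contain exactly the 50 genes of one
simulated cell-type program (78, 78 and 73 probesets, since genes carry 1–3
probesets each). Housekeeping probes, which vary only with noise, stay
isolated at this threshold. Scoring the clustering against the ground truth
gives an adjusted Rand index of 0.99 on this seed.

The same workflow is available from the shell:

```bash
coexmap simulate --seed 1 --out sim/
coexmap correlate --in sim/dataset.expression --r-min 0.7 --out edges.tsv
coexmap cluster --edges edges.tsv --inflation 2.2 --out clusters.tsv
coexmap enrich --clusters clusters.tsv --gmt sim/dataset.programs.gmt --out enrichment.tsv
```

with `threshold-scan`, `merge`, `map-signatures`, `layout` and a YAML-driven
`run` subcommand covering the remaining stages.

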