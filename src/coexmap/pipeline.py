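"""End-to-end orchestration: correlate -> threshold -> cluster -> map.

Two entry points mirror the two analysis modes: :func:`run_single`
analyses one dataset (correlation graph at a fixed or scanned threshold,
MCL clustering, optional gene-set enrichment and layout), and
:func:`run_merged` performs the cross-dataset meta-analysis (probe-set
intersection, per-dataset correlation matrices, entrywise mean, merged
graph and clusters, conservation mapping onto held-out datasets).  All
artifacts are written as plain TSV/JSON with a manifest recording the
inputs, parameters and seed.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import io as cio
from .io import ExpressionMatrix, GeneSetCollection
from .layout import fr_layout
from .mapping import ConservationTable, enrich_gene_sets, map_signatures
from .mcl import ClusterSet, MclParams, cluster_sizes, mcl_cluster
from .network import (
    CorrelationGraph,
    build_graph,
    correlation_matrix,
    default_threshold_grid,
    mean_pearson,
    select_threshold,
)

__all__ = ["PipelineConfig", "SingleResult", "MergedResult", "run_single", "run_merged"]


@dataclass
class PipelineConfig:
    """Parameters shared by the single and merged pipelines.

    Exactly one of ``r_min`` (fixed threshold) or ``threshold_scan``
    (pick the grid threshold whose node inclusion is closest to
    ``target_fraction``) governs graph construction.
    """

    r_min: float | None = 0.6
    threshold_scan: bool = False
    target_fraction: float = 0.40
    grid: Sequence[float] | None = None
    mcl: MclParams = field(default_factory=MclParams)
    adjust_method: str = "bh"
    min_cluster_size: int = 1
    compute_layout: bool = False
    layout_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_scan == (self.r_min is not None):
            raise ValueError("specify exactly one of r_min or threshold_scan")


@dataclass
class SingleResult:
    r_sel: float
    graph: CorrelationGraph
    clusters: ClusterSet
    enrichment: list | None
    layout: dict | None
    manifest: dict


@dataclass
class MergedResult:
    r_sel: float
    graph: CorrelationGraph
    clusters: ClusterSet
    conservation: dict[str, ConservationTable]
    manifest: dict


def _log(stage: str, message: str) -> None:
    print(f"[coexmap:{stage}] {message}", file=sys.stderr)


class _StageTimer:
    def __init__(self, manifest: dict) -> None:
        self.manifest = manifest
        self.manifest.setdefault("stages", {})

    def record(self, stage: str, started: float, **counts) -> None:
        elapsed = time.perf_counter() - started
        self.manifest["stages"][stage] = {"seconds": round(elapsed, 3), **counts}
        detail = ", ".join(f"{k}={v}" for k, v in counts.items())
        _log(stage, f"done in {elapsed:.2f}s ({detail})" if detail else f"done in {elapsed:.2f}s")


def _resolve_threshold(cfg: PipelineConfig, corr, manifest: dict) -> float:
    if cfg.threshold_scan:
        grid = cfg.grid if cfg.grid is not None else default_threshold_grid()
        r_sel = select_threshold(corr, cfg.target_fraction, grid)
        manifest["threshold"] = {"mode": "scan", "target_fraction": cfg.target_fraction, "r_sel": r_sel}
    else:
        r_sel = float(cfg.r_min)  # type: ignore[arg-type]
        manifest["threshold"] = {"mode": "fixed", "r_sel": r_sel}
    return r_sel


def run_single(
    matrix: ExpressionMatrix,
    cfg: PipelineConfig,
    gene_sets: GeneSetCollection | None = None,
    out_dir: str | Path | None = None,
) -> SingleResult:
    """Single-dataset pipeline: correlate, threshold, cluster, enrich."""
    manifest: dict = {
        "pipeline": "single",
        "seed": cfg.seed,
        "n_probes": matrix.n_probes,
        "n_samples": matrix.n_samples,
        "mcl": vars(cfg.mcl),
    }
    timer = _StageTimer(manifest)
    try:
        t = time.perf_counter()
        corr = correlation_matrix(matrix)
        timer.record("correlate", t, probes=corr.n)

        t = time.perf_counter()
        r_sel = _resolve_threshold(cfg, corr, manifest)
        graph = build_graph(corr, r_sel)
        timer.record(
            "graph", t, r_sel=r_sel, nodes=len(graph.nodes), edges=graph.n_edges
        )
        if graph.n_edges == 0:
            _log("graph", f"warning: no correlations reach r_min={r_sel}; graph is empty")

        t = time.perf_counter()
        clusters = mcl_cluster(graph, cfg.mcl)
        timer.record("cluster", t, clusters=len(clusters.clusters))

        enrichment = None
        if gene_sets is not None:
            t = time.perf_counter()
            enrichment = enrich_gene_sets(
                clusters, gene_sets, method=cfg.adjust_method
            )
            timer.record("enrich", t, tests=len(enrichment))

        layout = None
        if cfg.compute_layout:
            t = time.perf_counter()
            layout = fr_layout(graph, cfg.layout_iterations, cfg.seed)
            timer.record("layout", t, nodes=len(layout))
    except Exception as exc:
        stage = manifest.get("stages", {})
        raise RuntimeError(
            f"pipeline failed after stages {sorted(stage)}: {exc}"
        ) from exc

    result = SingleResult(
        r_sel=r_sel,
        graph=graph,
        clusters=clusters,
        enrichment=enrichment,
        layout=layout,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_single(result, Path(out_dir))
    return result


def run_merged(
    matrices: Sequence[ExpressionMatrix],
    cfg: PipelineConfig,
    validation: Sequence[tuple[str, ExpressionMatrix]] = (),
    validation_cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> MergedResult:
    """Cross-dataset meta-analysis over >= 2 datasets.

    Probes are intersected to the common universe, per-dataset Pearson
    matrices averaged entrywise, and the mean-correlation graph is built
    and clustered.  The merged clusters ("core signatures") are then
    mapped onto the clusters of each held-out validation dataset, which
    never contributes to the mean.
    """
    if len(matrices) < 2:
        raise ValueError("merged pipeline needs at least 2 datasets")
    manifest: dict = {
        "pipeline": "merged",
        "seed": cfg.seed,
        "n_datasets": len(matrices),
        "mcl": vars(cfg.mcl),
    }
    timer = _StageTimer(manifest)
    try:
        t = time.perf_counter()
        aligned = cio.intersect_probesets(list(matrices))
        timer.record("intersect", t, common_probes=aligned[0].n_probes)

        t = time.perf_counter()
        corrs = [correlation_matrix(m) for m in aligned]
        merged_corr = mean_pearson(corrs)
        timer.record("mean_pearson", t, probes=merged_corr.n)

        t = time.perf_counter()
        r_sel = _resolve_threshold(cfg, merged_corr, manifest)
        graph = build_graph(merged_corr, r_sel)
        timer.record("graph", t, r_sel=r_sel, nodes=len(graph.nodes), edges=graph.n_edges)

        t = time.perf_counter()
        clusters = mcl_cluster(graph, cfg.mcl)
        timer.record("cluster", t, clusters=len(clusters.clusters))

        conservation: dict[str, ConservationTable] = {}
        vcfg = validation_cfg or cfg
        for name, vmatrix in validation:
            t = time.perf_counter()
            vresult = run_single(vmatrix, vcfg)
            universe = set(merged_corr.ids) & set(vmatrix.row_ids)
            conservation[name] = map_signatures(
                clusters,
                vresult.clusters,
                universe,
                method=cfg.adjust_method,
                min_cluster_size=cfg.min_cluster_size,
            )
            timer.record(
                f"map:{name}", t,
                universe=len(universe),
                signatures=len(conservation[name].best),
            )
    except Exception as exc:
        stage = manifest.get("stages", {})
        raise RuntimeError(
            f"pipeline failed after stages {sorted(stage)}: {exc}"
        ) from exc

    result = MergedResult(
        r_sel=r_sel,
        graph=graph,
        clusters=clusters,
        conservation=conservation,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_merged(result, Path(out_dir))
    return result


def _write_clusters(cs: ClusterSet, path: Path) -> None:
    cio.write_cluster_table(cs.as_mapping(), path)


def _write_conservation(table: ConservationTable, path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write(
            "core_signature\tbest_target_cluster\toverlap_k\tcore_n\t"
            "target_K\tuniverse_N\todds_ratio\tp_raw\tp_adjusted\n"
        )
        for name, r in sorted(table.best.items()):
            fh.write(
                f"{name}\t{r.set_name}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                f"{r.odds_ratio:.6g}\t{r.p_raw:.6g}\t{r.p_adjusted:.6g}\n"
            )
        for name in table.unmapped:
            fh.write(f"{name}\tUNMAPPED\t0\t0\t0\t0\tnan\tnan\tnan\n")


def _write_enrichment(results, path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write("cluster\tgene_set\tk\tn\tK\tN\todds_ratio\tp_raw\tp_adjusted\n")
        for r in results:
            fh.write(
                f"{r.query_name}\t{r.set_name}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                f"{r.odds_ratio:.6g}\t{r.p_raw:.6g}\t{r.p_adjusted:.6g}\n"
            )


def _write_layout(layout: dict, path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write("id\tx\ty\tz\n")
        for node, (x, y, z) in sorted(layout.items()):
            fh.write(f"{node}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def _finish_manifest(manifest: dict, out: Path, files: list[str]) -> None:
    manifest["outputs"] = files
    with (out / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _write_single(result: SingleResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    files = ["edges.tsv", "clusters.tsv", "cluster_sizes.tsv"]
    cio.write_edge_list(result.graph.edge_triples(), out / "edges.tsv")
    _write_clusters(result.clusters, out / "clusters.tsv")
    with (out / "cluster_sizes.tsv").open("w", encoding="utf-8") as fh:
        fh.write("rank_name\tn_probesets\tn_genes\n")
        for name, n_probes, n_genes in cluster_sizes(result.clusters):
            fh.write(f"{name}\t{n_probes}\t{n_genes}\n")
    if result.enrichment is not None:
        _write_enrichment(result.enrichment, out / "enrichment.tsv")
        files.append("enrichment.tsv")
    if result.layout is not None:
        _write_layout(result.layout, out / "layout.tsv")
        files.append("layout.tsv")
    _finish_manifest(result.manifest, out, files)


def _write_merged(result: MergedResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    files = ["merged_edges.tsv", "merged_clusters.tsv"]
    cio.write_edge_list(result.graph.edge_triples(), out / "merged_edges.tsv")
    _write_clusters(result.clusters, out / "merged_clusters.tsv")
    for name, table in result.conservation.items():
        fname = f"conservation_{name}.tsv"
        _write_conservation(table, out / fname)
        files.append(fname)
    _finish_manifest(result.manifest, out, files)
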