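"""Reading and writing the flat-file dialects used throughout the pipeline.

The central exchange format is the ``.expression`` file: a tab-delimited
table with one row per probeset, a unique row identifier in the first
column (gene symbol concatenated to the probeset ID, ``SYMBOL|PROBESET``),
optional annotation ("class-set") columns, and natural-scale normalised
intensities for each sample in the remaining columns.  Edge lists
(``.pearson``-style), cluster tables and GMT gene-set collections follow
the same plain-TSV philosophy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_expression_file",
    "write_expression_file",
    "intersect_probesets",
    "write_edge_list",
    "read_edge_list",
    "read_gmt",
    "write_gmt",
    "read_cluster_table",
    "write_cluster_table",
    "probe_symbol",
]

ID_SEPARATOR = "|"


def probe_symbol(probe_id: str) -> str:
    """Gene symbol embedded in a ``SYMBOL|PROBESET`` row identifier.

    Probes without an embedded symbol stand for themselves: the whole
    identifier is returned, so each such probe counts as its own gene.
    """
    if ID_SEPARATOR in probe_id:
        symbol = probe_id.split(ID_SEPARATOR, 1)[0]
        if symbol:
            return symbol
    return probe_id


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of natural-scale normalised intensities.

    Parameters
    ----------
    row_ids
        Unique probe identifiers (``SYMBOL|PROBESET`` or bare probeset ID).
    sample_ids
        Ordered sample names, one per value column.
    values
        ``(n_probes, n_samples)`` array of finite, non-negative values.
    annotations
        Optional per-row class-set columns, keyed by column name; each
        entry is a list of strings aligned with ``row_ids``.
    """

    row_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    annotations: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D probes x samples array")
        n_probes, n_samples = self.values.shape
        if len(self.row_ids) != n_probes:
            raise ValueError(
                f"{len(self.row_ids)} row_ids for {n_probes} value rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample_ids for {n_samples} columns"
            )
        if n_samples < 3:
            raise ValueError(
                f"need at least 3 samples for correlation analysis, got {n_samples}"
            )
        seen: set[str] = set()
        for rid in self.row_ids:
            if rid in seen:
                raise ValueError(f"duplicate row identifier: {rid!r}")
            seen.add(rid)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be >= 0 (natural scale)")
        for name, col in self.annotations.items():
            if len(col) != n_probes:
                raise ValueError(
                    f"annotation column {name!r} has {len(col)} entries "
                    f"for {n_probes} rows"
                )

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row_index(self) -> dict[str, int]:
        return {rid: i for i, rid in enumerate(self.row_ids)}

    def subset_rows(self, ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``ids`` in the given order."""
        index = self.row_index()
        rows = [index[i] for i in ids]
        return ExpressionMatrix(
            row_ids=list(ids),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :],
            annotations={
                name: [col[r] for r in rows]
                for name, col in self.annotations.items()
            },
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), optionally with an explicit universe."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")
            for m in members:
                if not isinstance(m, str) or not m:
                    raise ValueError(
                        f"gene set {name!r} contains an empty/non-string member"
                    )


def read_expression_file(path: str | Path, n_annotation_cols: int = 0) -> ExpressionMatrix:
    """Parse a ``.expression`` TSV file.

    Column 1 is the unique row identifier, the next ``n_annotation_cols``
    columns are class-set annotations, and all remaining columns are
    numeric sample values.  Duplicate identifiers, non-numeric data cells
    and matrices with fewer than three samples are hard errors.
    """
    path = Path(path)
    if n_annotation_cols < 0:
        raise ValueError("n_annotation_cols must be >= 0")
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        cols = header.split("\t")
        if len(cols) < 1 + n_annotation_cols + 3:
            raise ValueError(
                f"{path}: header has {len(cols)} columns; need an ID column, "
                f"{n_annotation_cols} annotation columns and >=3 samples"
            )
        ann_names = cols[1 : 1 + n_annotation_cols]
        sample_ids = cols[1 + n_annotation_cols :]
        row_ids: list[str] = []
        ann_cols: dict[str, list[str]] = {name: [] for name in ann_names}
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(fields)}"
                )
            rid = fields[0]
            row_ids.append(rid)
            for k, name in enumerate(ann_names):
                ann_cols[name].append(fields[1 + k])
            data: list[float] = []
            for k, cell in enumerate(fields[1 + n_annotation_cols :]):
                try:
                    data.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in "
                        f"column {sample_ids[k]!r} (row {rid!r})"
                    ) from None
            rows.append(data)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return ExpressionMatrix(
        row_ids=row_ids,
        sample_ids=sample_ids,
        values=np.array(rows, dtype=float),
        annotations=ann_cols,
    )


def write_expression_file(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write ``matrix`` in the ``.expression`` dialect (6 decimal places)."""
    path = Path(path)
    ann_names = list(matrix.annotations)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(["ID", *ann_names, *matrix.sample_ids]) + "\n")
        for i, rid in enumerate(matrix.row_ids):
            ann = [matrix.annotations[name][i] for name in ann_names]
            vals = [f"{v:.6f}" for v in matrix.values[i]]
            fh.write("\t".join([rid, *ann, *vals]) + "\n")


def intersect_probesets(matrices: Sequence[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix to the probes present in all of them.

    All outputs share a single canonical (lexicographic) row order so that
    downstream correlation matrices are directly comparable entry by entry.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    common = set(matrices[0].row_ids)
    for m in matrices[1:]:
        common &= set(m.row_ids)
    if not common:
        raise ValueError("probe-set intersection across matrices is empty")
    order = sorted(common)
    return [m.subset_rows(order) for m in matrices]


def write_edge_list(
    edges: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    """Write an undirected weighted edge list as 3-column TSV.

    Each edge is stored once with the lexicographically smaller identifier
    first; weights are printed to 6 decimal places.  Self-edges are
    rejected.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for a, b, w in edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r} is not allowed")
            if b < a:
                a, b = b, a
            fh.write(f"{a}\t{b}\t{w:.6f}\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a 3-column TSV edge list written by :func:`write_edge_list`."""
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            a, b, w = fields
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-edge on {a!r}")
            try:
                weight = float(w)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric weight {w!r}"
                ) from None
            edges.append((a, b, weight))
    return edges


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, members per line)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need name, description "
                    f"and at least one member"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_cluster_table(
    clusters: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
    path: str | Path,
) -> None:
    """Write clusters as TSV with columns cluster_id, rank_name, member_id.

    Accepts either an ordered mapping ``{rank_name: members}`` or a
    size-ordered list of member lists (rank names are then generated as
    ``Cluster 1`` for the first/largest).
    """
    path = Path(path)
    if isinstance(clusters, Mapping):
        items = list(clusters.items())
    else:
        items = [(f"Cluster {i + 1}", members) for i, members in enumerate(clusters)]
    with path.open("w", encoding="utf-8") as fh:
        fh.write("cluster_id\trank_name\tmember_id\n")
        for cid, (name, members) in enumerate(items, start=1):
            for member in members:
                fh.write(f"{cid}\t{name}\t{member}\n")


def read_cluster_table(path: str | Path) -> dict[str, list[str]]:
    """Read a cluster TSV back into an ordered ``{rank_name: members}`` map."""
    path = Path(path)
    clusters: dict[str, list[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["cluster_id", "rank_name", "member_id"]:
            raise ValueError(f"{path}: unexpected cluster-table header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            _, name, member = fields
            clusters.setdefault(name, []).append(member)
    return clusters
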