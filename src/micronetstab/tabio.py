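"""Readers, writers and validated containers for every format the pipeline touches.

Canonical on-disk formats are plain TSV (count tables, metadata, edge lists,
result records), Newick (trees), GraphML (networks) and JSON (reports).
All writers are inverses of the corresponding readers up to column order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode


class DataValidationError(ValueError):
    """Raised when an input file or table violates the pipeline's contracts."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AsvTable:
    """Integer ASV count matrix, taxa as rows and samples as columns.

    Invariants enforced at construction: non-negative integer counts, unique
    taxon and sample identifiers, at least two samples.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[1] < 2:
            raise DataValidationError(
                f"ASV table needs at least 2 samples, got {df.shape[1]}"
            )
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate taxon ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate sample ids: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataValidationError("ASV counts must be numeric")
        if np.isnan(arr.astype(float)).any():
            r, c = np.argwhere(np.isnan(arr.astype(float)))[0]
            raise DataValidationError(
                f"missing count at taxon {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise DataValidationError(
                f"negative count at taxon {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            frac = arr.astype(float) - np.round(arr.astype(float))
            if np.abs(frac).max() > 0:
                r, c = np.argwhere(np.abs(frac) > 0)[0]
                raise DataValidationError(
                    f"non-integer count {arr[r, c]} at taxon {df.index[r]!r}, "
                    f"sample {df.columns[c]!r}"
                )
            object.__setattr__(self, "counts", df.astype(np.int64))

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances; all-zero samples yield NaN columns."""
        sums = self.counts.sum(axis=0).astype(float)
        sums[sums == 0] = np.nan
        return self.counts / sums

    def subset_taxa(self, taxa: Sequence[str]) -> "AsvTable":
        return AsvTable(self.counts.loc[list(taxa)])

    def subset_samples(self, samples: Sequence[str]) -> "AsvTable":
        return AsvTable(self.counts[list(samples)])


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample treatment label plus numeric covariates and outcomes."""

    frame: pd.DataFrame
    group_col: str = "group"

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate sample ids in metadata: {dups}")
        if self.group_col not in self.frame.columns:
            raise DataValidationError(
                f"metadata lacks group column {self.group_col!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def groups(self) -> pd.Series:
        return self.frame[self.group_col]

    def numeric_columns(self) -> list[str]:
        return [
            c
            for c in self.frame.columns
            if c != self.group_col and pd.api.types.is_numeric_dtype(self.frame[c])
        ]

    def align_to(self, table: AsvTable) -> "SampleMetadata":
        """Reorder metadata rows to the table's samples; error on any mismatch."""
        missing = [s for s in table.sample_ids if s not in self.frame.index]
        if missing:
            raise DataValidationError(
                f"samples present in counts but missing from metadata: {missing}"
            )
        return SampleMetadata(self.frame.loc[table.sample_ids], self.group_col)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_asv_table(path: str | Path, orientation: str = "taxa-rows") -> AsvTable:
    """Read a TSV count table. ``orientation`` is ``taxa-rows`` (first column =
    taxon id, header = sample ids) or ``samples-rows`` (the transpose)."""
    if orientation not in ("taxa-rows", "samples-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise DataValidationError(f"unparseable ASV table {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "samples-rows":
        df = df.T
    df.index.name = None
    df.columns.name = None
    return AsvTable(df)


def write_asv_table(
    table: AsvTable, path: str | Path, orientation: str = "taxa-rows"
) -> None:
    df = table.counts if orientation == "taxa-rows" else table.counts.T
    df.to_csv(path, sep="\t", index_label="taxon_id" if orientation == "taxa-rows" else "sample_id")


def read_metadata(path: str | Path, group_col: str = "group") -> SampleMetadata:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise DataValidationError(f"unparseable metadata {path}: {exc}") from exc
    df.index = df.index.astype(str)
    return SampleMetadata(df, group_col)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t", index_label="sample_id")


def read_tree(path: str | Path) -> TreeNode:
    """Read a Newick tree (scikit-bio TreeNode)."""
    try:
        source = str(path) if isinstance(path, Path) else path
        tree = TreeNode.read(source, format="newick")
    except Exception as exc:
        raise DataValidationError(f"unparseable Newick tree {path}: {exc}") from exc
    return tree


def match_tree_to_table(tree: TreeNode, table: AsvTable) -> TreeNode:
    """Reconcile tree tips with table taxa.

    Tips absent from the table are pruned (with a warning); table taxa absent
    from the tree are a hard error — silently imputing zero branch length
    would bias phylogenetic diversity.
    """
    tips = {t.name for t in tree.tips()}
    taxa = set(table.taxon_ids)
    missing = sorted(taxa - tips)
    if missing:
        raise DataValidationError(
            f"{len(missing)} table taxa absent from the tree, e.g. {missing[:5]}"
        )
    extra = tips - taxa
    if extra:
        warnings.warn(
            f"pruning {len(extra)} tree tips absent from the table", stacklevel=2
        )
        tree = tree.shear(sorted(taxa))
    return tree


# ---------------------------------------------------------------------------
# network and result writers
# ---------------------------------------------------------------------------


def write_network(graph: nx.Graph, path: str | Path, format: str = "edgelist") -> None:
    """Write a signed co-occurrence network.

    ``graphml`` keeps all node/edge attributes; ``edgelist`` is a TSV with
    columns source, target, rho, p_adj, sign.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "edgelist":
        rows = [
            {
                "source": u,
                "target": v,
                "rho": d.get("rho", np.nan),
                "p_adj": d.get("p_adj", np.nan),
                "sign": d.get("sign", "+" if d.get("rho", 0) > 0 else "-"),
            }
            for u, v, d in graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["source", "target", "rho", "p_adj", "sign"])
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edgelist":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(row.source, row.target, rho=row.rho, p_adj=row.p_adj, sign=row.sign)
        return g
    raise ValueError(f"unknown network format {format!r}")


def write_results(
    records: Sequence[Mapping] | pd.DataFrame | Mapping,
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Write tabular or nested result records as TSV (6 significant digits)
    or JSON (full precision)."""
    path = Path(path)
    if format == "json":
        obj = records
        if isinstance(records, pd.DataFrame):
            obj = records.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, default=_json_default)
            fh.write("\n")
    elif format == "tsv":
        df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    else:
        raise ValueError(f"unknown results format {format!r}")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


__all__ = [
    "AsvTable",
    "SampleMetadata",
    "DistanceMatrix",
    "DataValidationError",
    "read_asv_table",
    "write_asv_table",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "match_tree_to_table",
    "write_network",
    "read_network",
    "write_results",
]
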