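"""Readers and writers for the pipeline's plain-text formats.

Conventions: matrices (counts, expression, host ranges) are gene-/row-major
TSV or CSV with a header row; trees are newick with branch lengths; small
metadata tables (design, survival) are CSV.  Every reader validates and every
reader/writer pair round-trips its fixture byte-identically.
"""

from __future__ import annotations

import logging
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .types import (
    CountMatrix,
    ExpressionMatrix,
    GeneCatalog,
    HostRangeMatrix,
    Phylogeny,
    SampleDesign,
    SurvivalTable,
    TreeNode,
    ValidationError,
)

log = logging.getLogger("detoxshift")

__all__ = [
    "read_gene_catalog",
    "write_gene_catalog",
    "read_design",
    "write_design",
    "read_count_matrix",
    "write_count_matrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_newick",
    "write_newick",
    "read_host_matrix",
    "write_host_matrix",
    "read_survival",
    "write_survival",
]


def read_gene_catalog(path: str | Path) -> GeneCatalog:
    """Read a TSV with header ``gene_id<TAB>family`` into a GeneCatalog."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValidationError(f"{path}: empty gene catalog")
    for col in ("gene_id", "family"):
        if col not in df.columns:
            raise ValidationError(f"{path}: catalog must have columns gene_id, family")
    dup = df.loc[df["gene_id"].duplicated(), "gene_id"]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")
    try:
        catalog = GeneCatalog(dict(zip(df["gene_id"], df["family"])))
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from None
    log.info("read gene catalog: %d genes from %s", len(catalog), path)
    return catalog


def write_gene_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    df = pd.DataFrame(
        {"gene_id": list(catalog.entries), "family": list(catalog.entries.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, dtype={"sample_id": str, "species": str, "plant": str})
    try:
        design = SampleDesign(df.reset_index(drop=True))
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from None
    log.info("read design: %d samples from %s", len(df), path)
    return design


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, index=False)


def read_count_matrix(path: str | Path, design_path: str | Path) -> CountMatrix:
    """Read a genes x samples TSV and align the columns to the design order."""
    design = read_design(design_path)
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    only_counts = sorted(set(df.columns) - set(design.sample_ids))
    only_design = sorted(set(design.sample_ids) - set(df.columns))
    if only_counts or only_design:
        raise ValidationError(
            f"{path}: sample mismatch with design — only in counts {only_counts}, "
            f"only in design {only_design}"
        )
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.isfinite(arr.astype(float)).all() or not np.allclose(
            arr.astype(float), np.round(arr.astype(float))
        ):
            raise ValidationError(f"{path}: non-integer count entry")
        df = df.round().astype(int)
    df = df[design.sample_ids]  # normalize column order to the design
    try:
        counts = CountMatrix(df, design)
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from None
    log.info(
        "read counts: %d genes x %d samples from %s",
        counts.n_genes,
        counts.n_samples,
        path,
    )
    return counts


def write_count_matrix(counts: CountMatrix, path: str | Path) -> None:
    df = counts.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree, source: str) -> Phylogeny:
    def convert(dnode) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        children = [convert(c) for c in dnode.child_nodes()]
        length = dnode.edge.length
        if length is None:
            if dnode.parent_node is None:
                length = 0.0
            else:
                raise ValidationError(
                    f"{source}: missing branch length above "
                    f"{label or '<internal node>'}"
                )
        return TreeNode(label=label, length=float(length), children=children)

    root = convert(dtree.seed_node)
    tree = Phylogeny(root)
    if len(root.children) > 2:
        log.info("%s: tree root has %d children (unrooted-style/multifurcating)",
                 source, len(root.children))
    if tree.is_multifurcating():
        log.info("%s: tree contains multifurcations (handled natively)", source)
    return tree


def read_newick(path: str | Path) -> Phylogeny:
    path = Path(path)
    dtree = dendropy.Tree.get(path=str(path), schema="newick")
    return _from_dendropy(dtree, str(path))


def parse_newick(newick: str) -> Phylogeny:
    """Parse a newick string (convenience for tests and fixtures)."""
    dtree = dendropy.Tree.get(data=newick, schema="newick")
    return _from_dendropy(dtree, "<string>")


def write_newick(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Host range / survival
# ---------------------------------------------------------------------------


def read_host_matrix(path: str | Path, level: str = "order") -> HostRangeMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    try:
        return HostRangeMatrix(df.astype(int), level=level)
    except (ValidationError, ValueError) as err:
        raise ValidationError(f"{path}: {err}") from None


def write_host_matrix(matrix: HostRangeMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "group"
    df.to_csv(path)


def read_survival(path: str | Path) -> SurvivalTable:
    path = Path(path)
    df = pd.read_csv(path, dtype={"species": str, "plant": str})
    try:
        return SurvivalTable(df.reset_index(drop=True))
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from None


def write_survival(table: SurvivalTable, path: str | Path) -> None:
    table.table.to_csv(path, index=False)
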