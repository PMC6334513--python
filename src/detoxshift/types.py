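"""Domain types shared across the pipeline.

The analysis revolves around a small set of objects: a catalog of
detoxification genes grouped into the six classical families of the
three-phase xenobiotic detoxification system, an integer count matrix over a
species x plant x replicate factorial, a rooted phylogeny with binary
host-range characters at the tips, and a table of survival proportions from
the performance assay.  Each type validates its own invariants on
construction so that malformed inputs fail early with a named offender.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FAMILIES",
    "PLANTS",
    "COMMON_HOST",
    "SPECIES",
    "HIGH_PERFORMANCE",
    "LOW_PERFORMANCE",
    "STUDY_FAMILY_COUNTS",
    "GeneCatalog",
    "SampleDesign",
    "CountMatrix",
    "ExpressionMatrix",
    "TreeNode",
    "Phylogeny",
    "HostRangeMatrix",
    "SurvivalTable",
    "PerformanceGrouping",
]


class ValidationError(ValueError):
    """Raised when a domain object or input file violates an invariant."""


#: The six detoxification gene families (phase I, II and III of the system).
FAMILIES: tuple[str, ...] = ("P450", "GST", "COE", "UDPGT", "SULT", "ABC")

#: The four experimental host plants; eggplant is the common baseline host.
PLANTS: tuple[str, ...] = ("eggplant", "cassava", "kale", "pepper")
COMMON_HOST = "eggplant"

#: The six analysed B. tabaci cryptic species.
SPECIES: tuple[str, ...] = (
    "MEAM1",
    "MED-Q1",
    "Uganda-MED-ASL",
    "NW2",
    "AsiaII-1",
    "SSA1-SG3",
)

#: Host-performance bipartition observed in the survival assays.
HIGH_PERFORMANCE: frozenset[str] = frozenset({"MEAM1", "AsiaII-1", "SSA1-SG3"})
LOW_PERFORMANCE: frozenset[str] = frozenset({"NW2", "MED-Q1", "Uganda-MED-ASL"})

#: Catalog family sizes of the curated detoxification gene set (total 298).
STUDY_FAMILY_COUNTS: dict[str, int] = {
    "P450": 104,
    "GST": 25,
    "COE": 24,
    "UDPGT": 71,
    "SULT": 20,
    "ABC": 54,
}


# ---------------------------------------------------------------------------
# Gene catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneCatalog:
    """Map of gene id -> detoxification family.

    The catalog defines the analysis universe of detoxification genes and the
    family proportions used as the baseline of enrichment tests.
    """

    entries: dict[str, str]

    def __post_init__(self) -> None:
        bad = {g: f for g, f in self.entries.items() if f not in FAMILIES}
        if bad:
            g, f = next(iter(bad.items()))
            raise ValidationError(
                f"unknown family {f!r} for gene {g!r}; families must be one of {FAMILIES}"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries

    def family(self, gene_id: str) -> str:
        return self.entries[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.entries)

    def family_counts(self) -> np.ndarray:
        """Counts per family, ordered as :data:`FAMILIES`; sums to len(self)."""
        counts = np.zeros(len(FAMILIES), dtype=int)
        idx = {f: i for i, f in enumerate(FAMILIES)}
        for fam in self.entries.values():
            counts[idx[fam]] += 1
        return counts

    def family_proportions(self) -> np.ndarray:
        if len(self) == 0:
            raise ValidationError("empty catalog has no family proportions")
        return self.family_counts() / len(self)


# ---------------------------------------------------------------------------
# Sample design / counts / expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDesign:
    """Factorial sample sheet: sample_id, species, plant, replicate."""

    table: pd.DataFrame  # columns: sample_id, species, plant, replicate

    REQUIRED = ("sample_id", "species", "plant", "replicate")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"design table missing columns {missing}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r} in design")
        bad_plants = sorted(set(t["plant"]) - set(PLANTS))
        if bad_plants:
            raise ValidationError(
                f"unknown plant(s) {bad_plants}; plants must be among {PLANTS}"
            )
        if (t["replicate"].astype(int) <= 0).any():
            raise ValidationError("replicate numbers must be positive integers")
        # every observed species x plant cell must have at least one replicate
        cells = t.groupby(["species", "plant"], observed=True).size()
        n_sp = t["species"].nunique()
        n_pl = t["plant"].nunique()
        if len(cells) < n_sp * n_pl:
            have = set(cells.index)
            want = {(s, p) for s in t["species"].unique() for p in t["plant"].unique()}
            missing_cells = sorted(want - have)
            raise ValidationError(f"design cells without replicates: {missing_cells}")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    @property
    def plants(self) -> list[str]:
        return [p for p in PLANTS if p in set(self.table["plant"])]

    def cell_samples(self, species: str, plant: str) -> list[str]:
        t = self.table
        m = (t["species"] == species) & (t["plant"] == plant)
        return t.loc[m, "sample_id"].tolist()

    def cells(self) -> list[tuple[str, str]]:
        """Observed (species, plant) cells in canonical species/plant order."""
        present = set(zip(self.table["species"], self.table["plant"]))
        return [(s, p) for s in self.species for p in self.plants if (s, p) in present]


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer counts, genes as rows, samples as columns."""

    values: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate gene_id {dup!r} in count matrix")
        counts_samples = list(v.columns)
        design_samples = self.design.sample_ids
        if counts_samples != design_samples:
            only_counts = sorted(set(counts_samples) - set(design_samples))
            only_design = sorted(set(design_samples) - set(counts_samples))
            if only_counts or only_design:
                raise ValidationError(
                    "count matrix / design sample mismatch: "
                    f"only in counts {only_counts}, only in design {only_design}"
                )
            raise ValidationError(
                "count matrix columns must follow design sample order"
            )
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("count matrix contains non-integer entries")
        if (arr < 0).any():
            gene = v.index[np.argwhere(arr < 0)[0][0]]
            raise ValidationError(f"negative count for gene {gene!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Real-valued expression on a log2-like scale (genes x samples/cells)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of a rooted phylogeny; leaves carry tip labels."""

    label: str | None = None
    length: float = 0.0  # branch length to the parent (root: ignored)
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Phylogeny:
    """Rooted tree with non-negative branch lengths and unique tip labels.

    Multifurcations are represented natively (a node may have any number of
    children); the likelihood machinery handles them without resolving.
    """

    root: TreeNode

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            seen: set[str] = set()
            for lab in labels:
                if lab in seen:
                    raise ValidationError(f"duplicate tip label {lab!r}")
                seen.add(lab)
        for node in self.postorder():
            if node is not self.root and node.length < 0:
                raise ValidationError(
                    f"negative branch length at node {node.label or '<internal>'}"
                )
            if node.is_leaf and node.label is None:
                raise ValidationError("unlabelled tip in tree")

    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    @property
    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips]  # type: ignore[misc]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def is_multifurcating(self) -> bool:
        return any(len(n.children) > 2 for n in self.postorder())

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.label or ""
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    core += node.label
            if node is self.root:
                return core
            return f"{core}:{node.length:g}"

        return fmt(self.root) + ";"


# ---------------------------------------------------------------------------
# Host range / survival / grouping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HostRangeMatrix:
    """Binary species-group x host-taxon presence/absence matrix."""

    values: pd.DataFrame  # rows: species groups, columns: host taxa, entries 0/1
    level: str = "order"  # taxonomic level of the columns

    LEVELS = ("order", "family", "genus")

    def __post_init__(self) -> None:
        if self.level not in self.LEVELS:
            raise ValidationError(f"level must be one of {self.LEVELS}, got {self.level!r}")
        v = self.values
        if v.index.duplicated().any() or v.columns.duplicated().any():
            raise ValidationError("host range matrix labels must be unique")
        arr = v.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            i, j = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise ValidationError(
                f"non-binary entry {arr[i, j]!r} at ({v.index[i]!r}, {v.columns[j]!r})"
            )

    @property
    def groups(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.values.columns)

    def character(self, taxon: str) -> dict[str, int]:
        """Tip-state map (group -> 0/1) for one host taxon column."""
        return {g: int(v) for g, v in self.values[taxon].items()}


@dataclass(frozen=True)
class SurvivalTable:
    """Replicate survival proportions from the 24-hr adult performance assay."""

    table: pd.DataFrame  # columns: species, plant, replicate, proportion_survived

    REQUIRED = ("species", "plant", "replicate", "proportion_survived")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"survival table missing columns {missing}")
        p = t["proportion_survived"].to_numpy(dtype=float)
        if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
            row = t.iloc[int(np.argwhere((p < 0) | (p > 1) | ~np.isfinite(p))[0][0])]
            raise ValidationError(
                f"survival proportion {row['proportion_survived']!r} outside [0, 1] "
                f"(species {row['species']!r}, plant {row['plant']!r})"
            )


@dataclass(frozen=True)
class PerformanceGrouping:
    """Disjoint bipartition of the species set into high/low performance."""

    high: frozenset[str]
    low: frozenset[str]

    def __post_init__(self) -> None:
        if not self.high or not self.low:
            raise ValidationError("both performance groups must be non-empty")
        overlap = self.high & self.low
        if overlap:
            raise ValidationError(f"species in both groups: {sorted(overlap)}")

    @property
    def species(self) -> frozenset[str]:
        return self.high | self.low

    @classmethod
    def study_default(cls) -> "PerformanceGrouping":
        return cls(high=HIGH_PERFORMANCE, low=LOW_PERFORMANCE)


def cell_label(species: str, plant: str) -> str:
    """Canonical label for a species x plant condition cell."""
    return f"{species}:{plant}"


def split_cell_label(label: str) -> tuple[str, str]:
    species, _, plant = label.rpartition(":")
    if not species:
        raise ValidationError(f"malformed cell label {label!r}")
    return species, plant
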