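"""Classification of detoxification genes from DE results.

Three rule sets, applied to thresholded DE calls:

* **constitutive-unique** — on the common host (eggplant), a gene counted for
  species S iff it is significantly higher (or lower) in S than in *each* of
  the other species, at |log2FC| >= 1 and FDR <= 0.05;
* **plastic** — within each species, genes responding to the transfer from
  eggplant to a noncommon plant at |log2FC| >= 0.58 (1.5-fold) and
  FDR <= 0.05, with a qualitative per-species pattern class (high response on
  >1 plant / on exactly 1 plant / low response);
* **shared machinery** — genes plastic in more than one species that show
  the same direction (up or down) in at least two species.

Family enrichment of any resulting gene set is a 6-category chi-square
goodness-of-fit against the catalog's family proportions (df = 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import COMMON_HOST, FAMILIES, GeneCatalog, ValidationError

__all__ = [
    "constitutive_unique",
    "plastic_sets",
    "pattern_classes",
    "shared_machinery",
    "family_enrichment",
    "ClassificationReport",
    "classify_detox_genes",
]

CONSTITUTIVE_LFC = 1.0
PLASTIC_LFC = 0.58
PADJ_THRESHOLD = 0.05
HIGH_CUT = 20  # genes on a plant to count as a "high" plastic response


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} table missing columns {missing}")


def constitutive_unique(
    de_between: pd.DataFrame,
    species: list[str],
    lfc_threshold: float = CONSTITUTIVE_LFC,
    padj_threshold: float = PADJ_THRESHOLD,
) -> dict[str, dict[str, set[str]]]:
    """Per-species constitutively over-/under-expressed unique gene sets.

    ``de_between`` holds one row per gene per unordered species pair on the
    common host, with columns ``gene, species_a, species_b, log2fc, padj``
    where ``log2fc`` is b relative to a.  All pairs over ``species`` must be
    present.  Returns ``{species: {"over": set, "under": set}}``.
    """
    _require_columns(
        de_between, ("gene", "species_a", "species_b", "log2fc", "padj"), "between-species DE"
    )
    pairs_present = {
        frozenset(p) for p in zip(de_between["species_a"], de_between["species_b"])
    }
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            if frozenset((a, b)) not in pairs_present:
                raise ValidationError(f"missing between-species contrast ({a}, {b})")

    sig = de_between.loc[
        (de_between["log2fc"].abs() >= lfc_threshold)
        & (de_between["padj"] <= padj_threshold)
    ]
    # per gene: tally, for each species, how many partners it beats / trails
    n_other = len(species) - 1
    result = {s: {"over": set(), "under": set()} for s in species}
    if sig.empty:
        return result
    up_counts: dict[tuple[str, str], int] = {}
    for gene, a, b, lfc in zip(
        sig["gene"], sig["species_a"], sig["species_b"], sig["log2fc"]
    ):
        higher, lower = (b, a) if lfc > 0 else (a, b)
        up_counts[(gene, higher)] = up_counts.get((gene, higher), 0) + 1
        up_counts[(gene, lower)] = up_counts.get((gene, lower), 0) - 1
    for (gene, sp), score in up_counts.items():
        if sp not in result:
            continue
        if score == n_other:
            result[sp]["over"].add(gene)
        elif score == -n_other:
            result[sp]["under"].add(gene)
    return result


def plastic_sets(
    de_within: pd.DataFrame,
    lfc_threshold: float = PLASTIC_LFC,
    padj_threshold: float = PADJ_THRESHOLD,
) -> dict[tuple[str, str], dict[str, int]]:
    """Signed plastic gene sets per (species, noncommon plant).

    ``de_within`` holds one row per gene per within-species contrast
    (plant vs eggplant), columns ``gene, species, plant, log2fc, padj``.
    Returns ``{(species, plant): {gene: +1/-1}}`` for every contrast present,
    including empty dicts for contrasts with no calls.
    """
    _require_columns(de_within, ("gene", "species", "plant", "log2fc", "padj"), "within-species DE")
    if (de_within["plant"] == COMMON_HOST).any():
        raise ValidationError("within-species contrasts must be vs the common host")
    out: dict[tuple[str, str], dict[str, int]] = {
        key: {} for key in sorted(set(zip(de_within["species"], de_within["plant"])))
    }
    sig = de_within.loc[
        (de_within["log2fc"].abs() >= lfc_threshold)
        & (de_within["padj"] <= padj_threshold)
    ]
    for gene, sp, plant, lfc in zip(
        sig["gene"], sig["species"], sig["plant"], sig["log2fc"]
    ):
        out[(sp, plant)][gene] = 1 if lfc > 0 else -1
    return out


def pattern_classes(
    plastic: dict[tuple[str, str], dict[str, int]], high_cut: int = HIGH_CUT
) -> dict[str, str]:
    """Qualitative per-species plastic-response pattern.

    ``multi-host-high`` if >= high_cut genes respond on >= 2 plants,
    ``single-host-high`` if on exactly one plant, ``low`` otherwise.
    """
    species = sorted({sp for sp, _ in plastic})
    classes = {}
    for sp in species:
        n_high = sum(
            1 for (s, _), genes in plastic.items() if s == sp and len(genes) >= high_cut
        )
        if n_high >= 2:
            classes[sp] = "multi-host-high"
        elif n_high == 1:
            classes[sp] = "single-host-high"
        else:
            classes[sp] = "low"
    return classes


def shared_machinery(
    plastic: dict[tuple[str, str], dict[str, int]],
) -> tuple[set[str], set[str]]:
    """Genes plastic in >1 species, and the direction-consistent subset.

    Returns ``(shared_multi, machinery)``: shared_multi contains genes called
    in at least two species (any plant, any direction); machinery keeps those
    for which at least two species share the same direction on at least one
    of their called plants.
    """
    if len({sp for sp, _ in plastic}) < 2:
        raise ValidationError("need plastic sets from at least two species")
    per_gene_dirs: dict[str, dict[str, set[int]]] = {}
    for (sp, _), genes in plastic.items():
        for gene, direction in genes.items():
            per_gene_dirs.setdefault(gene, {}).setdefault(sp, set()).add(direction)
    shared_multi = {g for g, d in per_gene_dirs.items() if len(d) >= 2}
    machinery = set()
    for gene in shared_multi:
        for direction in (1, -1):
            n_species = sum(
                1 for dirs in per_gene_dirs[gene].values() if direction in dirs
            )
            if n_species >= 2:
                machinery.add(gene)
                break
    return shared_multi, machinery


def family_enrichment(
    gene_set: set[str], catalog: GeneCatalog
) -> tuple[float, int, float]:
    """Chi-square goodness of fit of a set's family mix vs the catalog.

    Expected counts are catalog family proportions times the set size;
    df = 5 for the six-family catalog.  Returns (chi2, df, p).
    """
    if not gene_set:
        raise ValidationError("gene set is empty")
    stray = sorted(g for g in gene_set if g not in catalog)
    if stray:
        raise ValidationError(f"gene(s) not in catalog: {stray[:5]}")
    idx = {f: i for i, f in enumerate(FAMILIES)}
    observed = np.zeros(len(FAMILIES))
    for g in gene_set:
        observed[idx[catalog.family(g)]] += 1
    expected = catalog.family_proportions() * len(gene_set)
    chi2, p = stats.chisquare(observed, expected)
    return float(chi2), len(FAMILIES) - 1, float(p)


@dataclass
class ClassificationReport:
    """Full classification output (sets, pattern classes, enrichment)."""

    constitutive: dict[str, dict[str, set[str]]]
    plastic: dict[tuple[str, str], dict[str, int]]
    patterns: dict[str, str]
    plastic_any: set[str] = field(default_factory=set)
    single_species: set[str] = field(default_factory=set)
    shared_multi: set[str] = field(default_factory=set)
    machinery: set[str] = field(default_factory=set)
    enrichment: dict[str, tuple[float, int, float]] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "constitutive": {
                sp: {k: sorted(v) for k, v in d.items()}
                for sp, d in self.constitutive.items()
            },
            "plastic": {
                f"{sp}:{plant}": {g: int(d) for g, d in sorted(genes.items())}
                for (sp, plant), genes in self.plastic.items()
            },
            "patterns": self.patterns,
            "plastic_any": sorted(self.plastic_any),
            "single_species": sorted(self.single_species),
            "shared_multi": sorted(self.shared_multi),
            "machinery": sorted(self.machinery),
            "enrichment": {
                k: {"chi2": v[0], "df": v[1], "p": v[2]}
                for k, v in self.enrichment.items()
            },
        }


def classify_detox_genes(
    de_between: pd.DataFrame,
    de_within: pd.DataFrame,
    catalog: GeneCatalog,
    species: list[str] | None = None,
    high_cut: int = HIGH_CUT,
) -> ClassificationReport:
    """Run the full classification chain on catalog genes.

    DE inputs may cover the whole transcriptome; only catalog genes enter the
    classification (thresholding has already been applied genome-wide through
    the adjusted p-values).
    """
    between_cat = de_between.loc[de_between["gene"].isin(catalog.entries)]
    within_cat = de_within.loc[de_within["gene"].isin(catalog.entries)]
    if species is None:
        species = sorted(
            set(de_between["species_a"]) | set(de_between["species_b"])
        )
    constitutive = constitutive_unique(between_cat, species)
    plastic = plastic_sets(within_cat)
    patterns = pattern_classes(plastic, high_cut=high_cut)
    plastic_any = {g for genes in plastic.values() for g in genes}
    shared_multi, machinery = shared_machinery(plastic)
    single = plastic_any - shared_multi
    enrichment = {}
    for name, genes in (
        ("plastic_any", plastic_any),
        ("single_species", single),
        ("shared_multi", shared_multi),
        ("machinery", machinery),
    ):
        if genes:
            enrichment[name] = family_enrichment(genes, catalog)
    return ClassificationReport(
        constitutive=constitutive,
        plastic=plastic,
        patterns=patterns,
        plastic_any=plastic_any,
        single_species=single,
        shared_multi=shared_multi,
        machinery=machinery,
        enrichment=enrichment,
    )
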