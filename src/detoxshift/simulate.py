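"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the study's count-matrix level: a 6-species x
4-plant x 3-replicate factorial of negative-binomial counts over a ~300-gene
detoxification catalog embedded in a >=20,000-gene background, plus binary
host characters evolved under the symmetric Mk process on a supplied tree and
binomial/beta-binomial survival proportions.

Two structural choices encode the study's central contrast:

* background genes carry a *phylogeny-axis* species signal — a shared
  loading separating {MEAM1, MED-Q1, Uganda-MED-ASL} from
  {NW2, AsiaII-1, SSA1-SG3} — plus plant-response loadings, so random
  background subsets cluster species by relatedness;
* detoxification genes carry a *performance-group* loading (high vs low
  survival groups) instead, plus the planted constitutive/plastic/machinery
  class effects, so the catalog clusters species by performance.

Counts are NB with Var = mu + alpha * mu^2 (mean/dispersion convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import (
    COMMON_HOST,
    FAMILIES,
    HIGH_PERFORMANCE,
    PLANTS,
    SPECIES,
    STUDY_FAMILY_COUNTS,
    CountMatrix,
    GeneCatalog,
    Phylogeny,
    SampleDesign,
    SurvivalTable,
    ValidationError,
    cell_label,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "default_design",
    "simulate_counts",
    "simulate_mk_history",
    "default_survival_means",
    "simulate_survival",
]

NONCOMMON = tuple(p for p in PLANTS if p != COMMON_HOST)

#: +1 for the Africa/Middle East/Asia-Minor-related side of the mtCOI tree.
PHYLO_AXIS = {
    "MEAM1": 1.0,
    "MED-Q1": 1.0,
    "Uganda-MED-ASL": 1.0,
    "NW2": -1.0,
    "AsiaII-1": -1.0,
    "SSA1-SG3": -1.0,
}

#: Plants on which each species mounts its main plastic response.
PRIMARY_PLANTS = {
    "AsiaII-1": ("cassava", "pepper"),
    "NW2": ("cassava", "pepper"),
    "MED-Q1": ("cassava",),
    "SSA1-SG3": ("kale",),
    "MEAM1": ("cassava",),
    "Uganda-MED-ASL": ("cassava",),
}

#: Weights for which species receives a single-species plastic gene,
#: proportional to the scale of per-species plastic responses.
SINGLE_PLASTIC_WEIGHTS = {
    "MEAM1": 5,
    "MED-Q1": 41,
    "Uganda-MED-ASL": 9,
    "NW2": 84,
    "AsiaII-1": 74,
    "SSA1-SG3": 27,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic scenario (defaults mirror the study)."""

    n_background: int = 25_000
    family_counts: dict[str, int] = field(
        default_factory=lambda: dict(STUDY_FAMILY_COUNTS)
    )
    # catalog class allocation
    n_constitutive_over_per_species: int = 4
    n_constitutive_under_per_species: int = 2
    machinery_multiplicity: tuple[tuple[int, int], ...] = ((4, 6), (3, 14), (2, 24))
    n_discordant_multi: int = 12
    n_single_plastic: int = 95
    # effect sizes, log2 scale
    constitutive_effect: float = 2.0
    plastic_effect: float = 1.3
    group_sd: float = 1.5
    detox_species_sd: float = 0.2
    background_phylo_sd: float = 0.8
    background_species_sd: float = 0.3
    plant_responsive_fraction: float = 0.25
    plant_effect_sd: float = 0.8
    # abundance / noise
    base_log2_background: tuple[float, float] = (3.0, 9.0)
    base_log2_detox: tuple[float, float] = (7.0, 9.0)
    dispersion_log_mean: float = math.log(0.05)
    dispersion_log_sd: float = 0.25
    library_factor_range: tuple[float, float] = (0.7, 1.3)

    def __post_init__(self) -> None:
        lo, hi = self.library_factor_range
        if lo <= 0 or hi <= 0:
            raise ValidationError("library factors must be positive")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated count matrix."""

    genes: pd.DataFrame  # index gene_id; columns is_detox, family, true_class
    mean_log2: pd.DataFrame  # genes x cells true log2 means
    dispersion: pd.Series  # per-gene NB dispersion alpha
    class_details: dict[str, dict]  # gene -> {species: ..., plants: ..., direction(s)}

    def genes_of_class(self, true_class: str) -> list[str]:
        g = self.genes
        return list(g.index[g["true_class"] == true_class])

    @property
    def constitutive(self) -> dict[str, tuple[str, int]]:
        """gene -> (species, direction) for planted constitutive-unique genes."""
        return {
            g: (self.class_details[g]["species"], self.class_details[g]["direction"])
            for g in self.genes_of_class("constitutive-unique")
        }

    @property
    def machinery(self) -> set[str]:
        return set(self.genes_of_class("shared-machinery"))

    def to_jsonable(self) -> dict:
        return {
            "classes": {
                g: {"class": c, **self.class_details.get(g, {})}
                for g, c in self.genes["true_class"].items()
                if c != "none"
            },
            "n_genes": int(len(self.genes)),
            "n_detox": int(self.genes["is_detox"].sum()),
        }


def default_design(n_replicates: int = 3) -> SampleDesign:
    """The study factorial: 6 species x 4 plants x n replicates."""
    rows = []
    for sp in SPECIES:
        for pl in PLANTS:
            for r in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{sp}.{pl}.r{r}",
                        "species": sp,
                        "plant": pl,
                        "replicate": r,
                    }
                )
    return SampleDesign(pd.DataFrame(rows))


def _build_catalog(config: SimulationConfig) -> GeneCatalog:
    entries: dict[str, str] = {}
    i = 1
    for fam in FAMILIES:
        for _ in range(config.family_counts.get(fam, 0)):
            entries[f"detox{i:04d}"] = fam
            i += 1
    return GeneCatalog(entries)


def _allocate_classes(
    detox_ids: list[str], config: SimulationConfig, species: list[str], rng
) -> tuple[pd.Series, dict[str, dict]]:
    """Assign truth classes to catalog genes, in catalog order."""
    classes = pd.Series("none", index=pd.Index(detox_ids), dtype=object)
    details: dict[str, dict] = {}
    it = iter(detox_ids)

    def take(n: int) -> list[str]:
        out = []
        for _ in range(n):
            try:
                out.append(next(it))
            except StopIteration:
                raise ValidationError(
                    "catalog too small for the requested class allocation"
                ) from None
        return out

    for sp in species:
        for direction, n in (
            (1, config.n_constitutive_over_per_species),
            (-1, config.n_constitutive_under_per_species),
        ):
            for g in take(n):
                classes[g] = "constitutive-unique"
                details[g] = {"species": sp, "direction": direction}

    for n_species, n_genes in config.machinery_multiplicity:
        for g in take(n_genes):
            subset = sorted(rng.choice(species, size=n_species, replace=False))
            direction = 1 if rng.random() < 0.75 else -1
            plants = ("cassava", "pepper") if rng.random() < 0.5 else ("cassava", "kale")
            classes[g] = "shared-machinery"
            details[g] = {
                "species": subset,
                "plants": list(plants),
                "direction": direction,
            }

    for g in take(config.n_discordant_multi):
        pair = sorted(rng.choice(species, size=2, replace=False))
        classes[g] = "plastic"
        details[g] = {
            "species": pair,
            "plants": ["cassava"],
            "directions": {pair[0]: 1, pair[1]: -1},
        }

    weights = np.array([SINGLE_PLASTIC_WEIGHTS.get(s, 1) for s in species], float)
    weights /= weights.sum()
    for g in take(config.n_single_plastic):
        sp = str(rng.choice(species, p=weights))
        plant = str(rng.choice(PRIMARY_PLANTS.get(sp, NONCOMMON)))
        direction = 1 if rng.random() < 0.6 else -1
        classes[g] = "plastic"
        details[g] = {"species": [sp], "plants": [plant], "direction": direction}

    return classes, details


def simulate_counts(
    design: SampleDesign,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, GeneCatalog, SimulationTruth]:
    """Draw an NB count matrix with planted detoxification structure.

    Counts for sample j of gene g are NB with mean ``library_factor_j *
    2^eta(g, cell(j))`` and per-gene dispersion alpha (gamma-Poisson
    mixture), where eta stacks base abundance, species, plant,
    performance-group and planted class effects on the log2 scale.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    species = [s for s in SPECIES if s in design.species] or design.species
    plants = design.plants
    cells = design.cells()
    cell_labels = [cell_label(s, p) for s, p in cells]

    catalog = _build_catalog(config)
    detox_ids = catalog.gene_ids
    bg_ids = [f"bg{i:05d}" for i in range(1, config.n_background + 1)]
    gene_ids = detox_ids + bg_ids
    n_detox, n_bg = len(detox_ids), len(bg_ids)
    n_genes = n_detox + n_bg

    classes, details = _allocate_classes(detox_ids, config, species, rng)

    sp_index = {s: i for i, s in enumerate(species)}
    group_axis = np.array([1.0 if s in HIGH_PERFORMANCE else -1.0 for s in species])
    phylo_axis = np.array([PHYLO_AXIS.get(s, 0.0) for s in species])

    # per-gene building blocks
    base = np.empty(n_genes)
    base[:n_detox] = rng.uniform(*config.base_log2_detox, size=n_detox)
    base[n_detox:] = rng.uniform(*config.base_log2_background, size=n_bg)

    # species-individual effects (gene x species)
    d_sp = np.zeros((n_genes, len(species)))
    d_sp[:n_detox] = rng.normal(0, config.detox_species_sd, (n_detox, len(species)))
    d_sp[n_detox:] = rng.normal(
        0, config.background_species_sd, (n_bg, len(species))
    )
    # background phylogeny-axis loading
    b_phylo = np.zeros(n_genes)
    b_phylo[n_detox:] = rng.normal(0, config.background_phylo_sd, n_bg)
    # performance-group loading: only unclassified catalog genes
    a_group = np.zeros(n_genes)
    unclassified = np.array(
        [classes[g] == "none" for g in detox_ids], dtype=bool
    )
    a_group[:n_detox][unclassified] = rng.normal(
        0, config.group_sd, int(unclassified.sum())
    )
    # background plant-response loadings (gene x plant), common host = 0
    plant_load = np.zeros((n_genes, len(plants)))
    responsive = rng.random(n_bg) < config.plant_responsive_fraction
    for j, pl in enumerate(plants):
        if pl == COMMON_HOST:
            continue
        load = rng.normal(0, config.plant_effect_sd, n_bg) * responsive
        plant_load[n_detox:, j] = load

    eta = np.empty((n_genes, len(cells)))
    for c, (sp, pl) in enumerate(cells):
        i = sp_index[sp]
        j = plants.index(pl)
        eta[:, c] = (
            base
            + d_sp[:, i]
            + b_phylo * phylo_axis[i]
            + a_group * group_axis[i]
            + plant_load[:, j]
        )

    # planted class effects
    gene_pos = {g: k for k, g in enumerate(detox_ids)}
    cell_pos = {c: k for k, c in enumerate(cells)}
    for g, cls in classes.items():
        if cls == "none":
            continue
        det = details[g]
        k = gene_pos[g]
        if cls == "constitutive-unique":
            sp = det["species"]
            for pl in plants:
                eta[k, cell_pos[(sp, pl)]] += det["direction"] * config.constitutive_effect
        elif cls == "shared-machinery":
            for sp in det["species"]:
                for pl in det["plants"]:
                    if (sp, pl) in cell_pos:
                        eta[k, cell_pos[(sp, pl)]] += (
                            det["direction"] * config.plastic_effect
                        )
        elif cls == "plastic":
            dirs = det.get("directions") or {s: det["direction"] for s in det["species"]}
            for sp in det["species"]:
                for pl in det["plants"]:
                    if (sp, pl) in cell_pos:
                        eta[k, cell_pos[(sp, pl)]] += dirs[sp] * config.plastic_effect

    alpha = np.exp(
        rng.normal(config.dispersion_log_mean, config.dispersion_log_sd, n_genes)
    )
    if (alpha <= 0).any():
        raise ValidationError("dispersions must be positive")
    lib = rng.uniform(*config.library_factor_range, size=len(design.sample_ids))

    mu_cells = np.exp2(eta)
    counts = np.empty((n_genes, len(design.sample_ids)), dtype=np.int64)
    sample_cell = [
        cell_pos[(sp, pl)]
        for sp, pl in zip(design.table["species"], design.table["plant"])
    ]
    shape = 1.0 / alpha  # gamma-Poisson: NB with Var = mu + alpha mu^2
    for j, c in enumerate(sample_cell):
        mu = lib[j] * mu_cells[:, c]
        lam = rng.gamma(shape=shape, scale=mu * alpha)
        counts[:, j] = rng.poisson(lam)

    values = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"), columns=design.sample_ids
    )
    truth_genes = pd.DataFrame(
        {
            "is_detox": [g in catalog for g in gene_ids],
            "family": [catalog.entries.get(g, "") for g in gene_ids],
            "true_class": [classes.get(g, "none") for g in gene_ids],
        },
        index=values.index,
    )
    truth = SimulationTruth(
        genes=truth_genes,
        mean_log2=pd.DataFrame(eta, index=values.index, columns=cell_labels),
        dispersion=pd.Series(alpha, index=values.index, name="dispersion"),
        class_details=details,
    )
    return CountMatrix(values, design), catalog, truth


# ---------------------------------------------------------------------------
# Mk character histories
# ---------------------------------------------------------------------------


def simulate_mk_history(
    tree: Phylogeny,
    rate: float,
    root_prior: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
    n_characters: int = 1,
) -> tuple[pd.DataFrame, list[dict[str, int]]]:
    """Evolve binary characters by the symmetric 2-state Markov process.

    A state flips over a branch of length t with probability
    ``(1 - exp(-2 rate t)) / 2``.  Returns tip states (tips x characters)
    and, per character, the true state of every node keyed by the node names
    of :func:`detoxshift.ancestral.node_names`.
    """
    from .ancestral import node_names

    if rate < 0:
        raise ValidationError(f"rate must be non-negative, got {rate}")
    if not math.isclose(sum(root_prior), 1.0):
        raise ValidationError("root prior must sum to 1")
    rng = np.random.default_rng(seed)
    names = node_names(tree)
    tip_rows: dict[str, list[int]] = {lab: [] for lab in tree.tip_labels}
    node_states: list[dict[str, int]] = []
    for _ in range(n_characters):
        root_state = int(rng.random() < root_prior[1])
        states: dict[int, int] = {}
        stack = [(tree.root, None)]
        while stack:
            node, parent_state = stack.pop()
            if parent_state is None:
                state = root_state
            else:
                p_change = (1.0 - math.exp(-2.0 * rate * node.length)) / 2.0
                state = parent_state ^ int(rng.random() < p_change)
            states[id(node)] = state
            for child in reversed(node.children):
                stack.append((child, state))
        node_states.append({names[nid]: s for nid, s in states.items()})
        for node in tree.tips:
            tip_rows[node.label].append(states[id(node)])  # type: ignore[index]
    tips = pd.DataFrame(
        tip_rows, index=[f"char{i + 1}" for i in range(n_characters)]
    ).T
    return tips, node_states


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


def default_survival_means() -> dict[tuple[str, str], float]:
    """True survival means mirroring the assay's structure.

    Every species survives well on the common host (with only a small
    residual group difference); on noncommon hosts the high-performance
    group stays high while the low-performance group drops, with mild
    additive plant severity.
    """
    severity = {"cassava": 0.0, "kale": 0.05, "pepper": 0.10}
    means = {}
    for sp in SPECIES:
        high = sp in HIGH_PERFORMANCE
        means[(sp, COMMON_HOST)] = 0.85 if high else 0.76
        for pl in NONCOMMON:
            base = 0.66 if high else 0.50
            means[(sp, pl)] = base - severity[pl]
    return means


def simulate_survival(
    group_means: dict[tuple[str, str], float] | None = None,
    n_insects: int = 50,
    n_replicates: int = 3,
    kappa: float | None = 50.0,
    seed: int = 0,
) -> SurvivalTable:
    """Replicate survival proportions: Binomial(n_insects, p) / n_insects.

    With ``kappa`` set, p varies between replicates as
    Beta(kappa * p, kappa * (1 - p)) (extra between-replicate dispersion).
    """
    means = group_means or default_survival_means()
    for (sp, pl), p in means.items():
        if not 0 <= p <= 1:
            raise ValidationError(f"survival mean {p} for ({sp}, {pl}) outside [0, 1]")
    if kappa is not None and kappa <= 0:
        raise ValidationError("kappa must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for (sp, pl), p in means.items():
        for r in range(1, n_replicates + 1):
            pr = p
            if kappa is not None and 0 < p < 1:
                pr = rng.beta(kappa * p, kappa * (1 - p))
            k = rng.binomial(n_insects, pr)
            rows.append(
                {
                    "species": sp,
                    "plant": pl,
                    "replicate": r,
                    "proportion_survived": k / n_insects,
                }
            )
    return SurvivalTable(pd.DataFrame(rows))
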