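"""Stage orchestration: chain the analysis stages from a flat config.

The config is a YAML mapping with a master ``seed``, an ``out_dir``, the
``stages`` to run, input paths, and optional per-stage settings.  Every
stochastic stage derives its own sub-seed from the master seed and its stage
name, so a re-run with the same config reproduces all outputs byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .ancestral import ancestral_host_report, report_table
from .classify import classify_detox_genes
from .de import (
    adjust_bh,
    estimate_dispersion,
    filter_low_counts,
    nb_wald_test,
    regularized_log,
    size_factors_median_ratio,
)
from .nulltest import (
    pca_correlation,
    profile_dendrogram,
    random_subset_null,
    variance_partition,
)
from .performance import performance_report
from .simulate import (
    SimulationConfig,
    default_design,
    simulate_counts,
    simulate_survival,
)
from .survey import binary_euclidean_distance, shared_taxa, survey_cluster
from .hierclust import cut_into_k
from .types import (
    COMMON_HOST,
    PerformanceGrouping,
    ValidationError,
)

log = logging.getLogger("detoxshift")

STAGES = (
    "simulate",
    "survey",
    "ancestral",
    "de",
    "classify",
    "clusternull",
    "performance",
)

DEFAULT_THRESHOLDS = {
    "min_reads": 10,
    "sample_fraction": 0.04,
    "constitutive_lfc": 1.0,
    "plastic_lfc": 0.58,
    "padj": 0.05,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(idx,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# Reusable stage cores
# ---------------------------------------------------------------------------


def run_de_stage(counts, thresholds: dict | None = None):
    """Filter, normalize and test all study contrasts.

    Returns ``(de_between, de_within, rld, size_factors, meta)`` where
    de_between has one row per gene per unordered species pair on the common
    host (log2fc = species_b over species_a) and de_within one row per gene
    per (species, noncommon plant) contrast (log2fc = plant over common
    host).  Adjusted p-values are BH within each contrast across all
    retained genes.
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    design = counts.design
    filtered = filter_low_counts(
        counts, min_reads=th["min_reads"], sample_fraction=th["sample_fraction"]
    )
    factors = size_factors_median_ratio(filtered)
    dispersions = estimate_dispersion(filtered, factors, design)
    rld = regularized_log(filtered, factors)

    species = design.species
    plants = design.plants
    between_rows = []
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            res = nb_wald_test(
                filtered, factors, dispersions, ((a, COMMON_HOST), (b, COMMON_HOST))
            )
            res = res.assign(padj=adjust_bh(res["p"]), species_a=a, species_b=b)
            between_rows.append(res.reset_index())
    de_between = pd.concat(between_rows, ignore_index=True).rename(
        columns={"gene_id": "gene"}
    )[["gene", "species_a", "species_b", "log2fc", "p", "padj"]]

    within_rows = []
    for sp in species:
        for pl in plants:
            if pl == COMMON_HOST:
                continue
            res = nb_wald_test(
                filtered, factors, dispersions, ((sp, COMMON_HOST), (sp, pl))
            )
            res = res.assign(padj=adjust_bh(res["p"]), species=sp, plant=pl)
            within_rows.append(res.reset_index())
    de_within = pd.concat(within_rows, ignore_index=True).rename(
        columns={"gene_id": "gene"}
    )[["gene", "species", "plant", "log2fc", "p", "padj"]]

    meta = {
        "n_genes_input": counts.n_genes,
        "n_genes_retained": filtered.n_genes,
        "thresholds": th,
    }
    return de_between, de_within, rld, factors, meta


def grouping_from_config(cfg: dict) -> PerformanceGrouping:
    g = cfg.get("grouping")
    if g is None:
        return PerformanceGrouping.study_default()
    return PerformanceGrouping(high=frozenset(g["high"]), low=frozenset(g["low"]))


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(cfg: dict, out_dir: str | Path | None = None) -> Path:
    """Run the configured stages, writing per-stage outputs under out_dir."""
    out = Path(out_dir or cfg.get("out_dir", "detoxshift_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", list(STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValidationError(f"unknown stage(s) {unknown}; choose from {STAGES}")
    inputs = dict(cfg.get("inputs", {}))
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    run_log: dict = {
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "thresholds": thresholds,
    }

    state: dict = {}

    def _fail(stage: str, err: Exception):
        raise ValidationError(f"stage {stage!r} failed: {err}") from err

    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("=== stage %s ===", stage)
        try:
            if stage == "simulate":
                sim_cfg = SimulationConfig(**cfg.get("simulate", {}))
                design = default_design()
                counts, catalog, truth = simulate_counts(
                    design, sim_cfg, seed=stage_seed(seed, "simulate")
                )
                survival = simulate_survival(seed=stage_seed(seed, "simulate"))
                io.write_count_matrix(counts, out / "counts.tsv")
                io.write_design(design, out / "design.csv")
                io.write_gene_catalog(catalog, out / "catalog.tsv")
                io.write_survival(survival, out / "survival.csv")
                (out / "truth.json").write_text(
                    json.dumps(truth.to_jsonable(), indent=1, sort_keys=True)
                )
                state.update(
                    counts=counts, catalog=catalog, truth=truth, survival=survival
                )
            elif stage == "survey":
                hosts = state.get("hosts")
                if hosts is None:
                    if "hosts" not in inputs:
                        _fail(stage, ValidationError("no host matrix input configured"))
                    hosts = io.read_host_matrix(
                        inputs["hosts"], level=cfg.get("survey", {}).get("level", "order")
                    )
                    state["hosts"] = hosts
                scfg = cfg.get("survey", {})
                dend = survey_cluster(hosts, linkage=scfg.get("linkage", "complete"))
                k = int(scfg.get("cut", 4))
                clusters = cut_into_k(dend, min(k, len(hosts.groups)))
                shared = shared_taxa(hosts, min_fraction=scfg.get("min_fraction", 0.5))
                rows = [
                    {"group": g, "cluster": ci}
                    for ci, cl in enumerate(clusters, 1)
                    for g in sorted(cl)
                ]
                pd.DataFrame(rows).to_csv(out / "survey_clusters.tsv", sep="\t", index=False)
                (out / "survey_dendrogram.nwk").write_text(dend.to_newick() + "\n")
                (out / "survey_shared_taxa.json").write_text(
                    json.dumps({"min_fraction": scfg.get("min_fraction", 0.5),
                                "shared_taxa": shared}, indent=1)
                )
                (out / "survey_distances.tsv").write_text(
                    binary_euclidean_distance(hosts).to_csv(sep="\t")
                )
            elif stage == "ancestral":
                if "tree" not in inputs or "hosts" not in inputs:
                    _fail(stage, ValidationError("ancestral stage needs tree and hosts inputs"))
                tree = io.read_newick(inputs["tree"])
                hosts = io.read_host_matrix(
                    inputs["hosts"], level=cfg.get("survey", {}).get("level", "order")
                )
                estimates = ancestral_host_report(tree, hosts)
                report_table(estimates).to_csv(
                    out / "ancestral.tsv", sep="\t", index=False, float_format="%.6g"
                )
                sidecar = {
                    e.character: {
                        "rate": e.rate,
                        "root_p_present": e.root_p_present,
                        "node_marginals": {
                            n: list(map(float, v))
                            for n, v in e.node_marginals.iterrows()
                        },
                    }
                    for e in estimates
                }
                (out / "ancestral_nodes.json").write_text(
                    json.dumps(sidecar, indent=1, sort_keys=True)
                )
            elif stage == "de":
                counts = state.get("counts")
                if counts is None:
                    if "counts" not in inputs or "design" not in inputs:
                        _fail(stage, ValidationError("de stage needs counts and design inputs"))
                    counts = io.read_count_matrix(inputs["counts"], inputs["design"])
                de_between, de_within, rld, factors, meta = run_de_stage(
                    counts, thresholds
                )
                de_between.to_csv(out / "de_between.tsv", sep="\t", index=False,
                                  float_format="%.6g")
                de_within.to_csv(out / "de_within.tsv", sep="\t", index=False,
                                 float_format="%.6g")
                io.write_expression_matrix(rld, out / "rld.tsv")
                factors.to_csv(out / "size_factors.tsv", sep="\t",
                               float_format="%.10g")
                run_log["de"] = meta
                state.update(
                    counts=counts, de_between=de_between, de_within=de_within, rld=rld
                )
            elif stage == "classify":
                catalog = state.get("catalog")
                if catalog is None:
                    if "catalog" not in inputs:
                        _fail(stage, ValidationError("classify stage needs a catalog input"))
                    catalog = io.read_gene_catalog(inputs["catalog"])
                if "de_between" not in state:
                    _fail(stage, ValidationError("classify stage needs the de stage first"))
                report = classify_detox_genes(
                    state["de_between"], state["de_within"], catalog
                )
                (out / "classification.json").write_text(
                    json.dumps(report.to_jsonable(), indent=1, sort_keys=True)
                )
                state["classification"] = report
            elif stage == "clusternull":
                if "rld" not in state:
                    _fail(stage, ValidationError("clusternull stage needs the de stage first"))
                ncfg = cfg.get("clusternull", {})
                grouping = grouping_from_config(cfg)
                rld = state["rld"]
                design = state["counts"].design
                pool_kind = ncfg.get("pool", "background")
                catalog = state.get("catalog")
                if pool_kind == "background" and catalog is not None:
                    pool = rld.values.loc[~rld.values.index.isin(catalog.entries)]
                else:
                    pool = rld.values
                from .types import ExpressionMatrix

                result = random_subset_null(
                    ExpressionMatrix(pool),
                    design,
                    grouping,
                    subset_size=int(ncfg.get("subset_size", 266)),
                    n_trials=int(ncfg.get("n_trials", 500)),
                    seed=stage_seed(seed, "clusternull"),
                )
                payload = result.to_jsonable()
                payload["pool"] = pool_kind
                # headline clustering: the full catalog
                if catalog is not None:
                    cat_expr = ExpressionMatrix(
                        rld.values.loc[rld.values.index.isin(catalog.entries)]
                    )
                    from .nulltest import bipartition_success

                    dend = profile_dendrogram(cat_expr, design)
                    payload["catalog_bipartition_success"] = bool(
                        bipartition_success(dend, grouping)
                    )
                pca_scores, fractions = pca_correlation(rld, design)
                payload["pca_explained_variance"] = [
                    float(f) for f in fractions[:5]
                ]
                vp = variance_partition(rld, design).mean(axis=0)
                payload["variance_fractions"] = {
                    k: float(v) for k, v in vp.items()
                }
                (out / "clusternull.json").write_text(
                    json.dumps(payload, indent=1, sort_keys=True)
                )
                state["nullresult"] = result
            elif stage == "performance":
                survival = state.get("survival")
                if survival is None:
                    if "survival" not in inputs:
                        _fail(stage, ValidationError("performance stage needs a survival input"))
                    survival = io.read_survival(inputs["survival"])
                rep = performance_report(survival)
                anova_tab = rep["anova"].table
                payload = {
                    "anova": {
                        eff: {
                            "SS": float(anova_tab.loc[eff, "SS"]),
                            "df": int(anova_tab.loc[eff, "df"]),
                            "F": None
                            if pd.isna(anova_tab.loc[eff, "F"])
                            else float(anova_tab.loc[eff, "F"]),
                            "p": None
                            if pd.isna(anova_tab.loc[eff, "p"])
                            else float(anova_tab.loc[eff, "p"]),
                        }
                        for eff in anova_tab.index
                    },
                    "letters": {
                        plant: res.letters for plant, res in rep["pairwise"].items()
                    },
                }
                (out / "performance.json").write_text(
                    json.dumps(payload, indent=1, sort_keys=True)
                )
        except ValidationError:
            raise
        except Exception as err:  # pragma: no cover - defensive stage labelling
            _fail(stage, err)

    (out / "run_log.json").write_text(json.dumps(run_log, indent=1, sort_keys=True))
    return out
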