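"""End-to-end orchestration: families -> profiles -> surveys -> enrichment ->
similarity -> prediction -> associations, with a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import core_io, enrichment, families, pathways, prediction, profiles, similarity

logger = logging.getLogger("phyloprof")

__all__ = ["RunConfig", "run_all", "annotated_object_ids", "object_pathway_sets"]


@dataclass
class RunConfig:
    """One config for the whole analysis; defaults follow the reference
    protocol (30% identity, 10,000 draws, 100,000 pairs, 50 trees,
    100 class / 20 map shuffle repeats)."""

    species_path: str
    annotation_path: str
    homology_path: str
    expression_path: str | None = None
    ppi_path: str | None = None
    out_dir: str = "phyloprof_out"
    min_identity: float = 30.0
    high_confidence_only: bool = True
    n_draws: int = 10_000
    n_pairs: int = 100_000
    n_trees: int = 50
    class_shuffles: int = 100
    map_shuffles: int = 20
    coexpr_n_genes: int = 500
    sample_keep_prob: float = 0.10
    secondary_classes: tuple[str, ...] = tuple(sorted(pathways.DEFAULT_SECONDARY_CLASSES))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        if "secondary_classes" in raw:
            raw["secondary_classes"] = tuple(raw["secondary_classes"])
        return cls(**raw)


def annotated_object_ids(
    genes: Sequence[core_io.GeneRecord], partition: families.GenePartition
) -> list[str]:
    """Objects with >= 1 member gene carrying a pathway annotation — the
    universe used for enrichment, pair sampling and prediction."""
    out = set()
    for g in genes:
        if g.pathway_maps:
            out.add(partition.assignment[g.gene_id])
    return sorted(out)


def object_pathway_sets(
    genes: Sequence[core_io.GeneRecord],
    partition: families.GenePartition,
    definitions: pathways.PathwayDefinitions,
    level: str = "map",
) -> dict[str, set[str]]:
    """object id -> union of member genes' pathway labels at one level."""
    out: dict[str, set[str]] = {}
    for g in genes:
        maps = definitions.included_maps_of(g)
        if not maps:
            continue
        oid = partition.assignment[g.gene_id]
        bucket = out.setdefault(oid, set())
        if level == "map":
            bucket.update(maps)
        else:
            bucket.update(definitions.class_of(m) for m in maps)
    return out


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the manifest."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0])
        for name, s in zip(
            ["enrich_class", "enrich_map", "pairsim", "predict_class", "predict_map",
             "coexpr", "ppi", "expr_subsample"],
            rng.spawn(8),
        )
    }
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stage_seeds": stage_seeds,
        "stages": {},
        "skipped": [],
    }

    def record(stage: str, outputs: Mapping[str, Path], n_rows: Mapping[str, int]) -> None:
        manifest["stages"][stage] = {
            "outputs": {
                k: {"path": str(p), "rows": n_rows.get(k), "sha256": _checksum(p)}
                for k, p in outputs.items()
            },
            "wall_s": round(time.time() - t0, 3),
        }
        logger.info("stage %s done: %s", stage, {k: n_rows.get(k) for k in outputs})

    # --- load inputs --------------------------------------------------------
    species = core_io.read_species_table(config.species_path)
    genes, hierarchy = core_io.read_annotation_table(config.annotation_path, species)
    edges = core_io.read_homology_table(config.homology_path)
    definitions = pathways.PathwayDefinitions(
        map_to_class=hierarchy,
        secondary_classes=frozenset(config.secondary_classes),
    )

    # --- families -----------------------------------------------------------
    partition = families.build_families(
        edges, genes, config.min_identity, config.high_confidence_only
    )
    fam_df = pd.DataFrame(
        {
            "gene_id": sorted(partition.assignment),
            "object_id": [partition.assignment[g] for g in sorted(partition.assignment)],
            "singleton": [
                partition.object_of(g).singleton for g in sorted(partition.assignment)
            ],
        }
    )
    core_io.write_results(fam_df, out / "families.tsv")
    record("families", {"families": out / "families.tsv"}, {"families": len(fam_df)})

    # --- profiles -----------------------------------------------------------
    profile_set = profiles.build_profile_matrix(partition, species)
    profile_set.to_frame().reset_index().pipe(
        core_io.write_results, out / "profiles.tsv"
    )
    _, newick = profiles.cluster_species(profile_set)
    (out / "species_tree.nwk").write_text(newick + "\n")
    groups, _hist = profiles.group_identical_profiles(profile_set)
    record(
        "profiles",
        {"profiles": out / "profiles.tsv", "species_tree": out / "species_tree.nwk"},
        {"profiles": len(profile_set.object_ids), "species_tree": 1},
    )

    # --- surveys ------------------------------------------------------------
    core_io.write_results(definitions.to_frame(), out / "pathways.tsv")
    presence, _counts = pathways.pathway_presence_matrix(genes, definitions, species)
    presence.rename_axis("pathway").reset_index().pipe(
        core_io.write_results, out / "pathway_presence.tsv"
    )
    core_io.write_results(
        pathways.pathway_gene_counts(genes, definitions), out / "pathway_gene_counts.tsv"
    )
    core_io.write_results(
        pathways.species_object_tally(partition, genes), out / "species_tally.tsv"
    )
    record(
        "survey",
        {
            "pathways": out / "pathways.tsv",
            "presence": out / "pathway_presence.tsv",
            "gene_counts": out / "pathway_gene_counts.tsv",
            "species_tally": out / "species_tally.tsv",
        },
        {"pathways": len(definitions.maps), "presence": len(presence)},
    )

    # --- enrichment (profiles restricted to annotated objects) -------------
    annotated = annotated_object_ids(genes, partition)
    annotated_profiles = profile_set.subset(annotated)
    for level in ("class", "map"):
        memberships = pathways.build_memberships(genes, partition, definitions, level)
        scan = enrichment.enrichment_scan(
            memberships,
            annotated_profiles,
            n_draws=config.n_draws,
            seed=stage_seeds[f"enrich_{level}"],
        )
        core_io.write_results(scan, out / f"enrichment_{level}.tsv", sort_by="p_adjusted")
        record(
            f"enrich_{level}",
            {"scan": out / f"enrichment_{level}.tsv"},
            {"scan": len(scan)},
        )

    # --- pairwise similarity ------------------------------------------------
    pw_sets = object_pathway_sets(genes, partition, definitions, level="map")
    pairs = similarity.sample_pairs(
        annotated_profiles, pw_sets, n_pairs=config.n_pairs, seed=stage_seeds["pairsim"]
    )
    core_io.write_results(pairs, out / "pairs.tsv", sort_by="g1")
    fit = similarity.fit_logistic(pairs["d_pp"], pairs["a_pw"])
    (out / "fit.json").write_text(
        json.dumps(
            {"a": fit.a, "b": fit.b, "converged": fit.converged, "rss": fit.rss, "n": fit.n},
            indent=2,
        )
        + "\n"
    )
    record(
        "pairsim",
        {"pairs": out / "pairs.tsv", "fit": out / "fit.json"},
        {"pairs": len(pairs), "fit": 1},
    )

    # --- prediction ---------------------------------------------------------
    hier = prediction.LabelHierarchy({m: definitions.class_of(m) for m in definitions.maps})
    comparison: dict[str, dict] = {}
    metrics_rows = []
    for level, n_runs in (("class", config.class_shuffles), ("map", config.map_shuffles)):
        res = prediction.compare_true_vs_random(
            annotated_profiles.matrix,
            annotated_profiles.object_ids,
            pw_sets,
            hier,
            level=level,
            n_trees=config.n_trees,
            n_runs=n_runs,
            seed=stage_seeds[f"predict_{level}"],
        )
        comparison[level] = {
            "mean_true_aucprc": res.mean_true,
            "mean_random_aucprc": res.mean_random,
            "wilcoxon_p": res.wilcoxon_p,
            "n_runs": res.n_runs,
        }
        for label, value in res.true_by_label.items():
            metrics_rows.append({"label": label, "level": level, "aucprc": value})
    core_io.write_results(pd.DataFrame(metrics_rows), out / "prediction_metrics.tsv")
    (out / "prediction_comparison.json").write_text(json.dumps(comparison, indent=2) + "\n")
    record(
        "predict",
        {
            "metrics": out / "prediction_metrics.tsv",
            "comparison": out / "prediction_comparison.json",
        },
        {"metrics": len(metrics_rows), "comparison": len(comparison)},
    )

    # --- associations (optional inputs) -------------------------------------
    gene_to_object = dict(partition.assignment)
    if config.expression_path:
        expr = core_io.read_expression_matrix(config.expression_path)
        expr = assoc_mod.preprocess_expression(
            expr, config.sample_keep_prob, seed=stage_seeds["expr_subsample"]
        )
        coex = assoc_mod.coexpression_vs_profile(
            expr,
            gene_to_object,
            profile_set,
            n_genes=config.coexpr_n_genes,
            seed=stage_seeds["coexpr"],
        )
        core_io.write_results(coex.records, out / "coexpr.tsv", sort_by="gene1")
        (out / "coexpr_summary.json").write_text(
            json.dumps(
                {
                    "pearson_r": coex.pearson_r,
                    "pearson_p": coex.pearson_p,
                    "linear_slope": coex.linear_slope,
                    "n_pairs": len(coex.records),
                    "n_selected": coex.n_selected,
                },
                indent=2,
            )
            + "\n"
        )
        record(
            "coexpr",
            {"records": out / "coexpr.tsv", "summary": out / "coexpr_summary.json"},
            {"records": len(coex.records), "summary": 1},
        )
    else:
        manifest["skipped"].append("coexpr")

    if config.ppi_path:
        ppi = core_io.read_ppi_table(config.ppi_path)
        comp = assoc_mod.ppi_profile_comparison(
            ppi, gene_to_object, profile_set, seed=stage_seeds["ppi"]
        )
        (out / "ppi_comparison.json").write_text(
            json.dumps(
                {
                    "median_interacting": comp.median_interacting,
                    "median_non_interacting": comp.median_non_interacting,
                    "wilcoxon_p": comp.wilcoxon_p,
                    "n_interacting": comp.n_interacting,
                    "n_non_interacting": comp.n_non_interacting,
                },
                indent=2,
            )
            + "\n"
        )
        record("ppi", {"comparison": out / "ppi_comparison.json"}, {"comparison": 1})
    else:
        manifest["skipped"].append("ppi")

    manifest["wall_s"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
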