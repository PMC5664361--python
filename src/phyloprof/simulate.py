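"""Synthetic input bundles with controllable planted structure.

Generates every table the pipeline consumes — species, annotation, homology,
expression, PPI — from a single seeded configuration, together with a
``truth`` record of all planted quantities. Profiles are generated directly
(not by evolving gain/loss on a phylogeny): the downstream analyses only ever
use the profile matrix.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["SimConfig", "SimBundle", "simulate_dataset", "fixture_small", "FIXTURE_CONFIG"]


@dataclass
class SimConfig:
    """Knobs of the generative model; all randomness flows from ``seed``."""

    n_species: int = 10
    kegg_fraction: float = 1.0
    n_families: int = 100
    n_singletons: int = 20
    poisson_lambda: float = 0.5  # member genes per present species = 1 + Poisson(lambda)
    n_classes: int = 3
    maps_per_class: int = 4
    n_secondary_classes: int = 1
    pathway_coherence: float = 0.5  # rho: fraction of maps with a shared archetype
    profile_flip_noise: float = 0.05  # eps: per-bit flip prob for coherent families
    presence_prob: float = 0.5  # pi: Bernoulli presence per species
    extra_map_prob: float = 0.0  # chance of each of up to 2 extra map labels
    within_family_identity: tuple[float, float] = (60.0, 95.0)
    cross_family_identity: tuple[float, float] = (5.0, 25.0)
    decoy_edge_rate: float = 0.2  # decoy cross-family edges per family
    min_identity_threshold: float = 30.0  # used only for feasibility warnings
    n_samples: int = 60
    block_correlation: float = 0.8
    ppi_beta: float = 6.0
    n_ppi_candidates: int = 1000
    annotate_singletons: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        for name in ("kegg_fraction", "pathway_coherence", "presence_prob", "extra_map_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.profile_flip_noise <= 0.5:
            raise ValueError("profile_flip_noise must be in [0, 0.5]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        if "within_family_identity" in raw:
            raw["within_family_identity"] = tuple(raw["within_family_identity"])
        if "cross_family_identity" in raw:
            raw["cross_family_identity"] = tuple(raw["cross_family_identity"])
        return cls(**raw)


@dataclass
class SimBundle:
    """In-memory simulated dataset plus the planted ground truth."""

    species: pd.DataFrame
    annotation: pd.DataFrame
    homology: pd.DataFrame
    expression: pd.DataFrame  # genes x samples, index = gene_id
    ppi: pd.DataFrame
    truth: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "species": out / "species.tsv",
            "annotation": out / "annotation.tsv",
            "homology": out / "homology.tsv",
            "expression": out / "expression.tsv",
            "ppi": out / "ppi.tsv",
            "truth": out / "truth.json",
        }
        self.species.to_csv(paths["species"], sep="\t", index=False)
        self.annotation.to_csv(paths["annotation"], sep="\t", index=False)
        self.homology.to_csv(paths["homology"], sep="\t", index=False)
        self.expression.rename_axis("gene_id").to_csv(paths["expression"], sep="\t")
        self.ppi.to_csv(paths["ppi"], sep="\t", index=False)
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True) + "\n")
        return paths


def _nonzero_bernoulli(rng: np.random.Generator, p: float, n: int) -> np.ndarray:
    while True:
        bits = (rng.random(n) < p).astype(np.uint8)
        if bits.any():
            return bits


def simulate_dataset(config: SimConfig) -> SimBundle:
    """Generate one complete input bundle under the planted model.

    Model: per-map archetype profiles; a fraction rho of maps is "coherent" —
    their member families realize the archetype with per-bit flip noise eps,
    all other families draw independent Bernoulli(pi) profiles. Singletons
    occupy one species. Within-family homology edges carry identities from
    the within range; decoy cross-family edges from the cross range (below
    the clustering threshold by default, so the planted partition is exactly
    recoverable). Expression co-varies within identical-profile blocks; PPI
    pairs interact with logistic probability in d_PP.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if cfg.within_family_identity[0] < cfg.min_identity_threshold:
        warnings.warn(
            "within-family identity range extends below the clustering "
            "threshold; planted families may not be recoverable"
        )

    # 1. species ------------------------------------------------------------
    species_ids = [f"SP{i + 1:02d}" for i in range(cfg.n_species)]
    n_kegg = max(2, round(cfg.kegg_fraction * cfg.n_species))
    kegg_flags = [i < n_kegg for i in range(cfg.n_species)]
    species_df = pd.DataFrame(
        {"species_id": species_ids, "kegg_flag": [int(f) for f in kegg_flags]}
    )

    # 2. pathway hierarchy and archetypes -----------------------------------
    classes = [f"C{c + 1}" for c in range(cfg.n_classes)]
    secondary_classes = classes[cfg.n_classes - cfg.n_secondary_classes :] if cfg.n_secondary_classes else []
    maps: list[str] = []
    map_to_class: dict[str, str] = {}
    for ci, cls in enumerate(classes):
        for mi in range(cfg.maps_per_class):
            mid = f"M{ci * cfg.maps_per_class + mi + 1:03d}"
            maps.append(mid)
            map_to_class[mid] = cls
    archetypes = {m: _nonzero_bernoulli(rng, cfg.presence_prob, cfg.n_species) for m in maps}
    n_coherent = int(round(cfg.pathway_coherence * len(maps)))
    coherent = sorted(rng.choice(maps, size=n_coherent, replace=False).tolist())
    coherent_set = set(coherent)

    # 3. objects: families then singletons ----------------------------------
    object_ids = [f"F{i + 1:04d}" for i in range(cfg.n_families)] + [
        f"S{i + 1:04d}" for i in range(cfg.n_singletons)
    ]
    obj_maps: dict[str, list[str]] = {}
    obj_profile: dict[str, np.ndarray] = {}
    for oid in object_ids:
        primary = maps[int(rng.integers(0, len(maps)))]
        assigned = [primary]
        for _ in range(2):
            if rng.random() < cfg.extra_map_prob:
                extra = maps[int(rng.integers(0, len(maps)))]
                if extra not in assigned:
                    assigned.append(extra)
        singleton = oid.startswith("S")
        if singleton:
            bits = np.zeros(cfg.n_species, dtype=np.uint8)
            bits[int(rng.integers(0, cfg.n_species))] = 1
            if not cfg.annotate_singletons:
                assigned = []
        elif primary in coherent_set:
            bits = archetypes[primary].copy()
            flips = rng.random(cfg.n_species) < cfg.profile_flip_noise
            bits = np.where(flips, 1 - bits, bits).astype(np.uint8)
            if not bits.any():
                bits[int(rng.integers(0, cfg.n_species))] = 1
        else:
            bits = _nonzero_bernoulli(rng, cfg.presence_prob, cfg.n_species)
        obj_maps[oid] = assigned
        obj_profile[oid] = bits

    # 4. genes and annotation ------------------------------------------------
    gene_rows: list[dict] = []
    gene_to_object: dict[str, str] = {}
    members: dict[str, list[str]] = {oid: [] for oid in object_ids}
    for oid in object_ids:
        present = [s for s, b in zip(species_ids, obj_profile[oid]) if b]
        ec_pool_map = obj_maps[oid][0] if obj_maps[oid] else "M000"
        ec = f"1.1.{int(ec_pool_map[1:])}.{1 + int(rng.integers(0, 2))}"
        counts = (
            [1] if oid.startswith("S") else (1 + rng.poisson(cfg.poisson_lambda, len(present))).tolist()
        )
        if oid.startswith("S"):
            present = [present[0]]
        for sp, k in zip(present, counts):
            for copy in range(int(k)):
                gid = f"{oid}_{sp}_{copy + 1}"
                gene_to_object[gid] = oid
                members[oid].append(gid)
                gene_rows.append(
                    {
                        "gene_id": gid,
                        "species": sp,
                        "ec": ec,
                        "maps": ";".join(obj_maps[oid]),
                        "classes": ";".join(map_to_class[m] for m in obj_maps[oid]),
                    }
                )
    annotation_df = pd.DataFrame(
        gene_rows, columns=["gene_id", "species", "ec", "maps", "classes"]
    )

    # 5. homology edges ------------------------------------------------------
    lo_w, hi_w = cfg.within_family_identity
    lo_c, hi_c = cfg.cross_family_identity
    species_of = dict(zip(annotation_df["gene_id"], annotation_df["species"]))
    edge_rows: list[dict] = []
    for oid in object_ids:
        mem = members[oid]
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                a, b = sorted((mem[i], mem[j]))
                edge_rows.append(
                    {
                        "gene_a": a,
                        "gene_b": b,
                        "pct_identity": round(float(rng.uniform(lo_w, hi_w)), 2),
                        "confidence": "high",
                        "relation": "paralog" if species_of[a] == species_of[b] else "ortholog",
                    }
                )
    all_genes = list(gene_to_object)
    n_decoys = int(round(cfg.decoy_edge_rate * cfg.n_families))
    made = 0
    while made < n_decoys and len(all_genes) > 1:
        g1, g2 = rng.choice(all_genes, size=2, replace=False)
        if gene_to_object[g1] == gene_to_object[g2]:
            continue
        a, b = sorted((g1, g2))
        edge_rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "pct_identity": round(float(rng.uniform(lo_c, hi_c)), 2),
                "confidence": "high",
                "relation": "ortholog",
            }
        )
        made += 1
    homology_df = pd.DataFrame(
        edge_rows, columns=["gene_a", "gene_b", "pct_identity", "confidence", "relation"]
    )

    # 6. expression for the reference species (first species) ---------------
    ref = species_ids[0]
    ref_genes = [g for g in all_genes if species_of[g] == ref]
    sample_ids = [f"SMP{j + 1:03d}" for j in range(cfg.n_samples)]
    profile_key = {oid: "".join(map(str, obj_profile[oid])) for oid in object_ids}
    factors: dict[str, np.ndarray] = {}
    r = cfg.block_correlation
    values = np.empty((len(ref_genes), cfg.n_samples))
    for i, g in enumerate(ref_genes):
        key = profile_key[gene_to_object[g]]
        if key not in factors:
            factors[key] = rng.normal(size=cfg.n_samples)
        values[i] = np.sqrt(r) * factors[key] + np.sqrt(1 - r) * rng.normal(size=cfg.n_samples)
    expression_df = pd.DataFrame(np.exp(values), index=ref_genes, columns=sample_ids)

    # 7. PPI pairs among objects present in the reference species -----------
    ref_objects = sorted({gene_to_object[g] for g in ref_genes})
    ppi_rows: list[dict] = []
    if len(ref_objects) >= 2:
        first_ref_gene = {}
        for g in ref_genes:
            first_ref_gene.setdefault(gene_to_object[g], g)
        n_obj = len(ref_objects)
        n_candidates = min(cfg.n_ppi_candidates, n_obj * (n_obj - 1) // 2)
        seen: set[tuple[int, int]] = set()
        while len(seen) < n_candidates:
            i = int(rng.integers(0, n_obj))
            j = int(rng.integers(0, n_obj - 1))
            if j >= i:
                j += 1
            seen.add((min(i, j), max(i, j)))
        for i, j in sorted(seen):
            p1, p2 = obj_profile[ref_objects[i]], obj_profile[ref_objects[j]]
            d_pp = np.sum(p1 & p2) / np.sum(p1 | p2)
            prob = 1.0 / (1.0 + np.exp(-cfg.ppi_beta * (d_pp - 0.5)))
            if rng.random() < prob:
                a, b = sorted((first_ref_gene[ref_objects[i]], first_ref_gene[ref_objects[j]]))
                ppi_rows.append({"protein_a": a, "protein_b": b, "evidence": "experimental"})
    ppi_df = pd.DataFrame(ppi_rows, columns=["protein_a", "protein_b", "evidence"])

    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "gene_to_object": gene_to_object,
        "object_profiles": profile_key,
        "object_maps": obj_maps,
        "map_to_class": map_to_class,
        "secondary_classes": secondary_classes,
        "coherent_maps": coherent,
        "archetypes": {m: "".join(map(str, a)) for m, a in archetypes.items()},
        "reference_species": ref,
    }
    return SimBundle(
        species=species_df,
        annotation=annotation_df,
        homology=homology_df,
        expression=expression_df,
        ppi=ppi_df,
        truth=truth,
    )


#: deterministic micro-dataset: 6 species, 12 families, 4 singletons, 3x2 maps
FIXTURE_CONFIG = SimConfig(
    n_species=6,
    kegg_fraction=1.0,
    n_families=12,
    n_singletons=4,
    poisson_lambda=0.4,
    n_classes=3,
    maps_per_class=2,
    n_secondary_classes=1,
    pathway_coherence=0.5,
    profile_flip_noise=0.0,
    presence_prob=0.6,
    extra_map_prob=0.0,
    within_family_identity=(45.0, 90.0),
    cross_family_identity=(5.0, 25.0),
    decoy_edge_rate=0.25,
    n_samples=20,
    block_correlation=0.7,
    ppi_beta=6.0,
    n_ppi_candidates=40,
    seed=20170402,
)


def fixture_small() -> SimBundle:
    """The deterministic, hand-checkable micro-dataset used across the tests.

    A companion file of expected values (families, profiles, per-pathway
    F_pw / F_all / E) derived with brute-force oracles ships as package data
    ``data/fixture_expected.json``.
    """
    return simulate_dataset(FIXTURE_CONFIG)
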