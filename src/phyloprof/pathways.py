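"""Two-level pathway hierarchy, primary/secondary metabolism classification,
pathway membership resolution and presence/count surveys."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GeneRecord, SpeciesSet, ValidationError
from .families import GenePartition

# KEGG class names treated as secondary metabolism by default
DEFAULT_SECONDARY_CLASSES = frozenset(
    {
        "metabolism of terpenoids and polyketides",
        "biosynthesis of other secondary metabolites",
    }
)

__all__ = [
    "PathwayDefinitions",
    "DEFAULT_SECONDARY_CLASSES",
    "classify_gene_metabolism",
    "pathway_presence_matrix",
    "ec_presence_by_map",
    "pathway_gene_counts",
    "build_memberships",
    "species_object_tally",
]


@dataclass
class PathwayDefinitions:
    """map -> class hierarchy plus the secondary-class configuration."""

    map_to_class: dict[str, str]
    secondary_classes: frozenset[str] = DEFAULT_SECONDARY_CLASSES
    excluded_classes: frozenset[str] = frozenset({"Overview"})
    excluded_maps: frozenset[str] = frozenset()

    @property
    def maps(self) -> list[str]:
        return sorted(
            m
            for m, c in self.map_to_class.items()
            if m not in self.excluded_maps and c not in self.excluded_classes
        )

    @property
    def classes(self) -> list[str]:
        return sorted({self.map_to_class[m] for m in self.maps})

    def is_secondary_map(self, map_id: str) -> bool:
        return self.map_to_class[map_id] in self.secondary_classes

    def class_of(self, map_id: str) -> str:
        try:
            return self.map_to_class[map_id]
        except KeyError:
            raise ValidationError(f"unknown pathway map: {map_id!r}") from None

    def included_maps_of(self, gene: GeneRecord) -> frozenset[str]:
        return frozenset(m for m in gene.pathway_maps if m in set(self.maps))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "map_id": m,
                "class_id": self.map_to_class[m],
                "secondary": self.is_secondary_map(m),
            }
            for m in self.maps
        ]
        return pd.DataFrame(rows, columns=["map_id", "class_id", "secondary"])


def classify_gene_metabolism(gene: GeneRecord, definitions: PathwayDefinitions) -> str:
    """Classify a gene as "primary", "secondary" or "none".

    A gene is secondary only if every annotated map is a secondary-metabolism
    map; one primary map suffices for "primary"; no maps -> "none".
    """
    maps = definitions.included_maps_of(gene)
    for m in gene.pathway_maps:
        definitions.class_of(m)  # raises on unknown ids, even excluded-class ones
    if not maps:
        return "none"
    if all(definitions.is_secondary_map(m) for m in maps):
        return "secondary"
    return "primary"


def pathway_presence_matrix(
    genes: Sequence[GeneRecord],
    definitions: PathwayDefinitions,
    species: SpeciesSet,
    level: str = "map",
) -> tuple[pd.DataFrame, pd.Series]:
    """Pathway x species presence matrix and per-pathway species counts.

    Cell (p, s) = 1 iff at least one gene of species s is annotated to p.
    """
    if level == "map":
        pathways = definitions.maps
        of_gene = lambda g: definitions.included_maps_of(g)
    elif level == "class":
        pathways = definitions.classes
        of_gene = lambda g: {definitions.class_of(m) for m in definitions.included_maps_of(g)}
    else:
        raise ValueError("level must be 'map' or 'class'")
    matrix = pd.DataFrame(
        0, index=pathways, columns=list(species.species_ids), dtype=int
    )
    for g in genes:
        for p in of_gene(g):
            matrix.loc[p, g.species_id] = 1
    counts = matrix.sum(axis=1)
    counts.name = "n_species"
    return matrix, counts


def ec_presence_by_map(
    genes: Sequence[GeneRecord],
    definitions: PathwayDefinitions,
    species: SpeciesSet,
) -> dict[str, pd.DataFrame]:
    """Per-map EC x species presence matrices (presence = identical EC seen)."""
    per_map: dict[str, pd.DataFrame] = {}
    cells: dict[str, set[tuple[str, str]]] = {}
    for g in genes:
        for m in definitions.included_maps_of(g):
            bucket = cells.setdefault(m, set())
            for ec in g.ec_numbers:
                bucket.add((ec, g.species_id))
    for m, pairs in cells.items():
        ecs = sorted({ec for ec, _ in pairs})
        df = pd.DataFrame(0, index=ecs, columns=list(species.species_ids), dtype=int)
        for ec, sp in pairs:
            df.loc[ec, sp] = 1
        per_map[m] = df
    return per_map


def pathway_gene_counts(
    genes: Sequence[GeneRecord], definitions: PathwayDefinitions
) -> pd.DataFrame:
    """Per-map gene counts: exclusive-secondary vs inclusive.

    ``exclusive`` counts only genes classified "secondary" (all their maps
    secondary); ``inclusive`` counts every gene annotated to the map.
    """
    rows = []
    for m in definitions.maps:
        members = [g for g in genes if m in g.pathway_maps]
        exclusive = sum(
            1 for g in members if classify_gene_metabolism(g, definitions) == "secondary"
        )
        rows.append(
            {
                "map_id": m,
                "class_id": definitions.class_of(m),
                "secondary": definitions.is_secondary_map(m),
                "exclusive_secondary_count": exclusive,
                "inclusive_count": len(members),
            }
        )
    return pd.DataFrame(rows)


def build_memberships(
    genes: Sequence[GeneRecord],
    partition: GenePartition,
    definitions: PathwayDefinitions,
    level: str = "map",
    secondary_exclusive: bool = True,
) -> dict[str, set[str]]:
    """Resolve pathway -> member gene-object ids.

    A gene object belongs to a pathway iff it contains >= 1 annotated member
    gene. When ``secondary_exclusive`` is set, secondary maps (and secondary
    classes) count only genes classified exclusively secondary, mirroring the
    primary-wins gene classification.
    """
    if level not in {"map", "class"}:
        raise ValueError("level must be 'map' or 'class'")
    memberships: dict[str, set[str]] = {
        p: set() for p in (definitions.maps if level == "map" else definitions.classes)
    }
    for g in genes:
        maps = definitions.included_maps_of(g)
        if not maps:
            continue
        if g.gene_id not in partition.assignment:
            warnings.warn(f"annotated gene {g.gene_id!r} missing from partition")
            continue
        oid = partition.assignment[g.gene_id]
        is_secondary_gene = classify_gene_metabolism(g, definitions) == "secondary"
        for m in maps:
            secondary_target = definitions.is_secondary_map(m)
            if secondary_exclusive and secondary_target and not is_secondary_gene:
                continue
            key = m if level == "map" else definitions.class_of(m)
            memberships[key].add(oid)
    return memberships


def species_object_tally(
    partition: GenePartition, genes: Sequence[GeneRecord]
) -> pd.DataFrame:
    """Per-species counts of genes in families vs singleton genes.

    The two counts sum to the species' total gene count.
    """
    species_of = {g.gene_id: g.species_id for g in genes}
    rows: dict[str, dict[str, int]] = {}
    for gene_id, oid in partition.assignment.items():
        sp = species_of[gene_id]
        row = rows.setdefault(sp, {"in_family": 0, "singleton": 0})
        if partition.objects[oid].singleton:
            row["singleton"] += 1
        else:
            row["in_family"] += 1
    out = (
        pd.DataFrame.from_dict(rows, orient="index")
        .rename_axis("species_id")
        .sort_index()
        .reset_index()
    )
    out["total"] = out["in_family"] + out["singleton"]
    return out
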