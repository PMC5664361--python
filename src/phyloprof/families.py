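"""Gene-family clustering by connected components of a thresholded homology
network, and partition evaluation against EC-based function labels."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .core_io import GeneRecord, HomologyEdge, ValidationError

__all__ = [
    "GenePartition",
    "GeneObject",
    "build_families",
    "function_label",
    "adjusted_rand_index",
]


@dataclass(frozen=True)
class GeneObject:
    """A gene family or singleton: the unit carrying one phylogenetic profile."""

    object_id: str
    members: frozenset[str]
    species: frozenset[str]
    singleton: bool

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("GeneObject must have at least one member")


@dataclass
class GenePartition:
    """Partition of all genes into gene objects (families + singletons)."""

    assignment: dict[str, str]  # gene_id -> object_id
    objects: dict[str, GeneObject]  # object_id -> GeneObject

    def __len__(self) -> int:
        return len(self.objects)

    @property
    def n_families(self) -> int:
        return sum(1 for o in self.objects.values() if not o.singleton)

    @property
    def n_singletons(self) -> int:
        return sum(1 for o in self.objects.values() if o.singleton)

    def object_of(self, gene_id: str) -> GeneObject:
        return self.objects[self.assignment[gene_id]]

    def as_label_map(self) -> dict[str, str]:
        return dict(self.assignment)


class _DSU:
    """Union-find over a fixed element universe."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_families(
    edges: Iterable[HomologyEdge],
    genes: Sequence[GeneRecord],
    min_identity: float = 30.0,
    require_high_confidence: bool = True,
    confidence_scope: str = "all",
) -> GenePartition:
    """Cluster genes into connected components of the retained homology network.

    An edge is retained iff ``pct_identity >= min_identity`` (inclusive
    boundary) and, when ``require_high_confidence`` is set, its confidence is
    ``high``. ``confidence_scope`` controls whether the confidence filter
    applies to ``"all"`` edges (default) or to ``"orthologs"`` only, in which
    case paralog edges pass regardless of confidence. Orthologs and paralogs
    are otherwise treated identically. Genes with no retained edge become
    singletons.

    Object ids are assigned deterministically (``GO``-prefixed, ordered by
    the lexicographically smallest member gene id), so the result is
    invariant to edge input order.
    """
    if not 0.0 <= min_identity <= 100.0:
        raise ValidationError(f"min_identity {min_identity} outside [0, 100]")
    if confidence_scope not in {"all", "orthologs"}:
        raise ValueError(f"confidence_scope must be 'all' or 'orthologs'")

    gene_index = {g.gene_id: i for i, g in enumerate(genes)}
    if len(gene_index) != len(genes):
        raise ValidationError("duplicate gene ids in annotation records")
    species_of = {g.gene_id: g.species_id for g in genes}

    unknown: set[str] = set()
    dsu = _DSU(len(genes))
    for e in edges:
        for g in e.pair:
            if g not in gene_index:
                unknown.add(g)
        if unknown:
            continue
        if e.pct_identity < min_identity:
            continue
        if require_high_confidence and e.confidence != "high":
            if confidence_scope == "all" or e.relation == "ortholog":
                continue
        dsu.union(gene_index[e.gene_a], gene_index[e.gene_b])
    if unknown:
        raise ValidationError(
            f"homology edges reference unknown gene(s): {sorted(unknown)}"
        )

    components: dict[int, list[str]] = {}
    for g, i in gene_index.items():
        components.setdefault(dsu.find(i), []).append(g)

    member_sets = sorted(
        (sorted(members) for members in components.values()), key=lambda m: m[0]
    )
    width = max(6, len(str(len(member_sets))))
    assignment: dict[str, str] = {}
    objects: dict[str, GeneObject] = {}
    for k, members in enumerate(member_sets, start=1):
        oid = f"GO{k:0{width}d}"
        objects[oid] = GeneObject(
            object_id=oid,
            members=frozenset(members),
            species=frozenset(species_of[g] for g in members),
            singleton=len(members) == 1,
        )
        for g in members:
            assignment[g] = oid
    return GenePartition(assignment=assignment, objects=objects)


def function_label(gene: GeneRecord) -> str:
    """Canonical function label: the sorted, ";"-joined EC set ("none" if empty)."""
    if not gene.ec_numbers:
        return "none"
    return ";".join(sorted(gene.ec_numbers))


def adjusted_rand_index(
    labels_a: Mapping[str, str], labels_b: Mapping[str, str]
) -> float:
    """Hubert-Arabie adjusted Rand index between two labelings of one universe.

    1.0 for identical partitions, ~0 in expectation under independence.
    """
    if set(labels_a) != set(labels_b):
        only_a = sorted(set(labels_a) - set(labels_b))[:5]
        only_b = sorted(set(labels_b) - set(labels_a))[:5]
        raise ValidationError(
            f"label maps cover different gene universes (e.g. {only_a} vs {only_b})"
        )
    keys = sorted(labels_a)
    ca = {l: i for i, l in enumerate(dict.fromkeys(labels_a[k] for k in keys))}
    cb = {l: i for i, l in enumerate(dict.fromkeys(labels_b[k] for k in keys))}
    a = np.array([ca[labels_a[k]] for k in keys])
    b = np.array([cb[labels_b[k]] for k in keys])
    return float(adjusted_rand_score(a, b))
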