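"""Binary phylogenetic profiles per gene object, identical-profile grouping,
and complete-linkage species clustering."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist

from .core_io import SpeciesSet, ValidationError
from .families import GeneObject, GenePartition

__all__ = [
    "ProfileSet",
    "ProfileGroup",
    "build_profile",
    "build_profile_matrix",
    "group_identical_profiles",
    "cluster_species",
]


@dataclass
class ProfileSet:
    """Profiles for an ordered set of gene objects over a fixed species order.

    ``matrix`` is an (objects x species) uint8 0/1 array; row i belongs to
    ``object_ids[i]``.
    """

    object_ids: list[str]
    matrix: np.ndarray
    species: SpeciesSet

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.object_ids), len(self.species)):
            raise ValidationError("profile matrix shape mismatch")

    def row(self, object_id: str) -> np.ndarray:
        idx = self.__dict__.get("_row_index")
        if idx is None:
            idx = {o: i for i, o in enumerate(self.object_ids)}
            self.__dict__["_row_index"] = idx
        return self.matrix[idx[object_id]]

    def subset(self, object_ids: Sequence[str]) -> "ProfileSet":
        wanted = set(object_ids)
        keep = [i for i, o in enumerate(self.object_ids) if o in wanted]
        return ProfileSet(
            [self.object_ids[i] for i in keep], self.matrix[keep], self.species
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.object_ids, columns=list(self.species.species_ids)
        ).rename_axis("object_id")


@dataclass(frozen=True)
class ProfileGroup:
    profile: tuple[int, ...]
    object_ids: tuple[str, ...]

    @property
    def occurrence(self) -> int:
        return len(self.object_ids)


def build_profile(obj: GeneObject, species: SpeciesSet) -> np.ndarray:
    """Presence/absence bit vector: bit s = 1 iff some member gene lives in s.

    Gene multiplicity within a species is ignored. Member species outside the
    SpeciesSet are an error.
    """
    bits = np.zeros(len(species), dtype=np.uint8)
    for sp in obj.species:
        bits[species.index(sp)] = 1
    return bits


def build_profile_matrix(partition: GenePartition, species: SpeciesSet) -> ProfileSet:
    object_ids = sorted(partition.objects)
    matrix = np.zeros((len(object_ids), len(species)), dtype=np.uint8)
    for i, oid in enumerate(object_ids):
        matrix[i] = build_profile(partition.objects[oid], species)
    return ProfileSet(object_ids, matrix, species)


def group_identical_profiles(
    profiles: ProfileSet,
) -> tuple[list[ProfileGroup], list[int]]:
    """Group objects by exact bit-vector equality.

    Returns the groups (ordered by descending occurrence, ties by profile
    bits) and the occurrence histogram sorted descending.
    """
    buckets: dict[tuple[int, ...], list[str]] = {}
    for oid, row in zip(profiles.object_ids, profiles.matrix):
        buckets.setdefault(tuple(int(b) for b in row), []).append(oid)
    groups = [
        ProfileGroup(profile=key, object_ids=tuple(sorted(oids)))
        for key, oids in buckets.items()
    ]
    groups.sort(key=lambda g: (-g.occurrence, g.profile))
    return groups, sorted((g.occurrence for g in groups), reverse=True)


def cluster_species(profiles: ProfileSet) -> tuple[np.ndarray, str]:
    """Complete-linkage / Euclidean hierarchical clustering of species columns.

    Returns the scipy linkage matrix and a Newick string whose branch lengths
    place each leaf at depth equal to the root merge height (tips at height
    0, internal nodes at their merge height).
    """
    n_species = len(profiles.species)
    if n_species < 2:
        raise ValidationError("species clustering needs at least 2 species")
    columns = profiles.matrix.T.astype(float)  # species x objects
    dist = pdist(columns, metric="euclidean")
    linkage = sch.linkage(dist, method="complete")
    newick = _to_newick(linkage, list(profiles.species.species_ids))
    return linkage, newick


def _to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    tree = sch.to_tree(linkage)

    def render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        parts = []
        for child in (node.get_left(), node.get_right()):
            length = node.dist - (0.0 if child.is_leaf() else child.dist)
            parts.append(f"{render(child)}:{length:.6g}")
        return "(" + ",".join(parts) + ")"

    return render(tree) + ";"
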