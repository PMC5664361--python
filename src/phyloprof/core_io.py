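"""Shared data model and tabular I/O.

All interchange files are TSV with a header row; in-cell lists use ";" as
separator. Identifiers are case-sensitive. Readers validate eagerly and
raise :class:`FormatError` (structural problems) or :class:`ValidationError`
(row-level problems, carrying 1-based line numbers of the offending rows).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LIST_SEP = ";"

__all__ = [
    "FormatError",
    "ValidationError",
    "HierarchyError",
    "SpeciesSet",
    "GeneRecord",
    "HomologyEdge",
    "PPITable",
    "read_species_table",
    "read_homology_table",
    "read_annotation_table",
    "read_expression_matrix",
    "read_ppi_table",
    "write_results",
    "read_results",
]


class FormatError(ValueError):
    """A file does not have the expected structure (e.g. missing column)."""


class ValidationError(ValueError):
    """One or more rows violate a value constraint; message lists line numbers."""


class HierarchyError(ValueError):
    """The map -> class assignment is inconsistent (a map under two classes)."""


@dataclass(frozen=True)
class SpeciesSet:
    """Ordered species universe; the order defines profile vector positions."""

    species_ids: tuple[str, ...]
    kegg_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.species_ids) < 2:
            raise ValidationError("SpeciesSet needs at least 2 species")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValidationError("duplicate species ids")
        if len(self.kegg_flags) != len(self.species_ids):
            raise ValidationError("kegg_flags length mismatch")

    def __len__(self) -> int:
        return len(self.species_ids)

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._index

    @property
    def _index(self) -> dict[str, int]:
        # cached lazily on the instance despite frozen dataclass
        idx = self.__dict__.get("_index_cache")
        if idx is None:
            idx = {s: i for i, s in enumerate(self.species_ids)}
            object.__setattr__(self, "_index_cache", idx)
        return idx

    def index(self, species_id: str) -> int:
        try:
            return self._index[species_id]
        except KeyError:
            raise ValidationError(f"unknown species id: {species_id!r}") from None

    @property
    def kegg_species(self) -> tuple[str, ...]:
        return tuple(s for s, f in zip(self.species_ids, self.kegg_flags) if f)


@dataclass(frozen=True)
class GeneRecord:
    """One gene: its species, EC annotations and two-level pathway labels."""

    gene_id: str
    species_id: str
    ec_numbers: frozenset[str] = frozenset()
    pathway_maps: frozenset[str] = frozenset()
    pathway_classes: frozenset[str] = frozenset()


@dataclass(frozen=True)
class HomologyEdge:
    """Undirected pairwise homology assertion; stored with gene_a < gene_b."""

    gene_a: str
    gene_b: str
    pct_identity: float
    confidence: str  # {"high", "low"}
    relation: str  # {"ortholog", "paralog"}

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(f"self-edge on gene {self.gene_a!r}")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValidationError(
                f"pct_identity {self.pct_identity} outside [0, 100]"
            )
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class PPITable:
    """Deduplicated undirected protein/gene interaction pairs."""

    pairs: list[tuple[str, str]]
    evidence: list[str]  # parallel to pairs; {"experimental", "predicted"}

    def experimental_pairs(self) -> list[tuple[str, str]]:
        return [p for p, e in zip(self.pairs, self.evidence) if e == "experimental"]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, expected header with columns {list(required)}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_species_table(path: str | Path) -> SpeciesSet:
    """Read species.tsv (columns: species_id, kegg_flag) preserving file order."""
    df = _read_tsv(path, ["species_id", "kegg_flag"])
    flags = []
    for lineno, raw in zip(df.index + 2, df["kegg_flag"]):
        v = raw.strip().lower()
        if v in {"1", "true", "yes", "y"}:
            flags.append(True)
        elif v in {"0", "false", "no", "n", ""}:
            flags.append(False)
        else:
            raise ValidationError(f"line {lineno}: unparseable kegg_flag {raw!r}")
    return SpeciesSet(tuple(df["species_id"]), tuple(flags))


_CONF_RANK = {"high": 0, "low": 1}


def read_homology_table(path: str | Path) -> list[HomologyEdge]:
    """Read homology.tsv and return validated, undirected-deduplicated edges.

    Duplicate pairs are resolved keeping the maximum ``pct_identity``; on
    identity ties, ``high`` confidence beats ``low``. The resulting edge set
    is independent of input row order.
    """
    df = _read_tsv(path, ["gene_a", "gene_b", "pct_identity", "confidence", "relation"])
    if df.empty:
        return []
    bad_lines: list[str] = []
    pct = pd.to_numeric(df["pct_identity"], errors="coerce")
    for lineno, value, raw in zip(df.index + 2, pct, df["pct_identity"]):
        if math.isnan(value):
            bad_lines.append(f"line {lineno}: non-numeric pct_identity {raw!r}")
        elif not 0.0 <= value <= 100.0:
            bad_lines.append(f"line {lineno}: pct_identity {raw} outside [0, 100]")
    for lineno, conf in zip(df.index + 2, df["confidence"]):
        if conf not in _CONF_RANK:
            bad_lines.append(f"line {lineno}: confidence must be high/low, got {conf!r}")
    for lineno, rel in zip(df.index + 2, df["relation"]):
        if rel not in {"ortholog", "paralog"}:
            bad_lines.append(f"line {lineno}: relation must be ortholog/paralog, got {rel!r}")
    for lineno, a, b in zip(df.index + 2, df["gene_a"], df["gene_b"]):
        if a == b:
            bad_lines.append(f"line {lineno}: self-edge on gene {a!r}")
    if bad_lines:
        raise ValidationError("; ".join(bad_lines))

    best: dict[tuple[str, str], HomologyEdge] = {}
    for a, b, p, conf, rel in zip(
        df["gene_a"], df["gene_b"], pct, df["confidence"], df["relation"]
    ):
        edge = HomologyEdge(a, b, float(p), conf, rel)
        prev = best.get(edge.pair)
        if prev is None or (
            (-edge.pct_identity, _CONF_RANK[edge.confidence])
            < (-prev.pct_identity, _CONF_RANK[prev.confidence])
        ):
            best[edge.pair] = edge
    return [best[k] for k in sorted(best)]


def _split_cell(cell: str) -> tuple[str, ...]:
    cell = cell.strip()
    if not cell:
        return ()
    return tuple(x for x in (p.strip() for p in cell.split(LIST_SEP)) if x)


def read_annotation_table(
    path: str | Path, species: SpeciesSet | None = None
) -> tuple[list[GeneRecord], dict[str, str]]:
    """Read annotation.tsv -> (gene records, map -> class hierarchy).

    Columns: gene_id, species, ec, maps, classes. ``maps`` and ``classes``
    are parallel ";"-separated lists (position i of ``classes`` is the parent
    class of map i), from which the two-level hierarchy is assembled; a map
    listed under two different classes anywhere in the file is an error.
    """
    df = _read_tsv(path, ["gene_id", "species", "ec", "maps", "classes"])
    records: list[GeneRecord] = []
    hierarchy: dict[str, str] = {}
    seen_ids: set[str] = set()
    for lineno, gid, sp, ec, maps, classes in zip(
        df.index + 2, df["gene_id"], df["species"], df["ec"], df["maps"], df["classes"]
    ):
        if gid in seen_ids:
            raise ValidationError(f"line {lineno}: duplicate gene_id {gid!r}")
        seen_ids.add(gid)
        if species is not None and sp not in species:
            raise ValidationError(f"line {lineno}: unknown species {sp!r}")
        map_list = _split_cell(maps)
        class_list = _split_cell(classes)
        if len(map_list) != len(class_list):
            raise ValidationError(
                f"line {lineno}: maps/classes lists differ in length "
                f"({len(map_list)} vs {len(class_list)})"
            )
        for m, c in zip(map_list, class_list):
            if hierarchy.setdefault(m, c) != c:
                raise HierarchyError(
                    f"line {lineno}: map {m!r} assigned to class {c!r} "
                    f"but previously to {hierarchy[m]!r}"
                )
        records.append(
            GeneRecord(
                gene_id=gid,
                species_id=sp,
                ec_numbers=frozenset(_split_cell(ec)),
                pathway_maps=frozenset(map_list),
                pathway_classes=frozenset(class_list),
            )
        )
    return records, hierarchy


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read expression.tsv (first column gene_id, remaining columns samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"duplicate gene ids in expression matrix: {dups[:5]}")
    if df.columns.has_duplicates:
        raise ValidationError("duplicate sample ids in expression matrix")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("expression matrix contains non-finite values")
    return df


def read_ppi_table(path: str | Path) -> PPITable:
    """Read ppi.tsv (columns: protein_a, protein_b, evidence), dedup undirected."""
    df = _read_tsv(path, ["protein_a", "protein_b", "evidence"])
    best: dict[tuple[str, str], str] = {}
    for lineno, a, b, ev in zip(df.index + 2, df["protein_a"], df["protein_b"], df["evidence"]):
        if a == b:
            raise ValidationError(f"line {lineno}: self-interaction on {a!r}")
        if ev not in {"experimental", "predicted"}:
            raise ValidationError(f"line {lineno}: evidence must be experimental/predicted")
        key = (a, b) if a < b else (b, a)
        # experimental evidence wins over predicted for duplicated pairs
        if best.get(key) != "experimental":
            best[key] = ev
    pairs = sorted(best)
    return PPITable(pairs=pairs, evidence=[best[p] for p in pairs])


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _format_float(x: object) -> object:
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return ""
        return f"{x:.6g}"
    return x


def write_results(
    results: pd.DataFrame | Iterable[Mapping[str, object]],
    path: str | Path,
    fmt: str = "tsv",
    sort_by: str | None = None,
) -> None:
    """Write a result table as TSV or JSON.

    Floats are serialized with 6 significant digits; rows are sorted by
    ``sort_by`` (default: the first column) for deterministic output.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame(list(results))
    df = results.copy()
    if len(df) and len(df.columns):
        key = sort_by if sort_by is not None else df.columns[0]
        if key in df.columns:
            df = df.sort_values(key, kind="mergesort").reset_index(drop=True)
    path = Path(path)
    if fmt == "tsv":
        out = df.map(_format_float) if len(df) else df
        out.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        rows = [
            {k: _json_value(v) for k, v in row.items()}
            for row in df.to_dict(orient="records")
        ]
        path.write_text(json.dumps(rows, indent=2) + "\n")
    else:
        raise ValueError(f"unknown format: {fmt!r}")


def _json_value(v: object) -> object:
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (float, np.floating)):
        if math.isnan(v):
            return None
        return float(f"{v:.6g}")
    if isinstance(v, np.bool_):
        return bool(v)
    return v


def read_results(path: str | Path, fmt: str = "tsv") -> pd.DataFrame:
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t")
    if fmt == "json":
        return pd.DataFrame(json.loads(Path(path).read_text()))
    raise ValueError(f"unknown format: {fmt!r}")
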