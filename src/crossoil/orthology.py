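"""Orthologous-group copy-number analysis.

Cross-ploidy comparison of gene-family sizes between two species. Because a
tetraploid genome carries twice the chromosome complement of a diploid one,
raw family sizes are not comparable; the statistic used throughout is the
*relative copy number* (family copy count divided by species ploidy). A family
is flagged copy-number divergent when the two species' relative copy numbers
differ by at least a configurable fold ratio, or when the family is entirely
absent from one species.

Orthologous-group (OG) membership is an input (e.g. produced upstream by
OrthoMCL-style clustering); this module only classifies and filters it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SpeciesInfo",
    "OrthoGroup",
    "OG_CLASSES",
    "relative_copy_number",
    "classify_og",
    "divergent_ogs",
    "select_query_ogs",
    "read_og_table",
    "divergence_table",
    "write_divergence_table",
]

OG_CLASSES = (
    "specific_A",
    "specific_B",
    "one_to_one",
    "one_to_many",
    "many_to_one",
    "many_to_many",
)


@dataclass(frozen=True)
class SpeciesInfo:
    """A species name and its ploidy (genome copy multiplicity)."""

    name: str
    ploidy: int

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise ValueError(f"ploidy must be >= 1, got {self.ploidy}")


@dataclass
class OrthoGroup:
    """One gene family: per-species member lists and derived copy counts."""

    og_id: str
    members: dict[str, list[str]] = field(default_factory=dict)

    def count(self, species: str) -> int:
        return len(self.members.get(species, ()))

    def genes(self) -> list[str]:
        return [g for gs in self.members.values() for g in gs]


def relative_copy_number(count: int, ploidy: int) -> float:
    """Family copy count divided by species ploidy.

    E.g. 41 soybean copies at ploidy 2 -> 20.5; 31 rapeseed copies at
    ploidy 4 -> 7.75.
    """
    if ploidy < 1:
        raise ValueError(f"ploidy must be >= 1, got {ploidy}")
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    return count / ploidy


def classify_og(og: OrthoGroup, a: SpeciesInfo, b: SpeciesInfo) -> str:
    """Classify an OG by its two raw copy counts.

    Returns one of ``OG_CLASSES``: species-specific (all copies in one
    species), 1:1, 1:many, many:1 or many:many.
    """
    ca, cb = og.count(a.name), og.count(b.name)
    if ca == 0 and cb == 0:
        raise ValueError(f"OG {og.og_id} has no members in either species")
    if ca == 0:
        return "specific_B"
    if cb == 0:
        return "specific_A"
    if ca == 1 and cb == 1:
        return "one_to_one"
    if ca == 1:
        return "one_to_many"
    if cb == 1:
        return "many_to_one"
    return "many_to_many"


def divergent_ogs(
    ogs: Iterable[OrthoGroup],
    a: SpeciesInfo,
    b: SpeciesInfo,
    fold: float = 2.0,
) -> set[str]:
    """OG ids whose relative copy numbers differ >= ``fold`` between species.

    A zero count opposite a non-zero count is always divergent (the ratio is
    undefined and species-specific presence is the strongest divergence).
    """
    if fold < 1:
        raise ValueError(f"fold must be >= 1, got {fold}")
    out: set[str] = set()
    for og in ogs:
        ca, cb = og.count(a.name), og.count(b.name)
        if ca == 0 and cb == 0:
            raise ValueError(f"OG {og.og_id} has no members in either species")
        if ca == 0 or cb == 0:
            out.add(og.og_id)
            continue
        ra = relative_copy_number(ca, a.ploidy)
        rb = relative_copy_number(cb, b.ploidy)
        if max(ra, rb) / min(ra, rb) >= fold:
            out.add(og.og_id)
    return out


def select_query_ogs(
    query_gene_ids: set[str], ogs: Iterable[OrthoGroup]
) -> list[OrthoGroup]:
    """OGs containing at least one query gene (homology-anchored families)."""
    if not query_gene_ids:
        raise ValueError("query gene set is empty")
    return [og for og in ogs if query_gene_ids.intersection(og.genes())]


def read_og_table(path: str | Path) -> list[OrthoGroup]:
    """Read a tab-separated OG membership table (og_id, species, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"og_id", "species", "gene_id"}
    if not expected.issubset(df.columns):
        raise ValueError(
            f"og table must have columns {sorted(expected)}, got {list(df.columns)}"
        )
    ogs: dict[str, OrthoGroup] = {}
    for og_id, species, gene in df[["og_id", "species", "gene_id"]].itertuples(
        index=False
    ):
        og = ogs.setdefault(og_id, OrthoGroup(og_id))
        og.members.setdefault(species, []).append(gene)
    return list(ogs.values())


def divergence_table(
    ogs: Iterable[OrthoGroup],
    a: SpeciesInfo,
    b: SpeciesInfo,
    fold: float = 2.0,
) -> pd.DataFrame:
    """Per-OG counts, relative copy numbers, class label and divergence flag."""
    ogs = list(ogs)
    flagged = divergent_ogs(ogs, a, b, fold=fold)
    rows = []
    for og in ogs:
        ca, cb = og.count(a.name), og.count(b.name)
        rows.append(
            {
                "og_id": og.og_id,
                "count_a": ca,
                "count_b": cb,
                "rcn_a": relative_copy_number(ca, a.ploidy),
                "rcn_b": relative_copy_number(cb, b.ploidy),
                "class": classify_og(og, a, b),
                "divergent": og.og_id in flagged,
            }
        )
    return pd.DataFrame(rows)


def write_divergence_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def genes_of(ogs: Iterable[OrthoGroup], og_ids: set[str] | None = None) -> set[str]:
    """All member genes, optionally restricted to the given OG ids."""
    out: set[str] = set()
    for og in ogs:
        if og_ids is None or og.og_id in og_ids:
            out.update(og.genes())
    return out


def ortholog_pairs(
    ogs: Iterable[OrthoGroup], a: SpeciesInfo, b: SpeciesInfo
) -> list[tuple[str, str, str]]:
    """All cross-species member pairs (gene_a, gene_b, og_id)."""
    pairs = []
    for og in ogs:
        for ga in og.members.get(a.name, ()):
            for gb in og.members.get(b.name, ()):
                pairs.append((ga, gb, og.og_id))
    return pairs
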