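"""Pathway enrichment by the hypergeometric (one-sided Fisher) test.

Given a candidate gene set, annotation gene sets (GMT), and a background
universe, each term's p-value is the upper tail P(X >= k) of a
hypergeometric draw: k annotated candidates out of n candidates, from a
universe of N genes of which K carry the annotation. Benjamini-Hochberg
step-up correction controls the FDR across terms; terms with fewer than
``small_term_cutoff`` background genes are excluded as unstable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PathwayAnnotation",
    "EnrichmentResult",
    "read_gmt",
    "fisher_enrichment",
    "bh_adjust",
    "top_terms",
]


@dataclass(frozen=True)
class PathwayAnnotation:
    term_id: str
    name: str
    background_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.background_genes:
            raise ValueError(f"term {self.term_id} has an empty gene set")


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    input_count: int  # k: candidates carrying the annotation
    background_count: int  # K: universe genes carrying the annotation
    input_size: int  # n: candidate genes in the universe
    universe_size: int  # N
    p_value: float
    corrected_p: float = float("nan")


def read_gmt(path: str | Path) -> list[PathwayAnnotation]:
    """Read GMT: term_id <TAB> name <TAB> gene1 <TAB> gene2 ..."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        out.append(
            PathwayAnnotation(parts[0], parts[1], frozenset(g for g in parts[2:] if g))
        )
    return out


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_enrichment(
    input_set: set[str],
    annotations: Iterable[PathwayAnnotation],
    universe: set[str] | None = None,
    small_term_cutoff: int = 5,
) -> list[EnrichmentResult]:
    """One-sided enrichment of ``input_set`` in each annotation term.

    The universe defaults to all genes carrying at least one annotation
    (KOBAS-style background); the input set is intersected with it. Results
    are sorted by ascending raw p (ties by term id) and carry BH-corrected
    values.
    """
    annotations = list(annotations)
    if universe is None:
        universe = set().union(*(a.background_genes for a in annotations)) if annotations else set()
    if not universe:
        raise ValueError("empty background universe")
    if not input_set <= universe:
        input_set = input_set & universe
    N = len(universe)
    n = len(input_set)
    results = []
    for ann in annotations:
        bg = ann.background_genes & universe
        K = len(bg)
        if K < small_term_cutoff:
            continue
        k = len(input_set & bg)
        p = hypergeom_upper_tail(k, N, K, n)
        results.append(
            EnrichmentResult(ann.term_id, ann.name, k, K, n, N, p)
        )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    corrected = bh_adjust([r.p_value for r in results])
    for r, cp in zip(results, corrected):
        r.corrected_p = cp
    return results


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def top_terms(results: list[EnrichmentResult], k: int = 10) -> list[EnrichmentResult]:
    """First ``k`` terms by ascending corrected p (ties by term id)."""
    return sorted(results, key=lambda r: (r.corrected_p, r.term_id))[:k]


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "name": [r.name for r in results],
            "input_number": [r.input_count for r in results],
            "background_number": [r.background_count for r in results],
            "p_value": [r.p_value for r in results],
            "corrected_p": [r.corrected_p for r in results],
        }
    )
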