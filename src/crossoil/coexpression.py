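"""Pearson co-expression neighborhoods and differential network comparison.

The co-expression network around a focal gene (e.g. PEPC1) is the set of
genes whose stage series correlates with the focal gene's at |r| >= 0.9 with
a t-test p <= 0.05, both thresholds enforced jointly. Two species' networks
are then compared through the ortholog map: neighbor pairs falling in the
same orthologous group are the conserved core, the remainder are the
species-specific periphery handed to pathway enrichment.

With only 4 stage samples the t-test at r = 0.9 gives p ~ 0.10, so the p
threshold dominates and the effective |r| cutoff exceeds 0.9; callers should
be aware that short stage courses admit only near-perfect correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .orthology import OrthoGroup, SpeciesInfo

__all__ = [
    "CorrelationEdge",
    "NetworkComparison",
    "pearson_r",
    "corr_pvalue",
    "neighbors",
    "compare_networks",
    "edges_table",
]


@dataclass(frozen=True)
class CorrelationEdge:
    gene_a: str
    gene_b: str
    r: float
    p_value: float
    n: int


@dataclass
class NetworkComparison:
    shared_og_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    specific_a: set[str] = field(default_factory=set)
    specific_b: set[str] = field(default_factory=set)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; raises on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def corr_pvalue(r: float, n: int) -> float:
    """Two-sided p for a product-moment correlation via the t transform.

    t = r*sqrt((n-2)/(1-r^2)) on n-2 df. At n=4 (df=2) this reduces to the
    closed form 1 - |t|/sqrt(2+t^2).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df=n - 2))


def neighbors(
    target: str,
    m: pd.DataFrame,
    r_min: float = 0.9,
    alpha: float = 0.05,
) -> list[CorrelationEdge]:
    """Genes co-expressed with ``target``: |r| >= r_min and p <= alpha.

    Constant-series genes are skipped (undefined correlation). Edges are
    returned sorted by descending |r|, ties by gene id.
    """
    if target not in m.index:
        raise KeyError(f"target gene {target!r} not in matrix")
    tv = m.loc[target].values.astype(float)
    n = tv.size
    if np.ptp(tv) == 0:
        raise ValueError(f"target gene {target!r} has a constant series")
    edges = []
    for gene, row in zip(m.index, m.values):
        if gene == target:
            continue
        if np.ptp(row) == 0:
            continue
        r = pearson_r(tv, row)
        if abs(r) < r_min:
            continue
        p = corr_pvalue(r, n)
        if p <= alpha:
            edges.append(CorrelationEdge(target, gene, r, p, n))
    edges.sort(key=lambda e: (-abs(e.r), e.gene_b))
    return edges


def compare_networks(
    nbrs_a: Iterable[CorrelationEdge],
    nbrs_b: Iterable[CorrelationEdge],
    ogs: Iterable[OrthoGroup],
    a: SpeciesInfo,
    b: SpeciesInfo,
) -> NetworkComparison:
    """Split two species' neighbor sets into ortholog-shared pairs and
    species-specific genes (the latter feed pathway enrichment)."""
    genes_a = {e.gene_b for e in nbrs_a}
    genes_b = {e.gene_b for e in nbrs_b}
    cmp = NetworkComparison()
    shared_a: set[str] = set()
    shared_b: set[str] = set()
    for og in ogs:
        for ga in og.members.get(a.name, ()):
            if ga not in genes_a:
                continue
            for gb in og.members.get(b.name, ()):
                if gb in genes_b:
                    cmp.shared_og_pairs.append((ga, gb, og.og_id))
                    shared_a.add(ga)
                    shared_b.add(gb)
    cmp.specific_a = genes_a - shared_a
    cmp.specific_b = genes_b - shared_b
    return cmp


def edges_table(edges: Iterable[CorrelationEdge]) -> pd.DataFrame:
    """Cytoscape-loadable undirected edge list."""
    edges = list(edges)
    return pd.DataFrame(
        {
            "gene_a": [e.gene_a for e in edges],
            "gene_b": [e.gene_b for e in edges],
            "r": [e.r for e in edges],
            "p_value": [e.p_value for e in edges],
            "n": [e.n for e in edges],
        }
    )
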