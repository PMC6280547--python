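"""Molecular-evolution utilities: distance trees, Ka/Ks, and branch LRTs.

Three pieces sit here. First, distance phylogenetics for protein families:
p-distances under pairwise deletion, Poisson correction d = -ln(1 - p),
neighbor-joining, and nonparametric bootstrap supports. Second, a
Nei-Gojobori (1986) counting estimator of Ka/Ks (omega) for in-frame codon
pairs: synonymous/nonsynonymous site and difference counting with pathway
averaging over multi-hit codons and Jukes-Cantor multiple-hit correction.
It is a desk-scale estimator of selective pressure; full codon-model
maximum-likelihood fitting is left to dedicated tools, whose reported
log-likelihoods can be compared here. Third, the likelihood-ratio test for
nested branch models: statistic 2|Delta lnL| against a chi-square with df =
the difference in free omega parameters.

Note on the LRT sign: the statistic uses the absolute log-likelihood
difference, and the result records whether the alternative model scored
below the null (``label_swap``) instead of silently reordering the inputs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats
from skbio import TreeNode

__all__ = [
    "ProteinAlignment",
    "SelectionEstimate",
    "LrtResult",
    "p_distance",
    "poisson_distance",
    "alignment_distances",
    "neighbor_joining",
    "bootstrap_support",
    "ng86_ka_ks",
    "branch_lrt",
    "read_alignment",
]

_GAPS = set("-.?X")


@dataclass
class ProteinAlignment:
    """Aligned residue rows of equal length, gap symbol '-'."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, cols: Sequence[int]) -> "ProteinAlignment":
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return ProteinAlignment(list(self.ids), rows)


def read_alignment(path: str | Path) -> ProteinAlignment:
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return ProteinAlignment(ids, rows)


def p_distance(row_a: str, row_b: str, pairwise_deletion: bool = True) -> float:
    """Fraction of differing sites among comparable (non-gap) columns."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    comparable = diffs = 0
    for x, y in zip(row_a.upper(), row_b.upper()):
        if pairwise_deletion and (x in _GAPS or y in _GAPS):
            continue
        comparable += 1
        if x != y:
            diffs += 1
    if comparable == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    return diffs / comparable


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance -ln(1 - p); requires p < 1."""
    if not 0 <= p < 1:
        raise ValueError(f"p-distance must be in [0, 1), got {p}")
    return -math.log(1.0 - p)


def alignment_distances(
    aln: ProteinAlignment, correction: str = "poisson"
) -> np.ndarray:
    """Pairwise distance matrix (pairwise deletion; Poisson or raw p)."""
    n = len(aln.ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        p = p_distance(aln.rows[i], aln.rows[j])
        d[i, j] = d[j, i] = poisson_distance(p) if correction == "poisson" else p
    return d


def neighbor_joining(d: np.ndarray, ids: Sequence[str]) -> TreeNode:
    """Standard Q-criterion neighbor joining; returns an unrooted tree
    (trifurcating root).

    Additive matrices are reproduced exactly (tip-to-tip path lengths equal
    the input distances). Negative branch-length estimates are clamped to 0
    with the deficit moved to the sister branch; the raw value is kept on the
    node as ``raw_length``.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or len(ids) != n:
        raise ValueError("distance matrix / id length mismatch")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    D = d.copy()
    active = list(range(n))

    def _attach(child: TreeNode, length: float) -> None:
        child.raw_length = length
        child.length = max(length, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Q), Q.shape)  # first min: deterministic
        if i_ > j_:
            i_, j_ = j_, i_
        li = 0.5 * sub[i_, j_] + (r[i_] - r[j_]) / (2 * (m - 2))
        lj = sub[i_, j_] - li
        if li < 0:  # transfer deficit to sister
            lj, li = sub[i_, j_], 0.0
        elif lj < 0:
            li, lj = sub[i_, j_], 0.0
        gi, gj = active[i_], active[j_]
        parent = TreeNode()
        ci, cj = nodes[gi], nodes[gj]
        _attach(ci, li)
        _attach(cj, lj)
        parent.extend([ci, cj])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0] + 1)
        for k_, gk in enumerate(active):
            if gk in (gi, gj):
                continue
            new_row[gk] = 0.5 * (D[gi, gk] + D[gj, gk] - D[gi, gj])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :] = new_row
        D[:, -1] = new_row
        nodes.append(parent)
        active = [a for a in active if a not in (gi, gj)] + [len(nodes) - 1]

    # resolve the final three lineages around the unrooted center
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = TreeNode()
    for g, length in zip((a, b, c), (la, lb, lc)):
        _attach(nodes[g], length)
    root.extend([nodes[a], nodes[b], nodes[c]])
    return root


def _bipartitions(tree: TreeNode, all_tips: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized as the side not
    containing the lexicographically smallest tip."""
    ref = min(all_tips)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(all_tips) - 2:
            continue
        if ref in side:
            side = all_tips - side
        parts.add(side)
    return parts


def bootstrap_support(
    aln: ProteinAlignment,
    n_reps: int = 1000,
    seed: int = 0,
    correction: str = "poisson",
) -> TreeNode:
    """NJ tree from the full alignment with bootstrap supports (percent).

    Columns are resampled with replacement ``n_reps`` times; each internal
    node's support is the percentage of replicate trees containing the same
    tip bipartition. Deterministic for a given seed.
    """
    if n_reps < 1:
        raise ValueError("need n_reps >= 1")
    tree = neighbor_joining(alignment_distances(aln, correction), aln.ids)
    all_tips = frozenset(aln.ids)
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    ncol = aln.n_cols
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep = aln.resample_columns(list(cols))
        rep_tree = neighbor_joining(alignment_distances(rep, correction), rep.ids)
        for part in _bipartitions(rep_tree, all_tips):
            counts[part] = counts.get(part, 0) + 1
    ref = min(all_tips)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(all_tips) - 2:
            continue
        if ref in side:
            side = all_tips - side
        node.support = 100.0 * counts.get(side, 0) / n_reps
        node.name = f"{node.support:g}"
    return tree


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) counting Ka/Ks

_CODON_AA: dict[str, str] = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


@dataclass
class SelectionEstimate:
    ka: float
    ks: float
    omega: float | None  # None when Ks = 0 or a correction is undefined
    s_sites: float = 0.0
    n_sites: float = 0.0
    s_diffs: float = 0.0
    n_diffs: float = 0.0


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes to stop codons count as nonsynonymous.
    """
    aa = _CODON_AA[codon]
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in _STOPS and _CODON_AA[mut] == aa:
                s += 1.0 / 3.0
    return s, 3.0 - s


def _codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences.

    Multi-hit codons average over all substitution orderings; paths passing
    through a stop codon are excluded (all paths are used if every path is
    blocked).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def _steps(path: tuple[int, ...]) -> tuple[float, float, bool] | None:
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in path:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                through_stop = True
                nd += 1.0
            elif cur in _STOPS:
                through_stop = True
                nd += 1.0
            elif _CODON_AA[cur] == _CODON_AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd, through_stop

    results = [_steps(p) for p in itertools.permutations(diff_pos)]
    valid = [r for r in results if not r[2]]
    pool = valid if valid else results
    sd = sum(r[0] for r in pool) / len(pool)
    nd = sum(r[1] for r in pool) / len(pool)
    return sd, nd


def _jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction; inf when saturated."""
    if p == 0:
        return 0.0
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return math.inf
    return -0.75 * math.log(arg)


def ng86_ka_ks(cds_a: str, cds_b: str) -> SelectionEstimate:
    """Counting Ka/Ks for a pair of aligned in-frame coding sequences.

    Codons containing gaps or stop codons in either sequence are skipped.
    """
    a, b = cds_a.upper().replace("U", "T"), cds_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if len(a) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        c1, c2 = a[i : i + 3], b[i : i + 3]
        if set(c1 + c2) - set(_BASES):
            continue
        if c1 in _STOPS or c2 in _STOPS:
            continue
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _codon_diffs(c1, c2)
        Sd += sd
        Nd += nd
    if S == 0 or N == 0:
        raise ValueError("no countable codons")
    ks = _jc_correct(Sd / S)
    ka = _jc_correct(Nd / N)
    omega = None
    if ks > 0 and math.isfinite(ks) and math.isfinite(ka):
        omega = ka / ks
    return SelectionEstimate(ka, ks, omega, S, N, Sd, Nd)


# ---------------------------------------------------------------------------
# Branch-model likelihood-ratio test


@dataclass
class LrtResult:
    lnl_null: float
    lnl_alt: float
    df: int
    statistic: float
    p_value: float
    label_swap: bool = False  # alternative scored below the null as given


def branch_lrt(lnl_null: float, lnl_alt: float, df: int) -> LrtResult:
    """LRT of nested models: statistic 2|lnL_alt - lnL_null|, chi-square df.

    ``label_swap`` records an alternative model whose reported likelihood is
    lower than the null's (as can happen with independently printed fits);
    the statistic is the absolute difference either way.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * abs(lnl_alt - lnl_null)
    p = float(stats.chi2.sf(stat, df))
    return LrtResult(lnl_null, lnl_alt, df, stat, p, label_swap=lnl_alt < lnl_null)
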