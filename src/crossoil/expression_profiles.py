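"""Short time-series expression profile clustering.

Developmental stage series (4 stages here: seed-oil initiation, two rapid
accumulation stages, and decline) are too short for model-free clustering, so
genes are assigned to a predefined catalogue of *model profiles*: temporal
shape vectors that start at 0 and move by integer unit steps (at most ``c``
units per stage transition). The approach mirrors the short time-series
expression mining strategy used for microarray stage courses:

1. each gene series ``(v0..vn)`` is log-normalized to
   ``(0, log2(v1/v0), ..., log2(vn/v0))``;
2. genes whose transformed series never reaches a minimum absolute change are
   discarded as flat;
3. each remaining gene joins the model profile with which its transformed
   series has the highest Pearson correlation;
4. per-profile significance is assessed by permuting the stage order: the
   expected cluster size is the mean size over all stage permutations, and
   the observed size is tested against an upper-tail binomial.

Cross-species comparability uses *relative expression content*: a gene's
expression divided by the per-stage mean over all genes of its species.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelProfile",
    "ProfileAssignment",
    "relative_expression",
    "log_normalize",
    "transform_matrix",
    "min_change_filter",
    "generate_model_profiles",
    "assign_genes",
    "profile_significance",
    "classify_trend",
    "candidate_genes",
]


@dataclass(frozen=True)
class ModelProfile:
    """A candidate temporal shape: starts at 0, unit steps bounded by +-c."""

    id: int
    shape: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.shape[0] != 0:
            raise ValueError("model profile shape must start at 0")


@dataclass
class ProfileAssignment:
    """Gene-to-profile memberships with per-profile permutation significance.

    ``gene_profile`` maps each assigned gene to a profile id; genes whose
    transformed series has zero variance are left out. ``observed``,
    ``expected``, ``p_value`` and ``significant`` are filled per profile by
    :func:`profile_significance`.
    """

    gene_profile: dict[str, int] = field(default_factory=dict)
    correlations: dict[str, float] = field(default_factory=dict)
    observed: dict[int, int] = field(default_factory=dict)
    expected: dict[int, float] = field(default_factory=dict)
    p_value: dict[int, float] = field(default_factory=dict)
    significant: dict[int, bool] = field(default_factory=dict)

    def genes_in(self, profile_id: int) -> set[str]:
        return {g for g, p in self.gene_profile.items() if p == profile_id}

    def significant_profiles(self) -> set[int]:
        return {p for p, s in self.significant.items() if s}


def relative_expression(m: pd.DataFrame) -> pd.DataFrame:
    """Divide each value by the per-stage mean over all genes.

    Makes expression levels comparable across species with different overall
    transcriptome scale; each output column has mean exactly 1.
    """
    if (m.values < 0).any():
        raise ValueError("expression values must be non-negative")
    means = m.mean(axis=0)
    if (means == 0).any():
        bad = list(means.index[means == 0])
        raise ValueError(f"all-zero stage(s): {bad}")
    return m / means


def log_normalize(v: np.ndarray) -> np.ndarray:
    """Transform ``(v0..vn)`` to ``(0, log2(v1/v0), ..., log2(vn/v0))``.

    Requires ``v0 > 0``; callers batch-filtering a matrix should drop such
    genes first (see :func:`transform_matrix`).
    """
    v = np.asarray(v, dtype=float)
    if v[0] <= 0:
        raise ValueError("first stage value must be positive")
    out = np.log2(v / v[0])
    out[0] = 0.0
    return out


def transform_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Log-normalize every row, dropping genes with v0 = 0.

    Genes whose first-stage value is zero have an undefined transform and are
    excluded (no pseudocount), reproducibly.
    """
    keep = m.iloc[:, 0] > 0
    kept = m.loc[keep]
    vals = np.log2(kept.values / kept.values[:, [0]])
    vals[:, 0] = 0.0
    return pd.DataFrame(vals, index=kept.index, columns=kept.columns)


def min_change_filter(transformed: np.ndarray, threshold: float = 2.0) -> bool:
    """Keep a gene iff its transformed series reaches |change| >= threshold."""
    return bool(np.max(np.abs(transformed)) >= threshold)


def _enumerate_shapes(n_stages: int, c: int) -> list[tuple[int, ...]]:
    steps = range(-c, c + 1)
    shapes = []
    for deltas in itertools.product(steps, repeat=n_stages - 1):
        shape = (0, *itertools.accumulate(deltas))
        shapes.append(tuple(shape))
    return shapes


def generate_model_profiles(
    n_stages: int = 4, c: int = 1, m: int = 20, seed: int = 0
) -> list[ModelProfile]:
    """Enumerate all unit-step shapes and pick ``m`` spread-out representatives.

    Candidates are all ``(2c+1)^(n_stages-1)`` shapes with per-step change in
    ``{-c..c}``. Selection is greedy max-min Euclidean distance seeded from
    the all-flat shape; ties break on lexicographically smallest shape, so the
    catalogue is deterministic. ``m=20`` at 4 stages with c=1 matches the
    cluster count used for the seed stage courses.
    """
    if n_stages < 2:
        raise ValueError("need at least 2 stages")
    candidates = _enumerate_shapes(n_stages, c)
    if m > len(candidates):
        raise ValueError(
            f"m={m} exceeds the {len(candidates)} enumerable shapes"
        )
    flat = tuple([0] * n_stages)
    chosen = [flat]
    remaining = sorted(set(candidates) - {flat})
    arr = {s: np.asarray(s, dtype=float) for s in candidates}
    while len(chosen) < m and remaining:
        best, best_d = None, -1.0
        for s in remaining:
            d = min(
                float(np.linalg.norm(arr[s] - arr[t])) for t in chosen
            )
            if d > best_d + 1e-12:
                best, best_d = s, d
        chosen.append(best)
        remaining.remove(best)
    return [ModelProfile(i, s) for i, s in enumerate(chosen)]


def _corr_with_profiles(vec: np.ndarray, shapes: np.ndarray) -> np.ndarray:
    """Pearson r of one vector against each profile row; NaN where undefined."""
    vc = vec - vec.mean()
    sv = np.sqrt((vc**2).sum())
    sc = shapes - shapes.mean(axis=1, keepdims=True)
    ss = np.sqrt((sc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (sc @ vc) / (ss * sv)
    return r


def assign_genes(
    transformed: pd.DataFrame, profiles: list[ModelProfile]
) -> ProfileAssignment:
    """Assign each gene to the profile maximizing Pearson correlation.

    Zero-variance (constant) transformed series are unassignable; flat model
    profiles can never win (their correlation is undefined). Ties go to the
    lowest profile id.
    """
    if not profiles:
        raise ValueError("profile list is empty")
    shapes = np.asarray([p.shape for p in profiles], dtype=float)
    ids = np.asarray([p.id for p in profiles])
    order = np.argsort(ids, kind="stable")
    shapes, ids = shapes[order], ids[order]

    asn = ProfileAssignment()
    vals = transformed.values
    for gene, vec in zip(transformed.index, vals):
        if np.ptp(vec) == 0:
            continue
        r = _corr_with_profiles(np.asarray(vec, float), shapes)
        r = np.where(np.isnan(r), -np.inf, r)
        best = int(np.argmax(r))  # argmax takes first max -> lowest id wins
        asn.gene_profile[gene] = int(ids[best])
        asn.correlations[gene] = float(r[best])
    return asn


def _permuted_counts(
    vecs: np.ndarray, shapes: np.ndarray, ids: np.ndarray, perm: tuple[int, ...]
) -> np.ndarray:
    """Assignment counts per profile after reordering stages by ``perm``.

    Reordering the raw series and re-applying the log transform equals
    permuting the transformed vector and re-anchoring at its new first
    element; Pearson correlation is shift-invariant, so the permuted vector
    is used directly.
    """
    pv = vecs[:, list(perm)]
    counts = np.zeros(len(ids), dtype=float)
    for vec in pv:
        if np.ptp(vec) == 0:
            continue
        r = _corr_with_profiles(vec, shapes)
        r = np.where(np.isnan(r), -np.inf, r)
        counts[int(np.argmax(r))] += 1
    return counts


def profile_significance(
    assignment: ProfileAssignment,
    transformed: pd.DataFrame,
    profiles: list[ModelProfile],
    max_exhaustive_stages: int = 5,
    n_sampled: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> ProfileAssignment:
    """Permutation significance of per-profile cluster sizes.

    The null model permutes the stage order of every gene and re-runs the
    assignment; a profile's expected size is the mean over permutations
    (exhaustive ``n!`` when the stage count is <= ``max_exhaustive_stages``,
    else ``n_sampled`` random permutations). The observed size is tested
    against Binomial(total, expected/total), upper tail; no multiplicity
    correction by default (raw p < alpha), matching how such cluster p-values
    are conventionally reported.
    """
    shapes = np.asarray([p.shape for p in profiles], dtype=float)
    ids = np.asarray(sorted(p.id for p in profiles))
    order = np.argsort([p.id for p in profiles], kind="stable")
    shapes = shapes[order]

    assigned = [g for g in transformed.index if g in assignment.gene_profile]
    total = len(assigned)
    for pid in ids:
        assignment.observed[int(pid)] = len(assignment.genes_in(int(pid)))
    if total == 0:
        for pid in ids:
            assignment.expected[int(pid)] = 0.0
            assignment.p_value[int(pid)] = 1.0
            assignment.significant[int(pid)] = False
        return assignment

    vecs = transformed.loc[assigned].values.astype(float)
    n_stages = vecs.shape[1]
    if n_stages <= max_exhaustive_stages:
        perms = list(itertools.permutations(range(n_stages)))
    else:
        rng = np.random.default_rng(seed)
        perms = [tuple(rng.permutation(n_stages)) for _ in range(n_sampled)]

    mean_counts = np.zeros(len(ids), dtype=float)
    for perm in perms:
        mean_counts += _permuted_counts(vecs, shapes, ids, perm)
    mean_counts /= len(perms)

    for pid, exp in zip(ids, mean_counts):
        obs = assignment.observed[int(pid)]
        frac = min(exp / total, 1.0)
        # P(X >= obs) under Binomial(total, frac)
        p = float(stats.binom.sf(obs - 1, total, frac)) if obs > 0 else 1.0
        assignment.expected[int(pid)] = float(exp)
        assignment.p_value[int(pid)] = min(p, 1.0)
        assignment.significant[int(pid)] = p < alpha
    return assignment


def classify_trend(
    profile: ModelProfile, window: tuple[int, int] = (1, 2)
) -> str:
    """Call a profile up/down/other over a stage window (0-based indices).

    The default window (stages 2..3) is the rapid oil-accumulation phase of
    the seed development course.
    """
    i, j = window
    if not (0 <= i < j < len(profile.shape)):
        raise ValueError(f"invalid window {window} for {len(profile.shape)} stages")
    if profile.shape[j] > profile.shape[i]:
        return "up"
    if profile.shape[j] < profile.shape[i]:
        return "down"
    return "other"


def candidate_genes(
    divergent_og_ids: set[str],
    og_members: dict[str, set[str]],
    assignment: ProfileAssignment,
    profiles: list[ModelProfile],
    query_og_ids: set[str] | None = None,
    window: tuple[int, int] = (1, 2),
    combine: str = "union",
) -> set[str]:
    """Combine copy-number divergence and temporal-trend evidence.

    A gene is a candidate if its family is copy-number divergent, or if it is
    assigned to a significant up/down-trending profile — restricted to the
    query (pathway-anchored) families. ``combine`` may be ``union`` (default)
    or ``intersect``.
    """
    if combine not in ("union", "intersect"):
        raise ValueError("combine must be 'union' or 'intersect'")
    if query_og_ids is None:
        query_og_ids = set(og_members)
    universe = {
        g for og in query_og_ids for g in og_members.get(og, set())
    }
    cnv_genes = {
        g
        for og in (divergent_og_ids & query_og_ids)
        for g in og_members.get(og, set())
    }
    trend_profiles = {
        p.id
        for p in profiles
        if classify_trend(p, window) in ("up", "down")
        and assignment.significant.get(p.id, False)
    }
    trend_genes = {
        g
        for g, pid in assignment.gene_profile.items()
        if pid in trend_profiles and g in universe
    }
    if combine == "union":
        return cnv_genes | trend_genes
    return cnv_genes & trend_genes


def profiles_table(profiles: list[ModelProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "profile_id": [p.id for p in profiles],
            "shape": [",".join(f"{x:g}" for x in p.shape) for p in profiles],
            "trend": [classify_trend(p) for p in profiles],
        }
    )


def significance_table(asn: ProfileAssignment) -> pd.DataFrame:
    pids = sorted(asn.observed)
    return pd.DataFrame(
        {
            "profile_id": pids,
            "observed": [asn.observed[p] for p in pids],
            "expected": [asn.expected.get(p, math.nan) for p in pids],
            "p_value": [asn.p_value.get(p, math.nan) for p in pids],
            "significant": [asn.significant.get(p, False) for p in pids],
        }
    )
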