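"""End-to-end orchestration: from input tables to the candidate report.

Stage order follows the analysis' dependency structure: orthologous-group
copy-number divergence -> per-species expression profile clustering ->
candidate-gene combination -> pathway enrichment -> regulatory overlay ->
focal-gene co-expression comparison. Each stage writes its own TSV next to
the final ``report.tsv``; a ``metadata.json`` records input hashes, stage
wall times and the seed, so a run is reproducible and auditable.

A stage whose inputs are not configured (e.g. no GMT file) is skipped; a
stage that fails is logged and its downstream dependents are skipped rather
than aborting the whole run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field, fields, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import coexpression, enrichment, expression_profiles as ep, orthology, regulation

logger = logging.getLogger("crossoil")

__all__ = ["RunConfig", "load_config", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Flat run configuration (YAML key-value file)."""

    species_a: str = "gma"
    species_b: str = "bna"
    ploidy_a: int = 2
    ploidy_b: int = 4
    og_table: str = ""
    expr_a: str = ""
    expr_b: str = ""
    gmt: str = ""
    mirna_fasta: str = ""
    transcripts_fasta: str = ""
    tf_pairs: str = ""
    query_genes: str = ""  # optional file, one gene id per line
    focal_gene_a: str = ""
    focal_gene_b: str = ""
    fold: float = 2.0
    min_change: float = 2.0
    alpha: float = 0.05
    r_min: float = 0.9
    max_expectation: float = 3.0
    fdr: float = 0.05
    small_term_cutoff: int = 5
    top_k: int = 10
    n_profiles: int = 20
    profile_change_unit: int = 1
    combine: str = "union"
    seed: int = 0

    _path_fields = (
        "og_table",
        "expr_a",
        "expr_b",
        "gmt",
        "mirna_fasta",
        "transcripts_fasta",
        "tf_pairs",
        "query_genes",
    )
    _required_paths = ("og_table", "expr_a", "expr_b")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    # resolve relative paths against the config file's directory
    base = Path(path).parent
    for name in RunConfig._path_fields:
        val = getattr(cfg, name)
        if val and not Path(val).is_absolute():
            setattr(cfg, name, str(base / val))
    return cfg


def validate_config(cfg: RunConfig) -> list[str]:
    """Empty list iff the configuration is runnable."""
    issues = []
    if cfg.ploidy_a < 1:
        issues.append(f"ploidy_a must be >= 1, got {cfg.ploidy_a}")
    if cfg.ploidy_b < 1:
        issues.append(f"ploidy_b must be >= 1, got {cfg.ploidy_b}")
    if cfg.fold < 1:
        issues.append(f"fold must be >= 1, got {cfg.fold}")
    for name, lo, hi in (("alpha", 0, 1), ("fdr", 0, 1)):
        v = getattr(cfg, name)
        if not lo < v <= hi:
            issues.append(f"{name} must lie in (0, 1], got {v}")
    if not 0 < cfg.r_min <= 1:
        issues.append(f"r_min must lie in (0, 1], got {cfg.r_min}")
    if cfg.min_change < 0:
        issues.append(f"min_change must be >= 0, got {cfg.min_change}")
    if cfg.max_expectation < 0:
        issues.append(f"max_expectation must be >= 0, got {cfg.max_expectation}")
    if cfg.combine not in ("union", "intersect"):
        issues.append(f"combine must be union|intersect, got {cfg.combine!r}")
    for name in RunConfig._required_paths:
        p = getattr(cfg, name)
        if not p:
            issues.append(f"{name} is required")
        elif not Path(p).exists():
            issues.append(f"{name}: no such file: {p}")
    for name in RunConfig._path_fields:
        p = getattr(cfg, name)
        if p and name not in RunConfig._required_paths and not Path(p).exists():
            issues.append(f"{name}: no such file: {p}")
    return issues


def _md5(path: str) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


@dataclass
class _RunState:
    report: pd.DataFrame | None = None
    meta: dict = dc_field(default_factory=dict)
    failed: set[str] = dc_field(default_factory=set)


def _species_profiles(
    cfg: RunConfig, expr_path: str, outdir: Path, tag: str
):
    """Transform, filter, assign and score one species' expression matrix."""
    m = pd.read_csv(expr_path, sep="\t", index_col=0)
    transformed = ep.transform_matrix(m)
    keep = [
        g
        for g, row in zip(transformed.index, transformed.values)
        if ep.min_change_filter(row, cfg.min_change)
    ]
    filtered = transformed.loc[keep]
    profiles = ep.generate_model_profiles(
        n_stages=m.shape[1], c=cfg.profile_change_unit, m=cfg.n_profiles
    )
    asn = ep.assign_genes(filtered, profiles)
    asn = ep.profile_significance(
        asn, filtered, profiles, seed=cfg.seed, alpha=cfg.alpha
    )
    ep.profiles_table(profiles).to_csv(
        outdir / f"profiles_{tag}.tsv", sep="\t", index=False
    )
    ep.significance_table(asn).to_csv(
        outdir / f"significance_{tag}.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {
            "gene": list(asn.gene_profile),
            "profile": [asn.gene_profile[g] for g in asn.gene_profile],
            "corr": [asn.correlations[g] for g in asn.gene_profile],
        }
    ).to_csv(outdir / f"assignments_{tag}.tsv", sep="\t", index=False)
    return m, profiles, asn


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> pd.DataFrame:
    """Execute all configured stages; returns the candidate report."""
    issues = validate_config(cfg)
    if issues:
        raise ValueError("invalid configuration: " + "; ".join(issues))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = _RunState()
    meta: dict = {"seed": cfg.seed, "stages": {}, "inputs": {}}
    for name in RunConfig._path_fields:
        p = getattr(cfg, name)
        if p:
            meta["inputs"][name] = {"path": p, "md5": _md5(p)}

    def _stage(name: str, func, *deps: str):
        if any(d in state.failed for d in deps):
            logger.warning("skipping %s: upstream failure in %s", name, deps)
            state.failed.add(name)
            return None
        t0 = time.perf_counter()
        try:
            out = func()
        except Exception:
            logger.exception("stage %s failed", name)
            state.failed.add(name)
            meta["stages"][name] = {"status": "failed"}
            return None
        meta["stages"][name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
        }
        return out

    sp_a = orthology.SpeciesInfo(cfg.species_a, cfg.ploidy_a)
    sp_b = orthology.SpeciesInfo(cfg.species_b, cfg.ploidy_b)

    # --- orthology / copy-number divergence
    def s_orthology():
        ogs = orthology.read_og_table(cfg.og_table)
        table = orthology.divergence_table(ogs, sp_a, sp_b, fold=cfg.fold)
        orthology.write_divergence_table(table, outdir / "divergent_ogs.tsv")
        if cfg.query_genes:
            queries = {
                ln.strip()
                for ln in Path(cfg.query_genes).read_text().splitlines()
                if ln.strip()
            }
            query_ogs = orthology.select_query_ogs(queries, ogs)
        else:
            query_ogs = ogs
        return ogs, table, query_ogs

    orth = _stage("orthology", s_orthology)

    # --- expression profiles per species
    prof_a = _stage(
        "profiles_a",
        lambda: _species_profiles(cfg, cfg.expr_a, outdir, cfg.species_a),
    )
    prof_b = _stage(
        "profiles_b",
        lambda: _species_profiles(cfg, cfg.expr_b, outdir, cfg.species_b),
    )

    # --- candidate combination
    def s_candidates():
        ogs, table, query_ogs = orth
        divergent = set(table.loc[table["divergent"], "og_id"])
        query_ids = {og.og_id for og in query_ogs}
        out: dict[str, set[str]] = {}
        for sp, prof in ((cfg.species_a, prof_a), (cfg.species_b, prof_b)):
            members = {
                og.og_id: set(og.members.get(sp, ())) for og in ogs
            }
            _, profiles, asn = prof
            out[sp] = ep.candidate_genes(
                divergent, members, asn, profiles,
                query_og_ids=query_ids, combine=cfg.combine,
            )
        all_c = sorted(out[cfg.species_a] | out[cfg.species_b])
        (outdir / "candidates.txt").write_text("".join(g + "\n" for g in all_c))
        return out

    cands = _stage("candidates", s_candidates, "orthology", "profiles_a", "profiles_b")

    # --- pathway enrichment
    def s_enrichment():
        anns = enrichment.read_gmt(cfg.gmt)
        tables = {}
        for sp in (cfg.species_a, cfg.species_b):
            res = enrichment.fisher_enrichment(
                cands[sp], anns, small_term_cutoff=cfg.small_term_cutoff
            )
            top = enrichment.top_terms(res, cfg.top_k)
            tab = enrichment.enrichment_table(top)
            tab.to_csv(outdir / f"enrichment_{sp}.tsv", sep="\t", index=False)
            tables[sp] = tab
        return tables

    if cfg.gmt:
        _stage("enrichment", s_enrichment, "candidates")

    # --- regulatory overlay
    def s_regulation():
        mirnas = regulation.read_fasta(cfg.mirna_fasta)
        transcripts = regulation.read_fasta(cfg.transcripts_fasta)
        hits = []
        for mid in sorted(mirnas):
            for tid in sorted(transcripts):
                hits.extend(
                    regulation.scan_transcript(
                        mirnas[mid], transcripts[tid],
                        max_expectation=cfg.max_expectation,
                        mirna_id=mid, target_id=tid,
                    )
                )
        tab = regulation.targets_table(hits)
        tab.to_csv(outdir / "targets.tsv", sep="\t", index=False)
        tf = (
            pd.read_csv(cfg.tf_pairs, sep="\t", dtype=str)
            if cfg.tf_pairs
            else None
        )
        all_c = cands[cfg.species_a] | cands[cfg.species_b]
        mh = tab.rename(
            columns={"miRNA_Acc": "mirna_id", "Target_Acc": "target_id",
                     "Expectation": "expectation"}
        )
        links = regulation.join_regulators(all_c, tf, mh)
        pd.DataFrame(
            {
                "regulator_id": [l.regulator_id for l in links],
                "target_gene": [l.target_gene for l in links],
                "kind": [l.kind for l in links],
                "evidence": [l.evidence for l in links],
            }
        ).to_csv(outdir / "regulators.tsv", sep="\t", index=False)
        return links

    links = None
    if cfg.mirna_fasta and cfg.transcripts_fasta:
        links = _stage("regulation", s_regulation, "candidates")

    # --- focal-gene co-expression comparison
    def s_network():
        ogs, _, _ = orth
        ma, _, _ = prof_a
        mb, _, _ = prof_b
        na = coexpression.neighbors(cfg.focal_gene_a, ma, cfg.r_min, cfg.alpha)
        nb = coexpression.neighbors(cfg.focal_gene_b, mb, cfg.r_min, cfg.alpha)
        coexpression.edges_table(na + nb).to_csv(
            outdir / "edges.tsv", sep="\t", index=False
        )
        cmpr = coexpression.compare_networks(na, nb, ogs, sp_a, sp_b)
        pd.DataFrame(
            cmpr.shared_og_pairs, columns=["gene_a", "gene_b", "og_id"]
        ).to_csv(outdir / "comparison.tsv", sep="\t", index=False)
        return cmpr

    network = None
    if cfg.focal_gene_a and cfg.focal_gene_b:
        network = _stage("network", s_network, "orthology", "profiles_a", "profiles_b")

    # --- final report
    def s_report():
        ogs, table, _ = orth
        og_of = {}
        for og in ogs:
            for sp, genes in og.members.items():
                for g in genes:
                    og_of[g] = og.og_id
        by_og = table.set_index("og_id")
        reg_by_gene: dict[str, list[str]] = {}
        for l in links or []:
            reg_by_gene.setdefault(l.target_gene, []).append(
                f"{l.kind}:{l.regulator_id}"
            )
        net_genes = set()
        if network is not None:
            net_genes = (
                {p[0] for p in network.shared_og_pairs}
                | {p[1] for p in network.shared_og_pairs}
                | network.specific_a
                | network.specific_b
            )
        rows = []
        for sp, prof in ((cfg.species_a, prof_a), (cfg.species_b, prof_b)):
            _, profiles, asn = prof
            trend_of = {p.id: ep.classify_trend(p) for p in profiles}
            for g in sorted(cands[sp]):
                og_id = og_of.get(g, "")
                og_row = by_og.loc[og_id] if og_id in by_og.index else None
                pid = asn.gene_profile.get(g)
                rows.append(
                    {
                        "gene": g,
                        "species": sp,
                        "og_id": og_id,
                        "og_class": og_row["class"] if og_row is not None else "",
                        "rcn_a": og_row["rcn_a"] if og_row is not None else "",
                        "rcn_b": og_row["rcn_b"] if og_row is not None else "",
                        "divergent": bool(og_row["divergent"])
                        if og_row is not None
                        else False,
                        "profile": pid if pid is not None else "",
                        "trend": trend_of.get(pid, "") if pid is not None else "",
                        "profile_p": asn.p_value.get(pid, "")
                        if pid is not None
                        else "",
                        "regulators": ";".join(sorted(reg_by_gene.get(g, []))),
                        "in_network": g in net_genes,
                    }
                )
        report = pd.DataFrame(rows)
        report.to_csv(outdir / "report.tsv", sep="\t", index=False)
        return report

    report = _stage("report", s_report, "orthology", "candidates")
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    if report is None:
        raise RuntimeError(
            f"pipeline could not produce a report; failed stages: {sorted(state.failed)}"
        )
    return report
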