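"""Two-species synthetic fixtures with known ground truth.

Emulates the study design the pipeline targets: a diploid low-oil species
("gma"-like) against a tetraploid high-oil species ("bna"-like), ~4 matched
developmental stages, RPKM-like non-negative expression with planted
temporal-profile structure, planted copy-number-divergent families, planted
miRNA target sites, and codon alignments evolved under planted selective
regimes. Every generator records what it planted in a :class:`GroundTruth`
so each downstream stage has a parameter-recovery test.

Defaults mirror the study conditions: ploidies 2 and 4, four stages, 20% of
families copy-number divergent, log2-scale Gaussian expression noise of 0.2.
All outputs are deterministic functions of the seed (byte-identical files).
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .expression_profiles import ModelProfile, generate_model_profiles

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_species_pair",
    "simulate_expression",
    "simulate_mirna_targets",
    "simulate_codon_alignment",
    "write_fixtures",
]

_RNA = "ACGU"
_DNA = "ACGT"
_DNA_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
# reverse complement of an RNA base, written in DNA (for target transcripts)
_RNA_TO_DNA_COMP = {"A": "T", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; same seed implies byte-identical outputs."""

    seed: int = 0
    species_a: str = "gma"
    species_b: str = "bna"
    ploidy_a: int = 2
    ploidy_b: int = 4
    n_ogs: int = 100
    frac_divergent: float = 0.2
    frac_specific: float = 0.25  # of the divergent OGs: absent in one species
    n_stages: int = 4
    noise_sd: float = 0.2
    genes_per_profile: int = 200
    n_profiles: int = 20
    n_planted_profiles: int = 10  # non-flat profiles carrying planted genes
    profile_change_unit: int = 1  # c: max unit change per stage step
    n_planted_targets: int = 5
    n_mirnas: int = 5
    mirna_length: int = 20
    transcript_length: int = 500
    site_mismatches: int = 1
    site_wobbles: int = 1
    n_codons: int = 300

    def __post_init__(self) -> None:
        if self.ploidy_a < 1 or self.ploidy_b < 1:
            raise ValueError("ploidies must be >= 1")
        if not 0 <= self.frac_divergent <= 1:
            raise ValueError("frac_divergent must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_stages < 3:
            raise ValueError("need at least 3 stages")
        if self.profile_change_unit < 1:
            raise ValueError("profile_change_unit must be a positive integer")


@dataclass
class GroundTruth:
    """What the generators planted, for parameter-recovery tests."""

    divergent_og_ids: set[str] = field(default_factory=set)
    gene_profile_labels: dict[str, int] = field(default_factory=dict)
    true_target_sites: list[tuple[str, str, int, int]] = field(default_factory=list)
    branch_omega_labels: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "divergent_og_ids": sorted(self.divergent_og_ids),
            "gene_profile_labels": dict(sorted(self.gene_profile_labels.items())),
            "true_target_sites": [list(t) for t in self.true_target_sites],
            "branch_omega_labels": dict(sorted(self.branch_omega_labels.items())),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _zt_geometric(rng: np.random.Generator, n: int, mean: float = 2.0) -> np.ndarray:
    """Zero-truncated geometric copy counts (support >= 1)."""
    return rng.geometric(p=1.0 / mean, size=n)


def simulate_species_pair(
    cfg: SimConfig, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], GroundTruth]:
    """Draw per-OG copy counts for the two species.

    Per-haploid family size is zero-truncated geometric (mean 2); raw counts
    are per-haploid size times ploidy, so non-divergent OGs have equal
    relative copy number by construction. A planted fraction is divergent:
    either species-specific (one count zero) or with a >= 2-fold relative
    copy-number ratio.
    """
    if cfg.n_ogs < 10:
        raise ValueError("need n_ogs >= 10")
    rng = np.random.default_rng(cfg.seed)
    truth = truth if truth is not None else GroundTruth()
    og_ids = [f"OG{i:05d}" for i in range(cfg.n_ogs)]
    n_div = int(round(cfg.frac_divergent * cfg.n_ogs))
    div_idx = set(rng.choice(cfg.n_ogs, size=n_div, replace=False).tolist())
    base = _zt_geometric(rng, cfg.n_ogs)

    rows = []
    gene_rows: dict[str, list[tuple[str, str]]] = {cfg.species_a: [], cfg.species_b: []}
    for i, og_id in enumerate(og_ids):
        m = int(base[i])
        ca, cb = m * cfg.ploidy_a, m * cfg.ploidy_b
        if i in div_idx:
            truth.divergent_og_ids.add(og_id)
            expand_b = bool(rng.integers(0, 2))
            if rng.random() < cfg.frac_specific:
                if expand_b:
                    ca = 0
                else:
                    cb = 0
            else:
                factor = int(rng.integers(2, 5))
                if expand_b:
                    cb = m * factor * cfg.ploidy_b
                else:
                    ca = m * factor * cfg.ploidy_a
        for sp, count in ((cfg.species_a, ca), (cfg.species_b, cb)):
            for k in range(count):
                gene = f"{sp}_{og_id}_g{k + 1}"
                rows.append((og_id, sp, gene))
                gene_rows[sp].append((gene, og_id))

    og_table = pd.DataFrame(rows, columns=["og_id", "species", "gene_id"])
    gene_tables = {
        sp: pd.DataFrame(v, columns=["gene_id", "og_id"]) for sp, v in gene_rows.items()
    }
    return og_table, gene_tables, truth


def simulate_expression(
    cfg: SimConfig,
    profiles: list[ModelProfile] | None = None,
    gene_ids: list[str] | None = None,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """RPKM-like stage series with planted temporal profiles.

    Each gene gets a profile label drawn from the ``n_planted_profiles``
    most spread-out non-flat profiles (a flat profile carries no recoverable
    temporal signal; planting on a few well-separated shapes keeps >= 200
    genes per planted profile at the default scale) and a positive
    per-gene baseline; its series is ``baseline * 2**(shape + noise)`` with
    Gaussian log2-scale noise, hence strictly positive values and, at zero
    noise, an exact log-ratio transform back to the planted shape.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    truth = truth if truth is not None else GroundTruth()
    if profiles is None:
        profiles = generate_model_profiles(
            cfg.n_stages, cfg.profile_change_unit, cfg.n_profiles
        )
    plantable = [p for p in profiles if len(set(p.shape)) > 1]
    if not plantable:
        raise ValueError("no non-flat profile to plant")
    plantable = plantable[: cfg.n_planted_profiles]
    if gene_ids is None:
        gene_ids = [
            f"gene{i:05d}" for i in range(cfg.genes_per_profile * len(plantable))
        ]
    labels = [plantable[i % len(plantable)].id for i in range(len(gene_ids))]
    shape_by_id = {p.id: np.asarray(p.shape, dtype=float) for p in plantable}

    baselines = 2.0 ** rng.normal(3.0, 1.5, size=len(gene_ids))
    noise = rng.normal(0.0, cfg.noise_sd, size=(len(gene_ids), cfg.n_stages))
    values = np.empty((len(gene_ids), cfg.n_stages))
    for row, (gene, lab, b) in enumerate(zip(gene_ids, labels, baselines)):
        values[row] = b * 2.0 ** (shape_by_id[lab] + noise[row])
        truth.gene_profile_labels[gene] = lab
    m = pd.DataFrame(
        values, index=pd.Index(gene_ids, name="gene"),
        columns=[f"t{i + 1}" for i in range(cfg.n_stages)],
    )
    return m, truth


def _random_seq(rng: np.random.Generator, n: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def _plant_site(
    rng: np.random.Generator, mirna: str, n_mismatches: int, n_wobbles: int
) -> str:
    """Perfect-complement DNA site for ``mirna`` with mutations planted
    outside the seed region (miRNA positions 2-7).

    The site is the reverse complement (target 5'->3'); a mismatch replaces
    the paired base with a non-pairing one, a wobble turns a G:C/U:A pair
    into G:U (only miRNA G/U positions can host one).
    """
    L = len(mirna)
    site = [_RNA_TO_DNA_COMP[b] for b in reversed(mirna)]  # 5'->3' DNA

    def target_index(mirna_pos: int) -> int:
        return L - mirna_pos  # 0-based index into site

    non_seed = [p for p in range(1, L + 1) if p not in range(2, 8)]
    wobblable = [p for p in non_seed if mirna[p - 1] in "GU"]
    rng.shuffle(wobblable)
    wob = wobblable[:n_wobbles]
    rest = [p for p in non_seed if p not in wob]
    rng.shuffle(rest)
    mis = rest[:n_mismatches]
    for p in wob:
        site[target_index(p)] = "T" if mirna[p - 1] == "G" else "G"
    for p in mis:
        mb = mirna[p - 1]
        # pick a target base that neither pairs nor wobbles with mb
        forbidden = {_RNA_TO_DNA_COMP[mb]}
        if mb == "G":
            forbidden.add("T")
        if mb == "U":
            forbidden.add("G")
        choices = [b for b in _DNA if b not in forbidden]
        site[target_index(p)] = choices[rng.integers(0, len(choices))]
    return "".join(site)


def simulate_mirna_targets(
    cfg: SimConfig, truth: GroundTruth | None = None
) -> tuple[dict[str, str], dict[str, str], GroundTruth]:
    """Random miRNAs (RNA) and transcripts (DNA) with planted target sites.

    Each planted transcript embeds one near-complementary site at a recorded
    1-based coordinate; flanking sequence is random.
    """
    if cfg.n_planted_targets < 1:
        raise ValueError("need n_planted_targets >= 1")
    rng = np.random.default_rng(cfg.seed + 2)
    truth = truth if truth is not None else GroundTruth()
    mirnas = {
        f"mir{i + 1:03d}": _random_seq(rng, cfg.mirna_length, _RNA)
        for i in range(cfg.n_mirnas)
    }
    transcripts: dict[str, str] = {}
    mirna_ids = sorted(mirnas)
    for t in range(cfg.n_planted_targets):
        mid = mirna_ids[t % len(mirna_ids)]
        tid = f"tx{t + 1:03d}"
        site = _plant_site(rng, mirnas[mid], cfg.site_mismatches, cfg.site_wobbles)
        start0 = int(rng.integers(0, cfg.transcript_length - len(site) + 1))
        seq = list(_random_seq(rng, cfg.transcript_length, _DNA))
        seq[start0 : start0 + len(site)] = site
        transcripts[tid] = "".join(seq)
        truth.true_target_sites.append((mid, tid, start0 + 1, start0 + len(site)))
    return mirnas, transcripts, truth


# ---------------------------------------------------------------------------
# Codon-alignment simulation under planted omega regimes

_STOP_DNA = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    {a + b + c for a in _DNA for b in _DNA for c in _DNA} - _STOP_DNA
)
_AA = {}
try:  # translation table for synonymy checks
    from Bio.Data.CodonTable import standard_dna_table

    _AA = dict(standard_dna_table.forward_table)
except ImportError:  # pragma: no cover
    raise


def _evolve(
    rng: np.random.Generator, codons: list[str], branch_len: float, omega: float
) -> list[str]:
    """Propose point mutations at neutral rate; thin acceptances so the
    nonsynonymous:synonymous acceptance ratio equals omega. Stops rejected."""
    codons = list(codons)
    n_sites = 3 * len(codons)
    p_syn = min(1.0, 1.0 / omega)
    p_non = min(1.0, omega)
    n_events = rng.poisson(branch_len * n_sites)
    for _ in range(n_events):
        ci = int(rng.integers(0, len(codons)))
        pos = int(rng.integers(0, 3))
        old = codons[ci]
        alt = _DNA[int(rng.integers(0, 4))]
        if alt == old[pos]:
            continue
        new = old[:pos] + alt + old[pos + 1 :]
        if new in _STOP_DNA:
            continue
        accept = p_syn if _AA[new] == _AA[old] else p_non
        if rng.random() < accept:
            codons[ci] = new
    return codons


def simulate_codon_alignment(
    cfg: SimConfig,
    tree_newick: str,
    omega_by_branch: dict[str, float] | None = None,
    default_omega: float = 1.0,
    truth: GroundTruth | None = None,
) -> tuple[dict[str, str], GroundTruth]:
    """Evolve in-frame codon sequences along a tree with branch-wise omega.

    Branch lengths are expected neutral substitutions per nucleotide site;
    ``omega_by_branch`` maps node names to omega (unnamed branches use
    ``default_omega``). No indels, so the tip sequences are an alignment;
    no in-frame stops are ever introduced.
    """
    if omega_by_branch is None:
        omega_by_branch = {}
    if any(w <= 0 for w in omega_by_branch.values()) or default_omega <= 0:
        raise ValueError("omega values must be > 0")
    tree = TreeNode.read(io.StringIO(tree_newick))
    if tree.count(tips=True) < 3:
        raise ValueError("tree must have at least 3 taxa")
    rng = np.random.default_rng(cfg.seed + 3)
    truth = truth if truth is not None else GroundTruth()
    root_codons = [
        _SENSE_CODONS[i]
        for i in rng.integers(0, len(_SENSE_CODONS), size=cfg.n_codons)
    ]
    out: dict[str, str] = {}

    def _walk(node: TreeNode, codons: list[str]) -> None:
        for child in node.children:
            omega = omega_by_branch.get(child.name, default_omega)
            if child.name:
                truth.branch_omega_labels[child.name] = omega
            bl = child.length or 0.0
            child_codons = _evolve(rng, codons, bl, omega)
            if child.is_tip():
                out[child.name] = "".join(child_codons)
            else:
                _walk(child, child_codons)

    _walk(tree, root_codons)
    return out, truth


# ---------------------------------------------------------------------------
# Fixture writing


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n{seqs[name]}\n")


def write_fixtures(
    cfg: SimConfig,
    outdir: str | Path,
    tree_newick: str = "((A:0.05,B:0.05):0.02,(C:0.05,D:0.05):0.02);",
    omega_by_branch: dict[str, float] | None = None,
) -> GroundTruth:
    """Generate and write the complete two-species fixture set.

    Writes og_table.tsv, expr_<species>.tsv, mirna.fasta, transcripts.fasta,
    codon_aln.fasta, tree.nwk and truth.json into ``outdir``. Expression is
    generated for the genes of each species' OG table so downstream joins
    close over the same universe.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = GroundTruth()
    og_table, gene_tables, truth = simulate_species_pair(cfg, truth)
    og_table.to_csv(outdir / "og_table.tsv", sep="\t", index=False)
    profiles = generate_model_profiles(
        cfg.n_stages, cfg.profile_change_unit, cfg.n_profiles
    )
    for k, sp in enumerate((cfg.species_a, cfg.species_b)):
        genes = gene_tables[sp]["gene_id"].tolist()
        sub = dataclasses.replace(cfg, seed=cfg.seed + 10 + k)
        m, truth = simulate_expression(sub, profiles, gene_ids=genes, truth=truth)
        m.to_csv(outdir / f"expr_{sp}.tsv", sep="\t")
    mirnas, transcripts, truth = simulate_mirna_targets(cfg, truth)
    _write_fasta(mirnas, outdir / "mirna.fasta")
    _write_fasta(transcripts, outdir / "transcripts.fasta")
    aln, truth = simulate_codon_alignment(
        cfg, tree_newick, omega_by_branch, truth=truth
    )
    _write_fasta(aln, outdir / "codon_aln.fasta")
    (outdir / "tree.nwk").write_text(tree_newick.strip() + "\n")
    (outdir / "truth.json").write_text(truth.to_json() + "\n")
    return truth
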