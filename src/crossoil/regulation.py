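"""miRNA target-site scoring and TF/miRNA regulatory overlay.

Plant miRNAs pair near-perfectly with their targets, so candidate sites are
found by scanning transcripts for antiparallel complementarity to the miRNA
and scoring each duplex with a penalty total — the *expectation* score
(psRNATarget-style; lower = stronger). Per miRNA position, counted from the
miRNA 5' end:

* Watson-Crick pair          0
* G:U wobble                 0.5
* mismatch                   1
* gap (unpaired miRNA base)  2
* non-gap penalties are doubled in the seed region, miRNA positions 2-7

The predicted inhibition mode follows pairing at the duplex center: a
mismatch or gap anywhere in miRNA positions 9-11 blocks slicing, giving
translational repression; otherwise cleavage. Target accessibility (UPE) is
an upstream-supplied annotation carried through, not computed here.

TF-target pair tables are joined onto candidate genes to complete the
regulatory overlay.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "DuplexAlignment",
    "RegulatorLink",
    "score_duplex",
    "call_inhibition",
    "scan_transcript",
    "join_regulators",
    "read_fasta",
    "targets_table",
]

MATCH, WOBBLE, MISMATCH, GAP = "match", "wobble", "mismatch", "gap"
_PENALTY = {MATCH: 0.0, WOBBLE: 0.5, MISMATCH: 1.0, GAP: 2.0}
SEED_REGION = range(2, 8)  # miRNA positions 2-7, 1-based

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLES = {("G", "U"), ("U", "G")}


def _rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU-")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    return s


def _pair_state(mirna_base: str, target_base: str) -> str:
    if target_base == "-":
        return GAP
    pair = (mirna_base, target_base)
    if pair in _PAIRS:
        return MATCH
    if pair in _WOBBLES:
        return WOBBLE
    return MISMATCH


@dataclass
class DuplexAlignment:
    """One miRNA:target pairing with per-position states and total penalty.

    ``mirna_fragment`` is the miRNA 5'->3'; ``target_fragment`` is the target
    site 5'->3' (may contain '-'), so miRNA position 1 pairs with the LAST
    character of the target fragment (antiparallel). Coordinates are 1-based
    inclusive.
    """

    mirna_id: str
    target_id: str
    mirna_fragment: str
    target_fragment: str
    pair_states: tuple[str, ...]
    expectation: float
    mirna_start: int = 1
    mirna_end: int = 0
    target_start: int = 0
    target_end: int = 0
    upe: float | None = None
    inhibition: str = ""


def score_duplex(
    mirna: str,
    target_window: str,
    allow_gap: bool = False,
    mirna_id: str = "",
    target_id: str = "",
) -> DuplexAlignment:
    """Score one duplex; both sequences 5'->3', U/T equivalent.

    The window must have the miRNA's length (ungapped) or one base fewer
    with ``allow_gap``, in which case the best single-gap placement is taken
    (gap penalty is not seed-doubled; at most one gap per duplex).
    """
    mi = _rna(mirna)
    tw = _rna(target_window)
    if "-" in mi or "-" in tw:
        raise ValueError("input sequences must be ungapped")
    L = len(mi)
    if len(tw) == L:
        candidates = [tw]
    elif allow_gap and len(tw) == L - 1:
        # '-' at aligned column c (5'->3') leaves miRNA position L-c+1 unpaired
        candidates = [tw[:c] + "-" + tw[c:] for c in range(L)]
    else:
        raise ValueError(
            f"target window length {len(tw)} incompatible with miRNA length {L}"
        )
    best: DuplexAlignment | None = None
    for aligned in candidates:
        states = []
        total = 0.0
        for pos in range(1, L + 1):  # miRNA position, 1-based from 5'
            st = _pair_state(mi[pos - 1], aligned[L - pos])
            pen = _PENALTY[st]
            if pos in SEED_REGION and st != GAP:
                pen *= 2.0
            states.append(st)
            total += pen
        if best is None or total < best.expectation:
            best = DuplexAlignment(
                mirna_id=mirna_id,
                target_id=target_id,
                mirna_fragment=mi,
                target_fragment=aligned,
                pair_states=tuple(states),
                expectation=total,
                mirna_start=1,
                mirna_end=L,
            )
    best.inhibition = call_inhibition(best)
    return best


def call_inhibition(d: DuplexAlignment) -> str:
    """Cleavage needs pairing across the slicing center (miRNA 9-11)."""
    center = d.pair_states[8:11]  # positions 9-11
    if any(s in (MISMATCH, GAP) for s in center):
        return "Translation"
    return "Cleavage"


def scan_transcript(
    mirna: str,
    transcript: str,
    max_expectation: float = 3.0,
    allow_gap: bool = True,
    mirna_id: str = "",
    target_id: str = "",
) -> list[DuplexAlignment]:
    """All target windows scoring <= ``max_expectation``.

    Evaluates every window of the miRNA's length and, with ``allow_gap``,
    every window one base shorter (best single-gap variant). Hits are sorted
    by expectation then target start; coordinates are 1-based inclusive on
    the transcript.
    """
    mi = _rna(mirna)
    tr = _rna(transcript)
    L = len(mi)
    hits: list[DuplexAlignment] = []
    lengths = [L] + ([L - 1] if allow_gap and L > 1 else [])
    for wlen in lengths:
        for start0 in range(0, len(tr) - wlen + 1):
            window = tr[start0 : start0 + wlen]
            d = score_duplex(
                mi, window, allow_gap=(wlen == L - 1),
                mirna_id=mirna_id, target_id=target_id,
            )
            if d.expectation <= max_expectation:
                d.target_start = start0 + 1
                d.target_end = start0 + wlen
                hits.append(d)
    hits.sort(key=lambda d: (d.expectation, d.target_start))
    return hits


@dataclass(frozen=True)
class RegulatorLink:
    regulator_id: str
    target_gene: str
    kind: str  # 'tf' or 'mirna'
    evidence: str = ""


def join_regulators(
    candidates: set[str],
    tf_pairs: pd.DataFrame | None = None,
    mirna_hits: pd.DataFrame | None = None,
) -> list[RegulatorLink]:
    """Regulator links whose target is a candidate gene (deduplicated).

    ``tf_pairs`` needs columns (tf_id, target_id); ``mirna_hits`` needs
    (mirna_id, target_id) and optionally expectation/inhibition evidence.
    """
    links: dict[tuple[str, str, str], RegulatorLink] = {}
    if tf_pairs is not None:
        for row in tf_pairs.itertuples(index=False):
            if row.target_id in candidates:
                key = (row.tf_id, row.target_id, "tf")
                links.setdefault(key, RegulatorLink(row.tf_id, row.target_id, "tf"))
    if mirna_hits is not None:
        for row in mirna_hits.itertuples(index=False):
            if row.target_id in candidates:
                ev = ""
                if hasattr(row, "expectation"):
                    ev = f"expectation={row.expectation:g}"
                key = (row.mirna_id, row.target_id, "mirna")
                links.setdefault(
                    key, RegulatorLink(row.mirna_id, row.target_id, "mirna", ev)
                )
    return sorted(links.values(), key=lambda l: (l.kind, l.regulator_id, l.target_gene))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def targets_table(hits: Iterable[DuplexAlignment]) -> pd.DataFrame:
    """Target predictions with the conventional column layout."""
    hits = list(hits)
    return pd.DataFrame(
        {
            "miRNA_Acc": [d.mirna_id for d in hits],
            "Target_Acc": [d.target_id for d in hits],
            "Expectation": [d.expectation for d in hits],
            "UPE": [d.upe for d in hits],
            "miRNA_start": [d.mirna_start for d in hits],
            "miRNA_end": [d.mirna_end for d in hits],
            "Target_start": [d.target_start for d in hits],
            "Target_end": [d.target_end for d in hits],
            "miRNA_aligned_fragment": [d.mirna_fragment for d in hits],
            "Target_aligned_fragment": [d.target_fragment for d in hits],
            "Inhibition": [d.inhibition for d in hits],
        }
    )
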