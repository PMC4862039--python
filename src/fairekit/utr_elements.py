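"""Detection of common UTR regulatory elements in mRNA-sense UTR sequences.

Three element classes are covered:

* uORF — an upstream open reading frame in the 5' UTR: an ATG with an
  in-frame stop codon (TAA/TAG/TGA) downstream within the UTR, total length
  at least ``min_codons`` codons including the stop. Overlapping uORFs are
  all reported.
* PAS — the polyadenylation signal hexamer AATAAA or ATTAAA in the 3' UTR.
* MBE — the Musashi-binding element, DNA consensus (A/G)T{1,3}AGT, in the
  3' UTR; overlapping matches are reported greedily left-to-right.

Sequences are DNA in mRNA sense (the transcribed strand read 5'→3').
uORFs are only ever reported for 5' UTRs, PAS and MBE only for 3' UTRs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

STOP_CODONS = ("TAA", "TAG", "TGA")
PAS_HEXAMERS = ("AATAAA", "ATTAAA")
MBE_PATTERN = re.compile(r"[AG]T{1,3}AGT")
DEFAULT_MIN_CODONS = 2


@dataclass(frozen=True)
class UtrElementHit:
    gene_id: str
    utr_side: str  # five_prime | three_prime
    element: str  # uORF | PAS | MBE
    start: int  # offset within the UTR sequence
    end: int  # exclusive

    def __post_init__(self) -> None:
        if self.utr_side not in (FIVE_PRIME, THREE_PRIME):
            raise ValueError(f"bad utr_side {self.utr_side!r}")
        if self.element == "uORF" and self.utr_side != FIVE_PRIME:
            raise ValueError("uORF hits are restricted to 5' UTRs")
        if self.element in ("PAS", "MBE") and self.utr_side != THREE_PRIME:
            raise ValueError(f"{self.element} hits are restricted to 3' UTRs")
        if not (0 <= self.start < self.end):
            raise ValueError("invalid hit span")


def detect_uorf(utr5_seq: str, gene_id: str = "",
                min_codons: int = DEFAULT_MIN_CODONS) -> list[UtrElementHit]:
    """All upstream ORFs in a 5' UTR sequence.

    Each ATG is extended in frame to the first stop codon within the UTR;
    ORFs shorter than ``min_codons`` codons (stop included) are dropped.
    """
    seq = utr5_seq.upper()
    hits = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            codon = seq[j : j + 3]
            if codon in STOP_CODONS:
                n_codons = (j + 3 - i) // 3
                if n_codons >= min_codons:
                    hits.append(UtrElementHit(gene_id, FIVE_PRIME, "uORF", i, j + 3))
                break
    return hits


def detect_pas(utr3_seq: str, gene_id: str = "") -> list[UtrElementHit]:
    """Every polyadenylation-signal hexamer occurrence in a 3' UTR."""
    seq = utr3_seq.upper()
    hits = []
    for i in range(len(seq) - 5):
        if seq[i : i + 6] in PAS_HEXAMERS:
            hits.append(UtrElementHit(gene_id, THREE_PRIME, "PAS", i, i + 6))
    return hits


def detect_mbe(utr3_seq: str, gene_id: str = "") -> list[UtrElementHit]:
    """Musashi-binding elements, consensus (A/G)T{1,3}AGT, greedy
    left-to-right with overlaps allowed (one hit per start position)."""
    seq = utr3_seq.upper()
    hits = []
    pos = 0
    while pos < len(seq):
        m = MBE_PATTERN.match(seq, pos)
        if m is not None:
            hits.append(UtrElementHit(gene_id, THREE_PRIME, "MBE", m.start(), m.end()))
        pos += 1
    return hits


def scan_utr_sequences(
    utr5_seqs: dict[str, str],
    utr3_seqs: dict[str, str],
    min_codons: int = DEFAULT_MIN_CODONS,
) -> list[UtrElementHit]:
    """Run all detectors over gene-keyed 5' and 3' UTR sequence dicts."""
    hits: list[UtrElementHit] = []
    for gene_id in sorted(utr5_seqs):
        hits.extend(detect_uorf(utr5_seqs[gene_id], gene_id, min_codons))
    for gene_id in sorted(utr3_seqs):
        hits.extend(detect_pas(utr3_seqs[gene_id], gene_id))
        hits.extend(detect_mbe(utr3_seqs[gene_id], gene_id))
    return hits


def extract_utr_sequences(genes, genome: dict[str, str], side: str,
                          restrict=None, clip_to=None) -> dict[str, str]:
    """mRNA-sense UTR sequences keyed by gene id.

    UTR spans are concatenated in genomic order and reverse-complemented for
    minus-strand genes. ``restrict`` limits output to the given gene ids.
    ``clip_to`` (peak-restricted mode) maps gene ids to lists of intervals —
    typically the peaks linked to that gene — and intersects the UTR spans
    with them, so only the peak-overlapped UTR portion is scanned.
    """
    from .motif_enrichment import reverse_complement

    if side not in (FIVE_PRIME, THREE_PRIME):
        raise ValueError(f"bad side {side!r}")
    out: dict[str, str] = {}
    for gene in genes:
        if restrict is not None and gene.gene_id not in restrict:
            continue
        spans = gene.utr5 if side == FIVE_PRIME else gene.utr3
        if clip_to is not None:
            windows = clip_to.get(gene.gene_id, [])
            clipped = []
            for s in spans:
                for w in windows:
                    lo, hi = max(s.start, w.start), min(s.end, w.end)
                    if w.contig == s.contig and lo < hi:
                        clipped.append(type(s)(s.contig, lo, hi, s.strand))
            spans = clipped
        if not spans:
            continue
        seq = "".join(
            genome[s.contig][s.start : s.end]
            for s in sorted(spans, key=lambda s: s.start)
        )
        if gene.strand == "-":
            seq = reverse_complement(seq)
        out[gene.gene_id] = seq
    return out


def summarize_utr_elements(hits: Iterable[UtrElementHit]) -> pd.DataFrame:
    """Rank-ordered element frequency table with proportions summing to 1.

    Descending count; ties broken by element name. Empty input yields an
    empty table.
    """
    counts: dict[str, int] = {}
    for hit in hits:
        counts[hit.element] = counts.get(hit.element, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["element", "count", "proportion"])
    total = sum(counts.values())
    rows = [
        {"element": el, "count": n, "proportion": n / total}
        for el, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["element", "count", "proportion"])


def hits_table(hits: Sequence[UtrElementHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "utr_side": h.utr_side,
                "element": h.element,
                "start": h.start,
                "end": h.end,
            }
            for h in hits
        ],
        columns=["gene_id", "utr_side", "element", "start", "end"],
    )
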