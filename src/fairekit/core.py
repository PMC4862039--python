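"""Core domain types shared across the pipeline.

All internal coordinates are 0-based, half-open ``[start, end)``. Conversion
from 1-based conventions (GFF3, VCF, printed supercontig ranges) happens only
in readers/writers, never downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

STRANDS = ("+", "-", ".")

BIOTYPES = ("protein_coding", "tRNA", "rRNA", "snRNA", "miRNA", "other_ncRNA")
NCRNA_BIOTYPES = ("tRNA", "rRNA", "snRNA", "miRNA", "other_ncRNA")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contig-scoped half-open coordinate span, optionally stranded.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``strand`` is ``+``,
    ``-`` or ``.`` (unstranded).
    """

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValidationError("interval contig must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        """True if the 0-based ``position`` lies inside the span."""
        return self.start <= position < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class FairePeak:
    """One open-chromatin interval (a FAIRE peak, "FP")."""

    peak_id: str
    interval: GenomicInterval
    enrichment_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.enrichment_p is not None and not (0.0 <= self.enrichment_p <= 1.0):
            raise ValidationError(
                f"peak {self.peak_id}: enrichment_p {self.enrichment_p} not in [0, 1]"
            )


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant; position is 1-based as in the source VCF."""

    contig: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"variant position {self.position} must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValidationError("variant ref and alt alleles must differ")

    @property
    def position0(self) -> int:
        """0-based position, the internal coordinate convention."""
        return self.position - 1


@dataclass
class GeneModel:
    """A gene with biotype, strand, TSS, exon structure and UTR spans.

    The TSS is the strand-appropriate terminus of the gene interval: the
    first base (``start``) of a + strand gene, the last base (``end - 1``)
    of a - strand gene.
    """

    gene_id: str
    biotype: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"gene {self.gene_id}: unknown biotype {self.biotype!r}"
            )
        if self.interval.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: gene must be stranded")
        if not self.exons:
            # Single-exon model spanning the whole gene.
            self.exons = [self.interval]
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for exon in self.exons:
            if not self.interval.contains_interval(exon):
                raise ValidationError(
                    f"gene {self.gene_id}: exon [{exon.start}, {exon.end}) "
                    "outside gene span"
                )
            if prev_end is not None and exon.start < prev_end:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons")
            prev_end = exon.end

    @property
    def contig(self) -> str:
        return self.interval.contig

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """0-based TSS position."""
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def is_noncoding(self) -> bool:
        return self.biotype != "protein_coding"

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, as intervals."""
        out = []
        for left, right in zip(self.exons, self.exons[1:]):
            if right.start > left.end:
                out.append(
                    GenomicInterval(self.contig, left.end, right.start, self.strand)
                )
        return out


PWM_PSEUDOCOUNT_DEFAULT = 0.01


class PWM:
    """A position frequency/weight matrix over {A, C, G, T}.

    ``counts`` is a (length, 4) array of counts or probabilities in A, C, G,
    T order. Probabilities are obtained by adding ``pseudocount`` times the
    position total to each cell and renormalizing, so each position's
    probabilities sum to 1 and are strictly positive.
    """

    BASES = "ACGT"

    def __init__(self, motif_id: str, counts, pseudocount: float = PWM_PSEUDOCOUNT_DEFAULT):
        import numpy as np

        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
            raise ValidationError(
                f"PWM {motif_id}: counts must be (length >= 1) x 4, got {counts.shape}"
            )
        if (counts < 0).any():
            raise ValidationError(f"PWM {motif_id}: negative counts")
        if pseudocount < 0:
            raise ValidationError(f"PWM {motif_id}: negative pseudocount")
        self.motif_id = motif_id
        self.counts = counts
        self.pseudocount = float(pseudocount)
        totals = counts.sum(axis=1)
        if (totals <= 0).any() and pseudocount == 0:
            raise ValidationError(f"PWM {motif_id}: zero-total position with zero pseudocount")
        # pseudocount is a fraction of each position's total, added per base;
        # positions with zero total fall back to a unit total.
        eff_totals = np.where(totals > 0, totals, 1.0)
        padded = counts + self.pseudocount * eff_totals[:, None]
        self.probs = padded / padded.sum(axis=1, keepdims=True)

    def __len__(self) -> int:
        return self.counts.shape[0]

    def __repr__(self) -> str:
        return f"PWM({self.motif_id!r}, length={len(self)})"

    def consensus(self) -> str:
        """Highest-probability base at each position."""
        return "".join(self.BASES[i] for i in self.probs.argmax(axis=1))


_PRINTED_RANGE = re.compile(
    r"^\s*(?P<contig>[^:\s]+)\s*:\s*(?P<start>[\d,]+)\s*[-–—]\s*(?P<end>[\d,]+)\s*$"
)


def parse_printed_range(text: str, strand: str = ".") -> GenomicInterval:
    """Parse a printed supercontig range like ``Supercont1.551:501192-503018``.

    Printed ranges are 1-based inclusive (the convention used for scaffold
    coordinates in genome-browser style listings); the result is converted to
    the internal 0-based half-open convention. En/em dashes and thousands
    separators are accepted so ranges can be quoted verbatim.
    """
    m = _PRINTED_RANGE.match(text)
    if m is None:
        raise ParseError(f"cannot parse printed range: {text!r}")
    start1 = int(m.group("start").replace(",", ""))
    end1 = int(m.group("end").replace(",", ""))
    return GenomicInterval(m.group("contig"), start1 - 1, end1, strand)
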