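"""Readers and writers for the standard formats the pipeline touches.

Every reader converts to the internal 0-based half-open convention at the
boundary: BED is already half-open (offset 0), GFF3 and VCF are 1-based
inclusive (start gets -1). Writers invert the conversion and emit
deterministic column and line order, so read -> write -> read is the
identity on the internal representation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np

from .core import (
    BIOTYPES,
    FairePeak,
    GeneModel,
    GenomicInterval,
    ParseError,
    PWM_PSEUDOCOUNT_DEFAULT,
    ValidationError,
    Variant,
)
from .core import PWM  # noqa: F401  (re-exported for callers)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# BED

def read_bed(path: PathLike, score_is_pvalue: bool = False) -> list[FairePeak]:
    """Read peaks from a BED3+ file.

    Column 4, when present, becomes the peak id (otherwise ``peak_<n>`` is
    assigned); column 5 becomes the enrichment p-value when
    ``score_is_pvalue`` is set.
    """
    peaks: list[FairePeak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: BED record needs >= 3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            peak_id = fields[3] if len(fields) > 3 and fields[3] != "." else f"peak_{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            enrichment_p: Optional[float] = None
            if score_is_pvalue and len(fields) > 4 and fields[4] not in (".", ""):
                enrichment_p = float(fields[4])
            peaks.append(
                FairePeak(peak_id, GenomicInterval(fields[0], start, end, strand), enrichment_p)
            )
    return peaks


def write_bed(peaks: Iterable[FairePeak], path: PathLike, score_is_pvalue: bool = False) -> None:
    """Write peaks as BED, preserving half-open coordinates verbatim."""
    with open(path, "w") as fh:
        for peak in peaks:
            iv = peak.interval
            fields = [iv.contig, str(iv.start), str(iv.end), peak.peak_id]
            if score_is_pvalue:
                fields.append("." if peak.enrichment_p is None else repr(peak.enrichment_p))
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_GENE_TYPES = {"gene", "ncRNA_gene", "pseudogene"}
_GFF_UTR5 = {"five_prime_UTR", "5'UTR"}
_GFF_UTR3 = {"three_prime_UTR", "3'UTR"}


def _gff_attributes(column: str) -> dict[str, str]:
    out = {}
    for item in column.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff(path: PathLike) -> list[GeneModel]:
    """Read gene models from GFF3.

    Genes, their exons and UTR spans are collected; mRNA features are
    transparent (children are attached to the enclosing gene). 1-based
    inclusive coordinates become 0-based half-open. Biotype comes from the
    ``biotype`` attribute, defaulting to protein_coding.
    """
    genes: dict[str, dict] = {}
    feature_to_gene: dict[str, str] = {}
    pending: list[tuple[int, str, GenomicInterval, str]] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF columns, got {len(fields)}")
            contig, _, ftype, start1, end1, _, strand, _, attrs_col = fields
            try:
                start0, end0 = int(start1) - 1, int(end1)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            attrs = _gff_attributes(attrs_col)
            interval = GenomicInterval(contig, start0, end0, strand if strand in "+-" else ".")

            if ftype in _GFF_GENE_TYPES:
                gene_id = attrs.get("ID")
                if not gene_id:
                    raise ParseError(f"{path}:{lineno}: gene feature without ID")
                biotype = attrs.get("biotype", "protein_coding")
                if biotype not in BIOTYPES:
                    biotype = "other_ncRNA" if ftype == "ncRNA_gene" else "protein_coding"
                genes[gene_id] = {
                    "biotype": biotype,
                    "interval": interval,
                    "exons": [],
                    "utr5": [],
                    "utr3": [],
                }
                feature_to_gene[gene_id] = gene_id
            elif ftype == "mRNA" or ftype.endswith("RNA") or ftype == "transcript":
                parent = attrs.get("Parent", "")
                own_id = attrs.get("ID")
                if own_id and parent in feature_to_gene:
                    feature_to_gene[own_id] = feature_to_gene[parent]
            elif ftype == "exon" or ftype in _GFF_UTR5 or ftype in _GFF_UTR3:
                parent = attrs.get("Parent", "")
                pending.append((lineno, ftype, interval, parent))

    for lineno, ftype, interval, parent in pending:
        gene_id = feature_to_gene.get(parent, parent)
        if gene_id not in genes:
            raise ParseError(f"{path}:{lineno}: {ftype} with unresolvable Parent {parent!r}")
        record = genes[gene_id]
        if not record["interval"].contains_interval(interval):
            raise ValidationError(
                f"{path}:{lineno}: {ftype} [{interval.start}, {interval.end}) "
                f"outside gene {gene_id} span"
            )
        key = "exons" if ftype == "exon" else ("utr5" if ftype in _GFF_UTR5 else "utr3")
        record[key].append(interval)

    models = []
    for gene_id, record in genes.items():
        # exon lists may repeat across isoforms in real GFF; deduplicate
        exons = sorted(set(record["exons"]), key=lambda e: e.start)
        models.append(
            GeneModel(
                gene_id=gene_id,
                biotype=record["biotype"],
                interval=record["interval"],
                exons=exons,
                utr5=sorted(set(record["utr5"]), key=lambda e: e.start),
                utr3=sorted(set(record["utr3"]), key=lambda e: e.start),
            )
        )
    models.sort(key=lambda g: (g.contig, g.interval.start, g.gene_id))
    return models


def write_gff(genes: Iterable[GeneModel], path: PathLike) -> None:
    """Write gene models as GFF3 (gene + exon + UTR features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(genes, key=lambda g: (g.contig, g.interval.start, g.gene_id)):
            iv = gene.interval
            fh.write(
                "\t".join(
                    [
                        iv.contig, "fairekit", "gene", str(iv.start + 1), str(iv.end),
                        ".", iv.strand, ".",
                        f"ID={gene.gene_id};biotype={gene.biotype}",
                    ]
                )
                + "\n"
            )
            for i, exon in enumerate(gene.exons, start=1):
                fh.write(
                    "\t".join(
                        [
                            exon.contig, "fairekit", "exon",
                            str(exon.start + 1), str(exon.end), ".", iv.strand, ".",
                            f"ID={gene.gene_id}.exon{i};Parent={gene.gene_id}",
                        ]
                    )
                    + "\n"
                )
            for ftype, spans in (("five_prime_UTR", gene.utr5), ("three_prime_UTR", gene.utr3)):
                for i, span in enumerate(spans, start=1):
                    fh.write(
                        "\t".join(
                            [
                                span.contig, "fairekit", ftype,
                                str(span.start + 1), str(span.end), ".", iv.strand, ".",
                                f"ID={gene.gene_id}.{ftype}{i};Parent={gene.gene_id}",
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: PathLike) -> list[Variant]:
    """Read SNP records from a VCF v4 text file.

    Indels and multi-allelic records are skipped (their count is logged);
    positions stay 1-based in the Variant type.
    """
    variants: list[Variant] = []
    n_skipped = 0
    saw_header = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if not line or line.startswith("#"):
                continue
            if not saw_header:
                raise ParseError(f"{path}:{lineno}: data before #CHROM header")
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected >= 5 VCF columns")
            contig, pos, _, ref, alt = fields[:5]
            if len(ref) != 1 or len(alt) != 1 or "," in alt or alt == ".":
                n_skipped += 1
                continue
            variants.append(Variant(contig, int(pos), ref, alt))
    if not saw_header:
        raise ParseError(f"{path}: missing #CHROM header line")
    if n_skipped:
        logger.info("read_vcf(%s): skipped %d non-SNP records", path, n_skipped)
    return variants


def write_vcf(variants: Iterable[Variant], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.contig, v.position)):
            fh.write(f"{v.contig}\t{v.position}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# JASPAR PFM

def read_jaspar(path: PathLike, pseudocount: float = PWM_PSEUDOCOUNT_DEFAULT) -> list["PWM"]:
    """Read motifs from JASPAR PFM text.

    Accepts both the classic 4-row count layout and the bracketed
    ``A [ 1 2 3 ]`` layout; counts are normalized to probabilities with the
    given pseudocount (a fraction of each position's total, added per base).
    """
    from .core import PWM

    motifs: list[PWM] = []
    current_id: Optional[str] = None
    rows: list[list[float]] = []

    def flush(lineno: int) -> None:
        nonlocal rows, current_id
        if current_id is None and not rows:
            return
        if len(rows) != 4:
            raise ParseError(f"{path}:{lineno}: motif {current_id!r} needs 4 base rows, got {len(rows)}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ParseError(f"{path}:{lineno}: motif {current_id!r} has rows of unequal length")
        counts = np.array(rows, dtype=float).T  # positions x ACGT
        motifs.append(PWM(current_id or f"motif_{len(motifs) + 1}", counts, pseudocount))
        rows, current_id = [], None

    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                current_id = line[1:].split()[0]
                continue
            body = line
            if body and body[0] in "ACGT" and ("[" in body or body[1:2].isspace()):
                body = body[1:]
            body = body.replace("[", " ").replace("]", " ")
            try:
                rows.append([float(tok) for tok in body.split()])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric PFM entry") from exc
        flush(lineno + 1)
    return motifs


def write_jaspar(motifs: Iterable["PWM"], path: PathLike) -> None:
    bases = "ACGT"
    with open(path, "w") as fh:
        for motif in motifs:
            fh.write(f">{motif.motif_id}\n")
            for b, base in enumerate(bases):
                row = " ".join(f"{motif.counts[p, b]:g}" for p in range(len(motif)))
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# FASTA (thin wrappers; pyfaidx serves random access on large genomes)

def read_fasta(path: PathLike) -> dict[str, str]:
    """Read an entire (small) FASTA file into an ordered dict of sequences."""
    seqs: dict[str, list[str]] = {}
    name: Optional[str] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise ParseError(f"{path}:{lineno}: duplicate sequence name {name!r}")
                seqs[name] = []
            elif name is None:
                raise ParseError(f"{path}:{lineno}: sequence data before header")
            else:
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(path: PathLike) -> list[tuple[GenomicInterval, float]]:
    """Read a bedGraph signal track (0-based half-open, like BED)."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
            out.append(
                (GenomicInterval(fields[0], int(fields[1]), int(fields[2])), float(fields[3]))
            )
    return out


def write_bedgraph(records: Iterable[tuple[GenomicInterval, float]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv, value in records:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Expression TSV

def read_expression(path: PathLike):
    """Read an expression table (columns gene_id, abundance) into a DataFrame."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "abundance"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expression table needs columns {sorted(required)}")
    if (df["abundance"] < 0).any():
        raise ValidationError(f"{path}: negative abundance values")
    return df


def write_expression(df, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
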