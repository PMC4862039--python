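"""Gene-centric classification of open-chromatin peaks.

Each peak is classified against every gene model it relates to. Within one
(peak, gene) pair the intragenic categories are mutually exclusive:

* ``exon_intron_boundary`` — the peak spans at least one splice junction of
  the gene (it covers bases on both sides of an exon/intron border);
* ``exonic`` — the peak lies fully inside one exon;
* ``intronic`` — the peak lies fully inside one intron.

A peak that merely straddles a gene edge (part inside, part outside, no
junction spanned) earns none of the three; "intragenic" means within the
gene.

A peak that does not touch the gene body but lies within ``window_upstream``
bp upstream of the TSS (strand-aware) is ``upstream_1kb``; within the
proximal-promoter window around the TSS it is additionally
``proximal_promoter``; upstream of a non-coding gene it is additionally
``ncRNA_upstream_1kb``. Overlap with a UTR span adds ``five_utr`` /
``three_utr``. A peak with no relation to any gene is ``intergenic``, which
is exclusive of everything else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import FairePeak, GeneModel, GenomicInterval, NCRNA_BIOTYPES

CATEGORIES = (
    "proximal_promoter",
    "upstream_1kb",
    "five_utr",
    "three_utr",
    "exonic",
    "intronic",
    "exon_intron_boundary",
    "ncRNA_upstream_1kb",
    "intergenic",
)

INTRAGENIC = ("exonic", "intronic", "exon_intron_boundary")

DEFAULT_WINDOW_UPSTREAM = 1000
DEFAULT_PROMOTER_UPSTREAM = 250
DEFAULT_PROMOTER_DOWNSTREAM = 50


@dataclass
class PeakAnnotation:
    """Category assignment(s) for one peak.

    ``tss_distance`` is the signed distance to the nearest TSS on the peak's
    contig: 0 when the peak contains the TSS, negative when the peak lies on
    the gene's upstream side, positive downstream. ``None`` when no gene
    shares the contig.
    """

    peak_id: str
    categories: set[str] = field(default_factory=set)
    associated_genes: list[tuple[str, str]] = field(default_factory=list)
    tss_distance: Optional[int] = None
    nearest_gene: Optional[str] = None


def tss_distance(peak: FairePeak, gene: GeneModel) -> int:
    """Signed distance from peak to the gene's TSS.

    0 when the TSS lies within the peak; otherwise the base-to-base gap
    between the TSS and the nearest peak edge, negative when the peak is on
    the gene's upstream side (strand-aware), positive downstream.
    """
    iv = peak.interval
    if iv.contig != gene.contig:
        raise ValueError(
            f"peak {peak.peak_id} on {iv.contig} vs gene {gene.gene_id} on {gene.contig}"
        )
    tss = gene.tss
    if iv.contains(tss):
        return 0
    if iv.end <= tss:  # peak entirely left of the TSS
        gap = tss - (iv.end - 1)
        return -gap if gene.strand == "+" else gap
    gap = iv.start - tss  # peak entirely right of the TSS
    return gap if gene.strand == "+" else -gap


def _upstream_window(gene: GeneModel, upstream_bp: int, downstream_bp: int = 0
                     ) -> GenomicInterval:
    """Strand-aware window around the TSS: ``upstream_bp`` before it through
    ``downstream_bp`` after it (TSS base included on the downstream side)."""
    tss = gene.tss
    if gene.strand == "+":
        start, end = tss - upstream_bp, tss + downstream_bp + 1
    else:
        start, end = tss - downstream_bp, tss + upstream_bp + 1
    return GenomicInterval(gene.contig, max(0, start), max(1, end), gene.strand)


def classify_peak(
    peak: FairePeak,
    genes: Sequence[GeneModel],
    window_upstream: int = DEFAULT_WINDOW_UPSTREAM,
    promoter_upstream: int = DEFAULT_PROMOTER_UPSTREAM,
    promoter_downstream: int = DEFAULT_PROMOTER_DOWNSTREAM,
) -> PeakAnnotation:
    """Classify one peak against the given gene models (same-contig genes
    are selected internally; others are ignored)."""
    if window_upstream <= 0:
        raise ValueError("window_upstream must be positive")
    ann = PeakAnnotation(peak_id=peak.peak_id)
    iv = peak.interval
    best: Optional[tuple[int, str, int]] = None  # (|distance|, gene_id, signed)

    for gene in genes:
        if gene.contig != iv.contig:
            continue
        dist = tss_distance(peak, gene)
        key = (abs(dist), gene.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (abs(dist), gene.gene_id, dist)

        related = False
        if iv.overlaps(gene.interval):
            junctions = []
            for intron in gene.introns():
                junctions.extend((intron.start, intron.end))
            spans_junction = any(iv.start < j < iv.end for j in junctions)
            if spans_junction:
                ann.categories.add("exon_intron_boundary")
                ann.associated_genes.append((gene.gene_id, "exon_intron_boundary"))
            elif any(e.contains_interval(iv) for e in gene.exons):
                ann.categories.add("exonic")
                ann.associated_genes.append((gene.gene_id, "exonic"))
            elif any(i.contains_interval(iv) for i in gene.introns()):
                ann.categories.add("intronic")
                ann.associated_genes.append((gene.gene_id, "intronic"))
            for span in gene.utr5:
                if iv.overlaps(span):
                    ann.categories.add("five_utr")
                    ann.associated_genes.append((gene.gene_id, "five_utr"))
                    break
            for span in gene.utr3:
                if iv.overlaps(span):
                    ann.categories.add("three_utr")
                    ann.associated_genes.append((gene.gene_id, "three_utr"))
                    break
            related = True
        else:
            # Strictly upstream relation: signed distance in [-window, 0).
            if -window_upstream <= dist < 0:
                ann.categories.add("upstream_1kb")
                ann.associated_genes.append((gene.gene_id, "upstream_1kb"))
                if gene.is_noncoding:
                    ann.categories.add("ncRNA_upstream_1kb")
                    ann.associated_genes.append((gene.gene_id, "ncRNA_upstream_1kb"))
                related = True

        # Proximal promoter: the peak touches the promoter window around the
        # TSS, whether or not it also overlaps the gene body.
        promoter = _upstream_window(gene, promoter_upstream, promoter_downstream)
        if iv.overlaps(promoter):
            ann.categories.add("proximal_promoter")
            ann.associated_genes.append((gene.gene_id, "proximal_promoter"))
            related = True

        del related  # relation tracked through associated_genes

    if not ann.categories:
        ann.categories.add("intergenic")
    if best is not None:
        ann.tss_distance = best[2]
        ann.nearest_gene = best[1]
    ann.associated_genes.sort()
    return ann


class GeneIndex:
    """Interval-tree index over gene models, padded so upstream windows are
    found by a single stab query."""

    def __init__(self, genes: Sequence[GeneModel], pad: int):
        self.genes = list(genes)
        self.pad = pad
        self.trees: dict[str, IntervalTree] = {}
        self.by_contig: dict[str, list[GeneModel]] = {}
        for gene in self.genes:
            self.by_contig.setdefault(gene.contig, []).append(gene)
            tree = self.trees.setdefault(gene.contig, IntervalTree())
            tree[max(0, gene.interval.start - pad) : gene.interval.end + pad] = gene

    def candidates(self, iv: GenomicInterval) -> list[GeneModel]:
        tree = self.trees.get(iv.contig)
        if tree is None:
            return []
        hits = [node.data for node in tree.overlap(iv.start, iv.end)]
        hits.sort(key=lambda g: (g.interval.start, g.gene_id))
        return hits

    def contig_genes(self, contig: str) -> list[GeneModel]:
        return self.by_contig.get(contig, [])


def annotate_peaks(
    peaks: Sequence[FairePeak],
    genes: Sequence[GeneModel],
    window_upstream: int = DEFAULT_WINDOW_UPSTREAM,
    promoter_upstream: int = DEFAULT_PROMOTER_UPSTREAM,
    promoter_downstream: int = DEFAULT_PROMOTER_DOWNSTREAM,
) -> tuple[list[PeakAnnotation], dict]:
    """Annotate every peak and summarize category counts.

    Returns the per-peak annotations and a summary dict with, per category,
    the number of peaks and the number of distinct genes hit, plus the
    intragenic percentage.
    """
    pad = max(window_upstream, promoter_upstream, promoter_downstream) + 1
    index = GeneIndex(genes, pad)
    annotations: list[PeakAnnotation] = []
    for peak in peaks:
        cands = index.candidates(peak.interval)
        ann = classify_peak(
            peak, cands, window_upstream, promoter_upstream, promoter_downstream
        )
        # Nearest-TSS search must see the whole contig, not just candidates.
        if ann.tss_distance is None or not cands:
            contig_genes = index.contig_genes(peak.interval.contig)
            if contig_genes:
                best = None
                for gene in contig_genes:
                    d = tss_distance(peak, gene)
                    key = (abs(d), gene.gene_id)
                    if best is None or key < (best[0], best[1]):
                        best = (abs(d), gene.gene_id, d)
                ann.tss_distance, ann.nearest_gene = best[2], best[1]
        else:
            # candidate set may miss a nearer TSS just outside the pad; check
            # against the contig-wide nearest only when the candidate distance
            # exceeds the pad (otherwise no farther gene can be nearer).
            if abs(ann.tss_distance) > pad:
                best = None
                for gene in index.contig_genes(peak.interval.contig):
                    d = tss_distance(peak, gene)
                    key = (abs(d), gene.gene_id)
                    if best is None or key < (best[0], best[1]):
                        best = (abs(d), gene.gene_id, d)
                ann.tss_distance, ann.nearest_gene = best[2], best[1]
        annotations.append(ann)

    summary = summarize_annotations(annotations, n_peaks_total=len(peaks))
    return annotations, summary


def intragenic_percentage(n_exonic: int, n_intronic: int, n_boundary: int,
                          n_total: int) -> float:
    """Percent of all peaks that are intragenic (exonic + intronic +
    boundary), the aggregate reported for gene-body peaks."""
    if n_total == 0:
        return 0.0
    return 100.0 * (n_exonic + n_intronic + n_boundary) / n_total


def summarize_annotations(annotations: Sequence[PeakAnnotation],
                          n_peaks_total: Optional[int] = None) -> dict:
    n_total = len(annotations) if n_peaks_total is None else n_peaks_total
    counts: dict[str, dict] = {}
    for cat in CATEGORIES:
        peaks_in_cat = [a for a in annotations if cat in a.categories]
        gene_ids = {
            g for a in peaks_in_cat for (g, rel) in a.associated_genes if rel == cat
        }
        counts[cat] = {"n_peaks": len(peaks_in_cat), "n_genes": len(gene_ids)}
    pct = intragenic_percentage(
        counts["exonic"]["n_peaks"],
        counts["intronic"]["n_peaks"],
        counts["exon_intron_boundary"]["n_peaks"],
        n_total,
    )
    return {
        "n_peaks": n_total,
        "categories": counts,
        "intragenic_pct": pct,
        "intragenic_pct_defined": n_total > 0,
    }


def noncoding_association(
    peaks: Sequence[FairePeak],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_WINDOW_UPSTREAM,
) -> pd.DataFrame:
    """Per-biotype summary of peaks within ``window`` bp upstream of
    non-coding gene TSSs.

    One row per ncRNA biotype present in ``genes``: number of peaks, number
    of distinct genes with an upstream peak, and the percentage of that
    biotype's genes with one.
    """
    nc_genes = [g for g in genes if g.is_noncoding]
    rows = []
    peaks_by_contig: dict[str, list[FairePeak]] = {}
    for p in peaks:
        peaks_by_contig.setdefault(p.interval.contig, []).append(p)
    for biotype in NCRNA_BIOTYPES:
        members = [g for g in nc_genes if g.biotype == biotype]
        if not members:
            continue
        hit_genes: set[str] = set()
        hit_peaks: set[str] = set()
        for gene in members:
            for peak in peaks_by_contig.get(gene.contig, []):
                if peak.interval.overlaps(gene.interval):
                    continue
                d = tss_distance(peak, gene)
                if -window <= d < 0:
                    hit_genes.add(gene.gene_id)
                    hit_peaks.add(peak.peak_id)
        rows.append(
            {
                "biotype": biotype,
                "n_peaks": len(hit_peaks),
                "n_genes": len(hit_genes),
                "n_genes_total": len(members),
                "pct_genes_with_peak": 100.0 * len(hit_genes) / len(members),
            }
        )
    return pd.DataFrame(
        rows, columns=["biotype", "n_peaks", "n_genes", "n_genes_total", "pct_genes_with_peak"]
    )


def write_annotation_table(annotations: Iterable[PeakAnnotation], path) -> None:
    """TSV export: peak_id, ';'-joined categories, nearest gene, tss_distance."""
    rows = []
    for a in annotations:
        rows.append(
            {
                "peak_id": a.peak_id,
                "categories": ";".join(sorted(a.categories)),
                "gene_id": a.nearest_gene if a.nearest_gene is not None else ".",
                "tss_distance": a.tss_distance if a.tss_distance is not None else ".",
            }
        )
    pd.DataFrame(rows, columns=["peak_id", "categories", "gene_id", "tss_distance"]).to_csv(
        path, sep="\t", index=False
    )


def write_summary_json(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
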