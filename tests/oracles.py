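"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's interval-tree / vectorized code
paths: everything is per-base loops or regex, so they serve as oracles for
the fast implementations.
"""

from __future__ import annotations

import re

from fairekit.core import FairePeak, GeneModel


def brute_tss_distance(peak: FairePeak, gene: GeneModel) -> int:
    """Signed peak-to-TSS distance by scanning peak bases."""
    iv = peak.interval
    tss = gene.tss
    if tss in range(iv.start, iv.end):
        return 0
    gap = min(abs(b - tss) for b in (iv.start, iv.end - 1))
    # upstream side: lower coordinates for + genes, higher for - genes
    if gene.strand == "+":
        upstream = iv.end - 1 < tss
    else:
        upstream = iv.start > tss
    return -gap if upstream else gap


def brute_classify(peak: FairePeak, genes, window_upstream=1000,
                   promoter_upstream=250, promoter_downstream=50) -> set[str]:
    """Per-base category assignment for one peak."""
    iv = peak.interval
    cats: set[str] = set()
    for gene in genes:
        if gene.contig != iv.contig:
            continue
        g = gene.interval
        peak_bases = range(iv.start, iv.end)
        if g.start < iv.end and iv.start < g.end:  # overlaps gene body
            labels = set()
            for b in peak_bases:
                if b < g.start or b >= g.end:
                    labels.add("outside")
                elif any(e.start <= b < e.end for e in gene.exons):
                    labels.add("exon")
                else:
                    labels.add("intron")
            if "exon" in labels and "intron" in labels:
                cats.add("exon_intron_boundary")
            elif labels == {"exon"}:
                cats.add("exonic")
            elif labels == {"intron"}:
                cats.add("intronic")
            for span in gene.utr5:
                if span.start < iv.end and iv.start < span.end:
                    cats.add("five_utr")
            for span in gene.utr3:
                if span.start < iv.end and iv.start < span.end:
                    cats.add("three_utr")
        else:
            d = brute_tss_distance(peak, gene)
            if -window_upstream <= d < 0:
                cats.add("upstream_1kb")
                if gene.biotype != "protein_coding":
                    cats.add("ncRNA_upstream_1kb")
        # promoter window, base by base
        tss = gene.tss
        if gene.strand == "+":
            win = range(tss - promoter_upstream, tss + promoter_downstream + 1)
        else:
            win = range(tss - promoter_downstream, tss + promoter_upstream + 1)
        if any(b in win for b in peak_bases):
            cats.add("proximal_promoter")
    if not cats:
        cats.add("intergenic")
    return cats


def brute_snps_in_peaks(snps, peaks) -> int:
    """Distinct SNPs inside >= 1 peak by double loop."""
    n = 0
    for s in snps:
        pos0 = s.position - 1
        for p in peaks:
            iv = p.interval
            if iv.contig == s.contig and iv.start <= pos0 < iv.end:
                n += 1
                break
    return n


def brute_scan_count(seqs: dict[str, str], pwm, threshold: float) -> int:
    """All-window PWM hit count on both strands, scored per base."""
    import numpy as np

    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    table = np.log2(pwm.probs / 0.25)
    m = len(pwm)
    count = 0
    for seq in seqs.values():
        seq = seq.upper()
        rc = "".join(comp[b] for b in reversed(seq))
        for s in (seq, rc):
            for o in range(len(s) - m + 1):
                window = s[o : o + m]
                if "N" in window:
                    continue
                score = sum(table[i, "ACGT".index(window[i])] for i in range(m))
                if score >= threshold:
                    count += 1
    return count


def brute_uorfs(seq: str, min_codons: int = 2) -> list[tuple[int, int]]:
    """Three-frame scan: every ATG with an in-frame stop within the UTR."""
    seq = seq.upper()
    out = []
    for frame in range(3):
        for i in range(frame, len(seq) - 2, 3):
            if seq[i : i + 3] != "ATG":
                continue
            j = i + 3
            while j + 3 <= len(seq):
                if seq[j : j + 3] in ("TAA", "TAG", "TGA"):
                    if (j + 3 - i) // 3 >= min_codons:
                        out.append((i, j + 3))
                    break
                j += 3
    return sorted(out)


def brute_pas(seq: str) -> list[int]:
    return [m.start() for m in re.finditer(r"(?=(AATAAA|ATTAAA))", seq.upper())]


def brute_mbe(seq: str) -> list[int]:
    return [m.start() for m in re.finditer(r"(?=([AG]T{1,3}AGT))", seq.upper())]
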