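"""Synthetic toy studies: genome, annotation, peaks, SNPs, expression, motifs.

The generator emits a complete, cross-consistent bundle (FASTA + GFF3 + BED +
VCF + expression TSV + signal bedGraph + JASPAR motifs + truth JSON) whose
statistical structure matches what the analysis modules assume:

* open-chromatin peaks ~550 bp wide;
* a configurable fraction at proximal promoters and a fraction intragenic
  (split between exons, introns and exon-intron boundaries);
* aggregate FAIRE signal elevated 100-200 bp upstream of TSSs;
* expression elevated (default 1.4x) for genes with a peak within 100 bp
  upstream of the TSS;
* SNPs placed uniformly or partitioned inside/outside peaks;
* motif instances planted in peak sequences at a chosen per-kb rate;
* UTR regulatory elements (uORF/PAS/MBE) planted at chosen rates in UTR
  sequences whose backgrounds are scrubbed of chance occurrences.

Placement uses per-gene "corridors": genes are separated by gaps large
enough that a peak planted relative to one gene can never stray into
another gene's upstream window or promoter, so every peak's planted
category is exactly what the annotation module should recover. The truth
JSON records every planted quantity for oracle tests.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import FairePeak, GeneModel, GenomicInterval, PWM, Variant
from . import io_formats
from .motif_enrichment import reverse_complement

UTR_LEN = 300
CORRIDOR = 2000  # reserved bp on each gene's flanks
MARGIN = 2100  # intergenic peaks keep this distance from any gene

NCRNA_LENGTHS = {"tRNA": 80, "rRNA": 1500, "snRNA": 160, "miRNA": 100}


class SimulationError(ValueError):
    """Infeasible simulation configuration (includes a sizing hint)."""


@dataclass
class SimConfig:
    """Study-generator parameters.

    Fractions are of ``n_peaks``; their sum must be <= 1 (the remainder is
    intergenic). ``frac_promoter`` peaks flank TSSs closely: a
    ``promoter_near_frac`` share sits fully upstream within 100 bp of the
    TSS (the high-expression class) and the rest straddle the TSS with
    summits drawn from ``tss_enrichment_window`` bp upstream.
    """

    seed: int = 0
    n_contigs: int = 3
    n_genes: int = 400  # protein-coding
    n_ncrna: dict = field(
        default_factory=lambda: {"tRNA": 12, "rRNA": 4, "snRNA": 6, "miRNA": 8}
    )
    n_peaks: int = 2000
    peak_width_mean: float = 550.0
    peak_width_sd: float = 60.0
    frac_promoter: float = 0.05
    promoter_near_frac: float = 0.4
    frac_upstream_1kb: float = 0.10
    frac_intragenic: float = 0.075
    frac_ncrna_upstream: float = 0.01
    intragenic_weights: tuple = (767, 4434, 3991)  # exonic : intronic : boundary
    tss_enrichment_window: tuple = (100, 200)
    n_snps: int = 1000
    frac_snps_in_peaks: Optional[float] = None  # None: uniform placement
    unexpressed_frac: float = 0.15
    base_abundance: float = 10.0
    expression_fold_near: float = 1.4
    noise_sigma: float = 0.5
    motif_plant_rate: float = 1.0  # consensus instances per kb of peak sequence
    utr_plant_rates: dict = field(
        default_factory=lambda: {"uORF": 1.2, "PAS": 0.7, "MBE": 0.5}
    )
    emit_fasta: bool = True

    def validate(self) -> None:
        fracs = (
            self.frac_promoter
            + self.frac_upstream_1kb
            + self.frac_intragenic
            + self.frac_ncrna_upstream
        )
        if not (0 <= fracs <= 1):
            raise SimulationError(f"placement fractions sum to {fracs}, must be in [0, 1]")
        for name in ("frac_promoter", "frac_upstream_1kb", "frac_intragenic",
                     "frac_ncrna_upstream", "promoter_near_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.n_peaks < 0 or self.n_genes < 1 or self.n_contigs < 1:
            raise SimulationError("n_peaks >= 0, n_genes >= 1, n_contigs >= 1 required")
        if self.peak_width_mean < 50:
            raise SimulationError("peak_width_mean must be >= 50 bp")


@dataclass
class StudyBundle:
    """In-memory view of one generated study plus its file paths."""

    config: SimConfig
    genes: list
    peaks: list
    variants: list
    expression: pd.DataFrame
    truth: dict
    genome: Optional[dict]
    signal: list  # bedGraph records
    motifs: list  # PWMs written to the bundle
    paths: dict


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-component generators derived from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, n)]).decode()


def make_demo_pwm(motif_id: str = "MA0001_demo", consensus: str = "TGACGTCATT",
                  weight: int = 97) -> PWM:
    """A sharply informative PWM around the given consensus (planted motif)."""
    counts = np.full((len(consensus), 4), 5.0)
    for i, base in enumerate(consensus):
        counts[i, "ACGT".index(base)] = weight
    return PWM(motif_id, counts)


def plant_motifs(
    peak_seqs: dict[str, str], pwm: PWM, rate: float, seed: int
) -> tuple[dict[str, str], list[tuple[str, int]]]:
    """Write PWM consensus instances into sequences at Poisson(rate x kb)
    non-overlapping loci; returns the new sequences and the planted loci."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    consensus = pwm.consensus()
    m = len(consensus)
    out: dict[str, str] = {}
    loci: list[tuple[str, int]] = []
    for seq_id in sorted(peak_seqs):
        seq = peak_seqs[seq_id]
        if len(seq) < m:
            out[seq_id] = seq
            continue
        n_plant = int(rng.poisson(rate * len(seq) / 1000.0)) if rate > 0 else 0
        n_plant = min(n_plant, len(seq) // m)
        chars = list(seq)
        taken: list[tuple[int, int]] = []
        for _ in range(n_plant):
            for _attempt in range(100):
                pos = int(rng.integers(0, len(seq) - m + 1))
                if all(pos + m <= a or pos >= b for a, b in taken):
                    chars[pos : pos + m] = consensus
                    taken.append((pos, pos + m))
                    loci.append((seq_id, pos))
                    break
        out[seq_id] = "".join(chars)
    return out, loci


# ---------------------------------------------------------------------------
# UTR sequence construction

_STOPS = ("TAA", "TAG", "TGA")
_PAS_RE = re.compile(r"A[AT]TAAA")
_MBE_RE = re.compile(r"[AG]T{1,3}AGT")
_ATG_RE = re.compile(r"ATG")


def _scrub(seq: str, patterns: list[re.Pattern], rng: np.random.Generator) -> str:
    """Remove chance pattern matches by mutating one base of each match."""
    chars = list(seq)
    for _ in range(50):
        dirty = False
        text = "".join(chars)
        for pat in patterns:
            for m in pat.finditer(text):
                i = m.start() + int(rng.integers(0, m.end() - m.start()))
                alternatives = [b for b in "ACGT" if b != chars[i]]
                chars[i] = alternatives[int(rng.integers(3))]
                dirty = True
        if not dirty:
            return "".join(chars)
    return "".join(chars)


def _make_utr5(rng: np.random.Generator, n_uorf: int
               ) -> tuple[str, list[tuple[str, int, str]]]:
    """A 5' UTR with up to ``n_uorf`` planted uORFs on an ATG-scrubbed
    background; returns the sequence and the actual plants
    (element, offset, text)."""
    seq = _scrub(_random_dna(rng, UTR_LEN), [_ATG_RE], rng)
    chars = list(seq)
    plants: list[tuple[str, int, str]] = []
    slot = UTR_LEN // max(1, n_uorf) if n_uorf else UTR_LEN
    for k in range(n_uorf):
        n_codons = int(rng.integers(1, 4))  # interior codons
        body = []
        for _ in range(n_codons):
            while True:
                codon = _random_dna(rng, 3)
                if codon not in _STOPS and codon != "ATG":
                    break
            body.append(codon)
        orf = "ATG" + "".join(body) + _STOPS[int(rng.integers(3))]
        lo = k * slot
        hi = min(UTR_LEN, (k + 1) * slot) - len(orf)
        if hi <= lo:
            continue
        pos = int(rng.integers(lo, hi))
        chars[pos : pos + len(orf)] = orf
        plants.append(("uORF", pos, orf))
    return "".join(chars), plants


def _make_utr3(rng: np.random.Generator, n_pas: int, n_mbe: int
               ) -> tuple[str, list[tuple[str, int, str]]]:
    """A 3' UTR with up to the requested PAS and MBE plants on a scrubbed
    background; returns the sequence and the actual plants."""
    seq = _scrub(_random_dna(rng, UTR_LEN), [_PAS_RE, _MBE_RE], rng)
    chars = list(seq)
    elements: list[tuple[str, str]] = []
    for _ in range(n_pas):
        elements.append(("PAS", "AATAAA" if rng.random() < 0.5 else "ATTAAA"))
    for _ in range(n_mbe):
        head = "A" if rng.random() < 0.5 else "G"
        ts = "T" * int(rng.integers(1, 4))
        elements.append(("MBE", head + ts + "AGT"))
    plants: list[tuple[str, int, str]] = []
    if not elements:
        return "".join(chars), plants
    slot = UTR_LEN // len(elements)
    for k, (kind, el) in enumerate(elements):
        lo = k * slot + 1  # avoid creating junction matches at offset 0
        hi = min(UTR_LEN, (k + 1) * slot) - len(el) - 1
        if hi <= lo:
            continue
        pos = int(rng.integers(lo, hi))
        chars[pos : pos + len(el)] = el
        plants.append((kind, pos, el))
    return "".join(chars), plants


# ---------------------------------------------------------------------------
# gene and peak placement

def _build_genes(cfg: SimConfig, rng: np.random.Generator
                 ) -> tuple[list[GeneModel], dict[str, int], dict[str, list[tuple[int, int]]]]:
    """Place genes on contigs; returns genes, contig lengths, and per-contig
    intergenic gaps."""
    w_max = int(cfg.peak_width_mean * 1.4)
    # size intergenic gaps so the expected intergenic peaks fit without overlap
    frac_placed = (
        cfg.frac_promoter + cfg.frac_upstream_1kb + cfg.frac_intragenic
        + cfg.frac_ncrna_upstream
    )
    est_inter = cfg.n_peaks * (1.0 - frac_placed)
    n_gaps = cfg.n_genes + sum(cfg.n_ncrna.values()) + cfg.n_contigs
    per_gap = int(np.ceil(est_inter / max(1, n_gaps)))
    gap_extra = per_gap * (w_max + 60)
    specs = []
    for i in range(cfg.n_genes):
        exons = [int(rng.integers(w_max + 150, w_max + 500)) for _ in range(3)]
        introns = [int(rng.integers(w_max + 300, w_max + 800)) for _ in range(2)]
        specs.append(("protein_coding", exons, introns))
    for biotype, count in sorted(cfg.n_ncrna.items()):
        for _ in range(count):
            specs.append((biotype, [NCRNA_LENGTHS[biotype]], []))
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]

    genes: list[GeneModel] = []
    contig_lengths: dict[str, int] = {}
    gaps: dict[str, list[tuple[int, int]]] = {}
    per_contig = int(np.ceil(len(specs) / cfg.n_contigs))
    idx = 0
    gene_no = 0
    for c in range(cfg.n_contigs):
        contig = f"Supercont1.{c + 1}"
        gaps[contig] = []
        pos = 2500 + int(rng.integers(0, 500))
        gaps[contig].append((0, pos))
        start_edge = pos
        for _ in range(per_contig):
            if idx >= len(specs):
                break
            biotype, exon_lens, intron_lens = specs[idx]
            idx += 1
            gene_no += 1
            strand = "+" if rng.random() < 0.5 else "-"
            gene_len = sum(exon_lens) + sum(intron_lens)
            gstart = pos
            exons = []
            cursor = gstart
            for k, elen in enumerate(exon_lens):
                exons.append(GenomicInterval(contig, cursor, cursor + elen, strand))
                cursor += elen
                if k < len(intron_lens):
                    cursor += intron_lens[k]
            gend = gstart + gene_len
            if biotype == "protein_coding":
                if strand == "+":
                    utr5 = [GenomicInterval(contig, gstart, gstart + UTR_LEN, strand)]
                    utr3 = [GenomicInterval(contig, gend - UTR_LEN, gend, strand)]
                else:
                    utr5 = [GenomicInterval(contig, gend - UTR_LEN, gend, strand)]
                    utr3 = [GenomicInterval(contig, gstart, gstart + UTR_LEN, strand)]
            else:
                utr5, utr3 = [], []
            genes.append(
                GeneModel(
                    gene_id=f"AAEL{gene_no:06d}",
                    biotype=biotype,
                    interval=GenomicInterval(contig, gstart, gend, strand),
                    exons=exons,
                    utr5=utr5,
                    utr3=utr3,
                )
            )
            gap = int(rng.integers(5500 + w_max + gap_extra, 7000 + w_max + gap_extra))
            gaps[contig].append((gend, gend + gap))
            pos = gend + gap
        contig_lengths[contig] = pos + 2500
        # final gap runs to the contig end
        last_start = gaps[contig][-1][0]
        gaps[contig][-1] = (last_start, contig_lengths[contig])
        del start_edge
    return genes, contig_lengths, gaps


def _sample_width(cfg: SimConfig, rng: np.random.Generator) -> int:
    lo, hi = 0.6 * cfg.peak_width_mean, 1.4 * cfg.peak_width_mean
    return int(np.clip(rng.normal(cfg.peak_width_mean, cfg.peak_width_sd), lo, hi))


def _place_peaks(cfg: SimConfig, rng: np.random.Generator, genes: list[GeneModel],
                 gaps: dict[str, list[tuple[int, int]]]):
    """Plant peaks per class; returns (peaks, per-peak truth, per-gene truth)."""
    coding = [g for g in genes if g.biotype == "protein_coding"]
    ncrna = [g for g in genes if g.biotype != "protein_coding"]

    n_prom = round(cfg.frac_promoter * cfg.n_peaks)
    n_near = round(n_prom * cfg.promoter_near_frac)
    n_straddle = n_prom - n_near
    n_up = round(cfg.frac_upstream_1kb * cfg.n_peaks)
    n_intra = round(cfg.frac_intragenic * cfg.n_peaks)
    n_nc = round(cfg.frac_ncrna_upstream * cfg.n_peaks)
    n_inter = cfg.n_peaks - (n_prom + n_up + n_intra + n_nc)
    if n_inter < 0:
        raise SimulationError("placement fractions exceed 1 after rounding")

    if n_prom + n_up > len(coding):
        raise SimulationError(
            f"need {n_prom + n_up} coding genes for TSS-flanking peaks but have "
            f"{len(coding)}; raise n_genes or lower frac_promoter/frac_upstream_1kb"
        )
    if n_nc > len(ncrna):
        raise SimulationError(
            f"need {n_nc} ncRNA genes but have {len(ncrna)}; raise n_ncrna or "
            "lower frac_ncrna_upstream"
        )

    gene_order = rng.permutation(len(coding))
    straddle_genes = [coding[i] for i in gene_order[:n_straddle]]
    near_genes = [coding[i] for i in gene_order[n_straddle : n_straddle + n_near]]
    far_genes = [coding[i] for i in gene_order[n_straddle + n_near : n_prom + n_up]]
    nc_order = rng.permutation(len(ncrna))
    nc_genes = [ncrna[i] for i in nc_order[:n_nc]]

    lo_win, hi_win = cfg.tss_enrichment_window
    peaks: list[FairePeak] = []
    peak_truth: dict[str, dict] = {}
    gene_truth: dict[str, dict] = {
        g.gene_id: {"expr_class": "none", "planted_peaks": []} for g in genes
    }

    def add_peak(contig, start, end, cls, gene_id=None, summit=None):
        pid = f"FP{len(peaks) + 1:06d}"
        peaks.append(FairePeak(pid, GenomicInterval(contig, start, end)))
        peak_truth[pid] = {"class": cls, "gene_id": gene_id, "summit": summit}
        if gene_id is not None:
            gene_truth[gene_id]["planted_peaks"].append(pid)
        return pid

    def upstream_extent(gene: GeneModel, edge_dist: int, width: int):
        """Peak fully upstream with nearest base ``edge_dist`` bp from TSS."""
        tss = gene.tss
        if gene.strand == "+":
            end = tss - edge_dist + 1
            return end - width, end
        start = tss + edge_dist
        return start, start + width

    for gene in straddle_genes:
        w = _sample_width(cfg, rng)
        mid = (lo_win + hi_win) / 2.0
        sd = (hi_win - lo_win) / 2.5
        c = int(np.clip(rng.normal(mid, sd), 60, hi_win + 40))
        tss = gene.tss
        if gene.strand == "+":
            summit = tss - c
        else:
            summit = tss + c
        start = summit - w // 2
        add_peak(gene.contig, start, start + w, "promoter_straddle",
                 gene.gene_id, summit)
        gene_truth[gene.gene_id]["expr_class"] = "straddle"

    for gene in near_genes:
        w = _sample_width(cfg, rng)
        e = int(rng.integers(10, 101))
        start, end = upstream_extent(gene, e, w)
        add_peak(gene.contig, start, end, "promoter_near", gene.gene_id,
                 (start + end) // 2)
        gene_truth[gene.gene_id]["expr_class"] = "near"

    for gene in far_genes:
        w = _sample_width(cfg, rng)
        e = int(rng.integers(300, 951))
        start, end = upstream_extent(gene, e, w)
        add_peak(gene.contig, start, end, "upstream_far", gene.gene_id)
        gene_truth[gene.gene_id]["expr_class"] = "far"

    for gene in nc_genes:
        w = _sample_width(cfg, rng)
        e = int(rng.integers(300, 901))
        start, end = upstream_extent(gene, e, w)
        add_peak(gene.contig, start, end, "ncrna_upstream", gene.gene_id)

    weights = np.array(cfg.intragenic_weights, dtype=float)
    weights /= weights.sum()
    for _ in range(n_intra):
        gene = coding[int(rng.integers(len(coding)))]
        w = _sample_width(cfg, rng)
        sub = ["exonic", "intronic", "boundary"][int(rng.choice(3, p=weights))]
        if sub == "exonic":
            if rng.random() < 0.5:
                exon = gene.exons[1]  # middle exon, away from UTRs
                start = int(rng.integers(exon.start + 5, exon.end - w - 4))
            else:
                # terminal-exon peak overlapping the 3' UTR (stays exonic)
                if gene.strand == "+":
                    exon = gene.exons[-1]
                    start = exon.end - w - int(rng.integers(0, 50))
                else:
                    exon = gene.exons[0]
                    start = exon.start + int(rng.integers(0, 50))
            add_peak(gene.contig, start, start + w, "exonic", gene.gene_id)
        elif sub == "intronic":
            intron = gene.introns()[int(rng.integers(2))]
            start = int(rng.integers(intron.start + 5, intron.end - w - 4))
            add_peak(gene.contig, start, start + w, "intronic", gene.gene_id)
        else:
            junctions = []
            for intron in gene.introns():
                junctions.extend([intron.start, intron.end])
            j = junctions[int(rng.integers(len(junctions)))]
            left = int(rng.integers(50, w - 49))
            start = j - left
            add_peak(gene.contig, start, start + w, "boundary", gene.gene_id)

    # intergenic peaks go into non-overlapping slots carved from the gaps
    w_max = int(cfg.peak_width_mean * 1.4)
    slot_size = w_max + 60
    slots = []
    for contig in sorted(gaps):
        for lo, hi in gaps[contig]:
            lo, hi = lo + MARGIN, hi - MARGIN
            for k in range((hi - lo) // slot_size):
                slots.append((contig, lo + k * slot_size))
    if n_inter > len(slots):
        raise SimulationError(
            f"{n_inter} intergenic peaks requested but only {len(slots)} slots "
            "available; raise n_genes/n_contigs or lower n_peaks"
        )
    for i in rng.permutation(len(slots))[:n_inter]:
        contig, lo = slots[i]
        w = _sample_width(cfg, rng)
        start = lo + int(rng.integers(0, slot_size - w))
        add_peak(contig, start, start + w, "intergenic")

    planted = {
        "promoter": n_prom,
        "promoter_straddle": n_straddle,
        "promoter_near": n_near,
        "upstream_far": n_up,
        "intragenic": n_intra,
        "ncrna_upstream": n_nc,
        "intergenic": n_inter,
    }
    return peaks, peak_truth, gene_truth, planted


def _place_snps(cfg: SimConfig, rng: np.random.Generator,
                contig_lengths: dict[str, int], peaks: list[FairePeak],
                genome: Optional[dict]) -> tuple[list[Variant], list[bool]]:
    contigs = sorted(contig_lengths)
    lengths = np.array([contig_lengths[c] for c in contigs], dtype=float)
    probs = lengths / lengths.sum()
    peak_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    for p in peaks:
        peak_spans[p.interval.contig].append((p.interval.start, p.interval.end))

    def in_peak(contig: str, pos0: int) -> bool:
        return any(a <= pos0 < b for a, b in peak_spans[contig])

    chosen: set[tuple[str, int]] = set()
    positions: list[tuple[str, int, bool]] = []

    def draw_uniform(target_in: Optional[bool]) -> None:
        for _ in range(200000):
            c = contigs[int(rng.choice(len(contigs), p=probs))]
            pos0 = int(rng.integers(0, contig_lengths[c]))
            flag = in_peak(c, pos0)
            if target_in is not None and flag != target_in:
                continue
            if (c, pos0) in chosen:
                continue
            chosen.add((c, pos0))
            positions.append((c, pos0, flag))
            return
        raise SimulationError("could not place SNPs; genome too small for n_snps")

    if cfg.frac_snps_in_peaks is None:
        for _ in range(cfg.n_snps):
            draw_uniform(None)
    else:
        k = round(cfg.frac_snps_in_peaks * cfg.n_snps)
        total_peak_bp = sum(b - a for spans in peak_spans.values() for a, b in spans)
        if k > 0 and total_peak_bp == 0:
            raise SimulationError("frac_snps_in_peaks > 0 but there are no peaks")
        flat = [(p.interval.contig, p.interval.start, p.interval.end) for p in peaks]
        for _ in range(k):
            for _attempt in range(1000):
                c, a, b = flat[int(rng.integers(len(flat)))]
                pos0 = int(rng.integers(a, b))
                if (c, pos0) not in chosen:
                    chosen.add((c, pos0))
                    positions.append((c, pos0, True))
                    break
            else:
                raise SimulationError("could not place in-peak SNPs; too few peak bp")
        for _ in range(cfg.n_snps - k):
            draw_uniform(False)

    variants = []
    flags = []
    bases = "ACGT"
    for c, pos0, flag in sorted(positions):
        ref = genome[c][pos0] if genome is not None else bases[int(rng.integers(4))]
        alts = [b for b in bases if b != ref]
        variants.append(Variant(c, pos0 + 1, ref, alts[int(rng.integers(3))]))
        flags.append(flag)
    return variants, flags


def _make_expression(cfg: SimConfig, rng: np.random.Generator,
                     genes: list[GeneModel], gene_truth: dict) -> pd.DataFrame:
    rows = []
    for gene in genes:
        cls = gene_truth[gene.gene_id]["expr_class"]
        unexpressed = rng.random() < cfg.unexpressed_frac
        if unexpressed:
            abundance = 0.0
        else:
            abundance = cfg.base_abundance * float(
                rng.lognormal(mean=0.0, sigma=cfg.noise_sigma)
            )
            if cls == "near":
                abundance *= cfg.expression_fold_near
        gene_truth[gene.gene_id]["expressed"] = not unexpressed
        gene_truth[gene.gene_id]["abundance"] = abundance
        rows.append({"gene_id": gene.gene_id, "abundance": abundance})
    return pd.DataFrame(rows, columns=["gene_id", "abundance"])


def _signal_track(peaks: list[FairePeak], peak_truth: dict
                  ) -> list[tuple[GenomicInterval, float]]:
    """Read-depth-like track: a low plateau over every peak plus a tall
    summit bump over TSS-proximal peaks (plateaus first so bumps win)."""
    plateaus = []
    bumps = []
    for p in peaks:
        iv = p.interval
        plateaus.append((GenomicInterval(iv.contig, iv.start, iv.end), 0.15))
        info = peak_truth[p.peak_id]
        if info["class"] in ("promoter_straddle", "promoter_near") and info["summit"]:
            s = info["summit"]
            bumps.append((GenomicInterval(iv.contig, max(0, s - 75), s + 75), 1.0))
    return plateaus + bumps


def generate_study(config: SimConfig, outdir) -> StudyBundle:
    """Generate one synthetic study and write its file bundle to ``outdir``.

    Deterministic: the same config (seed included) produces byte-identical
    files. Raises :class:`SimulationError` when the requested placements do
    not fit the genome, with a sizing hint.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (rng_genes, rng_peaks, rng_snps, rng_expr, rng_seq, rng_utr) = _rngs(config.seed, 6)

    genes, contig_lengths, gaps = _build_genes(config, rng_genes)
    peaks, peak_truth, gene_truth, planted = _place_peaks(config, rng_peaks, genes, gaps)

    genome: Optional[dict[str, str]] = None
    motif_loci: list = []
    motifs: list[PWM] = []
    utr_truth: dict[str, dict] = {}
    if config.emit_fasta:
        buffers = {
            c: bytearray(_random_dna(rng_seq, n), "ascii")
            for c, n in sorted(contig_lengths.items())
        }

        # plant UTR elements (mRNA-sense; reverse-complemented into - genes)
        utr_plants: dict[str, dict[str, list[tuple[str, int, str]]]] = {}
        for gene in genes:
            if gene.biotype != "protein_coding":
                continue
            rates = config.utr_plant_rates
            n_uorf = int(rng_utr.poisson(rates.get("uORF", 0.0)))
            n_pas = int(rng_utr.poisson(rates.get("PAS", 0.0)))
            n_mbe = int(rng_utr.poisson(rates.get("MBE", 0.0)))
            utr5_seq, plants5 = _make_utr5(rng_utr, n_uorf)
            utr3_seq, plants3 = _make_utr3(rng_utr, n_pas, n_mbe)
            utr_plants[gene.gene_id] = {"five": plants5, "three": plants3}
            for span, seq_mrna in ((gene.utr5[0], utr5_seq), (gene.utr3[0], utr3_seq)):
                genomic = seq_mrna if gene.strand == "+" else reverse_complement(seq_mrna)
                buffers[gene.contig][span.start : span.end] = genomic.encode("ascii")

        # plant motif instances in peak sequences
        planted_pwm = make_demo_pwm()
        control_pwm = make_demo_pwm("MA0002_control", consensus="ACTAGCAGGT")
        motifs = [planted_pwm, control_pwm]
        peak_seqs = {
            p.peak_id: buffers[p.interval.contig][p.interval.start : p.interval.end].decode()
            for p in peaks
        }
        plant_seed = (config.seed * 1000003 + 17) % (2**31)
        peak_seqs, motif_loci = plant_motifs(
            peak_seqs, planted_pwm, config.motif_plant_rate, plant_seed
        )
        by_id = {p.peak_id: p for p in peaks}
        for pid, seq in peak_seqs.items():
            iv = by_id[pid].interval
            buffers[iv.contig][iv.start : iv.end] = seq.encode("ascii")
        genome = {c: buf.decode() for c, buf in buffers.items()}
        # overlapping peaks can overwrite an earlier plant; keep only loci
        # whose consensus survives in the final genome
        consensus = planted_pwm.consensus()
        kept = []
        for pid, offset in motif_loci:
            iv = by_id[pid].interval
            g = genome[iv.contig][iv.start + offset : iv.start + offset + len(consensus)]
            if g == consensus:
                kept.append((pid, offset))
        motif_loci = kept

        # peak write-back can overwrite UTR plants where peaks overlap UTRs;
        # truth keeps only the plants whose text survives in the final genome
        for gene in genes:
            if gene.gene_id not in utr_plants:
                continue
            counts = {"uORF": 0, "PAS": 0, "MBE": 0}
            for side, spans in (("five", gene.utr5), ("three", gene.utr3)):
                final = "".join(genome[s.contig][s.start : s.end] for s in spans)
                if gene.strand == "-":
                    final = reverse_complement(final)
                for kind, pos, text in utr_plants[gene.gene_id][side]:
                    if final[pos : pos + len(text)] == text:
                        counts[kind] += 1
            utr_truth[gene.gene_id] = counts

    variants, snp_flags = _place_snps(config, rng_snps, contig_lengths, peaks, genome)
    expression = _make_expression(config, rng_expr, genes, gene_truth)
    signal = _signal_track(peaks, peak_truth)

    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "contig_lengths": contig_lengths,
        "planted_counts": planted,
        "peaks": peak_truth,
        "genes": gene_truth,
        "snps": [
            {"contig": v.contig, "position": v.position, "in_peak": f}
            for v, f in zip(variants, snp_flags)
        ],
        "n_snps_in_peaks": int(sum(snp_flags)),
        "motif_plants": [{"peak_id": s, "offset": o} for s, o in motif_loci],
        "utr_elements": utr_truth,
    }

    paths = {
        "gff": outdir / "genes.gff3",
        "bed": outdir / "peaks.bed",
        "vcf": outdir / "snps.vcf",
        "expression": outdir / "expression.tsv",
        "bedgraph": outdir / "faire_signal.bedgraph",
        "truth": outdir / "truth.json",
    }
    io_formats.write_gff(genes, paths["gff"])
    io_formats.write_bed(peaks, paths["bed"])
    io_formats.write_vcf(variants, paths["vcf"])
    io_formats.write_expression(expression, paths["expression"])
    io_formats.write_bedgraph(signal, paths["bedgraph"])
    if config.emit_fasta:
        paths["fasta"] = outdir / "genome.fa"
        paths["jaspar"] = outdir / "motifs.jaspar"
        io_formats.write_fasta(genome, paths["fasta"])
        io_formats.write_jaspar(motifs, paths["jaspar"])
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")

    return StudyBundle(
        config=config,
        genes=genes,
        peaks=peaks,
        variants=variants,
        expression=expression,
        truth=truth,
        genome=genome,
        signal=signal,
        motifs=motifs,
        paths={k: str(v) for k, v in paths.items()},
    )


def file_digests(paths: dict) -> dict[str, str]:
    """SHA-256 of every file in a bundle's path map (determinism checks)."""
    out = {}
    for key, path in sorted(paths.items()):
        out[key] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return out
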