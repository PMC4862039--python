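import numpy as np
import pytest

from fairekit.core import FairePeak, GeneModel, GenomicInterval
from fairekit.synthetic_data import SimConfig, generate_study


def make_gene(gene_id="g1", contig="chr", start=10_000, strand="+",
              exon_lens=(800, 900, 800), intron_lens=(1000, 1200),
              biotype="protein_coding", utr_len=0):
    """Compact gene-model builder for hand-constructed cases."""
    exons = []
    cursor = start
    for k, elen in enumerate(exon_lens):
        exons.append(GenomicInterval(contig, cursor, cursor + elen, strand))
        cursor += elen
        if k < len(intron_lens):
            cursor += intron_lens[k]
    end = start + sum(exon_lens) + sum(intron_lens)
    utr5, utr3 = [], []
    if utr_len:
        if strand == "+":
            utr5 = [GenomicInterval(contig, start, start + utr_len, strand)]
            utr3 = [GenomicInterval(contig, end - utr_len, end, strand)]
        else:
            utr5 = [GenomicInterval(contig, end - utr_len, end, strand)]
            utr3 = [GenomicInterval(contig, start, start + utr_len, strand)]
    return GeneModel(gene_id=gene_id, biotype=biotype,
                     interval=GenomicInterval(contig, start, end, strand),
                     exons=exons, utr5=utr5, utr3=utr3)


def make_peak(start, end, contig="chr", peak_id="p1"):
    return FairePeak(peak_id, GenomicInterval(contig, start, end))


def random_instance(rng, n_genes, n_peaks, contig_len=300_000, n_contigs=2):
    """Unstructured random genes and peaks for oracle-equivalence tests.

    Genes are placed non-overlapping per contig with random exon structure;
    peaks are placed uniformly at random, so every positional relation
    (straddles, containments, far misses) occurs by chance.
    """
    contigs = [f"c{i}" for i in range(n_contigs)]
    genes = []
    cursors = {c: 100 for c in contigs}
    for i in range(n_genes):
        contig = contigs[int(rng.integers(n_contigs))]
        n_exons = int(rng.integers(1, 4))
        exon_lens = tuple(int(rng.integers(100, 900)) for _ in range(n_exons))
        intron_lens = tuple(int(rng.integers(80, 1200)) for _ in range(n_exons - 1))
        start = cursors[contig] + int(rng.integers(0, 3000))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "protein_coding" if rng.random() < 0.8 else "tRNA"
        utr_len = int(rng.integers(0, min(80, min(exon_lens))))
        gene = make_gene(f"g{i:04d}", contig, start, strand, exon_lens,
                         intron_lens, biotype, utr_len)
        cursors[contig] = gene.interval.end
        genes.append(gene)
    peaks = []
    for j in range(n_peaks):
        contig = contigs[int(rng.integers(n_contigs))]
        width = int(rng.integers(30, 1200))
        start = int(rng.integers(0, max(cursors[contig] + 2000, contig_len) - width))
        peaks.append(make_peak(start, start + width, contig, f"p{j:05d}"))
    genes.sort(key=lambda g: (g.contig, g.interval.start, g.gene_id))
    return genes, peaks


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default synthetic study shared by read-only tests."""
    outdir = tmp_path_factory.mktemp("study")
    return generate_study(SimConfig(seed=11), outdir)


@pytest.fixture(scope="session")
def nofasta_bundle(tmp_path_factory):
    """Larger coordinate-only study (no sequences) for recovery statistics."""
    outdir = tmp_path_factory.mktemp("study_nofasta")
    cfg = SimConfig(seed=12, n_genes=1200, n_peaks=8000, n_snps=2000,
                    emit_fasta=False)
    return generate_study(cfg, outdir)
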