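import numpy as np
import pytest

from conftest import make_gene, make_peak, random_instance
from oracles import brute_classify, brute_tss_distance

from fairekit.core import FairePeak, GeneModel, GenomicInterval, parse_printed_range
from fairekit.interval_annotation import (
    annotate_peaks,
    classify_peak,
    intragenic_percentage,
    noncoding_association,
    summarize_annotations,
    tss_distance,
)


class TestTssDistance:
    def test_tss_inside_peak_is_zero(self):
        # reporter-style case: peak 550819-551917 (printed, 1-based) around
        # a TSS printed at 551773 -> 0-based 551772 lies inside
        iv = parse_printed_range("Supercont1.440:550819-551917")
        peak = FairePeak("B", iv)
        gene = make_gene("AAEL009947", "Supercont1.440", start=551772,
                         exon_lens=(1000,), intron_lens=())
        assert tss_distance(peak, gene) == 0

    def test_upstream_peak_negative_strandaware(self):
        # peak printed 501192-503018, gene TSS printed at 507860 (+ strand):
        # gap 507860 - 503018 = 4842 on the upstream side
        iv = parse_printed_range("Supercont1.551:501192-503018")
        peak = FairePeak("A", iv)
        gene = make_gene("AAEL011197", "Supercont1.551", start=507859,
                         exon_lens=(1000,), intron_lens=())
        assert tss_distance(peak, gene) == -4842

    def test_containment_is_strand_independent(self):
        for strand in "+-":
            gene = make_gene("g", "c", start=1000, strand=strand,
                             exon_lens=(500,), intron_lens=())
            tss = gene.tss
            peak = make_peak(tss - 100, tss + 100, "c")
            assert tss_distance(peak, gene) == 0

    def test_downstream_is_positive(self):
        gene = make_gene("g", "c", start=1000, strand="-",
                         exon_lens=(500,), intron_lens=())
        # for a - strand gene, lower coordinates are downstream
        peak = make_peak(100, 200, "c")
        assert tss_distance(peak, gene) == gene.tss - 199

    def test_contig_mismatch_raises(self):
        gene = make_gene("g", "c1")
        with pytest.raises(ValueError):
            tss_distance(make_peak(0, 10, "c2"), gene)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_agrees_with_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes, peaks = random_instance(rng, n_genes=30, n_peaks=150)
        for peak in peaks:
            for gene in genes:
                if gene.contig != peak.interval.contig:
                    continue
                assert tss_distance(peak, gene) == brute_tss_distance(peak, gene)


class TestClassifyPeak:
    def test_peak_inside_intron(self):
        gene = make_gene()  # exons 800/900/800, introns 1000/1200
        intron1 = gene.introns()[0]
        peak = make_peak(intron1.start + 10, intron1.start + 400)
        ann = classify_peak(peak, [gene])
        assert ann.categories == {"intronic"}

    def test_junction_peak_is_boundary_only(self):
        gene = make_gene()
        j = gene.exons[0].end  # exon1/intron1 junction
        ann = classify_peak(make_peak(j - 50, j + 50), [gene])
        assert "exon_intron_boundary" in ann.categories
        assert "exonic" not in ann.categories
        assert "intronic" not in ann.categories

    def test_edge_straddling_peak_is_not_intragenic(self):
        gene = make_gene(start=10_000)
        # part upstream of the gene, part in exon 1: inside no single exon,
        # spans no junction
        ann = classify_peak(make_peak(9_800, 10_200), [gene])
        assert not ann.categories & {"exonic", "intronic", "exon_intron_boundary"}
        assert "proximal_promoter" in ann.categories  # touches the TSS window

    def test_upstream_window_and_promoter(self):
        gene = make_gene(start=10_000, strand="+")
        ann = classify_peak(make_peak(9_000, 9_500), [gene])  # 500 bp upstream
        assert ann.categories == {"upstream_1kb"}
        ann2 = classify_peak(make_peak(9_700, 9_900), [gene])  # 100 bp upstream
        assert ann2.categories == {"upstream_1kb", "proximal_promoter"}
        ann3 = classify_peak(make_peak(7_000, 8_000), [gene])  # beyond 1 kb
        assert ann3.categories == {"intergenic"}

    def test_ncrna_upstream_flag(self):
        gene = make_gene(biotype="miRNA", start=50_000, exon_lens=(100,),
                         intron_lens=())
        ann = classify_peak(make_peak(49_000, 49_600), [gene])
        assert {"upstream_1kb", "ncRNA_upstream_1kb"} <= ann.categories

    def test_no_genes_means_intergenic(self):
        ann = classify_peak(make_peak(0, 100), [])
        assert ann.categories == {"intergenic"}
        assert ann.tss_distance is None

    def test_utr_overlap_adds_utr_categories(self):
        gene = make_gene(utr_len=200, start=20_000)
        # fully inside exon 1, overlapping the 5' UTR span
        ann = classify_peak(make_peak(20_050, 20_150), [gene])
        assert {"exonic", "five_utr"} <= ann.categories

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(100 + seed)
        genes, peaks = random_instance(rng, n_genes=40, n_peaks=300)
        annotations, _ = annotate_peaks(peaks, genes)
        for peak, ann in zip(peaks, annotations):
            expected = brute_classify(peak, genes)
            assert ann.categories == expected, peak

    def test_strand_reflection_preserves_counts(self):
        rng = np.random.default_rng(7)
        genes, peaks = random_instance(rng, n_genes=25, n_peaks=200, n_contigs=1)
        _, summary = annotate_peaks(peaks, genes)

        L = max(g.interval.end for g in genes) + max(p.interval.end for p in peaks) + 10
        flip = {"+": "-", "-": "+"}

        def mirror_iv(iv):
            return GenomicInterval(iv.contig, L - iv.end, L - iv.start,
                                   flip.get(iv.strand, iv.strand))

        mirrored_genes = [
            GeneModel(g.gene_id, g.biotype, mirror_iv(g.interval),
                      [mirror_iv(e) for e in reversed(g.exons)],
                      [mirror_iv(u) for u in reversed(g.utr5)],
                      [mirror_iv(u) for u in reversed(g.utr3)])
            for g in genes
        ]
        mirrored_peaks = [FairePeak(p.peak_id, mirror_iv(p.interval)) for p in peaks]
        _, mirrored_summary = annotate_peaks(mirrored_peaks, mirrored_genes)
        for cat, counts in summary["categories"].items():
            assert mirrored_summary["categories"][cat] == counts, cat

    def test_upstream_window_monotonicity(self):
        rng = np.random.default_rng(21)
        genes, peaks = random_instance(rng, n_genes=30, n_peaks=250)
        counts = []
        for window in (250, 500, 1000, 2000):
            _, summary = annotate_peaks(peaks, genes, window_upstream=window)
            counts.append(summary["categories"]["upstream_1kb"]["n_peaks"])
        assert counts == sorted(counts)

    def test_every_peak_categorized_and_intergenic_exclusive(self):
        rng = np.random.default_rng(3)
        genes, peaks = random_instance(rng, n_genes=30, n_peaks=300)
        annotations, _ = annotate_peaks(peaks, genes)
        for ann in annotations:
            assert ann.categories
            if "intergenic" in ann.categories:
                assert ann.categories == {"intergenic"}
                assert not ann.associated_genes


class TestSummaries:
    def test_intragenic_percentage_headline_arithmetic(self):
        pct = intragenic_percentage(767, 4434, 3991, 121_600)
        assert pct == pytest.approx(7.5592, abs=1e-3)
        assert abs(pct - 7.5) < 0.1  # "about 7.5 %"

    def test_zero_peaks_summary_is_flagged(self):
        summary = summarize_annotations([], n_peaks_total=0)
        assert summary["intragenic_pct"] == 0.0
        assert summary["intragenic_pct_defined"] is False
        assert all(v["n_peaks"] == 0 for v in summary["categories"].values())

    def test_category_counts_count_distinct_genes(self):
        gene_a = make_gene("a", start=10_000)
        gene_b = make_gene("b", start=40_000)
        intron_a = gene_a.introns()[0]
        intron_b = gene_b.introns()[0]
        peaks = [
            make_peak(intron_a.start + 5, intron_a.start + 105, peak_id="p1"),
            make_peak(intron_a.start + 200, intron_a.start + 300, peak_id="p2"),
            make_peak(intron_b.start + 5, intron_b.start + 105, peak_id="p3"),
        ]
        _, summary = annotate_peaks(peaks, [gene_a, gene_b])
        assert summary["categories"]["intronic"] == {"n_peaks": 3, "n_genes": 2}


class TestNoncodingAssociation:
    def test_three_of_ten_trna_genes(self):
        genes = [
            make_gene(f"t{i}", start=10_000 + 20_000 * i, biotype="tRNA",
                      exon_lens=(80,), intron_lens=())
            for i in range(10)
        ]
        peaks = [
            make_peak(genes[i].tss - 600, genes[i].tss - 100, peak_id=f"p{i}")
            for i in range(3)
        ]
        table = noncoding_association(peaks, genes)
        row = table[table["biotype"] == "tRNA"].iloc[0]
        assert row["n_genes"] == 3
        assert row["pct_genes_with_peak"] == pytest.approx(30.0)

    def test_no_ncrna_genes_gives_empty_table(self):
        genes = [make_gene("g", start=5_000)]
        assert noncoding_association([make_peak(0, 100)], genes).empty

    def test_all_mirna_genes_with_planted_upstream_peaks(self, tmp_path):
        from fairekit.synthetic_data import SimConfig, generate_study

        cfg = SimConfig(seed=9, n_genes=80, n_peaks=430,
                        n_ncrna={"miRNA": 43},
                        frac_promoter=0.0, frac_upstream_1kb=0.0,
                        frac_intragenic=0.0, frac_ncrna_upstream=0.1,
                        n_snps=10, emit_fasta=False)
        bundle = generate_study(cfg, tmp_path)
        table = noncoding_association(bundle.peaks, bundle.genes)
        row = table[table["biotype"] == "miRNA"].iloc[0]
        assert row["n_genes"] == 43
        assert row["pct_genes_with_peak"] == pytest.approx(100.0)
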