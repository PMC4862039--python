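import numpy as np
import pytest

from oracles import brute_mbe, brute_pas, brute_uorfs

from fairekit.utr_elements import (
    UtrElementHit,
    detect_mbe,
    detect_pas,
    detect_uorf,
    extract_utr_sequences,
    hits_table,
    scan_utr_sequences,
    summarize_utr_elements,
)


def random_seq(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


class TestUorf:
    def test_minimal_two_codon_orf(self):
        hits = detect_uorf("ATGTAA")
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (0, 6)

    def test_atg_without_stop_in_utr(self):
        assert detect_uorf("ATGAAA") == []

    def test_out_of_frame_stop_ignored(self):
        # stop TAA exists but not in frame with the ATG
        assert detect_uorf("ATGATAAC") == []

    def test_overlapping_uorfs_all_reported(self):
        seq = "ATGATGAAATAA"  # two ATGs sharing the downstream in-frame stop
        hits = detect_uorf(seq)
        assert len(hits) == 2

    def test_min_codons_configurable(self):
        assert detect_uorf("ATGTAA", min_codons=3) == []
        assert detect_uorf("ATGAAATAA", min_codons=3) != []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_three_frame_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            seq = random_seq(rng, 500)
            ours = sorted((h.start, h.end) for h in detect_uorf(seq))
            assert ours == brute_uorfs(seq)


class TestPas:
    def test_hexamer_at_offset(self):
        hits = detect_pas("GGAATAAAGG")
        assert [(h.start, h.end) for h in hits] == [(2, 8)]

    def test_both_variants_detected(self):
        assert len(detect_pas("AATAAA" + "C" * 10 + "ATTAAA")) == 2

    def test_absent_hexamer(self):
        assert detect_pas("GGGGCCCC") == []

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            seq = random_seq(rng, 400)
            assert [h.start for h in detect_pas(seq)] == brute_pas(seq)


class TestMbe:
    def test_consensus_instance(self):
        hits = detect_mbe("GTTAGT")
        assert [(h.start, h.end) for h in hits] == [(0, 6)]

    def test_first_base_must_be_purine(self):
        assert detect_mbe("CTTAGT") == []

    def test_variable_t_run(self):
        for ts in ("T", "TT", "TTT"):
            assert detect_mbe(f"A{ts}AGT"), ts
        assert detect_mbe("ATTTTAGT") == []  # four Ts exceed the T(1-3) run

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            seq = random_seq(rng, 400)
            assert [h.start for h in detect_mbe(seq)] == brute_mbe(seq)


class TestSideDiscipline:
    def test_uorf_restricted_to_five_prime(self):
        with pytest.raises(ValueError):
            UtrElementHit("g", "three_prime", "uORF", 0, 6)

    @pytest.mark.parametrize("element", ["PAS", "MBE"])
    def test_three_prime_elements_restricted(self, element):
        with pytest.raises(ValueError):
            UtrElementHit("g", "five_prime", element, 0, 6)

    def test_scan_routes_detectors_by_side(self):
        utr5 = {"g1": "ATGTAA" + "AATAAA"}  # PAS-like text in a 5' UTR
        utr3 = {"g1": "ATGTAA" + "AATAAA"}
        hits = scan_utr_sequences(utr5, utr3)
        sides = {(h.element, h.utr_side) for h in hits}
        assert ("uORF", "five_prime") in sides
        assert ("PAS", "three_prime") in sides
        assert ("uORF", "three_prime") not in sides
        assert ("PAS", "five_prime") not in sides


class TestSummary:
    def test_rank_order_and_proportions(self):
        hits = (
            [UtrElementHit("g", "five_prime", "uORF", 0, 6)] * 50
            + [UtrElementHit("g", "three_prime", "PAS", 0, 6)] * 30
            + [UtrElementHit("g", "three_prime", "MBE", 0, 6)] * 20
        )
        table = summarize_utr_elements(hits)
        assert list(table["element"]) == ["uORF", "PAS", "MBE"]
        assert list(table["proportion"]) == pytest.approx([0.5, 0.3, 0.2])

    def test_single_element_type(self):
        table = summarize_utr_elements(
            [UtrElementHit("g", "three_prime", "PAS", 0, 6)]
        )
        assert table.iloc[0]["proportion"] == 1.0

    def test_empty_input(self):
        assert summarize_utr_elements([]).empty

    def test_hits_table_columns(self):
        table = hits_table([UtrElementHit("g", "five_prime", "uORF", 2, 11)])
        assert table.iloc[0].tolist() == ["g", "five_prime", "uORF", 2, 11]


class TestExtractUtrSequences:
    def test_clip_to_peak_restricted_mode(self):
        from conftest import make_gene
        from fairekit.core import GenomicInterval

        gene = make_gene("g", start=1000, strand="+", exon_lens=(400,),
                         intron_lens=(), utr_len=20)
        genome = {"chr": "A" * 1000 + "ACGTACGTACGTACGTACGT" + "T" * 380}
        full = extract_utr_sequences([gene], genome, "five_prime")
        assert full["g"] == "ACGTACGTACGTACGTACGT"
        clipped = extract_utr_sequences(
            [gene], genome, "five_prime",
            clip_to={"g": [GenomicInterval("chr", 1004, 1012)]},
        )
        assert clipped["g"] == "ACGTACGT"
        # a peak missing the UTR entirely drops the gene
        none = extract_utr_sequences(
            [gene], genome, "five_prime",
            clip_to={"g": [GenomicInterval("chr", 1500, 1600)]},
        )
        assert "g" not in none

    def test_minus_strand_reverse_complemented(self):
        from conftest import make_gene

        gene = make_gene("g", start=1000, strand="-", exon_lens=(400,),
                         intron_lens=(), utr_len=10)
        genome = {"chr": "A" * 1000 + "ACGTACGTAC" + "G" * 380 + "TTTTTTTTTT"}
        utr5 = extract_utr_sequences([gene], genome, "five_prime")
        # 5' UTR of a - gene sits at the gene's high-coordinate end
        assert utr5["g"] == "AAAAAAAAAA"
        utr3 = extract_utr_sequences([gene], genome, "three_prime")
        assert utr3["g"] == "GTACGTACGT"


def test_planted_uorf_share_recovered(default_bundle):
    """UTR sequences are planted so uORFs are about half of all elements."""
    genes = default_bundle.genes
    genome = default_bundle.genome
    utr5 = extract_utr_sequences(genes, genome, "five_prime")
    utr3 = extract_utr_sequences(genes, genome, "three_prime")
    hits = scan_utr_sequences(utr5, utr3)
    table = summarize_utr_elements(hits).set_index("element")
    assert 0.45 <= table.loc["uORF", "proportion"] <= 0.55
    # and every planted element count is at least reached per side
    truth = default_bundle.truth["utr_elements"]
    planted_totals = {"uORF": 0, "PAS": 0, "MBE": 0}
    for counts in truth.values():
        for k in planted_totals:
            planted_totals[k] += counts[k]
    for element, planted in planted_totals.items():
        found = int(table.loc[element, "count"]) if element in table.index else 0
        assert found >= planted
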