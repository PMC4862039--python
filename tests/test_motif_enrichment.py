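import numpy as np
import pytest
from scipy import stats

from oracles import brute_scan_count

from fairekit.core import PWM
from fairekit.motif_enrichment import (
    dinucleotide_shuffle,
    dinucleotide_shuffle_sampler,
    enrichment_pvalue,
    incidence,
    max_score,
    pwm_log_odds,
    rank_motifs,
    reverse_complement,
    scan_sequences,
    MotifEnrichmentResult,
)
from fairekit.synthetic_data import make_demo_pwm, plant_motifs


def random_seqs(rng, n, length, prefix="s"):
    return {
        f"{prefix}{i}": "".join("ACGT"[b] for b in rng.integers(0, 4, length))
        for i in range(n)
    }


class TestLogOdds:
    def test_uniform_pwm_scores_zero(self):
        pwm = PWM("u", np.full((4, 4), 25.0), pseudocount=0.0)
        assert np.allclose(pwm_log_odds(pwm), 0.0)

    def test_hand_arithmetic(self):
        # P(A) ~= 0.97 after pseudocount vs background 0.25
        pwm = PWM("m", [[97, 1, 1, 1]], pseudocount=0.0)
        table = pwm_log_odds(pwm)
        assert table[0, 0] == pytest.approx(np.log2(0.97 / 0.25), abs=1e-9)

    def test_max_score_is_sum_of_position_maxima(self):
        pwm = make_demo_pwm()
        table = pwm_log_odds(pwm)
        assert max_score(pwm) == pytest.approx(table.max(axis=1).sum())

    def test_zero_background_rejected(self):
        pwm = make_demo_pwm()
        with pytest.raises(ValueError):
            pwm_log_odds(pwm, {"A": 0.0, "C": 0.4, "G": 0.3, "T": 0.3})


class TestScan:
    def test_consensus_sequence_is_hit(self):
        pwm = make_demo_pwm()
        assert max_score(pwm) > 8
        hits = scan_sequences({"s": pwm.consensus()}, pwm, threshold=6)
        assert len(hits) >= 1
        assert hits[0].offset == 0

    def test_reverse_complement_same_incidence(self):
        rng = np.random.default_rng(0)
        pwm = make_demo_pwm()
        seqs = random_seqs(rng, 20, 400)
        planted, _ = plant_motifs(seqs, pwm, rate=2.0, seed=1)
        rc = {k: reverse_complement(v) for k, v in planted.items()}
        assert incidence(planted, pwm) == incidence(rc, pwm)

    def test_windows_with_n_skipped(self):
        pwm = make_demo_pwm()
        seq = pwm.consensus()
        with_n = seq[:4] + "N" + seq[5:]
        assert incidence({"s": seq}, pwm) >= 1
        fwd_hits = [h for h in scan_sequences({"s": with_n}, pwm) if h.strand == "+"]
        assert fwd_hits == []

    def test_motif_longer_than_sequence(self):
        pwm = make_demo_pwm()
        assert scan_sequences({"s": "ACGT"}, pwm) == []

    def test_planted_motifs_all_found_and_brute_force_agreement(self):
        rng = np.random.default_rng(5)
        pwm = make_demo_pwm()
        seqs = random_seqs(rng, 100, 200)
        planted, loci = plant_motifs(
            {k: seqs[k] for k in list(seqs)[:30]}, pwm, rate=5.0, seed=2
        )
        merged = {**seqs, **planted}
        hits = scan_sequences(merged, pwm, threshold=6)
        found = {(h.sequence_id, h.offset) for h in hits}
        assert set(loci) <= found
        assert len(hits) == brute_scan_count(merged, pwm, threshold=6)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(6)
        pwm = make_demo_pwm()
        seqs, _ = plant_motifs(random_seqs(rng, 30, 300), pwm, rate=2.0, seed=3)
        counts = [incidence(seqs, pwm, threshold=t) for t in (2, 4, 6, 8, 12)]
        assert counts == sorted(counts, reverse=True)


class TestEnrichmentPvalue:
    def test_planted_signal_detected(self):
        """Motif planted at ten times the background rate: p <= 0.01 with
        200 background sets."""
        rng = np.random.default_rng(7)
        pwm = make_demo_pwm()
        base = random_seqs(rng, 40, 500)
        fp_seqs, _ = plant_motifs(base, pwm, rate=2.0, seed=4)

        def background(rng_):
            seqs = random_seqs(rng_, 40, 500, prefix="bg")
            out, _ = plant_motifs(seqs, pwm, rate=0.2, seed=int(rng_.integers(2**31)))
            return out

        result = enrichment_pvalue(fp_seqs, background, pwm, threshold=6,
                                   n_sets=200, seed=0)
        assert result.p_value <= 0.01

    def test_zero_incidence_gives_p_one(self):
        pwm = make_demo_pwm()
        fp_seqs = {"s": "A" * 50}

        def background(rng_):
            return random_seqs(rng_, 2, 50, prefix="bg")

        result = enrichment_pvalue(fp_seqs, background, pwm, n_sets=100, seed=0)
        assert result.incidence == 0
        assert result.p_value == 1.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        pwm = make_demo_pwm()
        fp_seqs = random_seqs(rng, 10, 300)

        def background(rng_):
            return random_seqs(rng_, 10, 300, prefix="bg")

        a = enrichment_pvalue(fp_seqs, background, pwm, n_sets=100, seed=9)
        b = enrichment_pvalue(fp_seqs, background, pwm, n_sets=100, seed=9)
        assert a.p_value == b.p_value

    def test_calibration_under_null(self):
        """FP sequences drawn from the background generator itself give
        uniform p-values (KS at alpha = 0.01, 200 trials)."""
        pwm = make_demo_pwm()
        outer = np.random.default_rng(10)
        pvals = []
        for trial in range(200):
            fp_seqs = random_seqs(outer, 6, 250)

            def background(rng_):
                return random_seqs(rng_, 6, 250, prefix="bg")

            result = enrichment_pvalue(fp_seqs, background, pwm, threshold=5,
                                       n_sets=100, seed=int(outer.integers(2**31)))
            pvals.append(result.p_value)
        # add-one empirical p on a discrete statistic is conservative near 1;
        # KS against uniform still should not reject under the null
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRankMotifs:
    def _result(self, motif_id, inc, p=0.001):
        return MotifEnrichmentResult(motif_id, inc, inc / 100.0, p, 100)

    def test_floor_and_descending_order(self):
        # headline-style incidences: 2813 and 1225 pass a floor of 100
        results = [
            self._result("CG11617", 2813),
            self._result("FOXA1", 1225),
            self._result("rare", 50),
        ]
        table = rank_motifs(results, floor=100)
        assert list(table["motif_id"]) == ["CG11617", "FOXA1"]

    def test_all_below_floor_empty(self):
        assert rank_motifs([self._result("x", 10)], floor=100).empty

    def test_ranking_invariant_to_input_order(self):
        results = [self._result(m, i) for m, i in
                   [("a", 500), ("b", 900), ("c", 500), ("d", 120)]]
        forward = rank_motifs(results, floor=100)
        backward = rank_motifs(list(reversed(results)), floor=100)
        assert forward.equals(backward)

    def test_top_k(self):
        results = [self._result(f"m{i}", 1000 - i) for i in range(30)]
        assert len(rank_motifs(results, floor=0, top_k=20)) == 20


class TestDinucleotideShuffle:
    def dinuc_counts(self, seq):
        from collections import Counter

        return Counter(zip(seq, seq[1:]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_preserves_dinucleotide_counts(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 300))
        shuffled = dinucleotide_shuffle(seq, rng)
        assert self.dinuc_counts(shuffled) == self.dinuc_counts(seq)
        assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]

    def test_sampler_changes_sequences(self):
        rng = np.random.default_rng(3)
        seqs = random_seqs(rng, 5, 200)
        sampler = dinucleotide_shuffle_sampler(seqs)
        out = sampler(np.random.default_rng(4))
        assert set(out) == set(seqs)
        assert any(out[k] != seqs[k] for k in seqs)
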