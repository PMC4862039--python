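"""Motif-incidence overrepresentation in peak sequences (Clover-style).

A PWM is scanned against every window of each sequence on both strands;
windows whose summed log2-odds against the background base composition meet
the bit threshold (default 6) are hits, and the number of hits is the
motif's incidence. The raw score is incidence per kilobase scanned, and the
enrichment p-value is empirical: the fraction of resampled background
sequence sets whose raw score is at least the observed one (add-one
corrected so finite resampling never reports p = 0).

The score is a documented simplification — "Clover-style", not
Clover-identical: only the hit threshold and the tail-probability semantics
of the p-value are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import PWM

DEFAULT_THRESHOLD = 6.0
UNIFORM_BG = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    sequence_id: str
    offset: int
    strand: str
    log_odds: float


@dataclass
class MotifEnrichmentResult:
    motif_id: str
    incidence: int
    raw_score: float  # hits per kb scanned
    p_value: Optional[float]
    n_background_sets: int

    def to_dict(self) -> dict:
        return {
            "motif_id": self.motif_id,
            "incidence": self.incidence,
            "raw_score": self.raw_score,
            "p_value": self.p_value,
            "n_background_sets": self.n_background_sets,
        }


def pwm_log_odds(pwm: PWM, background: dict[str, float] = UNIFORM_BG) -> np.ndarray:
    """Position-wise log2-odds score table, shape (motif length, 4).

    ``score[i, b] = log2(P_pwm(b | i) / P_bg(b))`` using the PWM's
    pseudocount-normalized probabilities.
    """
    bg = np.array([background[b] for b in "ACGT"], dtype=float)
    if (bg <= 0).any():
        raise ValueError("background frequencies must be positive")
    if not np.isclose(bg.sum(), 1.0):
        raise ValueError("background frequencies must sum to 1")
    return np.log2(pwm.probs / bg)


def max_score(pwm: PWM, background: dict[str, float] = UNIFORM_BG) -> float:
    """Best achievable window score: sum of per-position maxima."""
    return float(pwm_log_odds(pwm, background).max(axis=1).sum())


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to base indices; anything outside ACGT becomes 4."""
    out = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _scan_encoded(encoded: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Window scores for one strand; windows containing non-ACGT are NaN."""
    m = table.shape[0]
    n = len(encoded) - m + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for i in range(m):
        window_bases = encoded[i : i + n]
        bad = window_bases == 4
        valid &= ~bad
        safe = np.where(bad, 0, window_bases)
        scores += table[i, safe]
    scores[~valid] = np.nan
    return scores


def scan_sequences(
    seqs: dict[str, str],
    pwm: PWM,
    threshold: float = DEFAULT_THRESHOLD,
    both_strands: bool = True,
    background: dict[str, float] = UNIFORM_BG,
) -> list[MotifHit]:
    """Every window on either strand scoring at least ``threshold`` bits.

    Offsets are always on the forward sequence; a minus-strand hit at offset
    ``o`` covers forward bases ``[o, o + len(pwm))``. Windows containing N
    are skipped. Sequences shorter than the motif yield no hits.
    """
    table = pwm_log_odds(pwm, background)
    m = len(pwm)
    hits: list[MotifHit] = []
    for seq_id, seq in seqs.items():
        seq = seq.upper()
        encoded = _encode(seq)
        fwd = _scan_encoded(encoded, table)
        for offset in np.nonzero(fwd >= threshold)[0]:
            hits.append(MotifHit(pwm.motif_id, seq_id, int(offset), "+", float(fwd[offset])))
        if both_strands:
            rc = _encode(reverse_complement(seq))
            rev = _scan_encoded(rc, table)
            n = len(rev)
            for ro in np.nonzero(rev >= threshold)[0]:
                offset = n - 1 - int(ro)  # forward-strand coordinate of the window
                hits.append(MotifHit(pwm.motif_id, seq_id, offset, "-", float(rev[ro])))
    hits.sort(key=lambda h: (h.sequence_id, h.offset, h.strand))
    return hits


def incidence(
    seqs: dict[str, str],
    pwm: PWM,
    threshold: float = DEFAULT_THRESHOLD,
    both_strands: bool = True,
    background: dict[str, float] = UNIFORM_BG,
) -> int:
    return len(scan_sequences(seqs, pwm, threshold, both_strands, background))


def _raw_score(n_hits: int, seqs: dict[str, str]) -> float:
    total_kb = sum(len(s) for s in seqs.values()) / 1000.0
    return n_hits / total_kb if total_kb > 0 else 0.0


def enrichment_pvalue(
    fp_seqs: dict[str, str],
    background_generator: Callable[[np.random.Generator], dict[str, str]],
    pwm: PWM,
    threshold: float = DEFAULT_THRESHOLD,
    n_sets: int = 1000,
    seed: int = 0,
    background: dict[str, float] = UNIFORM_BG,
) -> MotifEnrichmentResult:
    """Empirical enrichment p-value against resampled background sets.

    ``background_generator`` is called once per set with a seeded
    ``numpy.random.Generator`` and must return a dict of sequences; the
    p-value is ``(1 + #{sets with raw score >= observed}) / (1 + n_sets)``.
    """
    if n_sets < 100:
        raise ValueError("n_sets must be >= 100")
    obs_hits = incidence(fp_seqs, pwm, threshold, background=background)
    obs_score = _raw_score(obs_hits, fp_seqs)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_sets):
        bg_seqs = background_generator(rng)
        if not bg_seqs or all(len(s) == 0 for s in bg_seqs.values()):
            raise ValueError("background generator yielded an empty set")
        bg_hits = incidence(bg_seqs, pwm, threshold, background=background)
        if _raw_score(bg_hits, bg_seqs) >= obs_score:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_sets)
    return MotifEnrichmentResult(
        motif_id=pwm.motif_id,
        incidence=obs_hits,
        raw_score=obs_score,
        p_value=p,
        n_background_sets=n_sets,
    )


def genome_background_sampler(
    genome: dict[str, str],
    peaks,
    lengths: Sequence[int],
) -> Callable[[np.random.Generator], dict[str, str]]:
    """Background generator sampling length-matched windows uniformly from
    non-peak genome sequence."""
    masked: dict[str, np.ndarray] = {}
    for contig, seq in genome.items():
        mask = np.zeros(len(seq), dtype=bool)
        masked[contig] = mask
    for p in peaks:
        iv = p.interval
        if iv.contig in masked:
            masked[iv.contig][iv.start : min(iv.end, len(masked[iv.contig]))] = True
    contigs = sorted(genome)

    def generate(rng: np.random.Generator) -> dict[str, str]:
        out: dict[str, str] = {}
        for i, length in enumerate(lengths):
            for _ in range(200):  # rejection sampling of non-peak windows
                contig = contigs[int(rng.integers(len(contigs)))]
                seq = genome[contig]
                if len(seq) < length:
                    continue
                start = int(rng.integers(0, len(seq) - length + 1))
                if masked[contig][start : start + length].any():
                    continue
                out[f"bg_{i}"] = seq[start : start + length]
                break
            else:
                raise ValueError("could not place a non-peak background window")
        return out

    return generate


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Random Eulerian walk on the dinucleotide graph: for every vertex except
    the terminal base a random "last exit" edge is drawn until the last-exit
    edges all lead to the terminal base, the remaining edges are shuffled,
    and the walk is read off. Start and end bases are preserved.
    """
    if len(seq) < 3 or len(set(seq)) == 1:
        return seq
    chars = sorted(set(seq))
    nexts: dict[str, list[str]] = {c: [] for c in chars}
    for a, b in zip(seq, seq[1:]):
        nexts[a].append(b)
    last = seq[-1]

    while True:
        lasts: dict[str, str] = {}
        for c in chars:
            if c == last or not nexts[c]:
                continue
            lasts[c] = nexts[c][int(rng.integers(len(nexts[c])))]
        ok = True
        for c in lasts:
            seen: set[str] = set()
            cur = c
            while cur in lasts and cur not in seen:
                seen.add(cur)
                cur = lasts[cur]
            if cur != last:
                ok = False
                break
        if ok:
            break

    order: dict[str, list[str]] = {}
    for c in chars:
        edges = list(nexts[c])
        if c in lasts:
            edges.remove(lasts[c])
        rng.shuffle(edges)
        if c in lasts:
            edges.append(lasts[c])
        order[c] = edges

    out = [seq[0]]
    cursor = {c: 0 for c in chars}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = order[cur][cursor[cur]]
        cursor[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def dinucleotide_shuffle_sampler(
    fp_seqs: dict[str, str],
) -> Callable[[np.random.Generator], dict[str, str]]:
    """Background generator that dinucleotide-shuffles each input sequence."""

    def generate(rng: np.random.Generator) -> dict[str, str]:
        return {k: dinucleotide_shuffle(v, rng) for k, v in fp_seqs.items()}

    return generate


def rank_motifs(results: Sequence[MotifEnrichmentResult], floor: int = 100,
                top_k: Optional[int] = None, alpha: float = 0.05) -> pd.DataFrame:
    """Table of motifs with incidence above ``floor``, sorted by descending
    incidence (ties by motif id), with a significance flag."""
    rows = [
        {
            "motif_id": r.motif_id,
            "incidence": r.incidence,
            "raw_score": r.raw_score,
            "p_value": r.p_value,
            "significant": (r.p_value is not None and r.p_value <= alpha),
        }
        for r in results
        if r.incidence > floor
    ]
    df = pd.DataFrame(
        rows, columns=["motif_id", "incidence", "raw_score", "p_value", "significant"]
    )
    df = df.sort_values(
        ["incidence", "motif_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if top_k is not None:
        df = df.head(top_k)
    return df
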