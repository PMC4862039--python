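"""SNP-to-peak mapping and the peak-resampling null for assortment bias.

A SNP maps to every peak whose interval contains its position (positions are
supercontig-scoped, so only same-contig peaks qualify). The null
distribution of SNP content is built by repeatedly sampling a fixed number
of peaks uniformly (without replacement by default) and counting the SNPs
they carry; the headline statistic is the mean SNP count per 1000 sampled
peaks. An observed count far in the tail of the null flags assortment bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import FairePeak, Variant
from intervaltree import IntervalTree


@dataclass
class SnpMapResult:
    n_snps_total: int
    n_snps_in_fp: int
    assignments: list[tuple[Variant, str]] = field(default_factory=list)
    per_peak_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class BootstrapResult:
    sample_size: int
    n_reps: int
    replicate_counts: np.ndarray
    mean_per_1000: float
    q025: float
    q975: float
    seed: int
    with_replacement: bool

    def to_dict(self) -> dict:
        return {
            "sample_size": self.sample_size,
            "n_reps": self.n_reps,
            "mean_per_1000": self.mean_per_1000,
            "q025": self.q025,
            "q975": self.q975,
            "seed": self.seed,
            "with_replacement": self.with_replacement,
        }


def map_snps_to_peaks(snps: Sequence[Variant], peaks: Sequence[FairePeak]) -> SnpMapResult:
    """Assign each SNP to every peak containing it.

    ``n_snps_in_fp`` counts distinct SNPs inside at least one peak; the
    per-peak counts (used as the resampling weights) count every SNP in
    every peak containing it, so a SNP in two overlapping peaks contributes
    to both.
    """
    trees: dict[str, IntervalTree] = {}
    for peak in peaks:
        iv = peak.interval
        trees.setdefault(iv.contig, IntervalTree())[iv.start : iv.end] = peak.peak_id

    assignments: list[tuple[Variant, str]] = []
    per_peak: dict[str, int] = {p.peak_id: 0 for p in peaks}
    n_in = 0
    for snp in snps:
        tree = trees.get(snp.contig)
        hits = sorted(node.data for node in tree.at(snp.position0)) if tree else []
        if hits:
            n_in += 1
        for peak_id in hits:
            assignments.append((snp, peak_id))
            per_peak[peak_id] += 1
    return SnpMapResult(
        n_snps_total=len(snps),
        n_snps_in_fp=n_in,
        assignments=assignments,
        per_peak_counts=per_peak,
    )


def bootstrap_snp_null(
    peak_snp_counts: Sequence[int],
    sample_size: int = 10000,
    n_reps: int = 10000,
    with_replacement: bool = False,
    seed: int = 0,
) -> BootstrapResult:
    """Null distribution of SNP counts in random peak samples.

    Each replicate draws ``sample_size`` peaks uniformly from the population
    (without replacement by default) and sums their SNP counts. The
    expectation of the per-1000 mean is 1000 * total SNPs in peaks / total
    peaks under either sampling mode.
    """
    counts = np.asarray(peak_snp_counts, dtype=np.int64)
    n_peaks = len(counts)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    if not with_replacement and sample_size > n_peaks:
        raise ValueError(
            f"sample_size {sample_size} exceeds population {n_peaks} without replacement"
        )
    rng = np.random.default_rng(seed)
    reps = np.empty(n_reps, dtype=np.int64)
    if with_replacement:
        for r in range(n_reps):
            idx = rng.integers(0, n_peaks, size=sample_size)
            reps[r] = counts[idx].sum()
    else:
        for r in range(n_reps):
            idx = rng.choice(n_peaks, size=sample_size, replace=False)
            reps[r] = counts[idx].sum()
    mean_per_1000 = 1000.0 * reps.mean() / sample_size
    return BootstrapResult(
        sample_size=sample_size,
        n_reps=n_reps,
        replicate_counts=reps,
        mean_per_1000=float(mean_per_1000),
        q025=float(np.quantile(reps, 0.025)),
        q975=float(np.quantile(reps, 0.975)),
        seed=seed,
        with_replacement=with_replacement,
    )


def assortment_bias_test(observed, null: BootstrapResult, alpha: float = 0.05) -> dict:
    """Compare an observed SNP-in-peak count with the resampling null.

    ``observed`` is either a :class:`SnpMapResult` over a set of peaks (its
    total per-peak SNP count is scaled linearly to the null's sample size)
    or a plain count already on the sample-size scale. The two-sided
    empirical p-value is the fraction of replicates deviating from the null
    mean at least as much as the observed count. A degenerate
    (zero-variance) null yields a flagged sentinel.
    """
    if null.n_reps < 100:
        raise ValueError("need >= 100 null replicates")
    reps = null.replicate_counts.astype(float)
    if isinstance(observed, SnpMapResult):
        n_peaks_obs = len(observed.per_peak_counts)
        if n_peaks_obs == 0:
            raise ValueError("observed result has no peaks")
        total_in_peaks = sum(observed.per_peak_counts.values())
        observed_scaled = total_in_peaks * null.sample_size / n_peaks_obs
    else:
        observed_scaled = float(observed)

    sd = reps.std(ddof=1)
    if sd == 0:
        return {
            "degenerate_null": True,
            "z_score": None,
            "p_value": None,
            "no_bias": None,
            "observed_scaled": observed_scaled,
        }
    z = (observed_scaled - reps.mean()) / sd
    dev = abs(observed_scaled - reps.mean())
    p = (1 + int(np.sum(np.abs(reps - reps.mean()) >= dev))) / (1 + null.n_reps)
    return {
        "degenerate_null": False,
        "z_score": float(z),
        "p_value": float(min(p, 1.0)),
        "no_bias": bool(p > alpha),
        "observed_scaled": float(observed_scaled),
    }
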