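"""Aggregate (metagene) signal around transcription start sites.

For every TSS the signal is sampled strand-aware over ``[-window, +window)``
(minus-strand genes are mirrored so "upstream" is always negative), then
averaged per bin across TSSs. The default source is a peak list scored as
0/1 base coverage; a bedGraph track may be supplied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import FairePeak, GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1000
DEFAULT_BIN = 25

NO_ENRICHMENT = None  # sentinel for a flat profile


@dataclass
class TssProfile:
    """Binned mean signal relative to the TSS (upstream negative)."""

    bin_edges: np.ndarray  # signed bp offsets, length n_bins + 1
    signal: np.ndarray  # per-bin mean, length n_bins
    n_tss: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.signal) != len(self.bin_edges) - 1:
            raise ValueError("signal length must be len(bin_edges) - 1")
        widths = np.diff(self.bin_edges)
        if len(set(widths.tolist())) != 1:
            raise ValueError("bins must have uniform width")
        if self.n_tss < 1:
            raise ValueError("profile needs at least one TSS")

    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "mean_signal": self.signal,
            }
        )


class _CoverageSource:
    """Per-base signal lookup over one contig namespace."""

    def __init__(self, contig_lengths: Optional[dict[str, int]] = None):
        self.contig_lengths = contig_lengths

    def window(self, contig: str, lo: int, hi: int) -> np.ndarray:
        """Values for bases [lo, hi); out-of-contig bases are NaN."""
        values = self._values(contig, lo, hi)
        offsets = np.arange(lo, hi)
        invalid = offsets < 0
        if self.contig_lengths is not None and contig in self.contig_lengths:
            invalid |= offsets >= self.contig_lengths[contig]
        values[invalid] = np.nan
        return values

    def _values(self, contig: str, lo: int, hi: int) -> np.ndarray:
        raise NotImplementedError


class PeakCoverage(_CoverageSource):
    """0/1 indicator: a base scores 1 when covered by at least one peak."""

    def __init__(self, peaks: Sequence[FairePeak],
                 contig_lengths: Optional[dict[str, int]] = None):
        super().__init__(contig_lengths)
        self.by_contig: dict[str, list[tuple[int, int]]] = {}
        for p in peaks:
            self.by_contig.setdefault(p.interval.contig, []).append(
                (p.interval.start, p.interval.end)
            )

    def _values(self, contig: str, lo: int, hi: int) -> np.ndarray:
        out = np.zeros(hi - lo, dtype=float)
        for start, end in self.by_contig.get(contig, []):
            a, b = max(start, lo), min(end, hi)
            if a < b:
                out[a - lo : b - lo] = 1.0
        return out


class BedGraphCoverage(_CoverageSource):
    """Signal from a bedGraph track; uncovered bases score 0."""

    def __init__(self, records: Sequence[tuple[GenomicInterval, float]],
                 contig_lengths: Optional[dict[str, int]] = None):
        super().__init__(contig_lengths)
        self.by_contig: dict[str, list[tuple[int, int, float]]] = {}
        for iv, value in records:
            self.by_contig.setdefault(iv.contig, []).append((iv.start, iv.end, value))

    def _values(self, contig: str, lo: int, hi: int) -> np.ndarray:
        out = np.zeros(hi - lo, dtype=float)
        for start, end, value in self.by_contig.get(contig, []):
            a, b = max(start, lo), min(end, hi)
            if a < b:
                out[a - lo : b - lo] = value
        return out


def aggregate_around_tss(
    signal_source: Union[Sequence[FairePeak], _CoverageSource],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_WINDOW,
    bin: int = DEFAULT_BIN,
    contig_lengths: Optional[dict[str, int]] = None,
) -> TssProfile:
    """Mean signal in ``bin``-bp bins over ``[-window, +window)`` around all
    TSSs, strand-aware.

    ``signal_source`` is a list of peaks (scored as 0/1 coverage) or a
    prepared coverage source. TSSs closer than ``window`` to a contig edge
    contribute only their in-range bases (logged, not an error).
    """
    if window % bin != 0:
        raise ValueError(f"window {window} must be a multiple of bin {bin}")
    if not genes:
        raise ValueError("need at least one gene")
    if isinstance(signal_source, _CoverageSource):
        source = signal_source
        if contig_lengths is not None:
            source.contig_lengths = contig_lengths
    else:
        source = PeakCoverage(signal_source, contig_lengths)

    n_bases = 2 * window
    sums = np.zeros(n_bases)
    counts = np.zeros(n_bases)
    n_edge = 0
    for gene in genes:
        tss = gene.tss
        if gene.strand == "+":
            values = source.window(gene.contig, tss - window, tss + window)
        else:
            # mirror: upstream of a - strand gene is the higher-coordinate side
            values = source.window(gene.contig, tss - window + 1, tss + window + 1)[::-1]
        valid = ~np.isnan(values)
        if not valid.all():
            n_edge += 1
        sums[valid] += values[valid]
        counts[valid] += 1

    if n_edge:
        logger.info("aggregate_around_tss: %d TSSs within %d bp of a contig edge", n_edge, window)

    n_bins = n_bases // bin
    bin_sums = sums.reshape(n_bins, bin).sum(axis=1)
    bin_counts = counts.reshape(n_bins, bin).sum(axis=1)
    with np.errstate(invalid="ignore"):
        signal = np.where(bin_counts > 0, bin_sums / np.maximum(bin_counts, 1), np.nan)
    edges = np.arange(-window, window + 1, bin)
    return TssProfile(bin_edges=edges, signal=signal, n_tss=len(genes))


def profile_peak_offset(profile: TssProfile) -> Optional[float]:
    """Center of the highest-signal bin, in signed bp relative to the TSS.

    Ties are broken toward the bin whose center is nearest 0. A flat
    profile returns the no-enrichment sentinel (None).
    """
    signal = profile.signal
    finite = signal[np.isfinite(signal)]
    if len(finite) == 0 or np.allclose(finite, finite[0]):
        return NO_ENRICHMENT
    centers = profile.bin_centers()
    top = np.nanmax(signal)
    candidates = [c for c, s in zip(centers, signal) if np.isfinite(s) and s == top]
    return float(min(candidates, key=lambda c: (abs(c), c)))


def write_profile_tsv(profile: TssProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)
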