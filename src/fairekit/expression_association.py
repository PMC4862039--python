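"""Association of peak annotations with gene expression.

A gene counts as peak-associated when at least one peak lies within 1 kb
upstream of its TSS or inside the gene body. Associated genes split into an
upstream class and an intragenic class (a gene with both kinds of peak
counts as upstream, so the split is exhaustive and mutually exclusive). The
positional-effect statistic compares mean abundance of genes whose nearest
upstream peak is very close to the TSS (<= ``near`` bp) against genes whose
nearest upstream peak is farther (``(near, window]`` bp).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import FairePeak, GeneModel, ValidationError
from .interval_annotation import tss_distance

DEFAULT_NEAR = 100
DEFAULT_WINDOW = 1000

UNDEFINED_FOLD = None  # sentinel when a comparison group is empty


@dataclass
class AssociationSummary:
    n_expressed: int
    n_expressed_with_fp: int
    frac_with_fp: float
    split_upstream: float
    split_intragenic: float
    fold_near_vs_far: Optional[float]
    n_near: int
    n_far: int
    fold_defined: bool

    def to_dict(self) -> dict:
        return {
            "n_expressed": self.n_expressed,
            "n_expressed_with_fp": self.n_expressed_with_fp,
            "frac_with_fp": self.frac_with_fp,
            "split_upstream": self.split_upstream,
            "split_intragenic": self.split_intragenic,
            "fold_near_vs_far": self.fold_near_vs_far,
            "n_near": self.n_near,
            "n_far": self.n_far,
            "fold_defined": self.fold_defined,
        }


def flag_expressed(expression: pd.DataFrame, threshold: float = 0.0) -> pd.DataFrame:
    """Add an ``expressed`` flag: abundance strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if expression["gene_id"].duplicated().any():
        dupes = expression.loc[expression["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"duplicate gene_id(s) in expression table: {dupes[:5]}")
    out = expression.copy()
    out["expressed"] = out["abundance"] > threshold
    return out


def gene_peak_relations(
    peaks: Sequence[FairePeak],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Per-gene table: has_upstream, has_intragenic, nearest upstream peak
    distance (positive bp, NaN when none within ``window``)."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        iv = p.interval
        trees.setdefault(iv.contig, IntervalTree())[iv.start : iv.end] = p
    rows = []
    for gene in genes:
        has_up = False
        has_intra = False
        nearest_up = np.nan
        tree = trees.get(gene.contig)
        g = gene.interval
        candidates = (
            [node.data for node in tree.overlap(g.start - window - 1, g.end + window + 1)]
            if tree is not None
            else []
        )
        for peak in candidates:
            if peak.interval.overlaps(gene.interval):
                has_intra = True
                continue
            d = tss_distance(peak, gene)
            if -window <= d < 0:
                has_up = True
                if np.isnan(nearest_up) or -d < nearest_up:
                    nearest_up = -d
        rows.append(
            {
                "gene_id": gene.gene_id,
                "has_upstream": has_up,
                "has_intragenic": has_intra,
                "nearest_upstream_bp": nearest_up,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "has_upstream", "has_intragenic", "nearest_upstream_bp"]
    )


def associate(
    relations: pd.DataFrame,
    expression: pd.DataFrame,
    near: int = DEFAULT_NEAR,
    window: int = DEFAULT_WINDOW,
    expressed_only_fold: bool = True,
    log_means: bool = False,
) -> AssociationSummary:
    """Join gene–peak relations with expression and summarize.

    ``relations`` is the output of :func:`gene_peak_relations`;
    ``expression`` must carry the ``expressed`` flag from
    :func:`flag_expressed`. The fold change is the ratio of arithmetic mean
    abundance (or mean log1p-abundance with ``log_means``) between genes
    whose nearest upstream peak is within ``near`` bp of the TSS and genes
    whose nearest upstream peak sits in ``(near, window]`` bp.
    """
    if "expressed" not in expression.columns:
        expression = flag_expressed(expression)
    merged = expression.merge(relations, on="gene_id", how="left")
    for col in ("has_upstream", "has_intragenic"):
        merged[col] = merged[col].eq(True)  # missing genes -> no relation

    expressed = merged[merged["expressed"]]
    if len(expressed) == 0:
        raise ValueError("no expressed genes; cannot summarize association")

    associated = expressed[expressed["has_upstream"] | expressed["has_intragenic"]]
    n_expressed = len(expressed)
    n_with = len(associated)
    # upstream takes precedence so the split is exhaustive and exclusive
    n_split_up = int(associated["has_upstream"].sum())
    n_split_intra = n_with - n_split_up

    pool = expressed if expressed_only_fold else merged
    near_mask = pool["nearest_upstream_bp"] <= near
    far_mask = (pool["nearest_upstream_bp"] > near) & (pool["nearest_upstream_bp"] <= window)
    near_ab = pool.loc[near_mask, "abundance"].to_numpy(dtype=float)
    far_ab = pool.loc[far_mask, "abundance"].to_numpy(dtype=float)
    if log_means:
        near_ab, far_ab = np.log1p(near_ab), np.log1p(far_ab)

    fold: Optional[float]
    if len(near_ab) == 0 or len(far_ab) == 0 or far_ab.mean() == 0:
        fold, fold_defined = UNDEFINED_FOLD, False
    else:
        fold, fold_defined = float(near_ab.mean() / far_ab.mean()), True

    return AssociationSummary(
        n_expressed=n_expressed,
        n_expressed_with_fp=n_with,
        frac_with_fp=n_with / n_expressed,
        split_upstream=(n_split_up / n_with) if n_with else 0.0,
        split_intragenic=(n_split_intra / n_with) if n_with else 0.0,
        fold_near_vs_far=fold,
        n_near=len(near_ab),
        n_far=len(far_ab),
        fold_defined=fold_defined,
    )


def per_gene_table(relations: pd.DataFrame, expression: pd.DataFrame) -> pd.DataFrame:
    """Per-gene export: abundance, nearest upstream peak distance and
    association class (upstream / intragenic / none)."""
    merged = expression.merge(relations, on="gene_id", how="left")
    for col in ("has_upstream", "has_intragenic"):
        merged[col] = merged[col].eq(True)  # missing genes -> no relation
    merged["association_class"] = np.where(
        merged["has_upstream"], "upstream",
        np.where(merged["has_intragenic"], "intragenic", "none"),
    )
    cols = ["gene_id", "abundance", "nearest_upstream_bp", "association_class"]
    return merged[cols].rename(columns={"nearest_upstream_bp": "nearest_fp_distance"})
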