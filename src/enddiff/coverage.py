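"""Per-base strand-specific coverage, gene expression and quantile normalization.

Coverage is counted per base: a base covered by 14 same-strand reads has
expression level 14.  A gene's expression is the mean coverage over its
annotated ORF on its own strand; genes with mean >= 5 in a condition are
called expressed there.  Expression matrices across conditions can be
quantile normalized (every column receives the across-column means of the
order statistics; ties get the mean over their rank range).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, Genome
from .mapping import MappedRead


@dataclass
class StrandedCoverageTrack:
    """Dense per-base, per-strand coverage arrays for one condition."""

    arrays: dict[str, dict[str, np.ndarray]]  # chrom -> strand -> array
    condition: str = ""

    @classmethod
    def zeros(cls, chrom_lengths: Mapping[str, int], condition: str = "",
              dtype=np.float64) -> "StrandedCoverageTrack":
        return cls(
            {c: {s: np.zeros(n, dtype=dtype) for s in "+-"}
             for c, n in chrom_lengths.items()},
            condition,
        )

    def values(self, chrom: str, strand: str) -> np.ndarray:
        return self.arrays[chrom][strand]

    def total(self) -> float:
        return float(sum(a.sum() for by_s in self.arrays.values()
                         for a in by_s.values()))


def accumulate_coverage(
    mapped_reads: Iterable[MappedRead],
    genome: Genome,
    condition: str = "",
) -> StrandedCoverageTrack:
    """Count, per base and strand, how many mapped reads cover it."""
    lengths = {c: genome.length(c) for c in genome.names()}
    diff = {c: {s: np.zeros(n + 1, dtype=np.int64) for s in "+-"}
            for c, n in lengths.items()}
    for r in mapped_reads:
        if r.chrom not in diff:
            raise ValueError(f"read {r.read_id!r} on unknown chromosome {r.chrom}")
        if r.start < 0 or r.end > lengths[r.chrom]:
            raise ValueError(f"read {r.read_id!r} outside chromosome bounds")
        d = diff[r.chrom][r.strand]
        d[r.start] += 1
        d[r.end] -= 1
    track = StrandedCoverageTrack.zeros(lengths, condition, dtype=np.int64)
    for c in diff:
        for s in "+-":
            track.arrays[c][s] = np.cumsum(diff[c][s][:-1])
    return track


def gene_expression(
    track: StrandedCoverageTrack, gene: GeneModel, exclude_introns: bool = False
) -> float:
    """Mean same-strand coverage over the annotated ORF span.

    Intron bases are part of the span by default; ``exclude_introns``
    restricts the mean to exonic ORF bases.
    """
    arr = track.values(gene.chrom, gene.strand)
    s, e = gene.orf_interval
    if not exclude_introns or not gene.introns:
        return float(np.mean(arr[s:e]))
    mask = np.ones(e - s, dtype=bool)
    for a, b in gene.introns:
        mask[a - s : b - s] = False
    return float(np.mean(arr[s:e][mask]))


def expression_matrix(
    tracks: Sequence[StrandedCoverageTrack],
    genes: Sequence[GeneModel],
    exclude_introns: bool = False,
) -> pd.DataFrame:
    """Genes x conditions matrix of mean-ORF coverage (raw scale)."""
    data = {
        t.condition or f"cond{i}": [gene_expression(t, g, exclude_introns)
                                    for g in genes]
        for i, t in enumerate(tracks)
    }
    return pd.DataFrame(data, index=[g.gene_id for g in genes])


def expressed_genes(matrix: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Boolean table: expressed (mean ORF coverage >= threshold) per condition,
    plus an ``anywhere`` column true when expressed in at least one condition."""
    flags = matrix >= threshold
    flags = flags.copy()
    flags["anywhere"] = flags.any(axis=1)
    return flags


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classical quantile normalization across conditions (columns).

    Each column's rank r is replaced by the across-column mean of the r-th
    order statistics; tied values receive the mean over their rank range.
    After normalization every column shares one sorted multiset.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile normalization needs >= 2 conditions; returned unchanged")
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    order_stat_means = np.sort(values, axis=0).mean(axis=1)
    ranks = matrix.rank(method="average").to_numpy() - 1.0  # 0-based, ties averaged
    lo = np.floor(ranks).astype(int)
    hi = np.ceil(ranks).astype(int)
    normalized = (order_stat_means[lo] + order_stat_means[hi]) / 2.0
    # fractional average ranks spanning more than two order statistics
    # (long ties) need the full range mean rather than the two endpoints
    for j in range(values.shape[1]):
        col = values[:, j]
        _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        if counts.max() > 2:
            sorted_idx = np.argsort(col, kind="stable")
            pos = np.empty_like(sorted_idx)
            pos[sorted_idx] = np.arange(len(col))
            for u in np.flatnonzero(counts > 2):
                members = np.flatnonzero(inverse == u)
                rank_lo = pos[members].min()
                rank_hi = pos[members].max()
                normalized[members, j] = order_stat_means[rank_lo : rank_hi + 1].mean()
    return pd.DataFrame(normalized, index=matrix.index, columns=matrix.columns)
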