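"""Differential 5'/3' transcript-end calling by coverage-topology comparison.

For each gene the reference and test condition's log2 coverage landscapes
are median-normalized over the annotated ORF, where expression should be
identical after normalization.  The per-base standard deviation of their
difference over the ORF is the gene's signal noise ``n``.  A differential
end is the first region — nearest the ORF boundary, judged by both a 10-bp
and an 80-bp sliding-window mean — whose normalized difference exceeds
``3.5 * n`` (but never less than a fourfold change, 2 log2 units) with one
sign over at least 40 consecutive bases.  Candidate regions must be
sufficiently expressed in the higher condition, must not be an annotated
intron, and must be mappable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .coverage import StrandedCoverageTrack
from .io_formats import GeneModel
from .mapping import MappabilityTrack, gene_mappable


@dataclass
class CallerParams:
    """Tunable thresholds of the end caller (log2 scale where noted)."""

    noise_multiplier: float = 3.5    # threshold = noise_multiplier * n ...
    min_fold_log2: float = 2.0       # ... but never below a fourfold change
    window_small: int = 10
    window_large: int = 80
    min_end_length: int = 40
    flank_max: int = 1000            # how far past the ORF boundary to scan
    inset_max: int = 300             # how far into the ORF (codon-loss truncations)
    min_region_expression: float = 5.0
    pseudocount: float = 1.0
    mappability_cutoff: float = 94.0
    conjunctive_windows: bool = True  # both windows must pass (vs either)

    def __post_init__(self) -> None:
        if self.window_small > self.window_large:
            raise ValueError("window_small must be <= window_large")
        if min(self.noise_multiplier, self.min_fold_log2, self.window_small,
               self.min_end_length, self.flank_max, self.inset_max) <= 0:
            raise ValueError("caller parameters must be positive")


@dataclass
class GeneNoise:
    """Per-gene signal noise: sd of the normalized log2 difference over the ORF."""

    gene_id: str
    n: float
    median_offset: float = 0.0

    def threshold(self, params: CallerParams) -> float:
        return max(params.noise_multiplier * self.n, params.min_fold_log2)


@dataclass
class DifferentialEnd:
    """A called condition-specific transcript end (genome coordinates)."""

    gene_id: str
    condition: str
    side: int                 # 5 or 3
    direction: str            # longer | shorter
    chrom: str
    interval: tuple[int, int]
    mean_log2_diff: float
    noise: float
    start_codon_lost: bool = False
    stop_codon_lost: bool = False

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["interval"] = list(self.interval)
        return d


@dataclass
class _GeneWindow:
    """Normalized per-base data over one gene's analysis window."""

    gene: GeneModel
    start: int                # genome coordinate of window base 0
    norm_ref: np.ndarray
    norm_cond: np.ndarray
    raw_ref: np.ndarray
    raw_cond: np.ndarray
    median_offset: float


def analysis_window(
    gene: GeneModel,
    chrom_length: int,
    params: CallerParams,
    neighbors: Sequence[GeneModel] = (),
) -> tuple[int, int]:
    """[ORF - flank, ORF + flank) clipped to the chromosome and to the
    nearest same-strand neighbor's ORF boundary on each side."""
    lo = max(0, gene.orf_start - params.flank_max)
    hi = min(chrom_length, gene.orf_end + params.flank_max)
    for other in neighbors:
        if other.gene_id == gene.gene_id or other.chrom != gene.chrom:
            continue
        if other.strand != gene.strand:
            continue
        if other.orf_end <= gene.orf_start:
            lo = max(lo, other.orf_end)
        elif other.orf_start >= gene.orf_end:
            hi = min(hi, other.orf_start)
    return lo, hi


def normalize_pair(
    track_ref: StrandedCoverageTrack,
    track_cond: StrandedCoverageTrack,
    gene: GeneModel,
    params: CallerParams | None = None,
    window: tuple[int, int] | None = None,
) -> _GeneWindow:
    """log2(coverage + pseudocount) over the analysis window, with the
    condition track shifted so the two ORF medians coincide."""
    params = params or CallerParams()
    chrom_len = len(track_ref.values(gene.chrom, gene.strand))
    if window is None:
        window = analysis_window(gene, chrom_len, params)
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"{gene.gene_id}: empty analysis window")
    raw_ref = np.asarray(track_ref.values(gene.chrom, gene.strand)[lo:hi], dtype=float)
    raw_cond = np.asarray(track_cond.values(gene.chrom, gene.strand)[lo:hi], dtype=float)
    norm_ref = np.log2(raw_ref + params.pseudocount)
    norm_cond = np.log2(raw_cond + params.pseudocount)
    s, e = gene.orf_start - lo, gene.orf_end - lo
    shift = float(np.median(norm_ref[s:e]) - np.median(norm_cond[s:e]))
    norm_cond = norm_cond + shift
    return _GeneWindow(gene, lo, norm_ref, norm_cond, raw_ref, raw_cond, shift)


def noise_level(gw: _GeneWindow) -> GeneNoise:
    """Population sd of the normalized difference over the annotated ORF."""
    gene = gw.gene
    s, e = gene.orf_start - gw.start, gene.orf_end - gw.start
    if e - s < 2:
        raise ValueError(f"{gene.gene_id}: ORF too short for a noise estimate")
    d = gw.norm_cond[s:e] - gw.norm_ref[s:e]
    return GeneNoise(gene.gene_id, float(np.std(d)), gw.median_offset)


def _sliding_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Mean of a w-window centered on each base, truncated at the edges."""
    c = np.concatenate(([0.0], np.cumsum(x)))
    n = len(x)
    idx = np.arange(n)
    lo = np.clip(idx - w // 2, 0, n)
    hi = np.clip(idx - w // 2 + w, 0, n)
    return (c[hi] - c[lo]) / np.maximum(hi - lo, 1)


def call_differential_end(
    gw: _GeneWindow,
    side: int,
    noise: GeneNoise,
    params: CallerParams | None = None,
    mappability: MappabilityTrack | None = None,
    condition: str = "",
) -> DifferentialEnd | None:
    """Call the differential end nearest the ORF boundary on one side.

    Scans outward from the start codon (side 5) or the stop codon (side 3)
    up to ``flank_max`` and inward into the ORF up to ``inset_max``.  A base
    qualifies when both sliding-window means of the normalized difference
    lie beyond ``+T`` (longer in the test condition) or ``-T`` (shorter);
    the nearest run of >= ``min_end_length`` uniformly signed qualifying
    bases is the candidate.  The candidate is rejected — yielding no call —
    when the higher condition's raw coverage over it is below
    ``min_region_expression``, when it lies inside an annotated intron, or
    when its mean mappability falls below the cutoff.
    """
    params = params or CallerParams()
    gene = gw.gene
    T = noise.threshold(params)
    d = gw.norm_cond - gw.norm_ref
    m_small = _sliding_mean(d, params.window_small)
    m_large = _sliding_mean(d, params.window_large)
    if params.conjunctive_windows:
        longer = (m_small > T) & (m_large > T)
        shorter = (m_small < -T) & (m_large < -T)
    else:
        longer = (m_small > T) | (m_large > T)
        shorter = (m_small < -T) | (m_large < -T)
    label = np.where(longer, 1, np.where(shorter, -1, 0))

    # the scan region for this side, in window-local coordinates
    n = len(d)
    s, e = gene.orf_start - gw.start, gene.orf_end - gw.start
    left_is_5 = gene.strand == "+"
    if (side == 5) == left_is_5:          # region around the left ORF edge
        boundary = s
        region = (max(0, s - params.flank_max), min(s + params.inset_max, e, n))
    else:                                  # region around the right ORF edge
        boundary = e - 1
        region = (max(s, e - params.inset_max, 0), min(e + params.flank_max, n))
    mask = np.zeros(n, dtype=bool)
    mask[region[0] : region[1]] = True
    label = np.where(mask, label, 0)

    runs = _uniform_runs(label, params.min_end_length)
    if not runs:
        return None
    # "first region" scanning outward from the ORF boundary: nearest run wins
    def run_distance(run):
        a, b, _sign = run
        if a <= boundary < b:
            return 0
        return min(abs(a - boundary), abs(b - 1 - boundary))
    a, b, sign = min(runs, key=run_distance)
    direction = "longer" if sign > 0 else "shorter"

    higher_raw = gw.raw_cond if direction == "longer" else gw.raw_ref
    if float(np.mean(higher_raw[a:b])) < params.min_region_expression:
        return None
    run_lo, run_hi = a + gw.start, b + gw.start
    for ia, ib in gene.introns:
        if run_lo >= ia and run_hi <= ib:
            return None
    if mappability is not None:
        mvals = mappability.values(gene.chrom, gene.strand)[run_lo:run_hi]
        if float(np.mean(mvals)) < params.mappability_cutoff:
            return None

    start_lost = stop_lost = False
    if direction == "shorter":
        sc = gene.start_codon_interval()
        pc = gene.stop_codon_interval()
        if side == 5 and run_lo < sc[1] and run_hi > sc[0]:
            start_lost = run_lo <= sc[0] and run_hi >= sc[1]
        if side == 3 and run_lo < pc[1] and run_hi > pc[0]:
            stop_lost = run_lo <= pc[0] and run_hi >= pc[1]
    return DifferentialEnd(
        gene_id=gene.gene_id,
        condition=condition,
        side=side,
        direction=direction,
        chrom=gene.chrom,
        interval=(run_lo, run_hi),
        mean_log2_diff=float(np.mean(d[a:b])),
        noise=noise.n,
        start_codon_lost=start_lost,
        stop_codon_lost=stop_lost,
    )


def _uniform_runs(label: np.ndarray, min_len: int) -> list[tuple[int, int, int]]:
    """Maximal runs of constant nonzero label with length >= min_len."""
    runs = []
    n = len(label)
    i = 0
    while i < n:
        if label[i] == 0:
            i += 1
            continue
        j = i
        while j < n and label[j] == label[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j, int(label[i])))
        i = j
    return runs


def call_all_ends(
    track_ref: StrandedCoverageTrack,
    track_cond: StrandedCoverageTrack,
    genes: Sequence[GeneModel],
    params: CallerParams | None = None,
    mappability: MappabilityTrack | None = None,
    condition: str = "",
) -> tuple[list[DifferentialEnd], dict]:
    """Call ends for every mappable gene; at most one call per gene per side.

    Returns the calls and a summary dict with counts by side x direction
    plus the list of genes skipped as unmappable.
    """
    params = params or CallerParams()
    condition = condition or track_cond.condition
    calls: list[DifferentialEnd] = []
    skipped: list[str] = []
    for gene in genes:
        if mappability is not None and not gene_mappable(
            mappability, gene, params.mappability_cutoff
        ):
            skipped.append(gene.gene_id)
            continue
        chrom_len = len(track_ref.values(gene.chrom, gene.strand))
        window = analysis_window(gene, chrom_len, params, neighbors=genes)
        gw = normalize_pair(track_ref, track_cond, gene, params, window)
        noise = noise_level(gw)
        for side in (5, 3):
            end = call_differential_end(gw, side, noise, params, mappability,
                                        condition)
            if end is not None:
                calls.append(end)
    summary = {
        "counts": {
            f"{side}_{direction}": sum(
                1 for c in calls if c.side == side and c.direction == direction
            )
            for side in (5, 3)
            for direction in ("longer", "shorter")
        },
        "n_genes": len(genes),
        "skipped_unmappable": skipped,
        "condition": condition,
    }
    return calls, summary
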