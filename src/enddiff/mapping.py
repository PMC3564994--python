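"""Exact unique-placement read mapping with iterative 3' trimming.

The mapper places a read only where it matches the genome exactly and
occurs exactly once across both strands.  Reads that fail at full length
are trimmed by 4 bases from the 3' end and retried, down to a 28-bp floor.
The same machinery drives the mappability simulation: one 76-mer and one
28-mer read is simulated starting at every base on each strand, and every
uniquely mapping read increments a per-strand track over its footprint, so
an interior base of globally unique sequence scores 76 + 28 = 104.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GeneModel, Genome, revcomp

SEED_LEN = 28
READ_LEN = 76
TRIM_STEP = 4
PERFECT_SCORE = READ_LEN + SEED_LEN  # 104
GENE_MAPPABLE_CUTOFF = 94  # smallest integer mean >= 90% of 104


class UniqueIndex:
    """Exact-occurrence lookup for 28-mers over both genome strands.

    ``query(kmer)`` returns every placement ``(chrom, strand, pos)`` where
    ``pos`` is the forward-strand coordinate of the leftmost base of the
    28-bp footprint; a '-' placement means the k-mer equals the reverse
    complement of the genome there.  Seeds containing N are not indexed
    (N never matches).
    """

    def __init__(self, genome: Genome, seed_len: int = SEED_LEN):
        self.genome = genome
        self.seed_len = seed_len
        index: dict[str, list[tuple[str, str, int]]] = {}
        k = seed_len
        for chrom, seq in genome.chromosomes.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((chrom, "+", pos))
                index.setdefault(revcomp(kmer), []).append((chrom, "-", pos))
        self._index = index

    def query(self, kmer: str) -> list[tuple[str, str, int]]:
        if len(kmer) != self.seed_len:
            raise ValueError(f"query length {len(kmer)} != seed length {self.seed_len}")
        return self._index.get(kmer, [])


@dataclass(frozen=True)
class MappedRead:
    """A uniquely placed read; ``start`` is the forward coordinate of its footprint."""

    read_id: str
    chrom: str
    strand: str
    start: int
    mapped_length: int
    n_trims: int = 0

    @property
    def end(self) -> int:
        return self.start + self.mapped_length


UNMAPPED = "unmapped"
MULTIMAPPED = "multimapped"


def build_index(genome: Genome) -> UniqueIndex:
    return UniqueIndex(genome)


def _placements(index: UniqueIndex, genome: Genome, seq: str, max_hits: int = 2):
    """All exact placements of ``seq`` across both strands (capped at max_hits)."""
    k = index.seed_len
    if len(seq) < k or "N" in seq:
        return []
    hits = []
    for chrom, strand, pos in index.query(seq[:k]):
        if strand == "+":
            start = pos
            if genome[chrom][start : start + len(seq)] == seq:
                hits.append((chrom, "+", start))
        else:
            # seed footprint is [pos, pos+k); the read extends 3'-ward on the
            # minus strand, i.e. leftward in forward coordinates
            start = pos + k - len(seq)
            if start >= 0 and revcomp(genome[chrom][start : pos + k]) == seq:
                hits.append((chrom, "-", start))
        if len(hits) >= max_hits:
            break
    return hits


def map_read(
    index: UniqueIndex, genome: Genome, seq: str, read_id: str = "", n_trims: int = 0
) -> MappedRead | str:
    """Place ``seq`` iff it occurs exactly once across both strands."""
    if len(seq) < index.seed_len:
        raise ValueError(f"read shorter than {index.seed_len} bp")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"read contains non-ACGTN characters {sorted(bad)}")
    hits = _placements(index, genome, seq)
    if not hits:
        return UNMAPPED
    if len(hits) > 1:
        return MULTIMAPPED
    chrom, strand, start = hits[0]
    return MappedRead(read_id, chrom, strand, start, len(seq), n_trims)


def map_with_trimming(
    index: UniqueIndex,
    genome: Genome,
    seq: str,
    read_id: str = "",
    min_len: int = SEED_LEN,
    trim_step: int = TRIM_STEP,
) -> MappedRead | str:
    """Trim 4 bp off the 3' end after each failed attempt, down to 28 bp.

    A multimapped attempt at an intermediate length continues the cascade;
    the read is unmapped only once the 28-bp attempt fails.
    """
    length = len(seq)
    while length >= min_len:
        result = map_read(index, genome, seq[:length], read_id,
                          n_trims=(len(seq) - length) // trim_step)
        if isinstance(result, MappedRead):
            return result
        length -= trim_step
    return UNMAPPED


@dataclass
class MappabilityTrack:
    """Per chromosome, per strand count of uniquely mapping simulated reads."""

    counts: dict[str, dict[str, np.ndarray]]  # chrom -> strand -> int array

    def values(self, chrom: str, strand: str) -> np.ndarray:
        return self.counts[chrom][strand]


def compute_mappability(
    genome: Genome,
    index: UniqueIndex | None = None,
    read_lengths: tuple[int, ...] = (READ_LEN, SEED_LEN),
) -> MappabilityTrack:
    """Simulate one read of each length from every start on each strand.

    Each simulated read is mapped at its own length only (no trimming);
    when it places uniquely it adds 1 over its footprint on its own strand.
    Reads whose footprint would cross a chromosome end are not simulated,
    so terminal bases score below the interior maximum of 104.
    """
    if index is None:
        index = build_index(genome)
    counts = {
        chrom: {s: np.zeros(genome.length(chrom), dtype=np.int32) for s in "+-"}
        for chrom in genome.names()
    }
    for chrom, seq in genome.chromosomes.items():
        clen = len(seq)
        for rlen in read_lengths:
            # diff arrays: unique footprints add +1 over [p, p+rlen)
            diff = {s: np.zeros(clen + 1, dtype=np.int32) for s in "+-"}
            for p in range(clen - rlen + 1):
                sub = seq[p : p + rlen]
                if "N" in sub:
                    continue
                n_hits = len(_placements(index, genome, sub, max_hits=2))
                # occurrence count across both strands is orientation-
                # independent, so the '-' read from this footprint is unique
                # exactly when the '+' read is
                if n_hits == 1:
                    for s in "+-":
                        diff[s][p] += 1
                        diff[s][p + rlen] -= 1
            for s in "+-":
                counts[chrom][s] += np.cumsum(diff[s][:-1])
    return MappabilityTrack(counts)


def gene_mappable(
    track: MappabilityTrack, gene: GeneModel, cutoff: float = GENE_MAPPABLE_CUTOFF
) -> bool:
    """True iff mean same-strand mappability over the ORF is >= 94 (90% of 104)."""
    values = track.values(gene.chrom, gene.strand)[gene.orf_start : gene.orf_end]
    return float(np.mean(values)) >= cutoff
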