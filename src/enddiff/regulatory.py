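"""uORF scanning, degenerate RBP-motif matching and sampling enrichment.

Differential 5' ends can introduce or remove upstream open reading frames
(uORFs), and differential ends of either side can gain or lose binding
motifs of RNA-binding proteins.  uORFs are ATG..first-in-frame-stop frames
whose start codon lies inside the differential region; motifs are IUPAC
consensus strings matched by plain set membership, no scoring.  Enrichment
of either feature is judged against a sampling null: segments of the same
lengths drawn from promoter windows (uORFs) or the whole genome (motifs),
with significance at z > 3.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .io_formats import GeneModel, Genome, Motif, revcomp

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

STOPS = ("TAA", "TAG", "TGA")


@dataclass
class UORF:
    """An upstream ORF: ATG..first in-frame stop on the coding strand.

    ``start_pos``/``stop_pos`` are genome coordinates of the first base of
    the start/stop codon in transcript orientation.
    """

    gene_id: str
    start_pos: int
    stop_pos: int
    n_intervening_codons: int
    minimal: bool
    frame: int                 # relative to the main ORF (0 = in register)
    overlaps_main_orf: bool
    end_id: str = ""


@dataclass(frozen=True)
class MotifMatch:
    motif_id: str
    consensus: str
    position: int              # offset within the searched sequence
    matched: str
    end_id: str = ""


@dataclass
class EnrichmentResult:
    """Observed feature count versus its sampling null."""

    label: str
    observed: int
    null_mean: float
    null_sd: float
    z: float
    n_samples: int
    significant: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# uORF scanning


def find_uorfs(
    genome: Genome,
    gene: GeneModel,
    end_interval: tuple[int, int],
    end_id: str = "",
    require_stop_upstream: bool = False,
) -> list[UORF]:
    """All uORFs whose ATG lies inside ``end_interval``, upstream of the
    main start codon on the coding strand.

    Each candidate ATG is extended codon by codon to its first in-frame
    stop, searching past the interval and into the main ORF; a uORF whose
    stop lies at or after the main ATG is flagged ``overlaps_main_orf``
    (and dropped entirely under ``require_stop_upstream``).  ATGs with no
    downstream in-frame stop before the ORF end are not uORFs.
    """
    lo, hi = end_interval
    chrom = genome[gene.chrom]
    if gene.strand == "+":
        if lo >= gene.orf_start:
            raise ValueError(f"{gene.gene_id}: interval is not upstream of the ORF")
        seq = chrom[lo : gene.orf_end]
        main_atg = gene.orf_start - lo
        coord = lambda off: lo + off
        ival_len = min(hi, gene.orf_end) - lo
    else:
        if hi <= gene.orf_end:
            raise ValueError(f"{gene.gene_id}: interval is not upstream of the ORF")
        seq = revcomp(chrom[gene.orf_start : hi])
        main_atg = hi - gene.orf_end
        coord = lambda off: hi - 1 - off
        ival_len = hi - max(lo, gene.orf_start)
    out: list[UORF] = []
    limit = min(ival_len, main_atg)
    for o in range(limit):
        if seq[o : o + 3] != "ATG":
            continue
        stop_off = None
        for j in range(o + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in STOPS:
                stop_off = j
                break
        if stop_off is None:
            continue
        overlaps = stop_off >= main_atg
        if require_stop_upstream and overlaps:
            continue
        out.append(
            UORF(
                gene_id=gene.gene_id,
                start_pos=coord(o),
                stop_pos=coord(stop_off),
                n_intervening_codons=(stop_off - o) // 3 - 1,
                minimal=stop_off == o + 3,
                frame=(main_atg - o) % 3,
                overlaps_main_orf=overlaps,
                end_id=end_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# motif matching


def _iupac_regex(consensus: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    body = "".join(
        c if len(IUPAC_SETS[c]) == 1 else "[" + IUPAC_SETS[c] + "]"
        for c in consensus
    )
    return re.compile(r"(?=(" + body + "))")


def match_motifs(sequence: str, motif: Motif, end_id: str = "") -> list[MotifMatch]:
    """Every position of ``sequence`` where the IUPAC consensus matches.

    Set membership only — no weighting; overlapping matches are all
    reported; N in the sequence matches no consensus letter.
    """
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains letters outside ACGTN: {sorted(bad)}")
    pattern = _iupac_regex(motif.consensus)
    return [
        MotifMatch(motif.motif_id, motif.consensus, m.start(), m.group(1), end_id)
        for m in pattern.finditer(sequence)
    ]


def count_matches(sequence: str, motifs: list[Motif]) -> int:
    return sum(len(match_motifs(sequence, m)) for m in motifs)


# ---------------------------------------------------------------------------
# sampling nulls and z-scores


def _promoter_eligible(genome: Genome, genes: list[GeneModel], window: int):
    ok = []
    for g in genes:
        if g.strand == "+" and g.orf_start >= window:
            ok.append(g)
        elif g.strand == "-" and g.orf_end + window <= genome.length(g.chrom):
            ok.append(g)
    return ok


def sample_uorf_null(
    genome: Genome,
    genes: list[GeneModel],
    end_lengths: list[int],
    n_iter: int = 1000,
    seed: int = 0,
    promoter_window: int = 1000,
) -> np.ndarray:
    """Null distribution of the total uORF count over random promoter segments.

    Per iteration, each differential-end length is matched by a random
    same-length segment wholly inside a random gene's [ATG - 1000, ATG)
    promoter window on its coding strand, and uORFs are counted with the
    same scanner; the totals over all segments form the null.
    """
    if any(l > promoter_window for l in end_lengths):
        raise ValueError("end length exceeds the promoter sampling window")
    eligible = _promoter_eligible(genome, genes, promoter_window)
    if not eligible:
        raise ValueError("no gene has a full promoter window inside its chromosome")
    rng = np.random.default_rng(seed)
    totals = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        total = 0
        for length in end_lengths:
            g = eligible[int(rng.integers(len(eligible)))]
            off = int(rng.integers(0, promoter_window - length + 1))
            if g.strand == "+":
                seg = (g.orf_start - promoter_window + off,
                       g.orf_start - promoter_window + off + length)
            else:
                seg = (g.orf_end + promoter_window - off - length,
                       g.orf_end + promoter_window - off)
            total += len(find_uorfs(genome, g, seg))
        totals[it] = total
    return totals


def sample_motif_null(
    genome: Genome,
    end_lengths: list[int],
    motifs: list[Motif],
    n_iter: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the total motif-match count over random genomic
    segments of the same lengths, drawn uniformly from either strand."""
    rng = np.random.default_rng(seed)
    chroms = genome.names()
    lengths = np.array([genome.length(c) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    totals = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        total = 0
        for length in end_lengths:
            ci = int(rng.choice(len(chroms), p=probs))
            chrom = chroms[ci]
            start = int(rng.integers(0, genome.length(chrom) - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = genome.fetch(chrom, start, start + length, strand)
            total += count_matches(seq, motifs)
        totals[it] = total
    return totals


def zscore(observed: int, null_totals: np.ndarray, label: str = "") -> EnrichmentResult:
    """z = (observed - null mean) / null sd, significant when z > 3."""
    null_totals = np.asarray(null_totals, dtype=float)
    if len(null_totals) < 100:
        raise ValueError("need at least 100 null samples for a z-score")
    mean = float(np.mean(null_totals))
    sd = float(np.std(null_totals, ddof=1))
    if sd == 0:
        raise ValueError("null standard deviation is zero; z undefined")
    z = (observed - mean) / sd
    return EnrichmentResult(
        label=label,
        observed=int(observed),
        null_mean=mean,
        null_sd=sd,
        z=z,
        n_samples=len(null_totals),
        significant=z > 3,
    )


def uorf_enrichment(
    genome: Genome,
    genes: list[GeneModel],
    ends,  # list[DifferentialEnd], 5' side
    n_iter: int = 1000,
    seed: int = 0,
    label: str = "uorfs",
) -> tuple[list[UORF], EnrichmentResult]:
    """Observed uORFs in the given 5' differential ends versus the
    promoter-sampling null of matched lengths."""
    by_id = {g.gene_id: g for g in genes}
    observed: list[UORF] = []
    lengths = []
    for i, end in enumerate(ends):
        gene = by_id[end.gene_id]
        found = find_uorfs(genome, gene, tuple(end.interval),
                           end_id=f"{end.gene_id}:{end.side}:{i}")
        observed.extend(found)
        lengths.append(end.interval[1] - end.interval[0])
    null = sample_uorf_null(genome, genes, lengths, n_iter=n_iter, seed=seed)
    return observed, zscore(len(observed), null, label)


def motif_enrichment(
    genome: Genome,
    genes: list[GeneModel],
    ends,  # list[DifferentialEnd]
    motifs: list[Motif],
    n_iter: int = 1000,
    seed: int = 0,
    label: str = "motifs",
) -> tuple[list[MotifMatch], EnrichmentResult]:
    """Observed motif matches on the coding-strand sequence of each
    differential end versus the genome-sampling null of matched lengths."""
    by_id = {g.gene_id: g for g in genes}
    matches: list[MotifMatch] = []
    lengths = []
    for i, end in enumerate(ends):
        gene = by_id[end.gene_id]
        seq = genome.fetch(gene.chrom, end.interval[0], end.interval[1], gene.strand)
        eid = f"{end.gene_id}:{end.side}:{i}"
        for m in motifs:
            matches.extend(match_motifs(seq, m, end_id=eid))
        lengths.append(end.interval[1] - end.interval[0])
    null = sample_motif_null(genome, lengths, motifs, n_iter=n_iter, seed=seed)
    return matches, zscore(len(matches), null, label)
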