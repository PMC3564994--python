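"""Poly(A) end tags: cleavage evidence from reads that failed to map.

A read ending in three or more adenines that are not encoded in the genome
("nongenomic") marks a poly-adenylation event.  Such reads fail normal
alignment; stripping the maximal trailing A-run and uniquely anchoring the
remainder recovers the cleavage position — the first base past the aligned
segment on the transcript's 3' side.  Tags are clustered into discrete
poly-adenylation sites and genes with multiple well-separated sites are
reported.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .io_formats import GeneModel, Genome
from .mapping import MappedRead, UniqueIndex, map_read

MIN_TAIL_A = 3
MIN_ANCHOR = 28


@dataclass(frozen=True)
class PolyATag:
    """One poly-adenylated read anchored to the genome.

    ``cleavage_pos`` is the 0-based coordinate of the first nongenomic base
    past the anchored segment on the transcript's 3' side: the base after
    the anchor for a '+' placement, the base before it for a '-' placement.
    """

    read_id: str
    chrom: str
    strand: str
    cleavage_pos: int
    n_tail_A: int


@dataclass
class PolyASite:
    """A cluster of tags; the representative is the modal cleavage position."""

    chrom: str
    strand: str
    position: int
    tag_count: int
    member_positions: list[int]


def _trailing_a_run(seq: str) -> int:
    n = 0
    for ch in reversed(seq):
        if ch != "A":
            break
        n += 1
    return n


def call_end_tag(
    index: UniqueIndex,
    genome: Genome,
    read_id: str,
    seq: str,
    min_tail: int = MIN_TAIL_A,
    min_anchor: int = MIN_ANCHOR,
) -> PolyATag | None:
    """Recover a poly(A) tag from a read that did not map at full length.

    The maximal trailing A-run (>= ``min_tail``) is stripped; if the
    remainder anchors uniquely on either strand and the genome does not
    itself continue with that many adenines past the anchor (the tail must
    be nongenomic), a tag is emitted at the first post-alignment position.
    Returns None when the tail is too short, the anchor is shorter than
    ``min_anchor``, the anchor is not unique, or the A-run is genomic.
    """
    a = _trailing_a_run(seq)
    if a < min_tail:
        return None
    anchor = seq[:-a]
    if len(anchor) < min_anchor:
        return None  # tail too long to anchor
    hit = map_read(index, genome, anchor, read_id)
    if not isinstance(hit, MappedRead):
        return None
    chrom_seq = genome[hit.chrom]
    if hit.strand == "+":
        cont = chrom_seq[hit.end : hit.end + a]
        if len(cont) == a and cont == "A" * a:
            return None  # genomic A-run: the read maps normally instead
        cleavage = hit.end
    else:
        cont = chrom_seq[max(0, hit.start - a) : hit.start]
        if len(cont) == a and cont == "T" * a:
            return None
        cleavage = hit.start - 1
    return PolyATag(read_id, hit.chrom, hit.strand, cleavage, a)


def cluster_tags(tags: list[PolyATag], cluster_window: int = 10) -> list[PolyASite]:
    """Single-linkage clustering of tags within ``cluster_window`` bases,
    separately per chromosome and strand."""
    sites: list[PolyASite] = []
    by_key: dict[tuple[str, str], list[PolyATag]] = {}
    for t in tags:
        by_key.setdefault((t.chrom, t.strand), []).append(t)
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda t: t.cleavage_pos)
        cluster: list[int] = []
        for t in group:
            if cluster and t.cleavage_pos - cluster[-1] > cluster_window:
                sites.append(_make_site(chrom, strand, cluster))
                cluster = []
            cluster.append(t.cleavage_pos)
        if cluster:
            sites.append(_make_site(chrom, strand, cluster))
    return sites


def _make_site(chrom: str, strand: str, positions: list[int]) -> PolyASite:
    mode, _count = min(Counter(positions).items(), key=lambda kv: (-kv[1], kv[0]))
    return PolyASite(chrom, strand, mode, len(positions), list(positions))


def assign_sites_to_genes(
    sites: list[PolyASite],
    genes: list[GeneModel],
    downstream_window: int = 300,
) -> dict[str, list[PolyASite]]:
    """Attach each site to the gene whose ORF or 3' flank (within
    ``downstream_window`` bp downstream, strand-aware) contains it; when
    several genes qualify the one with the nearest stop codon wins."""
    assigned: dict[str, list[PolyASite]] = {g.gene_id: [] for g in genes}
    for site in sites:
        best, best_dist = None, None
        for g in genes:
            if g.chrom != site.chrom or g.strand != site.strand:
                continue
            if g.strand == "+":
                lo, hi = g.orf_start, g.orf_end + downstream_window
                stop_edge = g.orf_end - 1
            else:
                lo, hi = g.orf_start - downstream_window, g.orf_end
                stop_edge = g.orf_start
            if lo <= site.position < hi:
                dist = abs(site.position - stop_edge)
                if best_dist is None or dist < best_dist:
                    best, best_dist = g.gene_id, dist
        if best is not None:
            assigned[best].append(site)
    return assigned


def multi_site_genes(
    sites: list[PolyASite],
    genes: list[GeneModel],
    min_tags: int = 10,
    min_separation: int = 50,
    downstream_window: int = 300,
) -> dict:
    """Among genes with more than ``min_tags`` tags, flag those with two or
    more discrete sites whose representatives are further than
    ``min_separation`` bp apart.  Returns per-gene records plus the
    multi-site fraction over the qualifying genes."""
    assigned = assign_sites_to_genes(sites, genes, downstream_window)
    records = {}
    n_qual = n_multi = 0
    for gid, gsites in assigned.items():
        total = sum(s.tag_count for s in gsites)
        if total <= min_tags:
            continue
        n_qual += 1
        positions = sorted(s.position for s in gsites)
        multi = len(positions) >= 2 and positions[-1] - positions[0] > min_separation
        n_multi += multi
        records[gid] = {
            "n_tags": total,
            "site_positions": positions,
            "multi_site": bool(multi),
        }
    return {
        "genes": records,
        "n_genes_over_threshold": n_qual,
        "n_multi_site": n_multi,
        "multi_site_fraction": (n_multi / n_qual) if n_qual else float("nan"),
    }
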