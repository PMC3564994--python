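"""Synthetic genomes, gene models, two-condition coverage and reads.

The generator emulates the study design the caller is built for: a compact
multi-chromosome genome; non-overlapping genes with clear promoters; a
reference condition (rich-medium growth) and a stress condition whose
coverage landscapes differ only where differential 5'/3' transcript ends
were planted; uORF cassettes written into extended 5' UTRs; and reads
carrying nongenomic poly(A) tails at planted cleavage sites.  Every planted
feature is recorded in a machine-readable :class:`PlantedTruth` so any
caller's output can be scored without further information.

All randomness flows through a single integer seed; identical seed and
parameters give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .io_formats import Genome, GeneModel, revcomp

STOP_CODONS = ("TAA", "TAG", "TGA")

#: Low-level transcription outside annotated transcripts, as a fraction of
#: base_depth.  Most of a real genome is expressed at some low level; 0.5%
#: keeps that texture while staying far below any calling threshold.
DEFAULT_BACKGROUND_FRACTION = 0.005


@dataclass
class NoiseSpec:
    """Count-noise model for per-base coverage.

    family
        ``poisson`` or ``negative_binomial`` (gamma-Poisson mixture).
    dispersion
        Negative-binomial dispersion (variance = mu + dispersion * mu^2).
    base_depth
        Mean per-base coverage over an expressed transcript.
    """

    family: str = "poisson"
    dispersion: float = 0.2
    base_depth: float = 50.0

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.dispersion <= 0 or self.base_depth <= 0:
            raise ValueError("dispersion and base_depth must be positive")

    def sample(self, expectation: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.family == "poisson":
            return rng.poisson(expectation)
        shape = 1.0 / self.dispersion
        lam = rng.gamma(shape, expectation * self.dispersion)
        return rng.poisson(lam)


@dataclass
class EndPlan:
    """A differential end to plant: side 5 or 3, longer or shorter, offset bp."""

    side: int
    direction: str
    offset: int
    fold: float = 20.0

    def __post_init__(self) -> None:
        if self.side not in (5, 3):
            raise ValueError("side must be 5 or 3")
        if self.direction not in ("longer", "shorter"):
            raise ValueError("direction must be 'longer' or 'shorter'")
        if self.offset < 1 or self.fold <= 1:
            raise ValueError("offset >= 1 and fold > 1 required")


@dataclass
class GenePlan:
    """Reference UTR lengths and the optional differential end for one gene."""

    utr5: int = 60
    utr3: int = 60
    end: EndPlan | None = None


@dataclass
class PlantedTruth:
    """Everything that was planted, keyed by gene id; JSON-serializable."""

    seed: int
    params: dict = field(default_factory=dict)
    genes: dict = field(default_factory=dict)

    def differential_ends(self) -> list[dict]:
        return [
            {"gene_id": gid, **rec["differential_end"]}
            for gid, rec in self.genes.items()
            if rec.get("differential_end")
        ]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        return cls(seed=d["seed"], params=d.get("params", {}), genes=d["genes"])


# ---------------------------------------------------------------------------
# genome and gene planting


def generate_genome(
    n_chrom: int,
    lengths: Sequence[int],
    gc: float = 0.38,
    seed: int = 0,
    repeat_spec: Sequence[tuple] | None = None,
) -> Genome:
    """Random i.i.d. genome at a given GC content.

    ``repeat_spec`` entries ``(src_chrom, src_start, src_end, dst_chrom,
    dst_start)`` copy segments verbatim to plant exact repeats for
    mappability tests.
    """
    if len(lengths) != n_chrom:
        raise ValueError("need one length per chromosome")
    if any(n < 2000 for n in lengths):
        raise ValueError("chromosome lengths must be >= 2000")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    chroms = {}
    for i, n in enumerate(lengths):
        name = f"chr{_roman(i + 1)}"
        chroms[name] = b"".join(rng.choice(bases, size=n, p=p)).decode()
    if repeat_spec:
        for src_chrom, src_start, src_end, dst_chrom, dst_start in repeat_spec:
            segment = chroms[src_chrom][src_start:src_end]
            s = chroms[dst_chrom]
            chroms[dst_chrom] = (
                s[:dst_start] + segment + s[dst_start + len(segment):]
            )
    return Genome(chroms)


def _roman(n: int) -> str:
    out, vals = "", [(10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    for v, sym in vals:
        while n >= v:
            out += sym
            n -= v
    return out


def plant_genes(
    genome: Genome,
    n_genes: int,
    orf_len_range: tuple[int, int] = (300, 1500),
    spacing_min: int = 1200,
    seed: int = 0,
) -> tuple[Genome, list[GeneModel]]:
    """Place non-overlapping genes with clean ORFs on alternating strands.

    Each planted ORF's sequence is rewritten on its coding strand to start
    with ATG, end with a stop codon and contain no internal in-frame stop;
    its length is a multiple of 3.  Consecutive gene footprints are at
    least ``spacing_min`` apart so a 1000-bp promoter window never reaches
    a neighbor.  Returns the edited genome and the gene models.
    """
    rng = np.random.default_rng(seed)
    editable = {c: bytearray(genome[c], "ascii") for c in genome.names()}
    genes: list[GeneModel] = []
    chrom_names = genome.names()
    ci = 0
    cursor = spacing_min
    for i in range(n_genes):
        orf_len = int(rng.integers(orf_len_range[0], orf_len_range[1] + 1))
        orf_len -= orf_len % 3
        placed = False
        while ci < len(chrom_names):
            chrom = chrom_names[ci]
            clen = genome.length(chrom)
            if cursor + orf_len + spacing_min <= clen:
                placed = True
                break
            ci += 1
            cursor = spacing_min
        if not placed:
            raise ValueError(
                f"genome too small: placed {i} of {n_genes} requested genes"
            )
        strand = "+" if i % 2 == 0 else "-"
        start, end = cursor, cursor + orf_len
        _write_clean_orf(editable[chrom], start, end, strand, rng)
        genes.append(
            GeneModel(
                gene_id=f"g{i:04d}",
                chrom=chrom,
                strand=strand,
                orf_interval=(start, end),
            )
        )
        cursor = end + spacing_min
    edited = Genome({c: editable[c].decode() for c in chrom_names})
    return edited, genes


def _write_clean_orf(buf: bytearray, start: int, end: int, strand: str,
                     rng: np.random.Generator) -> None:
    seq = buf[start:end].decode()
    coding = seq if strand == "+" else revcomp(seq)
    codons = [coding[i : i + 3] for i in range(0, len(coding), 3)]
    codons[0] = "ATG"
    codons[-1] = STOP_CODONS[int(rng.integers(3))]
    non_stop = [c for c in _all_codons() if c not in STOP_CODONS]
    for j in range(1, len(codons) - 1):
        if codons[j] in STOP_CODONS:
            codons[j] = non_stop[int(rng.integers(len(non_stop)))]
    coding = "".join(codons)
    new = coding if strand == "+" else revcomp(coding)
    buf[start:end] = new.encode()


def _all_codons() -> list[str]:
    return [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


# ---------------------------------------------------------------------------
# transcript geometry


def _spans(gene: GeneModel, plan: GenePlan) -> tuple[tuple[int, int], tuple[int, int], dict | None]:
    """Reference span, condition span and differential-end record (genome coords)."""
    s, e = gene.orf_interval
    if gene.strand == "+":
        ref = [s - plan.utr5, e + plan.utr3]
    else:
        ref = [s - plan.utr3, e + plan.utr5]
    cond = list(ref)
    end_rec = None
    if plan.end is not None:
        p = plan.end
        # pick which genome-side edge the plan changes: the 5' edge is the
        # left edge on '+', the right edge on '-'
        left_is_5 = gene.strand == "+"
        edits_left = (p.side == 5) == left_is_5
        if edits_left:
            new_edge = ref[0] - p.offset if p.direction == "longer" else ref[0] + p.offset
            interval = (min(ref[0], new_edge), max(ref[0], new_edge))
            cond[0] = new_edge
        else:
            new_edge = ref[1] + p.offset if p.direction == "longer" else ref[1] - p.offset
            interval = (min(ref[1], new_edge), max(ref[1], new_edge))
            cond[1] = new_edge
        end_rec = {
            "side": p.side,
            "direction": p.direction,
            "interval": list(interval),
            "fold": p.fold,
        }
    return tuple(ref), tuple(cond), end_rec


def _tss_and_cleavage(gene: GeneModel, span: tuple[int, int]) -> tuple[int, int]:
    """(TSS, cleavage) genome coordinates for a span, in transcript orientation.

    The cleavage coordinate is the 0-based position of the first base past
    the transcript on its 3' side (span end on '+', span start - 1 on '-')."""
    if gene.strand == "+":
        return span[0], span[1]
    return span[1] - 1, span[0] - 1


# ---------------------------------------------------------------------------
# coverage simulation


def simulate_condition_pair(
    genome: Genome,
    genes: Sequence[GeneModel],
    plans: dict[str, GenePlan],
    noise: NoiseSpec | None = None,
    seed: int = 0,
    background_fraction: float = DEFAULT_BACKGROUND_FRACTION,
    conditions: tuple[str, str] = ("reference", "condition"),
):
    """Simulate reference/condition coverage tracks with planted ends.

    Expected coverage is ``base_depth`` over each condition's transcript
    span on the gene's strand, on top of a uniform genome-wide background.
    A planted *longer* end is expressed only in the test condition (the
    reference sees just background there); a planted *shorter* end keeps a
    ``base_depth / fold`` residual in the test condition, since alternative
    start/cleavage use in a real population is a mixture rather than an
    all-or-nothing switch.  Counts are then drawn per :class:`NoiseSpec`.

    Returns ``(track_ref, track_cond, truth)`` where the tracks are
    :class:`~enddiff.coverage.StrandedCoverageTrack` instances.
    """
    from .coverage import StrandedCoverageTrack

    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    lengths = {c: genome.length(c) for c in genome.names()}
    bg = background_fraction * noise.base_depth
    exp = {
        lbl: {c: {s: np.full(n, bg) for s in "+-"} for c, n in lengths.items()}
        for lbl in ("ref", "cond")
    }
    truth = PlantedTruth(
        seed=seed,
        params={
            "noise": asdict(noise),
            "background_fraction": background_fraction,
            "conditions": list(conditions),
        },
    )
    by_id = {g.gene_id: g for g in genes}
    for gene in genes:
        plan = plans.get(gene.gene_id, GenePlan())
        ref_span, cond_span, end_rec = _spans(gene, plan)
        for span, lbl in ((ref_span, "ref"), (cond_span, "cond")):
            if span[0] < 0 or span[1] > lengths[gene.chrom]:
                raise ValueError(f"{gene.gene_id}: transcript span outside chromosome")
        if end_rec is not None:
            lo, hi = end_rec["interval"]
            for other in genes:
                if other.gene_id != gene.gene_id and other.chrom == gene.chrom:
                    if lo < other.orf_end and hi > other.orf_start:
                        raise ValueError(
                            f"{gene.gene_id}: differential region crosses "
                            f"{other.gene_id}'s footprint"
                        )
        arr_ref = exp["ref"][gene.chrom][gene.strand]
        arr_cond = exp["cond"][gene.chrom][gene.strand]
        arr_ref[ref_span[0] : ref_span[1]] = noise.base_depth
        arr_cond[cond_span[0] : cond_span[1]] = noise.base_depth
        if end_rec is not None and end_rec["direction"] == "shorter":
            lo, hi = end_rec["interval"]
            arr_cond[lo:hi] = noise.base_depth / end_rec["fold"]
        ref_tss, ref_cleav = _tss_and_cleavage(gene, ref_span)
        cond_tss, cond_cleav = _tss_and_cleavage(gene, cond_span)
        truth.genes[gene.gene_id] = {
            "chrom": gene.chrom,
            "strand": gene.strand,
            "orf_interval": list(gene.orf_interval),
            "ref_span": list(ref_span),
            "cond_span": list(cond_span),
            "tss": {"ref": ref_tss, "cond": cond_tss},
            "cleavage": {"ref": ref_cleav, "cond": cond_cleav},
            "differential_end": end_rec,
            "uorfs": [],
            "tailed_reads": [],
        }
    tracks = []
    for lbl, cond_name in zip(("ref", "cond"), conditions):
        t = StrandedCoverageTrack.zeros(lengths, cond_name, dtype=np.int64)
        for c in lengths:
            for s in "+-":
                t.arrays[c][s] = noise.sample(exp[lbl][c][s], rng)
        tracks.append(t)
    return tracks[0], tracks[1], truth


def design_truth_plan(
    genes: Sequence[GeneModel],
    n_differential: int,
    seed: int = 0,
    utr5: int = 200,
    utr3: int = 200,
    offset_range: tuple[int, int] = (100, 200),
    fold_range: tuple[float, float] = (8.0, 20.0),
) -> dict[str, GenePlan]:
    """Assign reference UTRs to every gene and plant ``n_differential``
    differential ends balanced over side x direction; the remaining genes
    are nulls (identical expectation in both conditions).

    Default geometry keeps shorter ends inside the reference UTR
    (alternative start-site/cleavage choice, the typical case); ends that
    truncate into the ORF are planted explicitly via :class:`EndPlan` when
    codon loss is the point.
    """
    if n_differential > len(genes):
        raise ValueError("more differential ends requested than genes")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(genes), size=n_differential, replace=False)
    combos = [(5, "longer"), (5, "shorter"), (3, "longer"), (3, "shorter")]
    plans = {g.gene_id: GenePlan(utr5=utr5, utr3=utr3) for g in genes}
    for k, gi in enumerate(chosen):
        side, direction = combos[k % 4]
        offset = int(rng.integers(offset_range[0], offset_range[1] + 1))
        fold = float(rng.uniform(*fold_range))
        plans[genes[gi].gene_id] = GenePlan(
            utr5=utr5, utr3=utr3, end=EndPlan(side, direction, offset, fold)
        )
    return plans


# ---------------------------------------------------------------------------
# uORF cassettes


def plant_uorfs(
    genome: Genome,
    gene: GeneModel,
    region: tuple[int, int],
    n_uorfs: int,
    seed: int = 0,
    cassette_len_range: tuple[int, int] = (6, 60),
) -> tuple[Genome, list[dict]]:
    """Write ``n_uorfs`` non-overlapping ATG..stop cassettes into ``region``.

    ``region`` is a genome-coordinate interval inside the gene's (extended)
    5' UTR; cassettes are written on the coding strand.  Cassette interiors
    contain no in-frame stop and no ATG anywhere, and junctions are chosen
    so no new ATG spans a cassette border.  Returns the edited genome and
    truth records with transcript-orientation start/stop coordinates.
    """
    rng = np.random.default_rng(seed)
    lo, hi = region
    if hi - lo < n_uorfs * (cassette_len_range[0] + 1):
        raise ValueError("region too small for requested cassettes")
    lens = []
    for _ in range(n_uorfs):
        L = int(rng.integers(cassette_len_range[0] // 3, cassette_len_range[1] // 3 + 1)) * 3
        lens.append(max(6, min(L, cassette_len_range[1])))
    if sum(lens) + n_uorfs > hi - lo:
        raise ValueError("region too small for requested cassettes")
    # spread cassettes over the region with >= 1 bp gaps
    free = (hi - lo) - sum(lens)
    gaps = _random_composition(free, n_uorfs + 1, minimum=1, rng=rng)
    offsets = []
    pos = lo + gaps[0]
    for L, gap in zip(lens, gaps[1:]):
        offsets.append((pos, pos + L))
        pos += L + gap
    buf = bytearray(genome[gene.chrom], "ascii")
    records = []
    for a, b in offsets:
        cassette = _make_cassette(b - a, rng)
        # avoid a border-spanning ATG: TAG as the stop never contributes an
        # A able to seed one, so fall back to it when the junction is risky
        after = genome.fetch(gene.chrom, *( (b, b + 2) if gene.strand == "+" else (a - 2, a) ), gene.strand)
        if cassette.endswith(("TAA", "TGA")) and after.startswith("TG"):
            cassette = cassette[:-3] + "TAG"
        written = cassette if gene.strand == "+" else revcomp(cassette)
        buf[a:b] = written.encode()
        if gene.strand == "+":
            start_pos, stop_pos = a, b - 3
        else:
            start_pos, stop_pos = b - 1, a + 2
        records.append(
            {
                "gene_id": gene.gene_id,
                "start_pos": start_pos,
                "stop_pos": stop_pos,
                "n_codons": (b - a) // 3 - 2,
                "interval": [a, b],
            }
        )
    edited = Genome({c: (buf.decode() if c == gene.chrom else genome[c])
                     for c in genome.names()})
    return edited, records


def _make_cassette(length: int, rng: np.random.Generator) -> str:
    """ATG + clean interior + stop, with no internal ATG or in-frame stop."""
    assert length % 3 == 0 and length >= 6
    stop = STOP_CODONS[int(rng.integers(3))]
    n_inner = length // 3 - 2
    non_stop = [c for c in _all_codons() if c not in STOP_CODONS and c != "ATG"]
    for _ in range(1000):
        inner = "".join(non_stop[int(rng.integers(len(non_stop)))]
                        for _ in range(n_inner))
        cassette = "ATG" + inner + stop
        if "ATG" not in cassette[1:]:
            return cassette
    raise RuntimeError("could not build an ATG-free cassette interior")


def _random_composition(total: int, parts: int, minimum: int,
                        rng: np.random.Generator) -> list[int]:
    if total < parts * minimum:
        raise ValueError("region too small")
    extra = total - parts * minimum
    cuts = np.sort(rng.integers(0, extra + 1, size=parts - 1))
    sizes = np.diff(np.concatenate(([0], cuts, [extra])))
    return [minimum + int(x) for x in sizes]


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    genome: Genome,
    genes: Sequence[GeneModel],
    truth: PlantedTruth,
    read_len: int = 76,
    depth: float = 20.0,
    polya_site_fraction: float = 0.05,
    tail_len_range: tuple[int, int] = (3, 12),
    seed: int = 0,
    span_key: str = "ref",
) -> list[tuple[str, str]]:
    """Sample sense-strand reads from each gene's transcript span.

    Ordinary reads are exact transcript substrings.  A
    ``polya_site_fraction`` fraction of each gene's reads are poly(A)
    tagged: they end exactly at the gene's cleavage site and their last
    ``k`` bases (k drawn from ``tail_len_range``) are nongenomic adenines.
    Cleavage sites are nudged by a few bases if the flanking genome would
    make the tail boundary ambiguous (a genomic A right before or after
    the site); the adjusted site is recorded in the truth as
    ``polya_site`` along with every tailed read.

    Mutates ``truth`` in place (polya_site, tailed_reads) and returns the
    reads as ``(read_id, sequence)`` pairs.
    """
    if tail_len_range[0] < 3:
        raise ValueError("minimum tail length is 3 (tag-calling floor)")
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    by_id = {g.gene_id: g for g in genes}
    for gid, rec in truth.genes.items():
        gene = by_id[gid]
        span = tuple(rec[f"{span_key}_span"])
        span_len = span[1] - span[0]
        if read_len > span_len:
            raise ValueError(f"{gid}: read length exceeds transcript length")
        n_reads = int(rng.poisson(depth * span_len / read_len))
        n_tailed = int(rng.binomial(n_reads, polya_site_fraction)) if n_reads else 0
        for j in range(n_reads - n_tailed):
            off = int(rng.integers(0, span_len - read_len + 1))
            if gene.strand == "+":
                seq = genome[gene.chrom][span[0] + off : span[0] + off + read_len]
            else:
                a = span[1] - off - read_len
                seq = revcomp(genome[gene.chrom][a : a + read_len])
            reads.append((f"{gid}:r{j}", seq))
        if n_tailed:
            site = _clean_cleavage_site(genome, gene, rec["cleavage"][span_key])
            rec["polya_site"] = site
            for j in range(n_tailed):
                k = int(rng.integers(tail_len_range[0], tail_len_range[1] + 1))
                anchor_len = read_len - k
                if gene.strand == "+":
                    anchor = genome[gene.chrom][site - anchor_len : site]
                else:
                    anchor = revcomp(
                        genome[gene.chrom][site + 1 : site + 1 + anchor_len]
                    )
                rid = f"{gid}:t{j}"
                reads.append((rid, anchor + "A" * k))
                rec["tailed_reads"].append(
                    {"read_id": rid, "cleavage_pos": site, "n_tail_A": k}
                )
        else:
            rec.setdefault("polya_site", None)
    return reads


def _clean_cleavage_site(genome: Genome, gene: GeneModel, site: int) -> int:
    """Shift ``site`` minimally so the poly(A) junction is unambiguous.

    Requires, in transcript orientation, that the last transcript base is
    not A and the first genomic base past the cleavage is not A; otherwise
    a maximal-A-run tag caller cannot place the cleavage to the base."""
    seq = genome[gene.chrom]

    def ok(p: int) -> bool:
        if gene.strand == "+":
            return 1 <= p < len(seq) and seq[p - 1] != "A" and seq[p] != "A"
        return 0 <= p < len(seq) - 1 and seq[p + 1] != "T" and seq[p] != "T"

    for delta in range(0, 30):
        for cand in ((site - delta, site + delta) if gene.strand == "+"
                     else (site + delta, site - delta)):
            if ok(cand):
                return cand
    raise ValueError(f"{gene.gene_id}: no clean cleavage site near {site}")
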