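"""Readers and writers for the external formats the pipeline touches.

Every coordinate inside the package is 0-based, half-open, on the forward
(plus) strand of the reference.  GFF3 (1-based, inclusive) is converted at
this boundary; bedGraph is already 0-based half-open.  Sequences are stored
uppercase DNA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

IUPAC_DNA = set("ACGTN")
IUPAC_DEGENERATE = set("ACGTURYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class Genome:
    """Ordered map of chromosome name -> uppercase DNA sequence."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, seq in self.chromosomes.items():
            if name in seen:
                raise FormatError(f"duplicate chromosome name {name!r}")
            seen.add(name)
            if len(seq) == 0:
                raise FormatError(f"empty sequence for chromosome {name!r}")
            bad = set(seq) - IUPAC_DNA
            if bad:
                raise FormatError(
                    f"non-IUPAC characters {sorted(bad)} in chromosome {name!r}"
                )

    def __getitem__(self, chrom: str) -> str:
        return self.chromosomes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def names(self) -> list[str]:
        return list(self.chromosomes)

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end) in transcript orientation for `strand`."""
        seq = self.chromosomes[chrom][start:end]
        return seq if strand == "+" else revcomp(seq)


@dataclass
class GeneModel:
    """An annotated ORF with optional introns, 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    orf_interval: tuple[int, int]
    introns: list[tuple[int, int]] = field(default_factory=list)
    dubious: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"unknown strand {self.strand!r} for {self.gene_id}")
        s, e = self.orf_interval
        if e <= s:
            raise FormatError(f"empty ORF interval for {self.gene_id}")
        self.introns = sorted(tuple(iv) for iv in self.introns)
        prev_end = s
        for a, b in self.introns:
            if a <= s or b >= e:
                raise FormatError(
                    f"intron [{a},{b}) not strictly inside ORF of {self.gene_id}"
                )
            if a < prev_end:
                raise FormatError(f"overlapping introns in {self.gene_id}")
            prev_end = b

    @property
    def orf_start(self) -> int:
        return self.orf_interval[0]

    @property
    def orf_end(self) -> int:
        return self.orf_interval[1]

    @property
    def orf_length(self) -> int:
        return self.orf_end - self.orf_start

    def coding_length(self) -> int:
        return self.orf_length - sum(b - a for a, b in self.introns)

    def five_prime_boundary(self) -> int:
        """Genome coordinate of the start-codon edge (first transcribed ORF base)."""
        return self.orf_start if self.strand == "+" else self.orf_end - 1

    def three_prime_boundary(self) -> int:
        """Genome coordinate of the stop-codon edge (last transcribed ORF base)."""
        return self.orf_end - 1 if self.strand == "+" else self.orf_start

    def start_codon_interval(self) -> tuple[int, int]:
        s, e = self.orf_interval
        return (s, s + 3) if self.strand == "+" else (e - 3, e)

    def stop_codon_interval(self) -> tuple[int, int]:
        s, e = self.orf_interval
        return (e - 3, e) if self.strand == "+" else (s, s + 3)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA genome; sequences are uppercased, record order kept."""
    chroms: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chroms:
            raise FormatError(f"duplicate FASTA record {record.id!r}")
        chroms[record.id] = str(record.seq).upper()
    if not chroms:
        raise FormatError(f"no FASTA records in {path}")
    return Genome(chroms)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (gene / CDS / intron subset)


def read_gff(path: str | Path, genome: Genome | None = None) -> list[GeneModel]:
    """Parse the minimal gene/CDS/intron GFF3 subset into GeneModels.

    1-based inclusive GFF coordinates become 0-based half-open.  A gene is
    anchored by its ``gene`` (or ``CDS`` when no gene line exists) feature;
    ``intron`` features attach to the gene named by their Parent attribute.
    The dubious flag comes from ``orf_classification=Dubious``.
    """
    genes: dict[str, dict] = {}
    introns: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"malformed GFF line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = parts
            if strand not in "+-":
                raise FormatError(f"unknown strand symbol {strand!r}")
            iv = (int(start) - 1, int(end))  # to 0-based half-open
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype in ("gene", "CDS"):
                gid = attr.get("ID") or attr.get("Parent")
                if gid is None:
                    raise FormatError(f"feature without ID/Parent: {line!r}")
                rec = genes.setdefault(
                    gid, {"chrom": chrom, "strand": strand, "iv": iv, "dubious": False}
                )
                rec["iv"] = (min(rec["iv"][0], iv[0]), max(rec["iv"][1], iv[1]))
                if attr.get("orf_classification") == "Dubious":
                    rec["dubious"] = True
            elif ftype == "intron":
                gid = attr.get("Parent")
                if gid is None:
                    raise FormatError(f"intron without Parent: {line!r}")
                introns.setdefault(gid, []).append(iv)
    models = []
    for gid, rec in genes.items():
        if genome is not None:
            if rec["chrom"] not in genome:
                raise FormatError(f"{gid}: unknown chromosome {rec['chrom']}")
            if rec["iv"][1] > genome.length(rec["chrom"]) or rec["iv"][0] < 0:
                raise FormatError(f"{gid}: CDS outside chromosome bounds")
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                orf_interval=rec["iv"],
                introns=introns.get(gid, []),
                dubious=rec["dubious"],
            )
        )
    return models


def write_gff(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write GeneModels back to GFF3 (gene + intron features, 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.dubious:
                attrs += ";orf_classification=Dubious"
            fh.write(
                f"{g.chrom}\tenddiff\tgene\t{g.orf_start + 1}\t{g.orf_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for a, b in g.introns:
                fh.write(
                    f"{g.chrom}\tenddiff\tintron\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                    f"Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# bedGraph (per-strand coverage)


def read_bedgraph(
    path: str | Path, chrom_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Reconstruct dense per-base float arrays from a bedGraph file.

    Bases not covered by any interval are 0.  Values must be non-negative
    and intervals must lie within the declared chromosome lengths.
    """
    arrays = {c: np.zeros(n, dtype=float) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split()[:4]
            s, e, v = int(start), int(end), float(value)
            if v < 0:
                raise FormatError(f"negative bedGraph value at {chrom}:{s}-{e}")
            if chrom not in arrays:
                raise FormatError(f"unknown chromosome {chrom!r} in bedGraph")
            if e > len(arrays[chrom]) or s < 0:
                raise FormatError(f"interval beyond chromosome end: {chrom}:{s}-{e}")
            arrays[chrom][s:e] = v
    return arrays


def write_bedgraph(arrays: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write dense arrays as bedGraph, merging equal-value runs, omitting zeros."""
    with open(path, "w") as fh:
        for chrom, arr in arrays.items():
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                if v == int(v):
                    fh.write(f"{chrom}\t{s}\t{e}\t{int(v)}\n")
                else:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# FASTQ and motif TSV


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, uppercase sequence); qualities are discarded."""
    with open(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq.upper()


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


@dataclass(frozen=True)
class Motif:
    motif_id: str
    consensus: str  # DNA-space (U already mapped to T)
    rna_origin: bool = False


def read_motifs(path: str | Path) -> list[Motif]:
    """Read a two-column TSV of (motif_id, IUPAC consensus); U is stored as T."""
    motifs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"motif line needs two columns: {line!r}")
            mid, consensus = fields[0], fields[1].upper()
            bad = set(consensus) - IUPAC_DEGENERATE
            if bad:
                raise FormatError(
                    f"illegal letters {sorted(bad)} in motif {mid!r}"
                )
            rna = "U" in consensus
            motifs.append(Motif(mid, consensus.replace("U", "T"), rna))
    return motifs


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
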