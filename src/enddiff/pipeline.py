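"""End-to-end orchestration: simulate -> map -> coverage -> tags -> ends ->
uORFs/motifs, with a manifest and truth-based scoring.

The coverage-level path is primary: the end caller consumes per-base
tracks, which the simulator produces directly.  Read-level simulation
exercises the mapper and the poly(A) end-tag stage.  Identical config and
seed give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .coverage import accumulate_coverage, expression_matrix
from .endtags import PolyATag, call_end_tag, cluster_tags, multi_site_genes
from .io_formats import Genome, Motif, write_bedgraph, write_fasta, write_fastq, write_gff, write_json
from .mapping import MappedRead, build_index, compute_mappability, map_with_trimming, map_read
from .regulatory import motif_enrichment, uorf_enrichment
from .synthetic import (
    GenePlan,
    NoiseSpec,
    PlantedTruth,
    design_truth_plan,
    generate_genome,
    plant_genes,
    simulate_condition_pair,
    simulate_reads,
)
from .topology import CallerParams, DifferentialEnd, call_all_ends


@dataclass
class RunConfig:
    """Parameters of one simulation + analysis run."""

    seed: int = 0
    conditions: tuple[str, str] = ("reference", "stress")
    # genome / genes
    chrom_lengths: tuple[int, ...] = (120_000, 120_000)
    gc: float = 0.38
    n_genes: int = 50
    orf_len_range: tuple[int, int] = (900, 1500)
    spacing_min: int = 1200
    # planted differential ends
    n_differential: int = 20
    utr5: int = 200
    utr3: int = 200
    offset_range: tuple[int, int] = (100, 200)
    fold_range: tuple[float, float] = (8.0, 20.0)
    # coverage noise
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    background_fraction: float = 0.005
    # reads
    with_reads: bool = True
    read_len: int = 76
    read_depth: float = 10.0
    polya_site_fraction: float = 0.05
    tail_len_range: tuple[int, int] = (3, 12)
    # analysis
    caller: CallerParams = field(default_factory=CallerParams)
    with_mappability: bool = False
    uorf_null_iters: int = 300
    motifs: Sequence[Motif] = ()

    def validate(self) -> None:
        if self.conditions[0] == self.conditions[1]:
            raise ValueError("reference condition must differ from the test condition")
        if self.n_differential > self.n_genes:
            raise ValueError("cannot plant more differential ends than genes")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute every stage in dependency order; returns all artifacts.

    With ``outdir`` set, standard-format files (FASTA, GFF3, bedGraph,
    FASTQ, TSVs, truth and manifest JSON) are written as well.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    stage_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=6)]
    warnings: list[str] = []

    # --- simulate ---------------------------------------------------------
    genome = generate_genome(
        len(config.chrom_lengths), list(config.chrom_lengths), config.gc,
        seed=stage_seeds[0],
    )
    genome, genes = plant_genes(
        genome, config.n_genes, config.orf_len_range, config.spacing_min,
        seed=stage_seeds[1],
    )
    plans = design_truth_plan(
        genes, config.n_differential, seed=stage_seeds[2],
        utr5=config.utr5, utr3=config.utr3,
        offset_range=config.offset_range, fold_range=config.fold_range,
    )
    track_ref, track_cond, truth = simulate_condition_pair(
        genome, genes, plans, config.noise, seed=stage_seeds[3],
        background_fraction=config.background_fraction,
        conditions=config.conditions,
    )

    # --- reads, mapping, end tags ----------------------------------------
    reads = mapped = tags = sites = tag_report = None
    if config.with_reads:
        reads = simulate_reads(
            genome, genes, truth, read_len=config.read_len,
            depth=config.read_depth,
            polya_site_fraction=config.polya_site_fraction,
            tail_len_range=config.tail_len_range, seed=stage_seeds[4],
        )
        index = build_index(genome)
        mapped, tags = [], []
        for rid, seq in reads:
            hit = map_read(index, genome, seq, rid)
            if isinstance(hit, MappedRead):
                mapped.append(hit)
                continue
            # unmapped at full length: poly(A) tag candidate first,
            # trimming rescue second
            tag = call_end_tag(index, genome, rid, seq)
            if tag is not None:
                tags.append(tag)
                continue
            rescued = map_with_trimming(index, genome, seq, rid)
            if isinstance(rescued, MappedRead):
                mapped.append(rescued)
        sites = cluster_tags(tags)
        tag_report = multi_site_genes(sites, genes)

    # --- mappability and end calling --------------------------------------
    mappability = compute_mappability(genome) if config.with_mappability else None
    ends, summary = call_all_ends(
        track_ref, track_cond, genes, config.caller, mappability,
        condition=config.conditions[1],
    )
    summary["skipped_unmappable"] and warnings.append(
        f"{len(summary['skipped_unmappable'])} genes skipped as unmappable"
    )

    # --- regulatory features ----------------------------------------------
    longer5 = [e for e in ends if e.side == 5 and e.direction == "longer"]
    uorfs, uorf_enr = [], None
    if longer5:
        uorfs, uorf_enr = uorf_enrichment(
            genome, genes, longer5, n_iter=config.uorf_null_iters,
            seed=stage_seeds[5], label=f"{config.conditions[1]}:5:longer:uorfs",
        )
    motif_matches, motif_enr = [], None
    if config.motifs and ends:
        motif_matches, motif_enr = motif_enrichment(
            genome, genes, ends, list(config.motifs),
            n_iter=config.uorf_null_iters, seed=stage_seeds[5],
            label=f"{config.conditions[1]}:motifs",
        )

    score = score_against_truth(ends, truth, tags=tags, uorfs=uorfs)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": asdict(config),
        "stage_seeds": stage_seeds,
        "warnings": warnings,
        "summary": {k: v for k, v in summary.items() if k != "skipped_unmappable"},
    }
    artifacts = {
        "genome": genome,
        "genes": genes,
        "plans": plans,
        "truth": truth,
        "track_ref": track_ref,
        "track_cond": track_cond,
        "reads": reads,
        "mapped": mapped,
        "tags": tags,
        "sites": sites,
        "tag_report": tag_report,
        "mappability": mappability,
        "ends": ends,
        "summary": summary,
        "uorfs": uorfs,
        "uorf_enrichment": uorf_enr,
        "motif_matches": motif_matches,
        "motif_enrichment": motif_enr,
        "score": score,
        "manifest": manifest,
    }
    if outdir is not None:
        _write_artifacts(artifacts, Path(outdir), config)
    return artifacts


def ends_table(ends: Sequence[DifferentialEnd]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id, "condition": e.condition, "side": e.side,
                "direction": e.direction, "chrom": e.chrom,
                "start": e.interval[0], "end": e.interval[1],
                "mean_log2_diff": e.mean_log2_diff, "n": e.noise,
                "start_codon_lost": e.start_codon_lost,
                "stop_codon_lost": e.stop_codon_lost,
            }
            for e in ends
        ]
    )


def mapped_table(mapped: Sequence[MappedRead]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"read_id": m.read_id, "chrom": m.chrom, "strand": m.strand,
             "start": m.start, "mapped_length": m.mapped_length,
             "n_trims": m.n_trims}
            for m in mapped
        ]
    )


def _write_artifacts(a: dict, outdir: Path, config: RunConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(a["genome"], outdir / "genome.fa")
    write_gff(a["genes"], outdir / "genes.gff3")
    for track, label in ((a["track_ref"], config.conditions[0]),
                         (a["track_cond"], config.conditions[1])):
        for strand, tag in (("+", "plus"), ("-", "minus")):
            write_bedgraph(
                {c: track.arrays[c][strand] for c in a["genome"].names()},
                outdir / f"{label}.{tag}.bedgraph",
            )
    write_json(a["truth"].to_dict(), outdir / "truth.json")
    if a["reads"] is not None:
        write_fastq(a["reads"], outdir / "reads.fastq")
        mapped_table(a["mapped"]).to_csv(outdir / "mapped.tsv", sep="\t", index=False)
        pd.DataFrame([t.__dict__ for t in a["tags"]]).to_csv(
            outdir / "tags.tsv", sep="\t", index=False
        )
    ends_table(a["ends"]).to_csv(outdir / "ends.tsv", sep="\t", index=False)
    write_json(a["summary"], outdir / "summary.json")
    write_json(a["score"], outdir / "score.json")
    write_json(a["manifest"], outdir / "manifest.json")


# ---------------------------------------------------------------------------
# scoring against planted truth


def _overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    denom = min(a[1] - a[0], b[1] - b[0])
    return inter / denom if denom else 0.0


def score_against_truth(
    ends: Sequence[DifferentialEnd],
    truth: PlantedTruth,
    tags: Sequence[PolyATag] | None = None,
    uorfs=None,
    min_overlap: float = 0.5,
) -> dict:
    """Precision/recall of calls against planted truth.

    A differential-end call matches when gene, side and direction agree and
    the intervals overlap by at least ``min_overlap`` of the shorter one;
    tags match on exact cleavage position, uORFs on exact start position.
    With zero calls precision is reported as 1.0 with a ``no_calls`` flag.
    """
    planted = truth.differential_ends()
    matched_truth: set[str] = set()
    matched_calls = 0
    boundary_errors: list[int] = []
    for call in ends:
        rec = truth.genes.get(call.gene_id)
        if rec is None:
            raise ValueError(f"call for unknown gene {call.gene_id}")
        t = rec.get("differential_end")
        if (
            t
            and t["side"] == call.side
            and t["direction"] == call.direction
            and _overlap_fraction(tuple(t["interval"]), call.interval) >= min_overlap
        ):
            matched_calls += 1
            matched_truth.add(call.gene_id)
            boundary_errors.append(
                max(abs(t["interval"][0] - call.interval[0]),
                    abs(t["interval"][1] - call.interval[1]))
            )
    null_genes = [gid for gid, rec in truth.genes.items()
                  if not rec.get("differential_end")]
    false_on_null = sum(1 for c in ends if c.gene_id in set(null_genes))
    report = {
        "ends": {
            "n_calls": len(ends),
            "n_planted": len(planted),
            "recall": len(matched_truth) / len(planted) if planted else float("nan"),
            "precision": (matched_calls / len(ends)) if ends else 1.0,
            "no_calls": not ends,
            "boundary_errors": boundary_errors,
            "mean_boundary_error": float(np.mean(boundary_errors)) if boundary_errors else float("nan"),
            "n_null_genes": len(null_genes),
            "false_calls_on_null_genes": false_on_null,
        }
    }
    if tags is not None:
        truth_tags = {
            t["read_id"]: t["cleavage_pos"]
            for rec in truth.genes.values()
            for t in rec.get("tailed_reads", [])
        }
        exact = sum(
            1 for t in tags
            if truth_tags.get(t.read_id) == t.cleavage_pos
        )
        report["tags"] = {
            "n_called": len(tags),
            "n_planted": len(truth_tags),
            "recall": exact / len(truth_tags) if truth_tags else float("nan"),
            "precision": (exact / len(tags)) if tags else 1.0,
            "no_calls": not tags,
        }
    if uorfs is not None:
        truth_starts = {
            (gid, u["start_pos"])
            for gid, rec in truth.genes.items()
            for u in rec.get("uorfs", [])
        }
        if truth_starts:
            found = {(u.gene_id, u.start_pos) for u in uorfs}
            hit = len(truth_starts & found)
            report["uorfs"] = {
                "n_found": len(found),
                "n_planted": len(truth_starts),
                "recall": hit / len(truth_starts),
            }
    return report
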