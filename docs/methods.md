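# Methods

## Model and assumptions

The caller treats a gene's transcript as a contiguous covered span on its
coding strand and asks whether, in a test condition, coverage topology
near either ORF boundary departs from a reference condition once overall
expression differences are removed. The underlying assumptions are:

- the protocol is strand-specific, so a gene's signal is read from its own
  strand only; antisense transcription is not modelled;
- after median normalization over the annotated ORF, the two conditions'
  log₂ coverage should agree over the ORF, so the spread of their
  difference there is a per-gene noise estimate rather than signal;
- a genuine end change produces a spatially coherent, uniformly signed
  block of difference adjacent to (or overlapping) the ORF, not scattered
  single-base excursions — hence the two sliding windows and the 40-bp
  minimum length.

Both conditions are compared pairwise against one reference; replicates
are assumed pooled upstream.

## Caller procedure and parameters

Per gene and side (5′/3′):

1. Analysis window: ORF ± `flank_max` (default 1000 bp, enough to contain
   the longest UTR extensions seen in compact genomes, which reach ~850
   bp), clipped to the chromosome and to the nearest same-strand
   neighbour's ORF so a neighbour's signal is never attributed to the
   gene.
2. Normalize: v → log₂(v + 1) (pseudocount 1, so zero coverage maps to 0);
   shift the test track by the difference of the two ORF medians.
3. Noise: *n* = population standard deviation of the per-base difference
   d over the ORF.
4. Threshold: T = max(3.5·*n*, 2.0 log₂ units). The 2.0 floor is a
   fourfold change; 3.5 is a deliberately conservative multiplier.
5. Qualify bases where both the 10-bp and the 80-bp centred window means
   of d exceed +T (longer) or fall below −T (shorter). Windows are
   truncated, not dropped, at window edges. A disjunctive either-window
   mode exists as a flag but is not the default ("determined by both" is
   read conjunctively).
6. Candidate runs are maximal stretches of ≥ `min_end_length` (40 bp)
   uniformly signed qualifying bases within the side's scan region
   (`flank_max` beyond the boundary, `inset_max` = 300 bp into the ORF so
   codon-loss truncations remain visible). The run nearest the ORF
   boundary is the single candidate — the "first region" encountered
   scanning outward from the boundary; this makes the reported end the one
   that changes UTR content.
7. The candidate is rejected (no call for that side) when the higher
   condition's mean raw coverage over it is < `min_region_expression`
   (5, mirroring the expressed-gene threshold), when it lies wholly inside
   an annotated intron, or when its mean mappability is < 94.
8. Shorter runs covering the annotated start/stop codon set the
   corresponding codon-loss flag.

Defaults live in `CallerParams`; all are overridable. Genes failing the
mappability gate (mean ORF score < 94 of a perfect 104) are skipped.

## Mapping and mappability

Reads place only where they match the genome exactly and uniquely across
both strands. Exact matching is this package's deterministic contract —
synthetic data contains no sequencing errors, and unique placement is the
property the downstream statistics rely on. Unmappable reads are trimmed
4 bp from the 3′ end and retried down to 28 bp; a multimapped attempt at
an intermediate length continues the cascade (maximizing recovered reads)
rather than aborting. Reads containing N never match.

Mappability simulates one 76-mer and one 28-mer from every start on each
strand and maps each at its own length only, without the trimming
cascade — the only reading consistent with the stated per-base maximum of
104 = 76 + 28. Reads whose footprint would cross a chromosome end are not
simulated, so terminal bases legitimately score < 104; synthetic genes are
kept ≥ 76 bp from chromosome ends.

## Poly(A) end tags

Tag calling consumes reads unmapped at full length, before trimming
rescue: a trimmed read has lost its 3′ evidence, and this ordering
prevents a read from being both rescued and tagged. The maximal trailing
A-run (≥ 3) is stripped; the remainder must anchor uniquely with ≥ 28 bp;
"nongenomic" is enforced as: the next `n_tail_A` genomic bases past the
anchor, in transcript orientation, are not all A. Cleavage coordinates are
the first base past the anchor on the transcript's 3′ side (anchor end on
'+', anchor start − 1 on '−'). Sites are single-linkage clusters within 10
bp (a convention; the paper-scale "discrete sites" notion is not defined
more precisely anywhere), represented by the modal position; the
multi-site report gates on > 10 tags per gene and > 50 bp separation,
the convention of the poly(A)-atlas literature.

## uORFs, motifs and enrichment

A uORF is any ATG on the coding strand whose position lies inside the
differential 5′-end interval and upstream of the main start codon,
extended codon by codon to its first in-frame stop, searching past the
interval and into the main ORF; uORFs whose stop lies at or after the
main ATG are kept but flagged `overlaps_main_orf` (out-of-register
overlaps are biologically real), with a strict drop mode available. ATGs
with no in-frame stop before the sequence ends are not uORFs.

Motif matching is position-wise IUPAC set membership (implemented as a
compiled regex with a look-ahead so overlapping hits are all reported); no
weighting or scoring. N in the subject sequence matches nothing.

Enrichment compares a total observed count with totals over random
same-length segments: for uORFs, segments are drawn inside [ATG − 1000,
ATG) promoter windows of randomly chosen genes (genes whose promoter
window leaves the chromosome are excluded); for motifs, segments are drawn
uniformly from the whole genome, either strand. z = (observed − null
mean)/null sd (sd with ddof = 1; ≥ 100 null samples required),
significant at z > 3. The default sampling depth is 1000 iterations.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design the caller targets: a
multi-chromosome random genome (GC 0.38, the compact-fungal-genome
regime); non-overlapping genes on alternating strands with clean ORFs
(ATG start, single terminal stop, no internal in-frame stops, length ≡ 0
mod 3) separated by ≥ 1200 bp so 1-kb promoter windows never overlap a
neighbour; reference transcripts with 200-bp UTRs; and a test condition
whose coverage differs only at planted differential ends. Longer ends are
expressed only in the test condition; shorter ends keep a base_depth/fold
residual (default fold 20, i.e. 5%) because alternative start/cleavage use
in a real population is a mixture. A uniform background of 0.5% of
base_depth covers the rest of the genome, echoing the observation that
most of a real genome is expressed at some low level. Counts are Poisson
by default; a gamma-Poisson (negative binomial) family with dispersion
0.2 is available — the dispersion default is a modelling convention, not
a measured value. Default planted ends are 100–200 bp at fold 8–20 over
50× depth, i.e. alternative sites within the UTR; ORF-truncating ends are
planted explicitly where codon loss is under test.

Read simulation draws 76-bp sense-strand reads uniformly over each
transcript span; a configurable fraction of each gene's reads end at its
cleavage site with 3–12 nongenomic adenines. Planted cleavage sites are
nudged by a few bases so that neither the last transcript base nor the
first genomic base past the site is an adenine: with a genomic A on
either side of the junction, maximal-A-run stripping is ambiguous at
single-base resolution and *no* caller could recover the position
exactly, so the truth would not be scoreable.

Not emulated: sequencing errors and quality strings, paired ends, spliced
reads, antisense transcription, 3′-bias or positional coverage trends,
and between-replicate variability. Passing tests therefore demonstrate
correctness of the algorithms under the stated noise model, not
robustness to artefacts of real libraries.

## Numerical choices

- Internal coordinates are 0-based half-open; GFF3 converts at the I/O
  boundary. Minus-strand intervals are stored in genome coordinates with
  transcript orientation applied at use sites.
- Quantile normalization replaces rank r with the across-column mean of
  the r-th order statistics; ties take the mean over their rank range.
  With ties this deliberately trades away the exact shared-multiset
  property (as in the common `ties=TRUE` implementations); for tie-free
  columns normalization is idempotent and all columns share one sorted
  multiset.
- Noise *n* uses the population sd (the ORF is the whole population of
  interest, not a sample); enrichment sds use ddof = 1.
- Sliding windows of even width w centre on base i as [i − w/2, i − w/2 + w).
- Run-to-boundary distance ties (inside vs outside runs equally near)
  resolve to whichever run sorts first; in practice the conjunctive
  window criterion makes exact ties vanishingly rare.
- Cluster representatives break count ties toward the smaller position.
- When n is computed over an ORF invaded by a planted truncation, the
  truncated span inflates *n* — the method is followed to the letter, so
  deep truncations of short ORFs can self-mask (see limitations).

## Known limitations

- **Noise inflation under deep truncation.** A shorter end that covers a
  large fraction of a short ORF raises *n* enough that T = 3.5·*n* can
  exceed the signal itself; such events are only callable when the
  truncated fraction of the ORF is small (roughly < 9%, where
  3.5·√(p(1−p)) < 1). This is a property of the published procedure, not
  of this implementation.
- Exact-match mapping understates the mappable fraction of real,
  error-containing reads; the trimming cascade recovers only 3′-end
  damage.
- The expression mean over the ORF includes intron bases by default (the
  annotated-ORF span); `exclude_introns=True` restricts to exonic bases.
- Enrichment nulls sample raw promoter windows without excluding segments
  that overlap neighbouring ORFs; in the synthetic genome the 1200-bp
  spacing makes this moot, but on dense real annotations the null may be
  slightly conservative.
- At most one call per gene per side per condition; multiple distinct end
  switches on the same side of one gene are reported only as the nearest.

## Problem sizes

Test and example studies use 30–200 genes on 60–500-kb genomes at 50×
simulated depth, 1000-iteration sampling nulls, and ~1500 tailed reads
for tag recovery — sizes at which every planted feature is individually
checkable while whole-suite runs stay interactive.
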