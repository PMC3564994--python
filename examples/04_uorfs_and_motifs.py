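"""uORFs and RBP motifs in differential 5' ends, with sampling enrichment.

Calls differential ends on a simulated study, scans the longer 5' ends for
upstream ORFs (ATG .. first in-frame stop on the coding strand), and
compares the observed count to random same-length segments drawn from
promoter windows (within 1000 bp of annotated start codons); enrichment is
significant at z > 3.  Also shows degenerate IUPAC motif matching: the
consensus AAACACAW accepts both AAACACAA and AAACACAT, with no scoring.
"""

from enddiff import (
    Motif,
    NoiseSpec,
    call_all_ends,
    design_truth_plan,
    generate_genome,
    match_motifs,
    plant_genes,
    simulate_condition_pair,
    uorf_enrichment,
)

genome = generate_genome(2, [60_000, 60_000], seed=30)
genome, genes = plant_genes(genome, 30, seed=31)
plans = design_truth_plan(genes, 12, seed=32)
ref, cond, _ = simulate_condition_pair(genome, genes, plans,
                                       NoiseSpec(base_depth=50), seed=33)
calls, _ = call_all_ends(ref, cond, genes, condition="salt")
longer5 = [c for c in calls if c.side == 5 and c.direction == "longer"]
print(f"{len(longer5)} longer 5' ends called")

uorfs, enr = uorf_enrichment(genome, genes, longer5, n_iter=1000, seed=34)
minimal = sum(u.minimal for u in uorfs)
print(f"observed uORFs in those ends: {enr.observed} ({minimal} minimal, "
      f"start+stop only)")
print(f"null (promoter sampling): mean {enr.null_mean:.1f}, sd {enr.null_sd:.2f} "
      f"-> z = {enr.z:.2f}, significant (z > 3): {enr.significant}")

w = Motif("Puf3-like", "AAACACAW")
for seq in ("AAACACAA", "AAACACAT", "AAACACAG"):
    hits = match_motifs(seq, w)
    print(f"  {w.consensus} vs {seq}: {'match' if hits else 'no match'}")
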