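"""Per-base mappability from simulated 76-mer and 28-mer reads.

A repeat-free region scores 104 at every interior base (76 overlapping
76-mers + 28 overlapping 28-mers per strand all place uniquely); a planted
exact repeat drives the score to 0 because every simulated read from it
multimaps.  A gene is usable for end calling when its mean score is >= 94
(90% of the perfect 104).
"""

from enddiff import compute_mappability, gene_mappable, generate_genome, plant_genes

genome = generate_genome(
    n_chrom=2, lengths=[30_000, 30_000], seed=10,
    repeat_spec=[("chrI", 20_000, 22_000, "chrII", 20_000)],  # 2-kb exact repeat
)
genome, genes = plant_genes(genome, n_genes=4, seed=11)  # genes lie before 15 kb

track = compute_mappability(genome)
v = track.values("chrI", "+")
print("interior unique base (chrI:15000):", v[15_000])
print("inside the planted repeat (chrI:21000):", v[21_000])
print("chromosome start (chrI:0):", v[0], "(only one read of each length starts there)")
for g in genes:
    print(f"{g.gene_id} on {g.chrom}{g.strand} mappable: {gene_mappable(track, g)}")
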