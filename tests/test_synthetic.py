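import numpy as np
import pytest

from enddiff.io_formats import revcomp
from enddiff.regulatory import find_uorfs
from enddiff.synthetic import (
    EndPlan,
    GenePlan,
    NoiseSpec,
    design_truth_plan,
    generate_genome,
    plant_genes,
    plant_uorfs,
    simulate_condition_pair,
    simulate_reads,
)

STOPS = {"TAA", "TAG", "TGA"}


class TestGenerateGenome:
    def test_deterministic_per_seed(self):
        a = generate_genome(2, [3000, 4000], seed=5)
        b = generate_genome(2, [3000, 4000], seed=5)
        assert a.chromosomes == b.chromosomes
        c = generate_genome(2, [3000, 4000], seed=6)
        assert c.chromosomes != a.chromosomes

    def test_repeat_spec_plants_exact_copy(self):
        g = generate_genome(2, [3000, 3000], seed=1,
                            repeat_spec=[("chrI", 0, 500, "chrII", 0)])
        assert g["chrI"][:500] == g["chrII"][:500]

    def test_gc_within_binomial_bound(self):
        n = 100_000
        g = generate_genome(1, [n], gc=0.5, seed=2)
        observed = sum(g["chrI"].count(b) for b in "GC")
        sd = np.sqrt(n * 0.25)
        assert abs(observed - 0.5 * n) <= 3 * sd

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(1, [100], seed=0)


class TestPlantGenes:
    def test_clean_orfs(self, small_genome_genes):
        genome, genes = small_genome_genes
        for g in genes:
            coding = genome.fetch(g.chrom, g.orf_start, g.orf_end, g.strand)
            assert len(coding) % 3 == 0
            assert coding.startswith("ATG")
            assert coding[-3:] in STOPS
            internal = {coding[i:i + 3] for i in range(3, len(coding) - 3, 3)}
            assert not internal & STOPS

    def test_footprints_do_not_overlap(self, small_genome_genes):
        _, genes = small_genome_genes
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g.orf_interval)
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert s2 - e1 >= 1200

    def test_strands_alternate(self, small_genome_genes):
        _, genes = small_genome_genes
        assert [g.strand for g in genes[:4]] == ["+", "-", "+", "-"]

    def test_genome_too_small(self):
        g = generate_genome(1, [3000], seed=0)
        with pytest.raises(ValueError):
            plant_genes(g, 10, orf_len_range=(900, 900), seed=0)


class TestSimulateConditionPair:
    @pytest.fixture(scope="class")
    def study(self, small_genome_genes):
        genome, genes = small_genome_genes
        plans = {g.gene_id: GenePlan(utr5=150, utr3=150) for g in genes}
        plans[genes[0].gene_id] = GenePlan(
            utr5=150, utr3=150, end=EndPlan(5, "longer", 200, fold=16)
        )
        plans[genes[1].gene_id] = GenePlan(
            utr5=150, utr3=150, end=EndPlan(3, "shorter", 120, fold=10)
        )
        noise = NoiseSpec(base_depth=50)
        return genome, genes, plans, simulate_condition_pair(
            genome, genes, plans, noise, seed=77
        )

    def test_deterministic(self, study):
        genome, genes, plans, (ref, cond, truth) = study
        ref2, cond2, truth2 = simulate_condition_pair(
            genome, genes, plans, NoiseSpec(base_depth=50), seed=77
        )
        for c in genome.names():
            for s in "+-":
                assert (ref.values(c, s) == ref2.values(c, s)).all()
                assert (cond.values(c, s) == cond2.values(c, s)).all()
        assert truth.to_dict() == truth2.to_dict()

    def test_null_genes_have_equal_expectation(self, study):
        genome, genes, plans, (ref, cond, truth) = study
        g = genes[2]  # no planted end
        span = truth.genes[g.gene_id]["ref_span"]
        r = ref.values(g.chrom, g.strand)[span[0]:span[1]].mean()
        c = cond.values(g.chrom, g.strand)[span[0]:span[1]].mean()
        sd = np.sqrt(50 / (span[1] - span[0]))
        assert abs(r - 50) < 3 * np.sqrt(2) * sd
        assert abs(r - c) < 3 * np.sqrt(2) * sd

    def test_longer_end_expressed_only_in_condition(self, study):
        genome, genes, plans, (ref, cond, truth) = study
        g = genes[0]
        lo, hi = truth.genes[g.gene_id]["differential_end"]["interval"]
        assert hi - lo == 200
        r = ref.values(g.chrom, g.strand)[lo:hi].mean()
        c = cond.values(g.chrom, g.strand)[lo:hi].mean()
        assert c > 40 and r < 2  # base_depth vs ~background

    def test_shorter_end_keeps_residual(self, study):
        genome, genes, plans, (ref, cond, truth) = study
        g = genes[1]
        lo, hi = truth.genes[g.gene_id]["differential_end"]["interval"]
        r = ref.values(g.chrom, g.strand)[lo:hi].mean()
        c = cond.values(g.chrom, g.strand)[lo:hi].mean()
        assert r > 40 and 2 < c < 10  # 50/fold residual, fold=10

    def test_mean_orf_coverage_clt_bound(self, study):
        genome, genes, plans, (ref, cond, truth) = study
        g = genes[3]
        s, e = g.orf_interval
        mean = ref.values(g.chrom, g.strand)[s:e].mean()
        assert abs(mean - 50) <= 3 * np.sqrt(50 / (e - s))

    def test_region_crossing_neighbor_rejected(self, small_genome_genes):
        genome, genes = small_genome_genes
        plans = {genes[0].gene_id: GenePlan(
            utr5=60, utr3=60, end=EndPlan(3, "longer", 5000, fold=10))}
        with pytest.raises(ValueError):
            simulate_condition_pair(genome, genes, plans, seed=0)


class TestDesignTruthPlan:
    def test_balanced_sides_and_directions(self, small_genome_genes):
        _, genes = small_genome_genes
        plans = design_truth_plan(genes, 8, seed=4)
        combos = [(p.end.side, p.end.direction)
                  for p in plans.values() if p.end is not None]
        assert len(combos) == 8
        assert all(combos.count(c) == 2 for c in {(5, "longer"), (5, "shorter"),
                                                  (3, "longer"), (3, "shorter")})


class TestPlantUorfs:
    def test_scanner_recovers_planted_cassettes(self, small_genome_genes):
        genome, genes = small_genome_genes
        for gene in genes[:4]:
            if gene.strand == "+":
                region = (gene.orf_start - 450, gene.orf_start - 50)
            else:
                region = (gene.orf_end + 50, gene.orf_end + 450)
            edited, records = plant_uorfs(genome, gene, region, 3, seed=8)
            found = find_uorfs(edited, gene, region)
            found_starts = {u.start_pos for u in found}
            assert {r["start_pos"] for r in records} <= found_starts
            ivs = sorted(r["interval"] for r in records)
            for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
                assert a2 >= b1  # non-overlapping cassettes

    def test_minimal_cassette(self, small_genome_genes):
        genome, genes = small_genome_genes
        gene = genes[0]
        region = (gene.orf_start - 200, gene.orf_start - 180)
        edited, records = plant_uorfs(genome, gene, region, 1, seed=1,
                                      cassette_len_range=(6, 6))
        [rec] = records
        cassette = edited.fetch(gene.chrom, *rec["interval"], gene.strand)
        assert cassette[:3] == "ATG" and cassette[3:] in STOPS
        uorfs = [u for u in find_uorfs(edited, gene, region)]
        minimal = [u for u in uorfs if u.start_pos == rec["start_pos"]]
        assert minimal and minimal[0].minimal

    def test_region_too_small(self, small_genome_genes):
        genome, genes = small_genome_genes
        gene = genes[0]
        with pytest.raises(ValueError):
            plant_uorfs(genome, gene, (gene.orf_start - 20, gene.orf_start - 10),
                        5, seed=0)


class TestSimulateReads:
    @pytest.fixture(scope="class")
    def readset(self, small_genome_genes):
        genome, genes = small_genome_genes
        plans = {g.gene_id: GenePlan(utr5=150, utr3=150) for g in genes}
        _, _, truth = simulate_condition_pair(genome, genes, plans, seed=3)
        reads = simulate_reads(genome, genes, truth, depth=5.0,
                               polya_site_fraction=0.1, seed=9)
        return genome, genes, truth, reads

    def test_untailed_reads_are_transcript_substrings(self, readset):
        genome, genes, truth, reads = readset
        by_id = {g.gene_id: g for g in genes}
        checked = 0
        for rid, seq in reads:
            gid, tag = rid.split(":")
            if tag.startswith("t"):
                continue
            g = by_id[gid]
            genomic = seq if g.strand == "+" else revcomp(seq)
            assert genomic in genome[g.chrom]
            checked += 1
        assert checked > 100

    def test_tailed_reads_end_in_nongenomic_As(self, readset):
        genome, genes, truth, reads = readset
        by_read = {r["read_id"]: (gid, r)
                   for gid, rec in truth.genes.items()
                   for r in rec["tailed_reads"]}
        assert len(by_read) >= 20
        seqs = dict(reads)
        by_gene = {g.gene_id: g for g in genes}
        for rid, (gid, r) in by_read.items():
            seq = seqs[rid]
            k = r["n_tail_A"]
            assert k >= 3 and seq[-k:] == "A" * k
            g = by_gene[gid]
            site = r["cleavage_pos"]
            cont = (genome[g.chrom][site] if g.strand == "+"
                    else revcomp(genome[g.chrom][site]))
            assert cont != "A"  # tail is nongenomic from its first base

    def test_read_count_within_binomial_bound(self, readset):
        genome, genes, truth, reads = readset
        spans = sum(r["ref_span"][1] - r["ref_span"][0]
                    for r in truth.genes.values())
        expected = 5.0 * spans / 76
        assert abs(len(reads) - expected) <= 3 * np.sqrt(expected)

    def test_minimum_tail_length_enforced(self, small_genome_genes):
        genome, genes = small_genome_genes
        plans = {g.gene_id: GenePlan() for g in genes}
        _, _, truth = simulate_condition_pair(genome, genes, plans, seed=3)
        with pytest.raises(ValueError):
            simulate_reads(genome, genes, truth, tail_len_range=(2, 5), seed=0)
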