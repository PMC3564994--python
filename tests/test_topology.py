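import numpy as np
import pytest

from enddiff.coverage import StrandedCoverageTrack
from enddiff.io_formats import GeneModel
from enddiff.synthetic import (
    EndPlan,
    GenePlan,
    NoiseSpec,
    design_truth_plan,
    generate_genome,
    plant_genes,
    simulate_condition_pair,
)
from enddiff.topology import (
    CallerParams,
    call_all_ends,
    call_differential_end,
    noise_level,
    normalize_pair,
)

GENE = GeneModel("g", "chrI", "+", (2000, 3000))


def _track(values, condition=""):
    arr = np.asarray(values, dtype=float)
    return StrandedCoverageTrack(
        {"chrI": {"+": arr, "-": np.zeros_like(arr)}}, condition
    )


def _uniform(length=6000, value=50.0):
    return np.full(length, value)


class TestNormalizePair:
    def test_identical_tracks_zero_shift_zero_difference(self):
        t = _track(_uniform())
        gw = normalize_pair(t, t, GENE)
        assert gw.median_offset == 0.0
        assert np.allclose(gw.norm_cond - gw.norm_ref, 0.0)

    def test_global_fourfold_scaling_removed(self):
        ref = _uniform(value=50.0)
        gw = normalize_pair(_track(ref), _track(4 * ref), GENE)
        s, e = GENE.orf_start - gw.start, GENE.orf_end - gw.start
        d = (gw.norm_cond - gw.norm_ref)[s:e]
        assert np.allclose(d, 0.0, atol=1e-9)

    def test_zero_coverage_gives_zero_log_track(self):
        gw = normalize_pair(_track(np.zeros(6000)), _track(np.zeros(6000)), GENE)
        assert np.allclose(gw.norm_ref, 0.0)  # log2(0 + 1)

    def test_window_clipped_at_same_strand_neighbor(self):
        from enddiff.topology import analysis_window

        neighbor = GeneModel("h", "chrI", "+", (500, 1500))
        opposite = GeneModel("k", "chrI", "-", (500, 1500))
        params = CallerParams()
        lo, hi = analysis_window(GENE, 6000, params, neighbors=[neighbor])
        assert lo == 1500
        lo2, _ = analysis_window(GENE, 6000, params, neighbors=[opposite])
        assert lo2 == 1000  # opposite strand does not clip


class TestNoiseLevel:
    def test_identical_tracks_zero_noise(self):
        t = _track(_uniform())
        assert noise_level(normalize_pair(t, t, GENE)).n == 0.0

    def test_alternating_difference_unit_sd(self):
        ref = _uniform()
        cond = ref.copy()
        # alternate cond so the normalized difference is +1/-1 over the ORF
        idx = np.arange(2000, 3000)
        cond[idx[::2]] = 2 * ref[idx[::2]] + 1  # log2 diff +1
        cond[idx[1::2]] = (ref[idx[1::2]] + 1) / 2 - 1  # log2 diff -1
        gw = normalize_pair(_track(ref), _track(cond), GENE)
        noise = noise_level(gw)
        assert noise.n == pytest.approx(1.0, abs=1e-9)
        assert noise.threshold(CallerParams()) == pytest.approx(3.5)

    def test_floor_applies_when_noise_small(self):
        t = _track(_uniform())
        noise = noise_level(normalize_pair(t, t, GENE))
        assert noise.threshold(CallerParams()) == 2.0  # fourfold floor


class TestCallDifferentialEnd:
    def _pair_with_region(self, lo, hi, ref_val, cond_val):
        ref = _uniform(value=50.0)
        cond = _uniform(value=50.0)
        ref[1500:2000] = 50  # 5' UTR expressed in both
        cond[1500:2000] = 50
        ref[lo:hi] = ref_val
        cond[lo:hi] = cond_val
        return _track(ref, "ypd"), _track(cond, "salt")

    def test_planted_longer_five_prime_called(self):
        # 200-bp region upstream of the UTR expressed only in the condition
        ref, cond = self._pair_with_region(1300, 1500, 0.3, 50.0)
        gw = normalize_pair(ref, cond, GENE)
        end = call_differential_end(gw, 5, noise_level(gw), condition="salt")
        assert end is not None
        assert (end.side, end.direction) == (5, "longer")
        assert abs(end.interval[0] - 1300) <= 10
        assert abs(end.interval[1] - 1500) <= 10

    def test_identical_tracks_no_call(self):
        t = _track(_uniform())
        gw = normalize_pair(t, t, GENE)
        for side in (5, 3):
            assert call_differential_end(gw, side, noise_level(gw)) is None

    def test_short_region_below_40bp_not_called(self):
        ref, cond = self._pair_with_region(1470, 1500, 0.3, 50.0)  # 30 bp
        gw = normalize_pair(ref, cond, GENE)
        assert call_differential_end(gw, 5, noise_level(gw)) is None

    def test_low_expression_region_rejected(self):
        # large fold contrast but the higher condition sits below 5x coverage
        ref, cond = self._pair_with_region(1300, 1500, 0.25, 4.9)
        gw = normalize_pair(ref, cond, GENE)
        assert call_differential_end(gw, 5, noise_level(gw)) is None
        # same shape, sufficiently expressed: the call goes through
        ref2, cond2 = self._pair_with_region(1300, 1500, 2.5, 49.0)
        gw2 = normalize_pair(ref2, cond2, GENE)
        assert call_differential_end(gw2, 5, noise_level(gw2)) is not None

    def test_intronic_run_rejected(self):
        intron = [(2100, 2300)]
        ref = _uniform(value=50.0)
        cond = ref.copy()
        cond[2100:2300] = 1.0  # looks like a shorter end but is the intron
        with_intron = GeneModel("g", "chrI", "+", (2000, 5000), introns=intron)
        without = GeneModel("g", "chrI", "+", (2000, 5000))
        gw = normalize_pair(_track(ref), _track(cond), with_intron)
        assert call_differential_end(gw, 5, noise_level(gw)) is None
        gw2 = normalize_pair(_track(ref), _track(cond), without)
        assert call_differential_end(gw2, 5, noise_level(gw2)) is not None


class StudyMixin:
    @staticmethod
    def study(seed, n_genes=30, n_diff=12, **plan_kw):
        genome = generate_genome(2, [60_000, 60_000], seed=seed)
        genome, genes = plant_genes(genome, n_genes, orf_len_range=(900, 1500),
                                    seed=seed + 1)
        plans = design_truth_plan(genes, n_diff, seed=seed + 2, **plan_kw)
        ref, cond, truth = simulate_condition_pair(
            genome, genes, plans, NoiseSpec(base_depth=50), seed=seed + 3
        )
        return genome, genes, ref, cond, truth


class TestCallAllEnds(StudyMixin):
    def test_recovery_on_simulated_study(self):
        _, genes, ref, cond, truth = self.study(101)
        calls, summary = call_all_ends(ref, cond, genes)
        planted = {d["gene_id"]: d for d in truth.differential_ends()}
        recovered = 0
        for c in calls:
            assert c.gene_id in planted, "call on a null gene"
            t = planted[c.gene_id]
            assert (c.side, c.direction) == (t["side"], t["direction"])
            recovered += 1
        assert recovered >= 0.9 * len(planted)
        assert sum(summary["counts"].values()) == len(calls)

    def test_swapping_conditions_flips_directions(self):
        _, genes, ref, cond, _ = self.study(202)
        fwd, _ = call_all_ends(ref, cond, genes)
        rev, _ = call_all_ends(cond, ref, genes)
        flip = {"longer": "shorter", "shorter": "longer"}
        fwd_set = {(c.gene_id, c.side, c.direction, c.interval) for c in fwd}
        rev_set = {(c.gene_id, c.side, flip[c.direction], c.interval) for c in rev}
        assert fwd_set == rev_set

    def test_threshold_monotonicity(self):
        _, genes, ref, cond, _ = self.study(303)
        loose, _ = call_all_ends(ref, cond, genes, CallerParams())
        for params in (CallerParams(noise_multiplier=6.0),
                       CallerParams(min_fold_log2=3.5)):
            strict, _ = call_all_ends(ref, cond, genes, params)
            assert {(c.gene_id, c.side) for c in strict} <= {
                (c.gene_id, c.side) for c in loose
            }

    def test_empty_gene_list(self):
        _, genes, ref, cond, _ = self.study(404, n_genes=4, n_diff=0)
        calls, summary = call_all_ends(ref, cond, [])
        assert calls == [] and summary["n_genes"] == 0


class TestCodonLoss(StudyMixin):
    def _truncation_study(self, side):
        genome = generate_genome(1, [60_000], seed=77)
        genome, genes = plant_genes(genome, 4, orf_len_range=(3000, 3300),
                                    seed=78)
        gene = genes[0]
        plans = {g.gene_id: GenePlan(utr5=150, utr3=150) for g in genes}
        plans[gene.gene_id] = GenePlan(
            utr5=150, utr3=150, end=EndPlan(side, "shorter", 300, fold=20)
        )
        ref, cond, truth = simulate_condition_pair(
            genome, genes, plans, NoiseSpec(base_depth=50), seed=79
        )
        calls, _ = call_all_ends(ref, cond, genes)
        return gene, [c for c in calls if c.gene_id == gene.gene_id]

    def test_stop_codon_loss_flagged(self):
        gene, calls = self._truncation_study(side=3)
        matching = [c for c in calls if c.side == 3]
        assert matching and matching[0].direction == "shorter"
        assert matching[0].stop_codon_lost
        assert not matching[0].start_codon_lost

    def test_start_codon_loss_flagged(self):
        gene, calls = self._truncation_study(side=5)
        matching = [c for c in calls if c.side == 5]
        assert matching and matching[0].direction == "shorter"
        assert matching[0].start_codon_lost
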