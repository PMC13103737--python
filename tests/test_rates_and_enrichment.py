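import numpy as np
import pytest

from canisv.io_formats import AnnotationSet, RepeatAnnotation, VariantRecord, VariantSet
from canisv.mei_genetics import MEILocus
from canisv.rates_and_enrichment import (
    count_snp_divergence,
    estimate_insertion_rate,
    filter_line1_3prime_intact,
    str_enrichment,
)
from canisv.sv_extraction import SVLocus


def snp(pos, gts, chrom="chr1"):
    rec = VariantRecord(chrom=chrom, pos=pos, ref_allele="A", alt_alleles=["G"])
    for (s, h), idx in gts.items():
        rec.allele_of[(s, h)] = idx
    return rec


class TestCountSnpDivergence:
    def make_vset(self):
        base = {("X", 1): 0, ("X", 2): 0, ("Y", 1): 0, ("Y", 2): 0}
        recs = [
            snp(100, {**base, ("X", 1): 1}),
            snp(200, {**base, ("X", 1): 1}),
            snp(300, {**base, ("Y", 1): 1}),  # X.1 vs Y.1 differ here too
            snp(5000, {**base, ("X", 1): 1}),  # inside mask
            snp(400, {**base, ("X", 1): 1, ("Y", 1): 1}),  # shared: no difference
        ]
        return VariantSet(records=recs, samples=["X", "Y"], contigs={"chr1": 10_000})

    def test_identical_haplotypes_give_zero(self):
        assert count_snp_divergence(self.make_vset(), "Y.2", "X.2") == 0

    def test_mask_excludes_sites(self):
        vset = self.make_vset()
        assert count_snp_divergence(vset, "X.1", "Y.1") == 4
        assert count_snp_divergence(vset, "X.1", "Y.1", mask={"chr1": [(4900, 5100)]}) == 3

    def test_indel_records_ignored(self):
        vset = self.make_vset()
        rec = VariantRecord(chrom="chr1", pos=600, ref_allele="A", alt_alleles=["ATTT"])
        for k in vset.records[0].allele_of:
            rec.allele_of[k] = 1 if k == ("X", 1) else 0
        vset.records.append(rec)
        assert count_snp_divergence(vset, "X.1", "Y.1") == 4

    def test_simulated_pair_matches_expectation(self, small_cohort):
        # D(hap, outgroup) ~ Poisson(2 mu T L); check within 4 sd
        p = small_cohort.params
        L = sum(p.chrom_lengths.values())
        expected = 2 * p.snp_mu * 10_000 * L
        d = count_snp_divergence(small_cohort.variant_set, "ACDsim.1", "GWsim.1")
        assert abs(d - expected) < 4 * np.sqrt(expected)


class TestEstimateInsertionRate:
    def test_divergence_time_from_stated_formula(self):
        est = estimate_insertion_rate([("c", 2000)], [("c", 9000)], genome_size=10**6)
        (c,) = est.per_comparison
        assert c.divergence_generations == pytest.approx(1_000_000)
        assert c.rate == pytest.approx(0.002)
        assert est.mean_rate_reciprocal == 500

    def test_zero_insertions_zero_rate(self):
        est = estimate_insertion_rate([("c", 0)], [("c", 9000)], genome_size=10**6)
        assert est.mean_rate == 0.0

    def test_zero_divergence_with_insertions_errors(self):
        with pytest.raises(ValueError):
            estimate_insertion_rate([("c", 10)], [("c", 0)], genome_size=10**6)

    def test_label_mismatch_errors(self):
        with pytest.raises(ValueError):
            estimate_insertion_rate([("a", 1)], [("b", 1)], genome_size=10**6)

    def test_internal_equations_self_consistent(self):
        est = estimate_insertion_rate(
            [("c1", 150), ("c2", 90)], [("c1", 9000), ("c2", 4500)], genome_size=2 * 10**6
        )
        assert est.self_consistent()
        assert est.mean_rate == pytest.approx(
            (est.per_comparison[0].rate + est.per_comparison[1].rate) / 2
        )


def _mei(chrom, pos, cons_end, cons_len=6000):
    base = SVLocus(
        chrom=chrom, pos=pos, alleles=["A", "A" + "G" * 60],
        hap_allele={("X", 1): 1, ("X", 2): 0}, longest_allele_index=1, max_size_diff=60,
        locus_id=f"{chrom}:{pos}",
    )
    mei = MEILocus(
        base=base, mei_type="LINE1",
        state_of={("X", 1): "DERIVED", ("X", 2): "ANCESTRAL"},
        derived_alleles=["A" + "G" * 60], n_derived_distinct=1,
    )
    annots = AnnotationSet(
        [RepeatAnnotation("q", 0, 60, "L1", "LINE/L1", "+", 1, cons_start=0, cons_end=cons_end)]
    )
    return mei, annots


class TestLine1ThreePrimeFilter:
    def test_boundary_within_100bp_kept(self):
        mei_ok, ann_ok = _mei("chr1", 100, cons_end=5950)
        mei_bad, ann_bad = _mei("chr1", 900, cons_end=5850)
        annots = {id(mei_ok): ann_ok, id(mei_bad): ann_bad}
        kept, report = filter_line1_3prime_intact(
            [mei_ok, mei_bad], lambda m: annots[id(m)], consensus_length=6000
        )
        assert [m.base.locus_id for m in kept] == ["chr1:100"]
        assert report["removed"] == 1

    def test_split_by_reference_l1_membership(self):
        mei_in, ann_in = _mei("chr1", 100, cons_end=5000)
        mei_out, ann_out = _mei("chr1", 50_000, cons_end=5000)
        annots = {id(mei_in): ann_in, id(mei_out): ann_out}
        _, report = filter_line1_3prime_intact(
            [mei_in, mei_out], lambda m: annots[id(m)], consensus_length=6000,
            ref_l1_intervals={"chr1": [(0, 6000)]},
        )
        assert report["removed_fraction_in_ref_l1"] == 1.0
        assert report["removed_fraction_not_in_ref_l1"] == 1.0
        assert report["contingency"][0][0] == 1 and report["contingency"][1][0] == 1


class TestStrEnrichment:
    CHROMS = {"chrA": 100_000, "chrB": 100_000}

    def test_class_covering_whole_genome_gives_fold_one(self):
        strs = [("chrA", 100, 150), ("chrB", 500, 540)]
        classes = {"all": {c: [(0, n)] for c, n in self.CHROMS.items()}}
        (res,) = str_enrichment(strs, classes, self.CHROMS, n_perm=20, seed=3)
        assert res.fold == pytest.approx(1.0)
        assert res.observed_overlap == 90

    def test_strs_inside_small_class_strongly_enriched(self):
        rng = np.random.default_rng(9)
        # class = 10% of the genome; every STR inside it
        classes = {"cls": {"chrA": [(0, 10_000)], "chrB": [(0, 10_000)]}}
        strs = [("chrA", int(p), int(p) + 20) for p in rng.integers(0, 9_980, size=200)]
        (res,) = str_enrichment(strs, classes, self.CHROMS, n_perm=100, seed=5)
        assert 7 < res.fold < 14  # expectation 10, permutation noise allowed

    def test_deterministic_under_seed(self):
        strs = [("chrA", 100, 160)]
        classes = {"cls": {"chrA": [(0, 10_000)]}}
        a = str_enrichment(strs, classes, self.CHROMS, n_perm=30, seed=11)
        b = str_enrichment(strs, classes, self.CHROMS, n_perm=30, seed=11)
        assert a[0].permuted_overlaps == b[0].permuted_overlaps

    def test_interval_longer_than_genome_errors(self):
        with pytest.raises(ValueError):
            str_enrichment([("chrA", 0, 200_001)], {"c": {}}, self.CHROMS, n_perm=5, seed=0)
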