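import filecmp
import os

import pytest

from canisv.io_formats import read_pangenome_vcf
from canisv.repeat_annotation import find_exact_tandem_repeats
from canisv.synthetic_data import (
    HAPLOTYPES,
    CohortParams,
    build_repeat_library,
    emit_cohort,
    leaves_below,
    simulate_cohort,
)

TINY = dict(
    sinec_rate=0.003, line1_rate=0.0008, n_transductions=4, n_doomed_transductions=1,
    n_str=3, n_vntr=2, n_ltr=2, n_satellite=1, n_mixed=2, n_partial=2,
    n_unclassified=2, n_deletion=3, n_intra_l1_deletion=2,
    n_ref_sinec=30, n_ref_line1=4, n_dup_pairs=5,
)


class TestRepeatLibrary:
    def test_designed_orfs_translate_without_internal_stops(self, library):
        assert "*" not in library.protein_orf1
        assert "*" not in library.protein_orf2
        o1s, o1e = library.orf1_span
        o2s, o2e = library.orf2_span
        assert o1e <= o2s  # non-overlapping
        assert library.line1_consensus[o1s : o1s + 3] == "ATG"
        assert library.line1_consensus[o2s : o2s + 3] == "ATG"

    def test_sinec_carries_internal_ct_run(self, library):
        runs = [
            r for r in find_exact_tandem_repeats(library.sinec_consensus, max_unit=2)
            if r.canonical_unit == "CT"
        ]
        assert runs and max(r.copies for r in runs) >= 8

    def test_same_seed_identical_different_seed_differs(self):
        a, b, c = build_repeat_library(5), build_repeat_library(5), build_repeat_library(6)
        assert a.line1_consensus == b.line1_consensus
        assert a.sinec_consensus == b.sinec_consensus
        assert c.line1_consensus != a.line1_consensus
        assert len(c.line1_consensus) == len(a.line1_consensus)  # same structural layout


class TestSimulateCohort:
    def test_ten_haplotypes_with_all_chromosomes(self, small_cohort):
        assert sorted(small_cohort.haplotypes) == sorted(HAPLOTYPES)
        for seqs in small_cohort.haplotypes.values():
            assert set(seqs) == set(small_cohort.params.chrom_lengths)

    def test_events_follow_the_genealogy(self, small_cohort):
        for ev in small_cohort.truth_events:
            assert ev.carriers == leaves_below(ev.branch)

    def test_private_branch_events_confined_to_one_sample(self, small_cohort):
        private = [e for e in small_cohort.truth_events if e.branch == "CCsim.2"]
        for ev in private:
            assert set(ev.carriers) == {"CCsim.2"}

    def test_tsd_duplicated_on_both_flanks(self, small_cohort):
        checked = 0
        for ev in small_cohort.truth_events:
            if ev.ref_span or not ev.tsd:
                continue
            ref = small_cohort.reference[ev.chrom]
            assert ref[ev.pos - len(ev.tsd) + 1 : ev.pos + 1] == ev.tsd
            for hap, body in ev.alleles_by_hap.items():
                assert body.endswith(ev.tsd)
            checked += 1
        assert checked > 20

    def test_haplotype_sequence_contains_planted_allele(self, small_cohort):
        # spot-check a handful of events: insertion body present in carrier sequence
        for ev in small_cohort.truth_events[:10]:
            if ev.ref_span:
                continue
            hap = ev.carriers[0]
            body = ev.alleles_by_hap[hap]
            assert body in small_cohort.haplotypes[hap][ev.chrom]

    def test_zero_line1_rate_plants_no_line1_events(self, library):
        params = CohortParams(seed=3, line1_rate=0.0, n_intra_l1_deletion=0, **{
            k: v for k, v in TINY.items() if k not in ("line1_rate", "n_intra_l1_deletion")
        })
        cohort = simulate_cohort(library, params)
        l1_types = {"LINE1", "LINE1+transduction", "nested"}
        assert not [e for e in cohort.truth_events if e.type in l1_types]

    def test_expected_snp_counts_scale_with_branch_length(self, small_cohort):
        import numpy as np

        p = small_cohort.params
        L = sum(p.chrom_lengths.values())
        for branch, count in small_cohort.truth_snps.items():
            gens = small_cohort.tree[branch][1]
            expected = p.snp_mu * gens * L
            assert abs(count - expected) <= 5 * np.sqrt(max(expected, 1.0))

    def test_genome_too_small_errors(self, library):
        params = CohortParams(
            seed=0, chrom_lengths={"chr1": 20_000, "chr2": 20_000}, **TINY
        )
        with pytest.raises(ValueError, match="too small"):
            simulate_cohort(library, params)


class TestEmitCohort:
    def test_emission_is_deterministic_byte_identical(self, library, tmp_path):
        params = CohortParams(seed=9, **TINY)
        paths_a = emit_cohort(simulate_cohort(library, params), str(tmp_path / "a"))
        paths_b = emit_cohort(simulate_cohort(library, params), str(tmp_path / "b"))
        for key in paths_a:
            assert filecmp.cmp(paths_a[key], paths_b[key], shallow=False), key

    def test_vcf_roundtrip_recovers_truth_carriers(self, small_cohort, tmp_path):
        paths = emit_cohort(small_cohort, str(tmp_path / "c"))
        vset = read_pangenome_vcf(paths["vcf"], vset_samples(small_cohort))
        by_id = {r.record_id: r for r in vset.records if r.record_id}
        for ev in small_cohort.truth_events:
            rec = by_id[ev.locus_id]
            if ev.ref_span:
                carriers = {
                    f"{s}.{h}" for (s, h), idx in rec.allele_of.items() if idx == 1
                }
            else:
                carriers = {
                    f"{s}.{h}" for (s, h), idx in rec.allele_of.items() if idx and idx > 0
                }
            assert carriers == set(ev.carriers), ev.locus_id

    def test_insertion_records_follow_anchor_convention(self, small_cohort, tmp_path):
        paths = emit_cohort(small_cohort, str(tmp_path / "d"))
        vset = read_pangenome_vcf(paths["vcf"], vset_samples(small_cohort))
        by_id = {r.record_id: r for r in vset.records if r.record_id}
        for ev in small_cohort.truth_events:
            rec = by_id[ev.locus_id]
            if ev.ref_span:
                assert len(rec.alt_alleles[0]) == 1  # deletion leaves the 1 bp empty site
            else:
                assert len(rec.ref_allele) == 1  # empty site is exactly 1 bp
                hap = ev.carriers[0]
                body = ev.alleles_by_hap[hap]
                assert any(len(a) == len(body) + 1 for a in rec.alt_alleles)


def vset_samples(cohort):
    return sorted({h.rsplit(".", 1)[0] for h in HAPLOTYPES})
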