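import numpy as np
import pytest

from canisv.io_formats import AnnotationSet, RepeatAnnotation
from canisv.line1_biology import (
    GenomeAligner,
    TransductionCall,
    extract_3prime_transduction,
    filter_transduction_alignments,
    find_intact_orfs,
    is_fully_intact,
    match_score,
    resolve_parentless,
    trim_polya,
)
from canisv.repeat_annotation import revcomp


def l1_annot(start, end, strand="+", seq_id="query"):
    return RepeatAnnotation(seq_id, start, end, "L1_sim", "LINE/L1", strand, 1, 0, end - start)


class TestFindIntactOrfs:
    def test_full_length_consensus_has_two_intact_orfs(self, library):
        cons = library.line1_consensus
        calls = find_intact_orfs(cons, AnnotationSet([l1_annot(0, len(cons))]), library)
        intact = sorted(c.matches for c in calls if c.intact)
        assert intact == ["ORF1p", "ORF2p"]
        assert is_fully_intact(calls)

    def test_midorf_stop_breaks_orf2_intactness(self, library):
        cons = library.line1_consensus
        o2s, o2e = library.orf2_span
        mid = o2s + ((o2e - o2s) // 2 // 3) * 3
        broken = cons[:mid] + "TAA" + cons[mid + 3 :]
        calls = find_intact_orfs(broken, AnnotationSet([l1_annot(0, len(broken))]), library)
        assert not any(c.intact and c.matches == "ORF2p" for c in calls)
        assert any(c.intact and c.matches == "ORF1p" for c in calls)

    def test_truncated_element_below_4kb_skipped(self, library):
        cons = library.line1_consensus
        frag = cons[-3500:]
        calls = find_intact_orfs(frag, AnnotationSet([l1_annot(0, 3500)]), library)
        assert calls == []

    def test_minus_strand_element_scanned_on_element_strand(self, library):
        cons = library.line1_consensus
        rc = revcomp(cons)
        calls = find_intact_orfs(rc, AnnotationSet([l1_annot(0, len(rc), "-")]), library)
        assert is_fully_intact(calls)


class TestTrimPolya:
    def test_strips_terminal_run_allowing_one_mismatch(self):
        assert trim_polya("ACGTAC" + "A" * 10) == "ACGTAC"
        assert trim_polya("ACGTAC" + "AAAAAGAAAA") == "ACGTAC"

    def test_short_run_untouched(self):
        assert trim_polya("ACGTACAA") == "ACGTACAA"


class TestExtractTransduction:
    def test_tag_downstream_of_element(self, library):
        cons = library.line1_consensus
        tag = "CGTACGTTAGCATCGGATCCATGCATTACGGATCAGGTACCATGGATCCTTAGCAGTACGTAGCATTGACCGGTAACGT"
        allele = cons + tag + "A" * 20
        call = extract_3prime_transduction(
            allele, AnnotationSet([l1_annot(0, len(cons))]), locus_id="L1"
        )
        assert call is not None and call.transduced_seq == tag

    def test_polya_only_yields_none(self, library):
        cons = library.line1_consensus
        allele = cons + "A" * 20
        assert extract_3prime_transduction(allele, AnnotationSet([l1_annot(0, len(cons))])) is None

    def test_minus_strand_takes_upstream_in_allele_coordinates(self, library):
        cons = library.line1_consensus
        tag = "CGTACGTTAGCATCGGATCCATGCATTACGGATCAGGTACCATGGATCC"
        plus_allele = cons + tag + "A" * 15
        minus_allele = revcomp(plus_allele)
        annots = AnnotationSet([l1_annot(len(minus_allele) - len(cons), len(minus_allele), "-")])
        call = extract_3prime_transduction(minus_allele, annots)
        assert call is not None and call.transduced_seq == tag


class TestFilterTransductionAlignments:
    def make_call(self, score, chrom="chr1", t_start=100_000, t_len=None, qlen=80):
        cigar = [("=", int(score))] if score >= 0 else []
        t_len = t_len if t_len is not None else int(score)
        aln_score = match_score(cigar)
        from canisv.io_formats import AlignmentRecord

        aln = AlignmentRecord(
            query_id="q", target_id=chrom, query_span=(0, qlen),
            target_span=(t_start, t_start + t_len), cigar=cigar, score=aln_score,
        )
        call = TransductionCall(locus_id="L", transduced_seq="C" * qlen, alignments=[aln])
        return call

    def test_score_boundary_24_fails_25_passes(self):
        fail, _ = filter_transduction_alignments(
            self.make_call(24), ("chr1", 0), [], ["chr1"]
        )
        ok, _ = filter_transduction_alignments(
            self.make_call(25), ("chr1", 0), [], ["chr1"]
        )
        assert fail.status == "FAIL" and fail.fail_reason == "score"
        assert ok.status == "PASS"

    def test_masked_query_boundary(self):
        call = self.make_call(80)
        masked24, _ = filter_transduction_alignments(
            call, ("chr1", 0), [(0, 56)], ["chr1"]  # 80-56=24 unmasked
        )
        assert masked24.status == "FAIL" and masked24.fail_reason == "masked"
        masked25, _ = filter_transduction_alignments(
            call, ("chr1", 0), [(0, 55)], ["chr1"]
        )
        assert masked25.status == "PASS"

    def test_proximity_boundary_at_7kb(self):
        near, _ = filter_transduction_alignments(
            self.make_call(80, t_start=10_000), ("chr1", 3_081), [], ["chr1"]
        )  # nearest edge 10_000 - 3_081 = 6_919 < 7000
        far, _ = filter_transduction_alignments(
            self.make_call(80, t_start=10_000), ("chr1", 2_999), [], ["chr1"]
        )
        assert near.status == "FAIL" and near.fail_reason == "proximal"
        assert far.status == "PASS"

    def test_unplaced_target_fails(self):
        call = self.make_call(80, chrom="scaffold_17")
        out, counts = filter_transduction_alignments(call, ("chr1", 0), [], ["chr1", "chr2"])
        assert out.status == "FAIL" and out.fail_reason == "unplaced"
        assert counts["unplaced"] == 1

    def test_excess_alignments_fail(self):
        call = self.make_call(80)
        call.alignments = call.alignments * 6
        out, _ = filter_transduction_alignments(call, ("chr1", 0), [], ["chr1"])
        assert out.status == "FAIL" and out.fail_reason == "excess_alignments"

    def test_genomic_span_excess_fails(self):
        call = self.make_call(80, t_len=181, qlen=80)
        out, _ = filter_transduction_alignments(call, ("chr1", 0), [], ["chr1"])
        assert out.status == "FAIL" and out.fail_reason == "genomic_span"

    def test_filtering_is_idempotent(self):
        call, _ = filter_transduction_alignments(self.make_call(80), ("chr1", 0), [], ["chr1"])
        again, _ = filter_transduction_alignments(call, ("chr1", 0), [], ["chr1"])
        assert again.status == call.status == "PASS"
        assert len(again.alignments) == len(call.alignments)


class TestGenomeAligner:
    def test_exact_hit_located_with_full_score(self):
        rng = np.random.default_rng(3)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=20_000))}
        query = genome["chr1"][12_000:12_080]
        (hit, *rest) = GenomeAligner(genome).align(query)
        assert hit.target_id == "chr1"
        assert hit.target_span == (12_000, 12_080)
        assert hit.score == 80

    def test_repetitive_query_reports_multiple_hits(self):
        rng = np.random.default_rng(4)
        unit = "".join(rng.choice(list("ACGT"), size=100))
        filler = "".join(rng.choice(list("ACGT"), size=500))
        genome = {"chr1": filler.join([unit] * 7)}
        hits = GenomeAligner(genome).align(unit[10:90])
        assert len(hits) >= 6


class TestResolveParentless:
    def make_pass_call(self, chrom, t_start, locus_id="T1"):
        from canisv.io_formats import AlignmentRecord

        aln = AlignmentRecord(
            query_id=locus_id, target_id=chrom, query_span=(0, 80),
            target_span=(t_start, t_start + 80), cigar=[("=", 80)], score=80.0,
        )
        return TransductionCall(
            locus_id=locus_id, transduced_seq="C" * 80, alignments=[aln], status="PASS"
        )

    def test_reference_and_segregating_and_parentless_labels(self):
        ref_annots = AnnotationSet([l1_annot(50_000, 55_500, seq_id="chr1")])

        class Dimorphic:
            chrom, pos = "chr2", 80_000

        calls = [
            self.make_pass_call("chr1", 55_600, "ref_child"),
            self.make_pass_call("chr2", 80_100, "seg_child"),
            self.make_pass_call("chr2", 200_000, "orphan"),
        ]
        resolved, families = resolve_parentless(calls, [Dimorphic()], ref_annots)
        kinds = {c.locus_id: c.source_kind for c in resolved}
        assert kinds == {
            "ref_child": "REFERENCE_SOURCE",
            "seg_child": "SEGREGATING_SOURCE",
            "orphan": "PARENTLESS",
        }
        assert sum(len(v) for v in families.values()) == 3

    def test_shared_source_forms_one_family(self):
        ref_annots = AnnotationSet([l1_annot(50_000, 55_500, seq_id="chr1")])
        calls = [
            self.make_pass_call("chr1", 55_600, "a"),
            self.make_pass_call("chr1", 55_650, "b"),
        ]
        _, families = resolve_parentless(calls, [], ref_annots)
        assert list(families.values()) == [["a", "b"]]
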