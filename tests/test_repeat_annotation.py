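"""Sequence-composition primitives against brute-force oracles and stated rules."""

from collections import Counter
from fractions import Fraction

import numpy as np
import pytest

from canisv.io_formats import AnnotationSet, RepeatAnnotation
from canisv.repeat_annotation import (
    annotate_with_library,
    find_exact_tandem_repeats,
    merge_repeat_annotations,
    sdust_mask,
    union_coverage,
)

# ---------------------------------------------------------------------------
# brute-force SDUST oracle: direct enumeration with exact rational scores
# ---------------------------------------------------------------------------

def sdust_oracle(seq, window=64, threshold=20):
    """Union of perfect low-complexity intervals, from the definition.

    Enumerates every interval of 4..window bases within ACGT segments,
    computes the triplet-collision score sum(c*(c-1)/2)/(l-1) as an exact
    fraction, and reports an interval when its score exceeds threshold/10
    and no proper subinterval scores strictly higher.
    """
    seq = seq.upper()
    n = len(seq)
    thr = Fraction(threshold, 10)
    scores = {}
    # segment at non-ACGT characters
    segments = []
    start = None
    for i, ch in enumerate(seq + "$"):
        if ch in "ACGT":
            if start is None:
                start = i
        else:
            if start is not None:
                segments.append((start, i))
                start = None
    for s0, s1 in segments:
        for i in range(s0, s1):
            counts = Counter()
            raw = 0
            for j in range(i + 3, min(i + window, s1) + 1):
                t = seq[j - 3 : j]
                raw += counts[t]
                counts[t] += 1
                if j - i >= 4:
                    scores[(i, j)] = Fraction(raw, j - i - 3)
    perfect = []
    for (i, j), sc in scores.items():
        if sc <= thr:
            continue
        if all(
            scores.get((a, b), Fraction(-1)) <= sc
            for a in range(i, j - 3)
            for b in range(a + 4, j + 1)
            if (a, b) != (i, j)
        ):
            perfect.append((i, j))
    merged = []
    for s, e in sorted(perfect):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def _assert_matches_oracle(seq, window=64, threshold=20):
    got = [(m.start, m.end) for m in sdust_mask(seq, window, threshold)]
    assert got == sdust_oracle(seq, window, threshold), seq


class TestSdust:
    def test_homopolymer_fully_masked(self):
        seq = "A" * 100
        assert [(m.start, m.end) for m in sdust_mask(seq)] == [(0, 100)]
        _assert_matches_oracle(seq)

    def test_dinucleotide_repeat_fully_masked(self):
        seq = "AC" * 50
        assert [(m.start, m.end) for m in sdust_mask(seq)] == [(0, 100)]

    def test_random_sequence_mask_matches_oracle(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        _assert_matches_oracle(seq)

    def test_non_acgt_breaks_intervals(self):
        seq = "A" * 30 + "N" + "A" * 30
        got = [(m.start, m.end) for m in sdust_mask(seq)]
        assert got == [(0, 30), (31, 61)]
        _assert_matches_oracle(seq)

    def test_masking_is_context_free(self):
        # symmetric DUST: a masked interval's content alone determines it
        core = "AT" * 12
        for flank in ("GCGTACGATCGTTAGC", "CTTGCAAGGTCGATCC"):
            seq = flank + core + flank[::-1]
            masked = sdust_mask(seq)
            assert any(m.start <= len(flank) and m.end >= len(flank) + len(core) - 2 for m in masked)

    @pytest.mark.parametrize("seed", range(6))
    def test_randomized_oracle_equivalence(self, seed):
        rng = np.random.default_rng(1000 + seed)
        for _ in range(12):
            kind = rng.integers(3)
            if kind == 0:
                n = int(rng.integers(10, 300))
                seq = "".join(rng.choice(list("ACGT"), size=n))
            elif kind == 1:  # short adversarial low-complexity
                n = int(rng.integers(8, 36))
                unit = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
                seq = (unit * (n // len(unit) + 1))[:n]
            else:  # random with a planted repeat island
                n = int(rng.integers(40, 120))
                seq = list(rng.choice(list("ACGT"), size=n))
                unit = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 3))))
                ins = (unit * 20)[: int(rng.integers(8, 24))]
                p = int(rng.integers(0, n - len(ins)))
                seq[p : p + len(ins)] = list(ins)
                seq = "".join(seq)
            _assert_matches_oracle(seq)


# ---------------------------------------------------------------------------
# exact tandem repeats
# ---------------------------------------------------------------------------

def etrf_oracle(seq, max_unit=6, min_copies=2, min_span=4):
    """Naive maximal-run enumeration with primitive-motif filtering."""
    n = len(seq)
    out = set()
    for p in range(1, min(max_unit, n // 2) + 1):
        i = 0
        while i + p < n:
            if seq[i + p] != seq[i]:
                i += 1
                continue
            # extend the run of matches starting at i+p
            j = i + p
            while j < n and seq[j] == seq[j - p]:
                j += 1
            start, end = i, j
            # maximal run start: back up to the first matching position
            span = end - start
            unit = seq[start : start + p]
            if span >= min_span and span // p >= min_copies:
                if (unit + unit).find(unit, 1) == len(unit):
                    out.add((start, end, unit, p, span // p))
            i = end - p + 1
    return out


class TestExactTandemRepeats:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATATATAT", [(0, 8, "AT", 2, 4)]),
            ("ACGACGACGT", [(0, 9, "ACG", 3, 3)]),
            ("AAAA", [(0, 4, "A", 1, 4)]),
        ],
    )
    def test_stated_examples(self, seq, expected):
        got = [(r.start, r.end, r.unit, r.unit_length, r.copies) for r in find_exact_tandem_repeats(seq)]
        assert got == expected

    def test_runs_reconstruct_input_and_are_maximal(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(10, 200))
            seq = "".join(rng.choice(list("ACGTA"), size=n))  # A-biased: more runs
            for r in find_exact_tandem_repeats(seq, max_unit=6):
                span = seq[r.start : r.end]
                rebuilt = (r.unit * (len(span) // r.unit_length + 1))[: len(span)]
                assert span == rebuilt
                p = r.unit_length
                if r.start - 1 >= 0 and r.start - 1 + p < n:
                    assert seq[r.start - 1] != seq[r.start - 1 + p]
                if r.end < n:
                    assert seq[r.end] != seq[r.end - p]

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            n = int(rng.integers(8, 150))
            seq = "".join(rng.choice(list("ACGT"), size=n, p=[0.4, 0.25, 0.2, 0.15]))
            got = {
                (r.start, r.end, r.unit, r.unit_length, r.copies)
                for r in find_exact_tandem_repeats(seq, max_unit=6)
            }
            assert got == etrf_oracle(seq)

    def test_homopolymer_not_reported_at_higher_periods(self):
        runs = find_exact_tandem_repeats("AAAAAAAA", max_unit=4)
        assert [(r.unit_length, r.copies) for r in runs] == [(1, 8)]

    def test_canonical_unit_is_smallest_rotation(self):
        (r,) = find_exact_tandem_repeats("TATATA", max_unit=2)
        assert r.unit == "TA" and r.canonical_unit == "AT"


# ---------------------------------------------------------------------------
# annotation merging
# ---------------------------------------------------------------------------

def _sinec(start, end, eid):
    return RepeatAnnotation("q", start, end, "SINEC_Cf", "SINE/tRNA-Lys", "+", eid)


class TestMergeRepeatAnnotations:
    def test_ct_run_between_sinec_fragments_absorbed(self):
        annots = AnnotationSet(
            [
                _sinec(0, 120, 3),
                RepeatAnnotation("q", 120, 150, "(CT)n", "Simple_repeat", "+", 0),
                _sinec(150, 200, 3),
            ]
        )
        merged = list(merge_repeat_annotations(annots))
        assert len(merged) == 1
        assert merged[0].interval() == (0, 200)
        assert merged[0].repeat_name == "SINEC_Cf"

    def test_simple_repeat_between_l1_fragments_merged(self):
        annots = AnnotationSet(
            [
                RepeatAnnotation("q", 0, 500, "L1_Canid", "LINE/L1", "+", 9),
                RepeatAnnotation("q", 500, 520, "(TTTG)n", "Simple_repeat", "+", 0),
                RepeatAnnotation("q", 520, 900, "L1_Canid", "LINE/L1", "+", 9),
            ]
        )
        merged = list(merge_repeat_annotations(annots))
        assert [a.interval() for a in merged if a.repeat_class == "LINE/L1"] == [(0, 900)]

    def test_adjacent_different_element_ids_not_merged(self):
        annots = AnnotationSet([_sinec(0, 100, 3), _sinec(100, 200, 4)])
        merged = list(merge_repeat_annotations(annots))
        assert sorted(a.interval() for a in merged) == [(0, 100), (100, 200)]

    def test_intervening_element_blocks_merge(self):
        annots = AnnotationSet(
            [
                RepeatAnnotation("q", 0, 500, "L1_Canid", "LINE/L1", "+", 9),
                _sinec(500, 700, 4),
                RepeatAnnotation("q", 700, 900, "L1_Canid", "LINE/L1", "+", 9),
            ]
        )
        merged = list(merge_repeat_annotations(annots))
        l1 = sorted(a.interval() for a in merged if a.repeat_class == "LINE/L1")
        assert l1 == [(0, 500), (700, 900)]

    def test_ct_run_inside_single_sinec_absorbed(self):
        annots = AnnotationSet(
            [_sinec(0, 200, 3), RepeatAnnotation("q", 80, 100, "(AG)n", "Simple_repeat", "+", 0)]
        )
        merged = list(merge_repeat_annotations(annots))
        assert [a.interval() for a in merged] == [(0, 200)]

    def test_merge_is_idempotent(self):
        annots = AnnotationSet(
            [
                _sinec(0, 120, 3),
                RepeatAnnotation("q", 120, 150, "(CT)n", "Simple_repeat", "+", 0),
                _sinec(150, 200, 3),
                RepeatAnnotation("q", 300, 340, "(A)n", "Low_complexity", "+", 0),
                _sinec(400, 480, 8),
            ]
        )
        once = merge_repeat_annotations(annots)
        twice = merge_repeat_annotations(once)
        assert [(a.seq_id, a.interval(), a.repeat_name) for a in once] == [
            (a.seq_id, a.interval(), a.repeat_name) for a in twice
        ]


class TestUnionCoverage:
    def test_overlapping_intervals(self):
        assert union_coverage([(0, 50), (40, 100)], 200) == pytest.approx(0.5)

    def test_empty_and_full(self):
        assert union_coverage([], 200) == 0.0
        assert union_coverage([(0, 200)], 200) == 1.0

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            union_coverage([(0, 1)], 0)


class TestLibraryAnnotator:
    def test_verbatim_consensus_fully_annotated(self, library):
        annots = list(annotate_with_library(library.sinec_consensus, library))
        hit = max(annots, key=lambda a: a.length)
        assert hit.repeat_name == "SINEC_sim"
        assert hit.start == 0 and hit.end == len(library.sinec_consensus)
        assert hit.cons_end == len(library.sinec_consensus)

    def test_three_prime_half_reports_consensus_offset(self, library):
        cons = library.line1_consensus
        half = len(cons) // 2
        annots = [a for a in annotate_with_library(cons[half:], library) if a.repeat_name == "L1_sim"]
        hit = max(annots, key=lambda a: a.length)
        assert abs(hit.cons_start - half) < 30
        assert hit.cons_end > len(cons) - 30

    def test_reverse_complement_hit_found_with_minus_strand(self, library):
        from canisv.repeat_annotation import revcomp

        annots = list(annotate_with_library(revcomp(library.sinec_consensus), library))
        hit = max(annots, key=lambda a: a.length)
        assert hit.repeat_name == "SINEC_sim" and hit.strand == "-"

    def test_random_sequence_yields_no_hits(self, library):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert len(annotate_with_library(seq, library)) == 0
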