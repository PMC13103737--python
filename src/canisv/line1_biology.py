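"""LINE-1-specific analyses.

Covers ORF intactness of full-length elements, extraction and filtering of
3' transductions (downstream genomic sequence carried along when a LINE-1
transcript reads through its own polyadenylation signal — a fingerprint of
the source element), and resolution of "parentless" transductions to
segregating, non-reference source elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import edlib
from Bio.Seq import Seq

from .io_formats import AlignmentRecord, AnnotationSet, parse_cigar
from .repeat_annotation import interval_union_length, revcomp


@dataclass
class OrfCall:
    """An ORF found on a LINE-1 allele, in element-strand coordinates."""

    start: int
    end: int
    frame: int
    strand: str
    protein: str
    matches: Optional[str]  # "ORF1p" | "ORF2p" | None
    intact: bool
    consensus_distance: Optional[int] = None
    insertion_codons: int = 0  # protein length in excess of the matched consensus


@dataclass
class TransductionCall:
    locus_id: str
    transduced_seq: str
    alignments: List[AlignmentRecord] = field(default_factory=list)
    status: str = "PENDING"  # PENDING | PASS | FAIL(<reason>)
    fail_reason: Optional[str] = None
    source_locus: Optional[str] = None
    source_kind: Optional[str] = None  # REFERENCE_SOURCE | SEGREGATING_SOURCE | PARENTLESS


def _l1_annotations(annots: AnnotationSet) -> List:
    return [a for a in annots if a.repeat_class.startswith("LINE/L1")]


def _find_orfs_one_strand(seq: str, min_codons: int) -> List[Tuple[int, int, int]]:
    """(start, end, frame) of ATG→stop ORFs of at least ``min_codons`` codons."""
    out = []
    n = len(seq)
    for frame in range(3):
        pos = frame
        orf_start = None
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if orf_start is None and codon == "ATG":
                orf_start = pos
            if codon in ("TAA", "TAG", "TGA") and orf_start is not None:
                if (pos + 3 - orf_start) // 3 >= min_codons:
                    out.append((orf_start, pos + 3, frame))
                orf_start = None
            pos += 3
        # open-ended ORF at sequence end is not reported: intactness needs a stop
    return out


def find_intact_orfs(
    allele: str,
    annots: AnnotationSet,
    library,
    min_len: int = 4000,
    min_codons: int = 300,
    max_consensus_distance_frac: float = 0.10,
) -> List[OrfCall]:
    """ORF scan of a LINE-1 allele, matched against the consensus proteins.

    Skipped (empty result) when the LINE-1 annotation span on the allele is
    shorter than ``min_len``.  ORFs of at least ``min_codons`` codons on the
    element strand are translated and matched to the consensus ORF1p/ORF2p
    by infix edit distance; a call is intact when the distance is at most
    ``max_consensus_distance_frac`` of the consensus length, which bounds
    missing consensus coverage at the same fraction.  A protein longer than
    its matched consensus (e.g. carrying a frame-preserving nested
    insertion) reports the excess in codons.
    """
    l1 = _l1_annotations(annots)
    if not l1:
        return []
    span = interval_union_length([(a.start, a.end) for a in l1])
    if span < min_len:
        return []
    strand = max(l1, key=lambda a: a.length).strand
    oriented = allele if strand == "+" else revcomp(allele)
    consensus = {"ORF1p": library.protein_orf1, "ORF2p": library.protein_orf2}
    calls: List[OrfCall] = []
    for start, end, frame in _find_orfs_one_strand(oriented, min_codons):
        protein = str(Seq(oriented[start:end]).translate())[:-1]
        best_name, best_dist = None, None
        for name, cons in consensus.items():
            res = edlib.align(cons, protein, mode="HW", task="distance")
            d = res["editDistance"]
            if best_dist is None or d / len(cons) < best_dist / len(consensus[best_name]):
                best_name, best_dist = name, d
        intact = False
        insertion_codons = 0
        if best_name is not None:
            cons_len = len(consensus[best_name])
            if best_dist / cons_len <= max_consensus_distance_frac:
                intact = True
                insertion_codons = max(0, len(protein) - cons_len)
            else:
                best_name = None
        calls.append(
            OrfCall(
                start=start,
                end=end,
                frame=frame,
                strand=strand,
                protein=protein,
                matches=best_name,
                intact=intact,
                consensus_distance=best_dist,
                insertion_codons=insertion_codons,
            )
        )
    return calls


def is_fully_intact(calls: Sequence[OrfCall]) -> bool:
    """True when both ORF1p and ORF2p have an intact call."""
    hits = {c.matches for c in calls if c.intact}
    return "ORF1p" in hits and "ORF2p" in hits


# ---------------------------------------------------------------------------
# 3' transductions
# ---------------------------------------------------------------------------

def trim_polya(seq: str, min_run: int = 5) -> str:
    """Strip the maximal 3' poly(A) run (allowing one non-A) if >= ``min_run`` A's.

    The single tolerated non-A must be followed (5'-ward) by at least two
    more A's, so a terminal tail never eats into ordinary sequence.
    """
    i = len(seq) - 1
    n_a = 0
    while i >= 0 and seq[i] == "A":
        n_a += 1
        i -= 1
    if i >= 2 and seq[i] != "A" and seq[i - 1] == "A" and seq[i - 2] == "A":
        j = i - 1
        while j >= 0 and seq[j] == "A":
            n_a += 1
            j -= 1
        i = j
    if n_a >= min_run:
        return seq[: i + 1]
    return seq


def extract_3prime_transduction(
    allele: str,
    annots: AnnotationSet,
    min_len: int = 25,
    locus_id: str = "",
) -> Optional[TransductionCall]:
    """Sequence strictly 3' (element orientation) of the longest LINE-1 annotation.

    The terminal poly(A) run is trimmed; returns ``None`` when the
    remaining segment is shorter than ``min_len``.
    """
    l1 = _l1_annotations(annots)
    if not l1:
        return None
    longest = max(l1, key=lambda a: (a.length, -a.start))
    if longest.strand == "+":
        segment = allele[longest.end :]
    else:
        segment = revcomp(allele[: longest.start])
    segment = trim_polya(segment)
    if len(segment) < min_len:
        return None
    return TransductionCall(locus_id=locus_id, transduced_seq=segment)


class GenomeAligner:
    """Seed-and-refine alignment of short queries against a reference.

    Fulfils the "align query to genome" contract of the transduction
    analysis: exact probe substrings of the query seed candidate sites,
    each refined by infix edit-distance alignment.  Both orientations are
    searched.  Deterministic; no external aligner required.
    """

    def __init__(self, reference: Mapping[str, str], probe_len: int = 20, max_candidates: int = 64):
        self.reference = {c: s.upper() for c, s in reference.items()}
        self.probe_len = probe_len
        self.max_candidates = max_candidates

    def _probes(self, query: str) -> List[int]:
        k = self.probe_len
        n = len(query)
        if n <= k:
            return [0]
        offsets = {0, (n - k) // 2, n - k}
        return sorted(offsets)

    def align(self, query: str, query_id: str = "query") -> List[AlignmentRecord]:
        query = query.upper()
        records: List[AlignmentRecord] = []
        for strand, oriented in (("+", query), ("-", revcomp(query))):
            candidates: Dict[str, List[int]] = {}
            for off in self._probes(oriented):
                probe = oriented[off : off + self.probe_len]
                for chrom, seq in self.reference.items():
                    start = 0
                    while True:
                        hit = seq.find(probe, start)
                        if hit < 0:
                            break
                        candidates.setdefault(chrom, []).append(hit - off)
                        start = hit + 1
                        if len(candidates.get(chrom, [])) > self.max_candidates:
                            break
            for chrom, positions in candidates.items():
                positions = sorted(set(positions))
                merged: List[int] = []
                for p in positions:
                    if not merged or p - merged[-1] > len(oriented) // 2:
                        merged.append(p)
                for p in merged:
                    w_start = max(0, p - 30)
                    w_end = min(len(self.reference[chrom]), p + len(oriented) + 30)
                    window = self.reference[chrom][w_start:w_end]
                    res = edlib.align(oriented, window, mode="HW", task="path")
                    if res["editDistance"] < 0 or not res["locations"]:
                        continue
                    t0, t1 = res["locations"][0]
                    cigar = parse_cigar(res["cigar"])
                    rec = AlignmentRecord(
                        query_id=query_id,
                        target_id=chrom,
                        query_span=(0, len(query)),
                        target_span=(w_start + t0, w_start + t1 + 1),
                        strand=strand,
                        cigar=cigar,
                        edit_distance=res["editDistance"],
                        score=match_score(cigar),
                    )
                    records.append(rec)
        # de-duplicate identical target spans, keep best score
        best: Dict[Tuple[str, int, int, str], AlignmentRecord] = {}
        for r in records:
            key = (r.target_id, r.target_span[0], r.target_span[1], r.strand)
            if key not in best or r.score > best[key].score:
                best[key] = r
        return sorted(best.values(), key=lambda r: -r.score)


def match_score(cigar: Sequence[Tuple[str, int]]) -> float:
    """Alignment match score: matches − mismatches − gap opens."""
    matches = sum(n for op, n in cigar if op == "=")
    mismatches = sum(n for op, n in cigar if op == "X")
    gap_opens = sum(1 for op, _n in cigar if op in ("I", "D"))
    return float(matches - mismatches - gap_opens)


def filter_transduction_alignments(
    call: TransductionCall,
    locus_pos: Tuple[str, int],
    query_mask: Sequence[Tuple[int, int]],
    primary_chroms: Sequence[str],
    min_score: float = 25,
    min_unmasked: int = 25,
    proximal_bp: int = 7000,
    max_hits: int = 5,
    span_excess: int = 100,
) -> Tuple[TransductionCall, Dict[str, int]]:
    """Apply the transduction alignment filters, in order.

    Filters: alignments to non-primary sequences; match score < 25; fewer
    than 25 unmasked query positions (RepeatMasker ∪ SDUST union, supplied
    as ``query_mask``); alignment within 7 kb of the locus (nearest edge);
    more than ``max_hits`` retained alignments (segmental duplication /
    interspersed-repeat homology); best-alignment genomic span exceeding
    the query span by more than 100 bp.  ``status`` becomes PASS, or FAIL
    with the first failing reason.  Idempotent on the retained set.
    """
    counts = {"input": len(call.alignments), "unplaced": 0, "score": 0, "masked": 0, "proximal": 0}
    primary = set(primary_chroms)
    qlen = len(call.transduced_seq)
    unmasked = qlen - interval_union_length(
        [(max(0, s), min(qlen, e)) for s, e in query_mask if e > 0 and s < qlen]
    )
    retained: List[AlignmentRecord] = []
    reasons: List[str] = []
    for aln in call.alignments:
        if aln.target_id not in primary:
            counts["unplaced"] += 1
            reasons.append("unplaced")
            continue
        if aln.score < min_score:
            counts["score"] += 1
            reasons.append("score")
            continue
        if unmasked < min_unmasked:
            counts["masked"] += 1
            reasons.append("masked")
            continue
        if aln.target_id == locus_pos[0]:
            dist = max(aln.target_span[0] - locus_pos[1], locus_pos[1] - aln.target_span[1], 0)
            if dist < proximal_bp:
                counts["proximal"] += 1
                reasons.append("proximal")
                continue
        retained.append(aln)
    out = TransductionCall(
        locus_id=call.locus_id,
        transduced_seq=call.transduced_seq,
        alignments=retained,
    )
    if not retained:
        out.status = "FAIL"
        out.fail_reason = reasons[0] if reasons else "no_alignment"
        counts["retained"] = 0
        return out, counts
    if len(retained) > max_hits:
        out.status = "FAIL"
        out.fail_reason = "excess_alignments"
        counts["excess"] = len(retained)
        counts["retained"] = 0
        return out, counts
    best = retained[0]
    t_span = best.target_span[1] - best.target_span[0]
    if t_span - qlen > span_excess:
        out.status = "FAIL"
        out.fail_reason = "genomic_span"
        counts["retained"] = 0
        return out, counts
    out.status = "PASS"
    counts["retained"] = len(retained)
    return out, counts


def resolve_parentless(
    calls: Sequence[TransductionCall],
    line1_loci: Sequence,
    ref_annots: AnnotationSet,
    window: int = 1000,
) -> Tuple[List[TransductionCall], Dict[str, List[str]]]:
    """Label PASS calls by source and group them into families.

    A call is REFERENCE_SOURCE when its best alignment lies within
    ``window`` of the 3' end of a LINE-1 annotated in the reference;
    SEGREGATING_SOURCE when it instead lies within ``window`` of a
    dimorphic LINE-1 locus (the paper's resolved-"parentless" scenario);
    else PARENTLESS.  Returns the annotated calls and a source → member
    locus-id map.
    """
    ref_l1 = [a for a in ref_annots if a.repeat_class.startswith("LINE/L1")]
    families: Dict[str, List[str]] = {}
    out: List[TransductionCall] = []
    for call in calls:
        if call.status != "PASS" or not call.alignments:
            out.append(call)
            continue
        best = max(call.alignments, key=lambda a: a.score)
        chrom = best.target_id
        a_start, a_end = best.target_span
        source = None
        kind = None
        for ann in ref_l1:
            if ann.seq_id != chrom:
                continue
            anchor = ann.end if ann.strand == "+" else ann.start
            if min(abs(a_start - anchor), abs(a_end - anchor)) <= window:
                source = f"ref:{chrom}:{ann.start}"
                kind = "REFERENCE_SOURCE"
                break
        if source is None:
            for locus in line1_loci:
                if locus.chrom != chrom:
                    continue
                if min(abs(a_start - locus.pos), abs(a_end - locus.pos)) <= window:
                    source = f"locus:{chrom}:{locus.pos}"
                    kind = "SEGREGATING_SOURCE"
                    break
        if source is None:
            source = f"parentless:{chrom}:{a_start // 2000}"
            kind = "PARENTLESS"
        annotated = TransductionCall(
            locus_id=call.locus_id,
            transduced_seq=call.transduced_seq,
            alignments=call.alignments,
            status=call.status,
            source_locus=source,
            source_kind=kind,
        )
        out.append(annotated)
        families.setdefault(source, []).append(call.locus_id)
    return out, families
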