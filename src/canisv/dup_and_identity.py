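"""Segmental-duplication pair summaries and alignment identity measures.

Duplication pairs come from an external self-alignment (a BEDPE-like
table with length and divergence columns).  After the base filter
(length >= 1 kb, divergence <= 10%) and an optional strict subset
(>= 10 kb, <= 5%), pairs are classified INTRA vs INTER chromosomal;
INTRA pairs split into TANDEM (paralogs separated by less than 200 kb)
vs DISPERSED, and INTER pairs are flagged CENTROMERIC when both paralogs
start within the first 5 Mb of their chromosome — canine autosomes are
telocentric, so interchromosomal duplications concentrate there.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .io_formats import AlignmentRecord
from .repeat_annotation import interval_union_length, merge_intervals


@dataclass
class DupPair:
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    length: int
    divergence: float
    orientation: str = "+"
    placement: Optional[str] = None  # INTRA | INTER
    config: Optional[str] = None  # TANDEM | DISPERSED (INTRA only)
    centromeric: bool = False  # INTER only

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("duplication length must be >= 1")
        if not 0 <= self.divergence <= 1:
            raise ValueError("divergence must be a fraction in [0,1]")

    @property
    def separation(self) -> Optional[int]:
        """Gap between the nearer ends of the paralog intervals (0 if overlapping)."""
        if self.chrom_a != self.chrom_b:
            return None
        if self.end_a <= self.start_b:
            return self.start_b - self.end_a
        if self.end_b <= self.start_a:
            return self.start_a - self.end_b
        return 0


def read_dup_pairs(path: str) -> List[DupPair]:
    """Read a tab-separated duplication-pair table (chrA..endB, length, divergence)."""
    pairs: List[DupPair] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            pairs.append(
                DupPair(
                    chrom_a=f[0], start_a=int(f[1]), end_a=int(f[2]),
                    chrom_b=f[3], start_b=int(f[4]), end_b=int(f[5]),
                    length=int(f[6]), divergence=float(f[7]),
                )
            )
    return pairs


def filter_and_classify_dup_pairs(
    pairs: Sequence[DupPair],
    min_len: int = 10_000,
    max_div: float = 0.05,
    tandem_sep: int = 200_000,
    centromeric_window: int = 5_000_000,
    base_min_len: int = 1_000,
    base_max_div: float = 0.10,
    mito_chrom: Optional[str] = None,
    primary_chroms: Optional[Sequence[str]] = None,
) -> Tuple[List[DupPair], Dict[str, int]]:
    """Apply the base and strict filters and classify retained pairs.

    Retained pairs get ``placement`` INTRA/INTER; INTRA pairs get
    ``config`` TANDEM (separation < ``tandem_sep``) or DISPERSED; INTER
    pairs are ``centromeric`` when both paralog starts fall before
    ``centromeric_window``.
    """
    counts = {
        "input": len(pairs), "removed_base": 0, "removed_mito": 0,
        "removed_unplaced": 0, "removed_strict": 0, "retained": 0,
    }
    primary = set(primary_chroms) if primary_chroms is not None else None
    out: List[DupPair] = []
    for p in pairs:
        if p.length < base_min_len or p.divergence > base_max_div:
            counts["removed_base"] += 1
            continue
        if mito_chrom is not None and mito_chrom in (p.chrom_a, p.chrom_b):
            counts["removed_mito"] += 1
            continue
        if primary is not None and (p.chrom_a not in primary or p.chrom_b not in primary):
            counts["removed_unplaced"] += 1
            continue
        if p.length < min_len or p.divergence > max_div:
            counts["removed_strict"] += 1
            continue
        counts["retained"] += 1
        q = DupPair(
            p.chrom_a, p.start_a, p.end_a, p.chrom_b, p.start_b, p.end_b,
            p.length, p.divergence, p.orientation,
        )
        if q.chrom_a == q.chrom_b:
            q.placement = "INTRA"
            q.config = "TANDEM" if q.separation < tandem_sep else "DISPERSED"
        else:
            q.placement = "INTER"
            q.centromeric = q.start_a < centromeric_window and q.start_b < centromeric_window
        out.append(q)
    return out, counts


def _pct(numer: int, denom: int, decimals: int = 1) -> float:
    if denom == 0:
        return 0.0
    quant = Decimal(1).scaleb(-decimals)
    return float(Decimal(100 * numer / denom).quantize(quant, rounding=ROUND_HALF_UP))


def summarize_dup_pairs(
    pairs: Sequence[DupPair],
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> Dict[str, object]:
    """Counts and rounded percentages for classified duplication pairs.

    Sub-percentages round half-up to one decimal; the centromeric share is
    additionally reported at integer precision.  When ``chrom_sizes`` is
    given, the non-redundant merged-interval coverage fraction of the
    genome is included.
    """
    intra = [p for p in pairs if p.placement == "INTRA"]
    inter = [p for p in pairs if p.placement == "INTER"]
    tandem = [p for p in intra if p.config == "TANDEM"]
    dispersed = [p for p in intra if p.config == "DISPERSED"]
    centro = [p for p in inter if p.centromeric]
    total = len(intra) + len(inter)
    summary: Dict[str, object] = {
        "total_pairs": total,
        "intra_pairs": len(intra),
        "inter_pairs": len(inter),
        "tandem_pairs": len(tandem),
        "dispersed_pairs": len(dispersed),
        "centromeric_inter_pairs": len(centro),
        "intra_pct": _pct(len(intra), total),
        "tandem_pct_of_intra": _pct(len(tandem), len(intra)),
        "dispersed_pct_of_intra": _pct(len(dispersed), len(intra)),
        "centromeric_pct_of_inter": _pct(len(centro), len(inter)),
        "centromeric_pct_of_inter_int": _pct(len(centro), len(inter), decimals=0),
    }
    if chrom_sizes is not None:
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for p in pairs:
            by_chrom.setdefault(p.chrom_a, []).append((p.start_a, p.end_a))
            by_chrom.setdefault(p.chrom_b, []).append((p.start_b, p.end_b))
        covered = sum(
            interval_union_length(merge_intervals(iv)) for iv in by_chrom.values()
        )
        summary["nonredundant_coverage_fraction"] = covered / sum(chrom_sizes.values())
    return summary


def alignment_identities(aln: AlignmentRecord) -> Tuple[float, float]:
    """Gap-excluded and gap-compressed identity of one alignment.

    Gap-excluded identity ignores indels entirely; gap-compressed identity
    counts each maximal run of insertion/deletion operations as a single
    difference.  Requires a resolved CIGAR (``=``/``X``, or ``M`` plus an
    edit distance to apportion mismatches).
    """
    if not aln.cigar:
        raise ValueError("alignment has no CIGAR")
    matches = sum(n for op, n in aln.cigar if op == "=")
    mismatches = sum(n for op, n in aln.cigar if op == "X")
    m_bases = sum(n for op, n in aln.cigar if op == "M")
    indel_bases = sum(n for op, n in aln.cigar if op in ("I", "D"))
    if m_bases:
        if aln.edit_distance is None:
            raise ValueError("M-only CIGAR requires an edit distance to derive mismatches")
        mm = aln.edit_distance - indel_bases
        if mm < 0 or mm > m_bases:
            raise ValueError("edit distance inconsistent with CIGAR")
        mismatches += mm
        matches += m_bases - mm
    gap_events = 0
    in_gap = False
    for op, _n in aln.cigar:
        if op in ("I", "D"):
            if not in_gap:
                gap_events += 1
                in_gap = True
        else:
            in_gap = False
    aligned = matches + mismatches
    if aligned == 0:
        raise ValueError("alignment has no aligned bases")
    gap_excluded = matches / aligned
    gap_compressed = matches / (aligned + gap_events)
    return gap_excluded, gap_compressed
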