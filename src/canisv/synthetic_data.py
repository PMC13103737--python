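"""Synthetic canine-like cohort generator.

Builds a small multi-chromosome reference, a repeat library (a SINEC-like
consensus with an internal (CT)N run and A-tail, a full-length LINE-1-like
consensus with two designed ORFs, an LTR unit, a satellite unit), and five
diploid samples related by a fixed labeled genealogy with one deep
wolf-like outgroup branch.  Mobile-element insertions, tandem-repeat
indels, deletions, nested alleles and 3' transductions are planted on
genealogy branches with known truth, then emitted as reference + haplotype
FASTA, a pangenome-style VCF, RepeatMasker-format truth annotations, a
duplication-pair table and a truth JSON, so every downstream stage of the
pipeline is testable without external data.

The genealogy is a fixed 5-sample tree.  Branch lengths are in
generations; every haplotype sits 10,000 generations from the dog/wolf
common ancestor.  The NGSD-like sample has a very recent haplotype
coalescence (50 generations), emulating strong inbreeding, so its planted
insertions are overwhelmingly homozygous.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
from Bio.Seq import Seq

from .io_formats import (
    AnnotationSet,
    RepeatAnnotation,
    VariantRecord,
    VariantSet,
    write_fasta,
    write_pangenome_vcf,
    write_repeatmasker_out,
)
from .repeat_annotation import revcomp

# ---------------------------------------------------------------------------
# Genealogy: node -> (parent, branch length in generations)
# ---------------------------------------------------------------------------

TREE: Dict[str, Tuple[Optional[str], int]] = {
    "root": (None, 0),
    "wolfAnc": ("root", 9000),
    "GWsim.1": ("wolfAnc", 1000),
    "GWsim.2": ("wolfAnc", 1000),
    "dogAnc": ("root", 7000),
    "cladeA": ("dogAnc", 1000),
    "cladeB": ("dogAnc", 1000),
    "ACDanc": ("cladeA", 1200),
    "CCanc": ("cladeA", 1200),
    "SHanc": ("cladeB", 1200),
    "NGSDanc": ("cladeB", 1950),
    "ACDsim.1": ("ACDanc", 800),
    "ACDsim.2": ("ACDanc", 800),
    "CCsim.1": ("CCanc", 800),
    "CCsim.2": ("CCanc", 800),
    "SHsim.1": ("SHanc", 800),
    "SHsim.2": ("SHanc", 800),
    "NGSDsim.1": ("NGSDanc", 50),
    "NGSDsim.2": ("NGSDanc", 50),
}

SAMPLES = ["ACDsim", "CCsim", "SHsim", "NGSDsim", "GWsim"]
HAPLOTYPES = [f"{s}.{h}" for s in SAMPLES for h in (1, 2)]
REFERENCE_SAMPLE = "REFsim"


def children_of(node: str) -> List[str]:
    return [n for n, (p, _) in TREE.items() if p == node]


def leaves_below(node: str) -> List[str]:
    if node in HAPLOTYPES:
        return [node]
    out: List[str] = []
    for c in children_of(node):
        out.extend(leaves_below(c))
    return out


def branch_nodes() -> List[str]:
    """Nodes with a parent (each identifies the branch above it)."""
    return [n for n, (p, _) in TREE.items() if p is not None]


def subtree_nodes(node: str) -> List[str]:
    out = [node]
    for c in children_of(node):
        out.extend(subtree_nodes(c))
    return out


# ---------------------------------------------------------------------------
# Repeat library
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _random_orf(rng: np.random.Generator, n_codons: int, stop: str = "TAA") -> str:
    body = "".join(rng.choice(_CODONS, size=n_codons - 2))
    return "ATG" + body + stop


@dataclass
class RepeatLibrary:
    """Consensus repeat set emulating the canonical canine repeat families."""

    sinec_consensus: str
    line1_consensus: str
    ltr_unit: str
    satellite_unit: str
    other_unit: str
    protein_orf1: str
    protein_orf2: str
    orf1_span: Tuple[int, int]  # on line1_consensus, 0-based half-open
    orf2_span: Tuple[int, int]

    def consensi(self) -> Dict[str, Tuple[str, str]]:
        return {
            "SINEC_sim": (self.sinec_consensus, "SINE/tRNA-Lys"),
            "L1_sim": (self.line1_consensus, "LINE/L1"),
            "LTR_sim": (self.ltr_unit, "LTR/ERV"),
            "SAT_sim": (self.satellite_unit, "Satellite"),
            "DNA_sim": (self.other_unit, "DNA/hAT"),
        }


def build_repeat_library(seed: int) -> RepeatLibrary:
    """Deterministically build the consensus library for a seed.

    The LINE-1 consensus carries two designed non-overlapping ORFs (the
    second, reverse-transcriptase-like, is ~1300 codons) and a 3' AATAAA
    polyadenylation signal; the SINEC consensus carries a (CT)10 internal
    run and an 18 bp A tail.
    """
    rng = np.random.default_rng(seed)
    head = _random_seq(rng, 80).replace("CT", "CA")  # keep the designed CT run maximal
    core = _random_seq(rng, 70).replace("CT", "GT")
    sinec = head + "CT" * 10 + core + "A" * 18

    utr5 = _random_seq(rng, 300)
    orf1 = _random_orf(rng, 345, stop="TGA")
    spacer = _random_seq(rng, 66)
    orf2 = _random_orf(rng, 1300, stop="TAA")
    utr3 = _random_seq(rng, 144) + "AATAAA"
    line1 = utr5 + orf1 + spacer + orf2 + utr3
    orf1_span = (len(utr5), len(utr5) + len(orf1))
    orf2_span = (orf1_span[1] + len(spacer), orf1_span[1] + len(spacer) + len(orf2))

    ltr = _random_seq(rng, 450)
    sat = _random_seq(rng, 120)
    other = _random_seq(rng, 300)
    prot1 = str(Seq(orf1).translate())[:-1]
    prot2 = str(Seq(orf2).translate())[:-1]
    return RepeatLibrary(
        sinec_consensus=sinec,
        line1_consensus=line1,
        ltr_unit=ltr,
        satellite_unit=sat,
        other_unit=other,
        protein_orf1=prot1,
        protein_orf2=prot2,
        orf1_span=orf1_span,
        orf2_span=orf2_span,
    )


# ---------------------------------------------------------------------------
# Parameters and truth records
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Study conditions for the synthetic cohort.

    Rates are per haploid lineage per generation; ``snp_mu`` is the SNP
    mutation rate per bp per generation (the canine point estimate
    4.5e-9).  The desk-scale default genome is 2 chromosomes of 1 Mb.
    """

    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    sinec_rate: float = 0.02
    line1_rate: float = 0.002
    snp_mu: float = 4.5e-9
    p_full_line1: float = 0.5
    tsd_range: Tuple[int, int] = (5, 20)
    n_transductions: int = 24
    n_doomed_transductions: int = 2
    n_str: int = 25
    n_vntr: int = 15
    n_ltr: int = 10
    n_satellite: int = 8
    n_mixed: int = 8
    n_partial: int = 8
    n_unclassified: int = 8
    n_deletion: int = 15
    n_intra_l1_deletion: int = 6
    n_ref_sinec: int = 200
    n_ref_line1: int = 8
    n_dup_pairs: int = 20
    p_het: float = 0.25
    element_divergence: float = 0.01
    outgroup_hap: str = "GWsim.1"
    seed: int = 0


@dataclass
class TruthEvent:
    locus_id: str
    type: str  # SINEC, LINE1, LINE1+transduction, nested, STR, VNTR, LTR, satellite, mixed, partial, unclassified, deletion, intra_l1_deletion
    chrom: str
    pos: int  # 0-based anchor position (VCF POS - 1)
    branch: str
    carriers: List[str]
    tsd: str = ""
    strand: str = "+"
    truncation: int = 0  # 5' bases of the LINE-1 consensus missing
    transduction_source: Optional[str] = None  # source id, or None
    source_kind: Optional[str] = None  # "reference" | "segregating"
    expect_fail: Optional[str] = None  # planted to fail a named filter
    nested_branch: Optional[str] = None
    alleles_by_hap: Dict[str, str] = field(default_factory=dict)  # hap -> body (no anchor)
    ref_span: int = 0  # deleted bases for deletion-type events

    def distinct_bodies(self) -> List[str]:
        seen: List[str] = []
        for h in HAPLOTYPES:
            b = self.alleles_by_hap.get(h)
            if b is not None and b not in seen:
                seen.append(b)
        return seen


@dataclass
class DupTruth:
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    length: int
    divergence: float


@dataclass
class SimulatedCohort:
    reference: Dict[str, str]
    haplotypes: Dict[str, Dict[str, str]]  # hap -> chrom -> seq
    truth_events: List[TruthEvent]
    truth_snps: Dict[str, int]  # branch -> realized SNP count
    snp_positions: List[Tuple[str, int, str, str, str]]  # (chrom, pos, ref, alt, branch)
    ref_annotations: AnnotationSet
    dup_pairs: List[DupTruth]
    variant_set: VariantSet
    params: CohortParams
    library: RepeatLibrary
    tree: Dict[str, Tuple[Optional[str], int]] = field(default_factory=lambda: dict(TREE))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

class _SlotAllocator:
    """Places non-overlapping feature slots on the reference with spacing."""

    def __init__(self, rng: np.random.Generator, chrom_lengths: Dict[str, int], gap: int = 150):
        self.rng = rng
        self.lengths = chrom_lengths
        self.gap = gap
        self.occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_lengths}

    def alloc(self, length: int, chrom: Optional[str] = None, min_start: int = 50) -> Tuple[str, int]:
        chroms = list(self.lengths)
        for _ in range(4000):
            c = chrom if chrom is not None else chroms[int(self.rng.integers(len(chroms)))]
            limit = self.lengths[c] - length - self.gap
            if limit <= min_start:
                continue
            start = int(self.rng.integers(min_start, limit))
            lo, hi = start - self.gap, start + length + self.gap
            if all(e <= lo or s >= hi for s, e in self.occupied[c]):
                self.occupied[c].append((start, start + length))
                return c, start
        raise ValueError("genome too small to place requested events without overlap")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    n_mut = rng.poisson(rate * len(seq))
    if n_mut == 0:
        return seq
    arr = bytearray(seq.encode())
    positions = rng.choice(len(arr), size=min(n_mut, len(arr)), replace=False)
    for p in positions:
        cur = arr[p]
        choices = [b for b in b"ACGT" if b != cur]
        arr[p] = choices[int(rng.integers(3))]
    return arr.decode()


def _sinec_copy(rng: np.random.Generator, library: RepeatLibrary, divergence: float) -> str:
    """A SINEC copy with jittered CT-run and A-tail lengths plus substitutions."""
    cons = library.sinec_consensus
    head, tail = cons[:80], cons[100:]
    ct = "CT" * int(rng.integers(7, 14))
    body = head + ct + tail.rstrip("A") + "A" * int(rng.integers(10, 26))
    return _mutate(rng, body, divergence)


def _sinec_subtree_variant(rng: np.random.Generator, seq: str) -> str:
    """Post-insertion allelic change: substitutions and tail-length drift."""
    seq = _mutate(rng, seq, 0.005)
    stripped = seq.rstrip("A")
    n_a = len(seq) - len(stripped)
    if n_a >= 5:
        seq = stripped + "A" * max(4, n_a + int(rng.integers(-3, 4)))
    return seq


def _fix_frame_stops(insert: str, frame_offset: int) -> str:
    """Remove stop codons read in the host ORF frame through ``insert``.

    ``frame_offset`` is the position of the insert within the host codon
    (0, 1 or 2).  Used for the nested SINEC-in-ORF2 allele, which must keep
    the host reading frame open.
    """
    arr = bytearray(insert.encode())
    start = (3 - frame_offset) % 3
    for i in range(start, len(arr) - 2, 3):
        codon = arr[i : i + 3].decode()
        if codon in _STOPS:
            arr[i + 1] = ord("C")
    return arr.decode()


def simulate_cohort(library: RepeatLibrary, params: CohortParams) -> SimulatedCohort:
    """Plant events on the genealogy and build all haplotype sequences.

    Every event is carried by exactly the haplotypes below its branch.
    LINE-1 insertions draw a 5' truncation (full length with probability
    ``p_full_line1``); a configurable number of full-length LINE-1s carry
    3' transductions of downstream tag sequences from designated source
    elements, including one source that is itself a planted dimorphic
    element absent from the outgroup; one nested SINEC-inside-LINE-1 allele
    is planted.  Target-site duplications are drawn from ``tsd_range`` and
    duplicated on both flanks.
    """
    if params.sinec_rate < 0 or params.line1_rate < 0:
        raise ValueError("insertion rates must be >= 0")
    if len(params.chrom_lengths) < 2:
        raise ValueError("need at least 2 chromosomes")
    rng = np.random.default_rng(params.seed)
    reference = {c: _random_seq(rng, n) for c, n in params.chrom_lengths.items()}
    alloc = _SlotAllocator(rng, params.chrom_lengths)
    ref_arrays = {c: bytearray(s.encode()) for c, s in reference.items()}

    def overwrite(chrom: str, start: int, seq: str) -> None:
        ref_arrays[chrom][start : start + len(seq)] = seq.encode()

    # --- reference-fixed repeats --------------------------------------------
    ref_annotations: List[RepeatAnnotation] = []
    eid = 0
    ref_line1_spans: List[Tuple[str, int, int]] = []
    for _ in range(params.n_ref_sinec):
        copy = _sinec_copy(rng, library, 0.05)
        c, s = alloc.alloc(len(copy))
        overwrite(c, s, copy)
        eid += 1
        ref_annotations.append(
            RepeatAnnotation(c, s, s + len(copy), "SINEC_sim", "SINE/tRNA-Lys", "+", eid, 0, len(copy))
        )
    for _ in range(params.n_ref_line1):
        copy = _mutate(rng, library.line1_consensus, 0.03)
        c, s = alloc.alloc(len(copy) + 120)  # leave room for a downstream tag region
        overwrite(c, s, copy)
        eid += 1
        ref_annotations.append(
            RepeatAnnotation(c, s, s + len(copy), "L1_sim", "LINE/L1", "+", eid, 0, len(copy))
        )
        ref_line1_spans.append((c, s, s + len(copy)))
    # one satellite array (repetitive target for the excess-alignment filter)
    sat_array = library.satellite_unit * 10
    c_sat, s_sat = alloc.alloc(len(sat_array))
    overwrite(c_sat, s_sat, sat_array)
    eid += 1
    ref_annotations.append(
        RepeatAnnotation(
            c_sat, s_sat, s_sat + len(sat_array), "SAT_sim", "Satellite", "+", eid,
            0, len(library.satellite_unit),
        )
    )

    # --- duplication pairs (physically copied) -------------------------------
    dup_pairs: List[DupTruth] = []
    for i in range(params.n_dup_pairs):
        length = int(np.exp(rng.uniform(np.log(500), np.log(6000))))
        div = float(rng.uniform(0.0, 0.12))
        ca, sa = alloc.alloc(length)
        same_chrom = bool(rng.random() < 0.5)
        cb, sb = alloc.alloc(length, chrom=ca if same_chrom else None)
        src = ref_arrays[ca][sa : sa + length].decode()
        overwrite(cb, sb, _mutate(rng, src, div))
        dup_pairs.append(DupTruth(ca, sa, sa + length, cb, sb, sb + length, length, div))

    reference = {c: a.decode() for c, a in ref_arrays.items()}

    # --- branch-level event processes ----------------------------------------
    branches = branch_nodes()
    events: List[TruthEvent] = []
    locus_counter = [0]

    def next_id() -> str:
        locus_counter[0] += 1
        return f"L{locus_counter[0]:05d}"

    def draw_tsd(chrom: str, anchor: int) -> str:
        tlen = int(rng.integers(params.tsd_range[0], params.tsd_range[1] + 1))
        return reference[chrom][anchor - tlen + 1 : anchor + 1]

    def plant_insertion(etype: str, branch: str, body_builder, slot: int = 40, **kw) -> TruthEvent:
        chrom, start = alloc.alloc(slot, min_start=params.tsd_range[1] + 5)
        anchor = start + slot // 2
        tsd = draw_tsd(chrom, anchor)
        ev = TruthEvent(
            locus_id=next_id(), type=etype, chrom=chrom, pos=anchor, branch=branch,
            carriers=leaves_below(branch), tsd=tsd, **kw,
        )
        body_builder(ev)
        return ev

    def sinec_body(ev: TruthEvent) -> None:
        strand = "+" if rng.random() < 0.5 else "-"
        copy = _sinec_copy(rng, library, params.element_divergence)
        elem = copy if strand == "+" else revcomp(copy)
        ev.strand = strand
        base = elem + ev.tsd
        _assign_heterogeneous_alleles(ev, base, elem_len=len(elem))

    def _assign_heterogeneous_alleles(ev: TruthEvent, base_body: str, elem_len: int) -> None:
        """Walk the subtree below the event branch, drifting the element copy."""
        tail = base_body[elem_len:]

        def walk(node: str, elem_seq: str) -> None:
            kids = children_of(node)
            if not kids:
                ev.alleles_by_hap[node] = elem_seq + tail
                return
            for kid in kids:
                seq = elem_seq
                if rng.random() < params.p_het:
                    seq = _sinec_subtree_variant(rng, seq) if ev.type == "SINEC" else _mutate(rng, seq, 0.002)
                walk(kid, seq)

        walk(ev.branch, base_body[:elem_len])

    # SINEC / LINE-1 insertion processes
    for branch in branches:
        _, gens = TREE[branch]
        for _ in range(rng.poisson(params.sinec_rate * gens)):
            events.append(plant_insertion("SINEC", branch, sinec_body))

    line1_events: List[TruthEvent] = []

    def line1_body(ev: TruthEvent, force_full: bool = False, tag: str = "") -> None:
        cons = library.line1_consensus
        full = force_full or (rng.random() < params.p_full_line1)
        trunc = 0 if full else int(rng.integers(500, len(cons) - 1000))
        copy = _mutate(rng, cons[trunc:], params.element_divergence)
        strand = "+"
        polya = "A" * int(rng.integers(10, 26))
        elem = copy + tag + polya
        ev.strand = strand
        ev.truncation = trunc
        _assign_heterogeneous_alleles(ev, elem + ev.tsd, elem_len=len(copy))

    if params.line1_rate > 0:
        for branch in branches:
            _, gens = TREE[branch]
            for _ in range(rng.poisson(params.line1_rate * gens)):
                ev = plant_insertion("LINE1", branch, line1_body, slot=60)
                line1_events.append(ev)
                events.append(ev)

    # --- transduction sources and offspring ----------------------------------
    if params.line1_rate > 0 and params.n_transductions > 0:
        source_tags: Dict[str, Tuple[str, str, str, int]] = {}
        # (tag, kind, chrom, tag position)
        for i, (c, s, e) in enumerate(ref_line1_spans[:2]):
            tag = reference[c][e : e + 90]
            source_tags[f"refL1_{i}"] = (tag, "reference", c, e)

        def seg_source_body(ev: TruthEvent) -> None:
            line1_body(ev, force_full=True)

        seg_source = plant_insertion("LINE1", "cladeA", seg_source_body, slot=60)
        seg_source.type = "LINE1"
        events.append(seg_source)
        line1_events.append(seg_source)
        seg_tag = reference[seg_source.chrom][seg_source.pos + 1 : seg_source.pos + 91]
        source_tags[seg_source.locus_id] = (seg_tag, "segregating", seg_source.chrom, seg_source.pos + 1)

        source_ids = list(source_tags)
        seg_branches = [b for b in subtree_nodes("cladeA") if b != "cladeA"]
        for i in range(params.n_transductions):
            src = source_ids[i % len(source_ids)]
            tag, kind, tchrom, tpos = source_tags[src]
            branch = (
                seg_branches[int(rng.integers(len(seg_branches)))]
                if kind == "segregating"
                else branches[int(rng.integers(len(branches)))]
            )
            for _attempt in range(50):
                ev = plant_insertion(
                    "LINE1+transduction", branch,
                    lambda e: line1_body(e, force_full=True, tag=tag), slot=60,
                )
                if ev.chrom != tchrom or abs(ev.pos - tpos) > 8000:
                    break
            ev.transduction_source = src
            ev.source_kind = kind
            events.append(ev)
            line1_events.append(ev)
        # doomed transductions: tag drawn from the satellite array (repetitive)
        for _ in range(params.n_doomed_transductions):
            tag = library.satellite_unit[:80]
            branch = branches[int(rng.integers(len(branches)))]
            ev = plant_insertion(
                "LINE1+transduction", branch,
                lambda e: line1_body(e, force_full=True, tag=tag), slot=60,
            )
            ev.transduction_source = "satellite"
            ev.source_kind = "repetitive"
            ev.expect_fail = "masked_or_excess"
            events.append(ev)
            line1_events.append(ev)

        # --- nested SINEC-inside-LINE-1 (host on CCanc, nesting on CCsim.2) --
        def nested_body(ev: TruthEvent) -> None:
            cons = library.line1_consensus
            host = cons  # keep the host un-mutated so both ORFs stay intact
            polya = "A" * 18
            full_body = host + polya + ev.tsd
            ev.truncation = 0
            for hap in ev.carriers:
                ev.alleles_by_hap[hap] = full_body
            # nested SINEC into ORF2, opposite orientation, frame-preserving
            o2s, _o2e = library.orf2_span
            insert_at = o2s + 1200  # inside ORF2, between the designed domains
            s_copy = _sinec_copy(rng, library, params.element_divergence)
            s_tsd = host[insert_at - 8 : insert_at]
            insert = revcomp(s_copy) + s_tsd
            if len(insert) % 3:
                insert += "A" * (3 - len(insert) % 3)
            frame_offset = (insert_at - o2s) % 3
            insert = _fix_frame_stops(insert, frame_offset)
            nested_allele = host[:insert_at] + insert + host[insert_at:] + polya + ev.tsd
            for hap in leaves_below("CCsim.2"):
                ev.alleles_by_hap[hap] = nested_allele

        nested = plant_insertion("nested", "CCanc", nested_body, slot=60)
        nested.nested_branch = "CCsim.2"
        events.append(nested)
        line1_events.append(nested)

    # --- fixed-count accessory event classes ----------------------------------
    total_len = sum(TREE[b][1] for b in branches)
    weights = np.array([TREE[b][1] for b in branches], dtype=float) / total_len

    def random_branch() -> str:
        return branches[int(rng.choice(len(branches), p=weights))]

    def simple_insertion(etype: str, body: str) -> TruthEvent:
        def builder(ev: TruthEvent) -> None:
            full = body + ev.tsd
            for hap in ev.carriers:
                ev.alleles_by_hap[hap] = full

        return plant_insertion(etype, random_branch(), builder)

    def tandem_body(unit_len_range: Tuple[int, int], span_range: Tuple[int, int]) -> str:
        while True:
            ulen = int(rng.integers(unit_len_range[0], unit_len_range[1] + 1))
            unit = _random_seq(rng, ulen)
            if (unit + unit).find(unit, 1) == len(unit):
                break
        span = int(rng.integers(span_range[0], span_range[1] + 1))
        return (unit * (span // ulen + 1))[:span]

    for _ in range(params.n_str):
        events.append(simple_insertion("STR", tandem_body((1, 6), (60, 150))))
    for _ in range(params.n_vntr):
        events.append(simple_insertion("VNTR", tandem_body((8, 12), (150, 400))))
    for _ in range(params.n_ltr):
        events.append(simple_insertion("LTR", _mutate(rng, library.ltr_unit, params.element_divergence)))
    for _ in range(params.n_satellite):
        events.append(
            simple_insertion("satellite", _mutate(rng, library.satellite_unit * 3, params.element_divergence))
        )
    for _ in range(params.n_mixed):
        frag1 = library.sinec_consensus[:120]
        frag2 = library.ltr_unit[:100]
        glue = _random_seq(rng, 50)
        events.append(simple_insertion("mixed", _mutate(rng, frag1 + glue + frag2, 0.01)))
    for _ in range(params.n_partial):
        frag = library.sinec_consensus[:60]
        events.append(simple_insertion("partial", _mutate(rng, frag + _random_seq(rng, 140), 0.01)))
    for _ in range(params.n_unclassified):
        events.append(simple_insertion("unclassified", _random_seq(rng, int(rng.integers(80, 200)))))

    # plain deletions of reference backbone
    for _ in range(params.n_deletion):
        span = int(rng.integers(60, 301))
        chrom, start = alloc.alloc(span + 10, min_start=60)
        ev = TruthEvent(
            locus_id=next_id(), type="deletion", chrom=chrom, pos=start, branch=random_branch(),
            carriers=[], ref_span=span,
        )
        ev.carriers = leaves_below(ev.branch)
        events.append(ev)

    # intra-LINE-1 deletions: interior chunks of reference-fixed LINE-1s
    for i in range(params.n_intra_l1_deletion):
        c, s, e = ref_line1_spans[i % len(ref_line1_spans)]
        span = int(rng.integers(300, 801))
        offset = int(rng.integers(400, (e - s) - span - 250))
        ev = TruthEvent(
            locus_id=next_id(), type="intra_l1_deletion", chrom=c, pos=s + offset - 1,
            branch=random_branch(), carriers=[], ref_span=span,
        )
        ev.carriers = leaves_below(ev.branch)
        events.append(ev)

    # --- SNPs -----------------------------------------------------------------
    genome_len = sum(params.chrom_lengths.values())
    chroms = list(params.chrom_lengths)
    chrom_offsets = np.cumsum([0] + [params.chrom_lengths[c] for c in chroms])
    forbidden: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    for ev in events:
        if ev.ref_span:
            forbidden[ev.chrom].append((ev.pos - 2, ev.pos + ev.ref_span + 2))
        else:
            forbidden[ev.chrom].append((ev.pos - params.tsd_range[1] - 2, ev.pos + 2))

    def is_forbidden(chrom: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in forbidden[chrom])

    truth_snps: Dict[str, int] = {}
    snp_positions: List[Tuple[str, int, str, str, str]] = []
    used: set = set()
    for branch in branches:
        _, gens = TREE[branch]
        count = rng.poisson(params.snp_mu * gens * genome_len)
        truth_snps[branch] = int(count)
        placed = 0
        while placed < count:
            g = int(rng.integers(genome_len))
            ci = int(np.searchsorted(chrom_offsets, g, side="right") - 1)
            chrom, pos = chroms[ci], g - int(chrom_offsets[ci])
            if (chrom, pos) in used or is_forbidden(chrom, pos):
                continue
            used.add((chrom, pos))
            ref_base = reference[chrom][pos]
            alt = "ACGT"[int(rng.integers(4))]
            while alt == ref_base:
                alt = "ACGT"[int(rng.integers(4))]
            snp_positions.append((chrom, pos, ref_base, alt, branch))
            placed += 1

    # --- build haplotype sequences -------------------------------------------
    haplotypes: Dict[str, Dict[str, str]] = {}
    snps_by_branch: Dict[str, List[Tuple[str, int, str]]] = {}
    for chrom, pos, _r, alt, branch in snp_positions:
        snps_by_branch.setdefault(branch, []).append((chrom, pos, alt))

    for hap in HAPLOTYPES:
        # collect branches on this haplotype's path to the root
        path = []
        node = hap
        while node is not None:
            path.append(node)
            node = TREE[node][0]
        path_set = set(path)
        edits: Dict[str, List[Tuple[int, int, str]]] = {c: [] for c in chroms}
        for ev in events:
            if hap not in ev.carriers:
                continue
            if ev.ref_span:
                edits[ev.chrom].append((ev.pos + 1, ev.pos + 1 + ev.ref_span, ""))
            else:
                body = ev.alleles_by_hap[hap]
                edits[ev.chrom].append((ev.pos + 1, ev.pos + 1, body))
        for branch, snps in snps_by_branch.items():
            if branch in path_set:
                for chrom, pos, alt in snps:
                    edits[chrom].append((pos, pos + 1, alt))
        seqs: Dict[str, str] = {}
        for chrom in chroms:
            ref = reference[chrom]
            pieces: List[str] = []
            cursor = 0
            for start, end, repl in sorted(edits[chrom]):
                pieces.append(ref[cursor:start])
                pieces.append(repl)
                cursor = end
            pieces.append(ref[cursor:])
            seqs[chrom] = "".join(pieces)
        haplotypes[hap] = seqs

    # --- VCF ------------------------------------------------------------------
    records: List[VariantRecord] = []
    for ev in events:
        if ev.ref_span:
            anchor = reference[ev.chrom][ev.pos]
            ref_allele = reference[ev.chrom][ev.pos : ev.pos + ev.ref_span + 1]
            alts = [anchor]
            alleles = [ref_allele] + alts
            body_of = {h: anchor if h in ev.carriers else ref_allele for h in HAPLOTYPES}
        else:
            anchor = reference[ev.chrom][ev.pos]
            bodies = ev.distinct_bodies()
            alts = [anchor + b for b in bodies]
            alleles = [anchor] + alts
            body_of = {
                h: (anchor + ev.alleles_by_hap[h]) if h in ev.carriers else anchor
                for h in HAPLOTYPES
            }
        rec = VariantRecord(
            chrom=ev.chrom, pos=ev.pos, ref_allele=alleles[0],
            alt_alleles=list(alleles[1:]), record_id=ev.locus_id,
        )
        for sample in SAMPLES:
            for h in (1, 2):
                rec.allele_of[(sample, h)] = alleles.index(body_of[f"{sample}.{h}"])
        rec.allele_of[(REFERENCE_SAMPLE, 1)] = 0
        rec.allele_of[(REFERENCE_SAMPLE, 2)] = 0
        records.append(rec)
    for chrom, pos, ref_base, alt, branch in snp_positions:
        carriers = set(leaves_below(branch))
        rec = VariantRecord(chrom=chrom, pos=pos, ref_allele=ref_base, alt_alleles=[alt])
        for sample in SAMPLES:
            for h in (1, 2):
                rec.allele_of[(sample, h)] = 1 if f"{sample}.{h}" in carriers else 0
        rec.allele_of[(REFERENCE_SAMPLE, 1)] = 0
        rec.allele_of[(REFERENCE_SAMPLE, 2)] = 0
        records.append(rec)
    records.sort(key=lambda r: (chroms.index(r.chrom), r.pos))
    vset = VariantSet(
        records=records, samples=list(SAMPLES), reference_sample=REFERENCE_SAMPLE,
        contigs=dict(params.chrom_lengths),
    )

    return SimulatedCohort(
        reference=reference,
        haplotypes=haplotypes,
        truth_events=events,
        truth_snps=truth_snps,
        snp_positions=snp_positions,
        ref_annotations=AnnotationSet(ref_annotations),
        dup_pairs=dup_pairs,
        variant_set=vset,
        params=params,
        library=library,
    )


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def emit_cohort(cohort: SimulatedCohort, outdir: str) -> Dict[str, str]:
    """Write the cohort to ``outdir``; returns a name → path map.

    Emits reference FASTA, haplotype FASTA, a pangenome-style VCF (anchor
    base included in insertion alleles; the empty site is exactly 1 bp),
    RepeatMasker-format truth annotations for the reference and for every
    distinct locus allele, an allele FASTA, a duplication-pair table and a
    truth JSON.  Byte-identical for identical cohorts.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "reference_fasta": os.path.join(outdir, "reference.fa"),
        "haplotypes_fasta": os.path.join(outdir, "haplotypes.fa"),
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "reference_out": os.path.join(outdir, "reference.out"),
        "alleles_out": os.path.join(outdir, "alleles.out"),
        "alleles_fasta": os.path.join(outdir, "alleles.fa"),
        "dup_pairs": os.path.join(outdir, "dup_pairs.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_fasta(cohort.reference, paths["reference_fasta"])
    hap_seqs = {
        f"{hap}#{chrom}": seq
        for hap, seqs in cohort.haplotypes.items()
        for chrom, seq in seqs.items()
    }
    write_fasta(hap_seqs, paths["haplotypes_fasta"])
    write_pangenome_vcf(cohort.variant_set, paths["vcf"])
    write_repeatmasker_out(cohort.ref_annotations, paths["reference_out"])

    allele_annots: List[RepeatAnnotation] = []
    allele_seqs: Dict[str, str] = {}
    lib = cohort.library
    type_to_name = {
        "SINEC": ("SINEC_sim", "SINE/tRNA-Lys"),
        "LINE1": ("L1_sim", "LINE/L1"),
        "LINE1+transduction": ("L1_sim", "LINE/L1"),
        "nested": ("L1_sim", "LINE/L1"),
        "LTR": ("LTR_sim", "LTR/ERV"),
        "satellite": ("SAT_sim", "Satellite"),
    }
    eid = 0
    for ev in cohort.truth_events:
        for i, body in enumerate(ev.distinct_bodies()):
            sid = f"{ev.locus_id}|a{i + 1}"
            allele_seqs[sid] = body
            if ev.type in type_to_name:
                name, rclass = type_to_name[ev.type]
                cons_len = {
                    "SINEC_sim": len(lib.sinec_consensus),
                    "L1_sim": len(lib.line1_consensus),
                    "LTR_sim": len(lib.ltr_unit),
                    "SAT_sim": len(lib.satellite_unit),
                }[name]
                elem_len = len(body) - len(ev.tsd)
                eid += 1
                allele_annots.append(
                    RepeatAnnotation(
                        sid, 0, max(1, elem_len), name, rclass, ev.strand, eid,
                        cons_start=ev.truncation, cons_end=cons_len,
                    )
                )
    write_repeatmasker_out(AnnotationSet(allele_annots), paths["alleles_out"])
    write_fasta(allele_seqs, paths["alleles_fasta"])

    with open(paths["dup_pairs"], "w") as fh:
        fh.write("#chrA\tstartA\tendA\tchrB\tstartB\tendB\tlength\tdivergence\n")
        for d in cohort.dup_pairs:
            fh.write(
                f"{d.chrom_a}\t{d.start_a}\t{d.end_a}\t{d.chrom_b}\t{d.start_b}\t"
                f"{d.end_b}\t{d.length}\t{d.divergence:.4f}\n"
            )

    truth = {
        "params": {
            **{k: v for k, v in asdict(cohort.params).items() if k != "chrom_lengths"},
            "chrom_lengths": dict(cohort.params.chrom_lengths),
        },
        "tree": {n: {"parent": p, "generations": g} for n, (p, g) in cohort.tree.items()},
        "truth_snps": cohort.truth_snps,
        "events": [
            {
                "locus_id": ev.locus_id,
                "type": ev.type,
                "chrom": ev.chrom,
                "pos": ev.pos,
                "branch": ev.branch,
                "carriers": ev.carriers,
                "tsd": ev.tsd,
                "strand": ev.strand,
                "truncation": ev.truncation,
                "transduction_source": ev.transduction_source,
                "source_kind": ev.source_kind,
                "expect_fail": ev.expect_fail,
                "nested_branch": ev.nested_branch,
                "ref_span": ev.ref_span,
                "n_distinct_alleles": len(ev.distinct_bodies()),
            }
            for ev in cohort.truth_events
        ],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
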