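"""Readers and writers for the standard formats the pipeline touches.

Everything is normalized to a single internal coordinate convention:
0-based, half-open intervals.  VCF ``POS`` (1-based) and RepeatMasker
begin/end (1-based, inclusive) are converted at the boundary, in both
directions, so that writing and re-reading is an involution.

Sequence alphabets are uppercased on read; ``N`` is allowed.  Soft-masking
is carried as annotations, never as case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

log = logging.getLogger(__name__)

#: Sentinel for a missing haplotype allele assignment.
MISSING = None

HapKey = Tuple[str, int]  # (sample name, haplotype index in {1, 2})


@dataclass
class VariantRecord:
    """One pangenome VCF site with per-haplotype allele assignments.

    ``pos`` is stored 0-based.  ``allele_of`` maps ``(sample, hap)`` with
    ``hap`` in {1, 2} to an index into ``[ref_allele] + alt_alleles``, or
    :data:`MISSING`.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: List[str]
    allele_of: Dict[HapKey, Optional[int]] = field(default_factory=dict)
    record_id: Optional[str] = None

    @property
    def alleles(self) -> List[str]:
        return [self.ref_allele] + list(self.alt_alleles)

    def allele_seq(self, sample: str, hap: int) -> Optional[str]:
        idx = self.allele_of.get((sample, hap), MISSING)
        return None if idx is MISSING else self.alleles[idx]


@dataclass
class VariantSet:
    """Parsed pangenome VCF: ordered records plus sample bookkeeping."""

    records: List[VariantRecord]
    samples: List[str]
    reference_sample: Optional[str] = None
    contigs: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class RepeatAnnotation:
    """A repeat interval in RepeatMasker terms, 0-based half-open.

    ``element_id`` is the RepeatMasker join ID: identical across fragments
    of one interrupted element.  ``cons_start``/``cons_end`` are matched
    consensus coordinates (0-based half-open) when known.
    """

    seq_id: str
    start: int
    end: int
    repeat_name: str
    repeat_class: str
    strand: str = "+"
    element_id: int = 0
    cons_start: Optional[int] = None
    cons_end: Optional[int] = None
    score: float = 0.0
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid annotation interval [{self.start},{self.end}) on {self.seq_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)


class AnnotationSet:
    """A collection of :class:`RepeatAnnotation` with per-sequence access."""

    def __init__(self, annotations: Sequence[RepeatAnnotation] = ()) -> None:
        self.annotations: List[RepeatAnnotation] = sorted(
            annotations, key=lambda a: (a.seq_id, a.start, a.end)
        )

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)

    def for_seq(self, seq_id: str) -> List[RepeatAnnotation]:
        return [a for a in self.annotations if a.seq_id == seq_id]

    def add(self, annotation: RepeatAnnotation) -> None:
        self.annotations.append(annotation)
        self.annotations.sort(key=lambda a: (a.seq_id, a.start, a.end))


@dataclass
class AlignmentRecord:
    """A pairwise alignment with resolved CIGAR.

    CIGAR operations are ``=``, ``X``, ``M``, ``I`` (insertion to target /
    extra query) and ``D`` (deletion from query / extra target).  Spans are
    0-based half-open on the original (+) strands.
    """

    query_id: str
    target_id: str
    query_span: Tuple[int, int]
    target_span: Tuple[int, int]
    strand: str = "+"
    cigar: List[Tuple[str, int]] = field(default_factory=list)
    edit_distance: Optional[int] = None
    score: float = 0.0

    def query_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in ("M", "=", "X", "I"))

    def target_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in ("M", "=", "X", "D"))

    def spans_consistent(self) -> bool:
        if not self.cigar:
            return True
        q = self.query_span[1] - self.query_span[0]
        t = self.target_span[1] - self.target_span[0]
        return self.query_consumed() == q and self.target_consumed() == t


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_pangenome_vcf(
    path: str,
    samples: Sequence[str],
    reference_sample: Optional[str] = None,
) -> VariantSet:
    """Read a multi-sample pangenome VCF into a :class:`VariantSet`.

    Diploid GT ``a|b`` maps haplotype 1 to ``a`` and haplotype 2 to ``b``;
    ``.`` yields :data:`MISSING` for both haplotypes.  Unphased ``a/b`` is
    accepted and treated as ordered, with a warning (haplotype-resolved
    inputs are inherently phased).  Multiallelic sites are kept unsplit.
    """
    vf = pysam.VariantFile(path)
    header_samples = list(vf.header.samples)
    wanted = list(samples)
    if reference_sample is not None and reference_sample in header_samples:
        wanted_all = wanted + [reference_sample]
    else:
        wanted_all = wanted
    for s in wanted_all:
        if s not in header_samples:
            raise ValueError(f"sample {s!r} not present in VCF {path}")

    contigs = {name: c.length or 0 for name, c in vf.header.contigs.items()}
    records: List[VariantRecord] = []
    warned_unphased = False
    for line_no, rec in enumerate(vf, start=1):
        if rec.alts is None:
            alts: List[str] = []
        else:
            alts = [a.upper() for a in rec.alts]
        vr = VariantRecord(
            chrom=rec.chrom,
            pos=rec.start,
            ref_allele=rec.ref.upper(),
            alt_alleles=alts,
            record_id=rec.id,
        )
        for s in wanted_all:
            call = rec.samples[s]
            try:
                gt = call["GT"]
            except KeyError as exc:  # pragma: no cover - malformed input
                raise ValueError(f"malformed GT for sample {s} at record {line_no}") from exc
            if gt is None:
                gt = (None, None)
            if not call.phased and any(a is not None for a in gt) and not warned_unphased:
                log.warning("unphased genotype encountered; treating allele order as haplotype order")
                warned_unphased = True
            hap1 = gt[0] if len(gt) >= 1 else None
            hap2 = gt[1] if len(gt) >= 2 else None
            n_alleles = 1 + len(alts)
            for hap, a in ((1, hap1), (2, hap2)):
                if a is not None and not (0 <= a < n_alleles):
                    raise ValueError(
                        f"allele index {a} out of range at {rec.chrom}:{rec.pos} sample {s}"
                    )
                vr.allele_of[(s, hap)] = a
        records.append(vr)
    vf.close()
    return VariantSet(
        records=records,
        samples=wanted,
        reference_sample=reference_sample,
        contigs=contigs,
    )


def write_pangenome_vcf(vset: VariantSet, path: str) -> None:
    """Write a :class:`VariantSet` as phased VCF 4.2 (round-trips with the reader)."""
    header = pysam.VariantHeader()
    for name, length in vset.contigs.items():
        if length:
            header.contigs.add(name, length=length)
        else:
            header.contigs.add(name)
    # Contigs referenced by records but absent from the contig map.
    for rec in vset.records:
        if rec.chrom not in header.contigs:
            header.contigs.add(rec.chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    all_samples = list(vset.samples)
    if vset.reference_sample is not None and vset.reference_sample not in all_samples:
        all_samples.append(vset.reference_sample)
    for s in all_samples:
        header.add_sample(s)
    out = pysam.VariantFile(path, "w", header=header)
    for rec in vset.records:
        vrec = out.new_record(
            contig=rec.chrom,
            start=rec.pos,
            alleles=tuple([rec.ref_allele] + rec.alt_alleles),
            id=rec.record_id,
        )
        for s in all_samples:
            gt = (rec.allele_of.get((s, 1)), rec.allele_of.get((s, 2)))
            vrec.samples[s]["GT"] = gt
            vrec.samples[s].phased = True
        out.write(vrec)
    out.close()


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW   perc perc perc  query     position in query              matching"
    "       repeat           position in repeat\n"
    "score   div. del. ins.  sequence  begin  end          (left)    repeat"
    "         class/family     begin  end    (left)   ID\n"
    "\n"
)


def read_repeatmasker_out(path: str) -> AnnotationSet:
    """Parse a RepeatMasker ``.out`` table into an :class:`AnnotationSet`.

    Query coordinates (1-based inclusive) convert to 0-based half-open;
    strand ``C`` is stored as ``-``.  For ``C`` rows the consensus begin
    column holds ``(left)`` and the last repeat column holds the begin.
    """
    annotations: List[RepeatAnnotation] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line_no <= 3 or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 14:
                raise ValueError(f"{path}:{line_no}: unparsable RepeatMasker row")
            try:
                score = float(fields[0])
                div = float(fields[1])
                seq_id = fields[4]
                qbegin = int(fields[5])
                qend = int(fields[6])
                strand_raw = fields[8]
                name = fields[9]
                rclass = fields[10]
                r1, r2, r3 = fields[11], fields[12], fields[13]
                element_id = int(fields[14]) if len(fields) > 14 else 0
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{line_no}: unparsable RepeatMasker row") from exc
            if qend < qbegin:
                raise ValueError(f"{path}:{line_no}: end {qend} < begin {qbegin}")
            if strand_raw == "+":
                strand = "+"
                cons_start, cons_end = int(r1) - 1, int(r2)
            elif strand_raw in ("C", "-"):
                strand = "-"
                cons_start, cons_end = int(r3) - 1, int(r2)
            else:
                raise ValueError(f"{path}:{line_no}: bad strand {strand_raw!r}")
            annotations.append(
                RepeatAnnotation(
                    seq_id=seq_id,
                    start=qbegin - 1,
                    end=qend,
                    repeat_name=name,
                    repeat_class=rclass,
                    strand=strand,
                    element_id=element_id,
                    cons_start=cons_start,
                    cons_end=cons_end,
                    score=score,
                    divergence=div,
                )
            )
    return AnnotationSet(annotations)


def write_repeatmasker_out(annots: AnnotationSet, path: str) -> None:
    """Write annotations in RepeatMasker ``.out`` layout (round-trips with the reader)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for a in annots:
            cons_start = (a.cons_start if a.cons_start is not None else 0) + 1
            cons_end = a.cons_end if a.cons_end is not None else a.length
            if a.strand == "+":
                strand = "+"
                rcols = (str(cons_start), str(cons_end), "(0)")
            else:
                strand = "C"
                rcols = ("(0)", str(cons_end), str(cons_start))
            fh.write(
                f"{a.score:7.0f} {a.divergence:5.1f}  0.0  0.0  {a.seq_id}  "
                f"{a.start + 1}  {a.end}  (0)  {strand}  {a.repeat_name}  "
                f"{a.repeat_class}  {rcols[0]}  {rcols[1]}  {rcols[2]}  {a.element_id}\n"
            )


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------

_CIGAR_OPS = set("MIDNSHP=X")


def parse_cigar(cg: str) -> List[Tuple[str, int]]:
    """Parse a CIGAR string like ``50M5I45M`` into op/length pairs."""
    ops: List[Tuple[str, int]] = []
    num = ""
    for ch in cg:
        if ch.isdigit():
            num += ch
        elif ch in _CIGAR_OPS:
            if not num:
                raise ValueError(f"malformed CIGAR {cg!r}")
            ops.append((ch, int(num)))
            num = ""
        else:
            raise ValueError(f"bad CIGAR character {ch!r} in {cg!r}")
    if num:
        raise ValueError(f"trailing number in CIGAR {cg!r}")
    return ops


def cigar_to_string(cigar: Sequence[Tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def read_alignments_paf(path: str) -> List[AlignmentRecord]:
    """Read PAF alignments (with optional ``cg:Z`` and ``NM:i`` tags).

    Records whose CIGAR does not account for the stated query/target spans
    are skipped with a logged warning.  Records without a ``cg`` tag are
    kept with an empty CIGAR.
    """
    records: List[AlignmentRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{line_no}: PAF line has fewer than 12 columns")
            qname, _qlen, qstart, qend = fields[0], fields[1], int(fields[2]), int(fields[3])
            strand = fields[4]
            tname, _tlen, tstart, tend = fields[5], fields[6], int(fields[7]), int(fields[8])
            nmatch = int(fields[9])
            cigar: List[Tuple[str, int]] = []
            edit_distance = None
            for tag in fields[12:]:
                if tag.startswith("cg:Z:"):
                    cigar = parse_cigar(tag[5:])
                elif tag.startswith("NM:i:"):
                    edit_distance = int(tag[5:])
            rec = AlignmentRecord(
                query_id=qname,
                target_id=tname,
                query_span=(qstart, qend),
                target_span=(tstart, tend),
                strand=strand,
                cigar=cigar,
                edit_distance=edit_distance,
                score=float(nmatch),
            )
            if not rec.spans_consistent():
                n_skipped += 1
                log.warning("%s:%d: CIGAR/span mismatch, record skipped", path, line_no)
                continue
            records.append(rec)
    if n_skipped:
        log.warning("%s: skipped %d PAF records with inconsistent CIGARs", path, n_skipped)
    return records


# ---------------------------------------------------------------------------
# FASTA helpers
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> Dict[str, str]:
    """Read a FASTA file into an ordered name → uppercase sequence map."""
    seqs: Dict[str, str] = {}
    name = None
    chunks: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks).upper()
    return seqs


def write_fasta(seqs: Dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
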