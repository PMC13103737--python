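"""Sequence-composition machinery.

Four primitives feed the structural-variant classifier:

* :func:`sdust_mask` — symmetric DUST low-complexity masking.  The score of
  a window is the triplet-collision count ``sum c_t(c_t-1)/2`` divided by
  ``l - 1`` where ``l`` is the number of triplets in the window; intervals
  of up to ``window`` bp whose score exceeds ``threshold / 10`` and that are
  *perfect* (no proper subinterval scores strictly higher) are reported,
  merged.  Masking is symmetric: the result depends only on the interval
  content, never on flanking context.
* :func:`find_exact_tandem_repeats` — maximal exact tandem runs per period.
* :func:`merge_repeat_annotations` — RepeatMasker fragment joining,
  including absorption of (CT)n-type microsatellite annotations into the
  surrounding SINEC (SINECs carry an internal CT run of variable length
  that RepeatMasker tends to call out separately).
* :func:`annotate_with_library` — a lightweight consensus-library
  annotator (k-mer anchoring + edit-distance refinement) used where no
  external RepeatMasker output is supplied.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

import edlib
import numpy as np

from .io_formats import AnnotationSet, RepeatAnnotation

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class MaskedInterval:
    """A low-complexity interval, 0-based half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty masked interval [{self.start},{self.end})")


@dataclass
class TandemRepeatRun:
    """A maximal exact tandem run.

    ``unit`` is the phase-aligned motif (``seq[start:start+unit_length]``),
    so the run reconstructs as ``unit`` repeated with a possibly partial
    final copy.  ``canonical_unit`` gives the lexicographically smallest
    rotation, for phase-independent comparisons.  ``copies`` counts whole
    copies only.
    """

    start: int
    end: int
    unit: str
    unit_length: int
    copies: int

    @property
    def canonical_unit(self) -> str:
        u = self.unit
        return min(u[i:] + u[:i] for i in range(len(u)))

    @property
    def span(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Symmetric DUST
# ---------------------------------------------------------------------------

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(f):
            return f

        return deco(args[0]) if args and callable(args[0]) else deco


@njit(cache=True)
def _sdust_segment(trip: np.ndarray, window: int, thr10: float, delta: np.ndarray, offset: int) -> None:
    """Accumulate perfect-interval coverage deltas for one clean segment.

    ``trip`` holds triplet codes for a segment free of non-ACGT characters
    (length ``n - 2`` for a segment of ``n`` bases).  Perfect intervals
    ``[i, j)`` (4 <= j-i <= window) add +1 at ``delta[offset+i]`` and -1 at
    ``delta[offset+j]``.
    """
    n = trip.shape[0] + 2  # segment length in bases
    NEG = -1e30
    prev = np.full(n + 1, NEG)  # prev[j] = best subinterval score within [i+1, j)
    cur = np.full(n + 1, NEG)
    counts = np.zeros(64, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        jmax = min(i + window, n)
        for j in range(i, min(i + 4, jmax + 1)):
            cur[j] = NEG
        if i + 4 <= jmax:
            counts[:] = 0
            raw = 0
            # seed with triplets of [i, i+3): exactly one triplet (at i)
            counts[trip[i]] = 1
            for j in range(i + 4, jmax + 1):
                t = trip[j - 3]
                raw += counts[t]
                counts[t] += 1
                den = j - i - 3  # (number of triplets) - 1
                score = raw / den
                best_sub = prev[j] if prev[j] > cur[j - 1] else cur[j - 1]
                if score >= best_sub and score > thr10:
                    delta[offset + i] += 1
                    delta[offset + j] -= 1
                cur[j] = score if score > best_sub else best_sub
        tmp = prev
        prev = cur
        cur = tmp


def sdust_mask(seq: str, window: int = 64, threshold: int = 20) -> List[MaskedInterval]:
    """Mask low-complexity sequence with the symmetric DUST algorithm.

    Returns the union of all perfect intervals scoring above
    ``threshold / 10``, merged into sorted, non-overlapping intervals.
    Non-ACGT characters break triplets: no reported interval spans them.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    n = len(seq)
    if n < 4:
        return []
    codes = _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    delta = np.zeros(n + 1, dtype=np.int64)
    # split into runs of ACGT
    valid = codes >= 0
    boundaries = np.flatnonzero(np.diff(np.concatenate(([0], valid.view(np.int8), [0]))))
    for s, e in zip(boundaries[::2], boundaries[1::2]):
        if e - s < 4:
            continue
        seg = codes[s:e]
        trip = seg[:-2] * 16 + seg[1:-1] * 4 + seg[2:]
        _sdust_segment(trip, window, threshold / 10.0, delta, s)
    cov = np.cumsum(delta[:-1])
    masked = cov > 0
    edges = np.flatnonzero(np.diff(np.concatenate(([0], masked.view(np.int8), [0]))))
    return [MaskedInterval(int(a), int(b)) for a, b in zip(edges[::2], edges[1::2])]


# ---------------------------------------------------------------------------
# Exact tandem repeats
# ---------------------------------------------------------------------------

def _is_primitive(unit: str) -> bool:
    return (unit + unit).find(unit, 1) == len(unit)


def find_exact_tandem_repeats(
    seq: str,
    max_unit: Optional[int] = 6,
    min_copies: int = 2,
    min_span: int = 4,
) -> List[TandemRepeatRun]:
    """Find maximal exact tandem runs with unit length up to ``max_unit``.

    A run of period ``p`` is a maximal interval where ``seq[i] == seq[i-p]``
    throughout.  Only primitive motifs are reported (a homopolymer is a
    unit-1 run, never also a unit-2 run); overlapping runs of different
    periods are all reported.  ``max_unit=None`` removes the unit-length cap
    (used when annotating individual alleles rather than scanning genomes).
    """
    n = len(seq)
    if n < 2:
        return []
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    cap = max_unit if max_unit is not None else n // 2
    runs: List[TandemRepeatRun] = []
    for p in range(1, min(cap, n // 2) + 1):
        m = arr[p:] == arr[:-p]
        if not m.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], m.view(np.int8), [0]))))
        for a, b in zip(edges[::2], edges[1::2]):
            start = int(a)  # first matching position is seq index a+p; run begins at a
            end = int(b) + p
            span = end - start
            if span < min_span or span // p < min_copies:
                continue
            unit = seq[start : start + p].upper()
            if not _is_primitive(unit):
                continue
            runs.append(
                TandemRepeatRun(start=start, end=end, unit=unit, unit_length=p, copies=span // p)
            )
    runs.sort(key=lambda r: (r.start, r.unit_length))
    return runs


def interval_union_length(intervals: Iterable[Tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s >= last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def union_coverage(intervals: Iterable[Tuple[int, int]], length: int) -> float:
    """Fraction of ``[0, length)`` covered by the union of ``intervals``."""
    if length <= 0:
        raise ValueError("length must be positive")
    clipped = [(max(0, s), min(length, e)) for s, e in intervals if e > 0 and s < length]
    return interval_union_length(clipped) / length


# ---------------------------------------------------------------------------
# RepeatMasker fragment merging
# ---------------------------------------------------------------------------

_CT_NAMES = {"(CT)n", "(AG)n", "(TC)n", "(GA)n"}
_SIMPLE_CLASSES = {"Simple_repeat", "Low_complexity"}


def _is_simple(a: RepeatAnnotation) -> bool:
    return a.repeat_class in _SIMPLE_CLASSES


def _is_sinec(a: RepeatAnnotation) -> bool:
    return a.repeat_name.startswith("SINEC")


def merge_repeat_annotations(annots: AnnotationSet) -> AnnotationSet:
    """Join fragmented element annotations and absorb SINEC-internal runs.

    Fragments sharing an ``element_id`` and separated only by
    Simple_repeat/Low_complexity annotations merge into one interval
    spanning both (keeping the element's name and class); a (CT)n/(AG)n/
    (TC)n/(GA)n annotation strictly between two fragments of one SINEC, or
    inside a SINEC interval, is absorbed into the SINEC.  Idempotent.
    """
    out: List[RepeatAnnotation] = []
    by_seq: Dict[str, List[RepeatAnnotation]] = defaultdict(list)
    for a in annots:
        by_seq[a.seq_id].append(a)

    for seq_id, items in by_seq.items():
        items = sorted(items, key=lambda a: (a.start, a.end))
        elements: Dict[int, List[RepeatAnnotation]] = defaultdict(list)
        others: List[RepeatAnnotation] = []
        for a in items:
            if _is_simple(a) or a.element_id == 0:
                others.append(a)
            else:
                elements[a.element_id].append(a)

        merged_elements: List[RepeatAnnotation] = []
        consumed_simple: set = set()
        for eid, frags in elements.items():
            frags.sort(key=lambda a: a.start)
            classes: Dict[str, int] = defaultdict(int)
            for f in frags:
                classes[(f.repeat_name, f.repeat_class)] += f.length
            if len(classes) > 1:
                log.warning("element_id %s on %s has conflicting classes; keeping majority", eid, seq_id)
            name, rclass = max(classes, key=classes.get)
            groups: List[List[RepeatAnnotation]] = [[frags[0]]]
            for f in frags[1:]:
                gap_lo, gap_hi = groups[-1][-1].end, f.start
                between = [
                    o for o in items
                    if o is not f and o not in groups[-1]
                    and o.start < gap_hi and o.end > gap_lo
                    and not (o.element_id == eid and not _is_simple(o))
                ]
                if all(_is_simple(o) for o in between):
                    groups[-1].append(f)
                    consumed_simple.update(id(o) for o in between)
                else:
                    groups.append([f])
            for g in groups:
                cons_starts = [f.cons_start for f in g if f.cons_start is not None]
                cons_ends = [f.cons_end for f in g if f.cons_end is not None]
                merged_elements.append(
                    RepeatAnnotation(
                        seq_id=seq_id,
                        start=g[0].start,
                        end=max(f.end for f in g),
                        repeat_name=name,
                        repeat_class=rclass,
                        strand=g[0].strand,
                        element_id=eid,
                        cons_start=min(cons_starts) if cons_starts else None,
                        cons_end=max(cons_ends) if cons_ends else None,
                        score=max(f.score for f in g),
                        divergence=sum(f.divergence * f.length for f in g) / sum(f.length for f in g),
                    )
                )

        # absorb CT-run annotations inside SINEC intervals; drop merged-away simples
        sinec_ivals = [(m.start, m.end) for m in merged_elements if _is_sinec(m)]
        for o in others:
            if id(o) in consumed_simple:
                continue
            if o.repeat_name in _CT_NAMES and any(
                s <= o.start and o.end <= e for s, e in sinec_ivals
            ):
                continue
            out.append(o)
        out.extend(merged_elements)

    return AnnotationSet(out)


# ---------------------------------------------------------------------------
# Library annotator
# ---------------------------------------------------------------------------

def _extend_exact(seq: str, cons: str, qs: int, qe: int, cs: int, ce: int) -> Tuple[int, int, int, int]:
    while qs > 0 and cs > 0 and seq[qs - 1] == cons[cs - 1]:
        qs -= 1
        cs -= 1
    while qe < len(seq) and ce < len(cons) and seq[qe] == cons[ce]:
        qe += 1
        ce += 1
    return qs, qe, cs, ce


class LibraryAnnotator:
    """Consensus-library annotator with a precomputed k-mer index.

    ``library`` is either a mapping ``name -> (consensus, repeat_class)`` or
    an object exposing ``consensi()`` returning such a mapping (e.g. a
    :class:`~canisv.synthetic_data.RepeatLibrary`).  Query k-mers anchor
    candidate hits on both strands of every consensus; anchor clusters are
    refined by edit-distance alignment and reported when identity reaches
    ``min_identity``.  Overlapping hits are resolved best-score-first.
    """

    def __init__(
        self,
        library: Union[Mapping[str, Tuple[str, str]], object],
        min_identity: float = 0.8,
        k: int = 16,
        max_kmer_mult: int = 16,
    ):
        if hasattr(library, "consensi"):
            consensi = library.consensi()
        else:
            consensi = dict(library)
        self.min_identity = min_identity
        self.k = k
        self.oriented: Dict[Tuple[str, str], str] = {}
        self.classes: Dict[str, str] = {}
        self.cons_len: Dict[str, int] = {}
        index: Dict[str, List[Tuple[str, str, int]]] = defaultdict(list)
        for name, (cons, rclass) in consensi.items():
            cons = cons.upper()
            self.classes[name] = rclass
            self.cons_len[name] = len(cons)
            for strand, oriented in (("+", cons), ("-", revcomp(cons))):
                self.oriented[(name, strand)] = oriented
                for i in range(max(0, len(oriented) - k + 1)):
                    index[oriented[i : i + k]].append((name, strand, i))
        self.index = {
            kmer: entries for kmer, entries in index.items() if len(entries) <= max_kmer_mult
        }

    def annotate(self, seq: str) -> AnnotationSet:
        seq = seq.upper()
        k = self.k
        anchors: Dict[Tuple[str, str], List[Tuple[int, int]]] = defaultdict(list)
        for i in range(len(seq) - k + 1):
            for name, strand, p in self.index.get(seq[i : i + k], ()):
                anchors[(name, strand)].append((i, p))
        hits: List[Tuple[float, int, int, str, str, str, int, int]] = []
        for (name, strand), pairs in anchors.items():
            oriented = self.oriented[(name, strand)]
            pairs.sort(key=lambda a: (a[0] - a[1], a[0]))
            clusters: List[List[Tuple[int, int]]] = [[pairs[0]]]
            for a in pairs[1:]:
                prev = clusters[-1][-1]
                if abs((a[0] - a[1]) - (prev[0] - prev[1])) <= 32 and abs(a[0] - prev[0]) <= 250:
                    clusters[-1].append(a)
                else:
                    clusters.append([a])
            for cl in clusters:
                if len(cl) < 2:
                    continue
                qs = min(a[0] for a in cl)
                qe = max(a[0] for a in cl) + k
                cs = min(a[1] for a in cl)
                ce = max(a[1] for a in cl) + k
                qs, qe, cs, ce = _extend_exact(seq, oriented, qs, qe, cs, ce)
                res = edlib.align(seq[qs:qe], oriented[cs:ce], mode="NW", task="distance")
                dist = res["editDistance"]
                span = max(qe - qs, ce - cs)
                identity = 1.0 - dist / span if span else 0.0
                if identity < self.min_identity:
                    continue
                score = (qe - qs) - 2 * dist
                cons_total = self.cons_len[name]
                if strand == "+":
                    cons_start, cons_end = cs, ce
                else:
                    cons_start, cons_end = cons_total - ce, cons_total - cs
                hits.append((score, qs, qe, name, self.classes[name], strand, cons_start, cons_end))
        return _resolve_hits(hits)


def annotate_with_library(
    seq: str,
    library: Union[Mapping[str, Tuple[str, str]], object],
    min_identity: float = 0.8,
    k: int = 16,
    max_kmer_mult: int = 16,
) -> AnnotationSet:
    """One-shot convenience wrapper around :class:`LibraryAnnotator`."""
    return LibraryAnnotator(library, min_identity, k, max_kmer_mult).annotate(seq)


def _resolve_hits(hits: List[Tuple[float, int, int, str, str, str, int, int]]) -> AnnotationSet:
    hits.sort(key=lambda h: (-h[0], h[1]))
    accepted: List[Tuple[float, int, int, str, str, str, int, int]] = []
    occupied: List[Tuple[int, int]] = []
    for h in hits:
        _, qs, qe, *_ = h
        overlap = sum(max(0, min(qe, e) - max(qs, s)) for s, e in occupied)
        if overlap > 0.5 * (qe - qs):
            continue
        accepted.append(h)
        occupied.append((qs, qe))

    # assign element ids: collinear same-consensus same-strand hits share one
    accepted.sort(key=lambda h: h[1])
    annotations: List[RepeatAnnotation] = []
    next_id = 1
    last_by_key: Dict[Tuple[str, str], Tuple[int, int]] = {}
    for score, qs, qe, name, rclass, strand, cs, ce in accepted:
        key = (name, strand)
        eid = None
        if key in last_by_key:
            prev_id, prev_ce = last_by_key[key]
            collinear = cs >= prev_ce - 30 if strand == "+" else True
            if collinear and strand == "+":
                eid = prev_id
        if eid is None:
            eid = next_id
            next_id += 1
        last_by_key[key] = (eid, ce)
        annotations.append(
            RepeatAnnotation(
                seq_id="query",
                start=qs,
                end=qe,
                repeat_name=name,
                repeat_class=rclass,
                strand=strand,
                element_id=eid,
                cons_start=cs,
                cons_end=ce,
                score=float(score),
            )
        )
    return AnnotationSet(annotations)
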