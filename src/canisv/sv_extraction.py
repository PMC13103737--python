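"""Extraction of insertion/deletion SV loci from the pangenome VCF.

Three filters, applied in order, turn VCF sites into the analyzable locus
set: (i) any missing genotype among the analyzed haplotypes removes the
site, (ii) sites not variable among the analyzed samples are removed,
(iii) sites where the longest and shortest allele carried by analyzed
haplotypes differ by less than ``min_size_diff`` (50 bp) are removed.  A
site failing several filters is attributed to the first, so the counts
partition the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .io_formats import MISSING, VariantSet

HapKey = Tuple[str, int]


@dataclass
class SVLocus:
    """A retained insertion/deletion locus.

    ``alleles`` lists only the alleles actually carried by analyzed
    haplotypes (reference-only alleles are dropped); the VCF anchor base is
    retained, so the empty site is exactly 1 bp.
    """

    chrom: str
    pos: int
    alleles: List[str]
    hap_allele: Dict[HapKey, int]
    longest_allele_index: int
    max_size_diff: int
    locus_id: Optional[str] = None
    classification: Optional[object] = None  # filled by sv_classification

    @property
    def n_haplotypes(self) -> int:
        return len(self.hap_allele)


def extract_sv_loci(
    variants: VariantSet,
    samples: Sequence[str],
    min_size_diff: int = 50,
) -> Tuple[List[SVLocus], Dict[str, int]]:
    """Apply the three locus filters and build :class:`SVLocus` objects.

    Returns the retained loci and a filter-attrition count dict whose
    values partition the input site count.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample list")
    if variants.reference_sample in samples:
        raise ValueError("reference sample must be excluded from analyzed samples")
    counts = {"input": 0, "missing_genotype": 0, "not_variable": 0, "size_diff": 0, "retained": 0}
    loci: List[SVLocus] = []
    spans: List[Tuple[str, int, int]] = []
    hap_keys = [(s, h) for s in samples for h in (1, 2)]
    for rec in variants:
        counts["input"] += 1
        assigned = [rec.allele_of.get(k, MISSING) for k in hap_keys]
        if any(a is MISSING for a in assigned):
            counts["missing_genotype"] += 1
            continue
        carried = sorted(set(assigned))
        if len(carried) < 2:
            counts["not_variable"] += 1
            continue
        all_alleles = rec.alleles
        lengths = [len(all_alleles[i]) for i in carried]
        size_diff = max(lengths) - min(lengths)
        if size_diff < min_size_diff:
            counts["size_diff"] += 1
            continue
        counts["retained"] += 1
        ref_len = len(all_alleles[0])
        spans.append((rec.chrom, rec.pos, rec.pos + ref_len))
        remap = {old: new for new, old in enumerate(carried)}
        alleles = [all_alleles[i] for i in carried]
        hap_allele = {k: remap[a] for k, a in zip(hap_keys, assigned)}
        longest = max(range(len(alleles)), key=lambda i: (len(alleles[i]), -i))
        loci.append(
            SVLocus(
                chrom=rec.chrom,
                pos=rec.pos,
                alleles=alleles,
                hap_allele=hap_allele,
                longest_allele_index=longest,
                max_size_diff=size_diff,
                locus_id=rec.record_id,
            )
        )
    # retained loci whose reference footprints overlap (records are treated
    # independently; the count documents how often that assumption is stressed)
    spans.sort()
    overlapping = sum(
        1
        for (c0, _s0, e0), (c1, s1, _e1) in zip(spans, spans[1:])
        if c0 == c1 and s1 < e0
    )
    counts["overlapping_retained"] = overlapping
    return loci, counts


def longest_allele(locus: SVLocus) -> str:
    """The maximum-length allele carried by an analyzed haplotype.

    Ties break to the lower allele index.  The returned sequence still
    carries the 1 bp VCF anchor base; strip it with :func:`allele_body`
    before composition analysis.
    """
    return locus.alleles[locus.longest_allele_index]


def allele_body(allele: str) -> str:
    """Strip the 1 bp VCF anchor base from an allele sequence."""
    return allele[1:]
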